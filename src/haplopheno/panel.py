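"""Domain containers and readers/writers for the formats the pipeline touches.

Conventions
-----------
* VCF and phenotype files carry 1-based positions; every internal interval
  (gene spans, coding intervals, region queries) is half-open 0-based.
  Conversion happens only at the I/O boundary.
* Genotype calls are unphased diploid states; phased separators ("|") are
  treated as unphased.  Multi-allelic records and indels are excluded on
  read by default (``strict=True`` turns exclusion into an error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("haplopheno")

VALID_BASES = frozenset("ACGT")
CONDITIONS = ("NONSTRESS", "STRESS")


class PanelFormatError(ValueError):
    """Malformed input file (header, column, or record level)."""


class ValidationError(ValueError):
    """Structurally valid file with semantically invalid content."""


class Call(IntEnum):
    """Diploid genotype state at a biallelic SNP."""

    MISSING = -1
    REF_HOM = 0
    HET = 1
    ALT_HOM = 2


@dataclass(frozen=True, order=True)
class Locus:
    """A biallelic SNP site. ``pos`` is 1-based as printed in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValidationError(
                f"locus {self.chrom}:{self.pos} alleles must be single bases, "
                f"got {self.ref!r}/{self.alt!r}"
            )
        if self.pos < 1:
            raise ValidationError(f"locus position must be 1-based positive, got {self.pos}")

    @property
    def snp_id(self) -> str:
        return f"S{self.chrom}_{self.pos}"


@dataclass
class GenotypePanel:
    """N accessions x M biallelic SNP loci with call states in {-1, 0, 1, 2}.

    ``calls[i, j]`` is the :class:`Call` of accession *i* at locus *j*.
    ``depths`` optionally carries per-call read depth (same shape, -1 unknown).
    """

    accession_ids: list[str]
    loci: list[Locus]
    calls: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValidationError("accession ids must be unique")
        if len(self.accession_ids) < 1:
            raise ValidationError("panel needs at least one accession")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.accession_ids), len(self.loci)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValidationError("calls contain states outside {MISSING, REF_HOM, HET, ALT_HOM}")
        keys = [(l.chrom, l.pos) for l in self.loci]
        if keys != sorted(keys):
            raise ValidationError("loci must be sorted by (chromosome, position)")
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate loci (same chromosome and position)")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int32)
            if self.depths.shape != self.calls.shape:
                raise ValidationError("depth matrix shape does not match calls")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def snp_ids(self) -> list[str]:
        return [l.snp_id for l in self.loci]

    def subset_loci(self, indices: Sequence[int]) -> "GenotypePanel":
        idx = list(indices)
        return GenotypePanel(
            accession_ids=list(self.accession_ids),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            depths=None if self.depths is None else self.depths[:, idx].copy(),
        )

    def subset_accessions(self, names: Sequence[str]) -> "GenotypePanel":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise ValidationError(f"accessions not in panel: {missing[:5]}")
        idx = [pos[n] for n in names]
        return GenotypePanel(
            accession_ids=list(names),
            loci=list(self.loci),
            calls=self.calls[idx, :].copy(),
            depths=None if self.depths is None else self.depths[idx, :].copy(),
        )

    def loci_in_interval(self, chrom: str, start0: int, end0: int) -> list[int]:
        """Indices of loci inside a half-open 0-based interval."""
        return [
            j
            for j, l in enumerate(self.loci)
            if l.chrom == chrom and start0 <= l.pos - 1 < end0
        ]

    def dosage(self, impute: bool = True) -> np.ndarray:
        """Alt-allele dosage matrix (0/1/2); missing as NaN or column mean."""
        d = self.calls.astype(float)
        d[self.calls == Call.MISSING] = np.nan
        if impute:
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            nan_r, nan_c = np.where(np.isnan(d))
            d[nan_r, nan_c] = col_mean[nan_c]
        return d


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {Call.REF_HOM: "0/0", Call.HET: "0/1", Call.ALT_HOM: "1/1", Call.MISSING: "./."}


def read_vcf(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    strict: bool = False,
    with_depth: bool = False,
) -> GenotypePanel:
    """Read a VCF v4.x into a :class:`GenotypePanel`.

    GT mapping: 0/0 -> REF_HOM, 1/1 -> ALT_HOM, 0/1 or 1/0 -> HET,
    ./. -> MISSING.  Non-SNP and multi-allelic records are skipped with a
    logged count, or raise when ``strict``.

    Parameters
    ----------
    region : (chrom, start0, end0), half-open 0-based; only loci inside are kept.
    with_depth : also collect FORMAT/DP into ``panel.depths``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise PanelFormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    if not samples:
        raise PanelFormatError(f"{path} has no sample columns")

    records: list[tuple[Locus, np.ndarray, np.ndarray | None]] = []
    n_skipped = 0
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1 \
                or v.REF not in VALID_BASES or alts[0] not in VALID_BASES:
            if strict:
                raise PanelFormatError(
                    f"non-biallelic-SNP record at {v.CHROM}:{v.POS} (REF={v.REF}, ALT={alts})"
                )
            n_skipped += 1
            continue
        if region is not None:
            chrom, start0, end0 = region
            if v.CHROM != chrom or not (start0 <= v.POS - 1 < end0):
                continue
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(v.gt_types)
        calls = np.full(len(samples), Call.MISSING, dtype=np.int8)
        calls[gt == 0] = Call.REF_HOM
        calls[gt == 1] = Call.HET
        calls[gt == 3] = Call.ALT_HOM
        dp = None
        if with_depth:
            raw = v.format("DP")
            dp = (
                np.full(len(samples), -1, dtype=np.int32)
                if raw is None
                else np.asarray(raw).reshape(-1).astype(np.int32)
            )
        records.append((Locus(v.CHROM, v.POS, v.REF, alts[0]), calls, dp))
    if n_skipped:
        log.info("read_vcf: skipped %d non-SNP/multi-allelic records in %s", n_skipped, path)

    records.sort(key=lambda r: (r[0].chrom, r[0].pos))
    loci = [r[0] for r in records]
    calls = (
        np.stack([r[1] for r in records], axis=1)
        if records
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depths = None
    if with_depth:
        depths = (
            np.stack([r[2] for r in records], axis=1)
            if records
            else np.zeros((len(samples), 0), dtype=np.int32)
        )
    return GenotypePanel(accession_ids=samples, loci=loci, calls=calls, depths=depths)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT (and DP when depths are present)."""
    path = Path(path)
    has_dp = panel.depths is not None
    chroms = []
    for l in panel.loci:
        if l.chrom not in chroms:
            chroms.append(l.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplopheno\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.accession_ids)
            + "\n"
        )
        fmt = "GT:DP" if has_dp else "GT"
        for j, l in enumerate(panel.loci):
            cells = []
            for i in range(panel.n_accessions):
                gt = _GT_STRINGS[Call(panel.calls[i, j])]
                if has_dp:
                    gt = f"{gt}:{int(panel.depths[i, j])}"
                cells.append(gt)
            fh.write(
                f"{l.chrom}\t{l.pos}\t{l.snp_id}\t{l.ref}\t{l.alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with optional coding sub-intervals (all half-open 0-based)."""

    gene_id: str
    locus_id: str
    chrom: str
    start: int
    end: int
    coding_intervals: tuple[tuple[int, int], ...] = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"{self.gene_id}: bad span [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        prev_end = None
        for s, e in self.coding_intervals:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(f"{self.gene_id}: coding interval [{s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.gene_id}: coding intervals overlap or are unsorted")
            prev_end = e


def read_gene_models(bed_path: str | Path, coding_path: str | Path | None = None) -> list[GeneModel]:
    """Read gene spans from a 6-column BED (name = ``gene_id|locus_id``) plus an
    optional sidecar TSV of coding intervals (gene_id, start, end)."""
    coding: dict[str, list[tuple[int, int]]] = {}
    if coding_path is not None:
        for line in Path(coding_path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            gid, s, e = line.split("\t")[:3]
            coding.setdefault(gid, []).append((int(s), int(e)))
    genes = []
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise PanelFormatError(f"BED line needs >= 4 columns: {line!r}")
        chrom, start, end, name = parts[:4]
        strand = parts[5] if len(parts) >= 6 else "+"
        gene_id, _, locus_id = name.partition("|")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                locus_id=locus_id or gene_id,
                chrom=chrom,
                start=int(start),
                end=int(end),
                coding_intervals=tuple(sorted(coding.get(gene_id, []))),
                strand=strand,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], bed_path: str | Path, coding_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}|{g.locus_id}\t0\t{g.strand}\n")
    with open(coding_path, "w") as fh:
        for g in genes:
            for s, e in g.coding_intervals:
                fh.write(f"{g.gene_id}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

PHENO_COLUMNS = ["accession_id", "season", "condition", "block", "replicate", "spy_grams"]


@dataclass
class PhenotypeTable:
    """Plot-level single-plant-yield records.

    One row per (accession, season, condition, replicate); ``spy_grams`` is the
    grain yield of a single plant in grams (non-negative).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.df.columns]
        if missing:
            raise PanelFormatError(f"phenotype table missing columns: {missing}")
        self.df = self.df[PHENO_COLUMNS].copy()
        self.df["replicate"] = self.df["replicate"].astype(int)
        self.df["spy_grams"] = self.df["spy_grams"].astype(float)
        for col in ("accession_id", "season", "condition", "block"):
            self.df[col] = self.df[col].astype(str)
        bad_cond = sorted(set(self.df["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValidationError(f"unknown condition tokens: {bad_cond}")
        neg = self.df.index[self.df["spy_grams"] < 0].tolist()
        if neg:
            raise ValidationError(f"negative spy_grams at rows {neg[:5]}")
        key = ["accession_id", "season", "condition", "replicate"]
        dup = self.df[self.df.duplicated(key, keep=False)]
        if len(dup):
            offenders = dup[key].drop_duplicates().head(5).to_dict("records")
            raise ValidationError(f"duplicate plot keys: {offenders}")

    @property
    def accessions(self) -> list[str]:
        return sorted(self.df["accession_id"].unique())

    def subset(self, season: str | None = None, condition: str | None = None) -> pd.DataFrame:
        df = self.df
        if season is not None:
            df = df[df["season"] == season]
        if condition is not None:
            df = df[df["condition"] == condition]
        return df


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise PanelFormatError(f"cannot parse phenotype CSV {path}: {exc}") from exc
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Q matrix (ADMIXTURE ancestry proportions)
# ---------------------------------------------------------------------------


@dataclass
class QMatrix:
    """ADMIXTURE-style ancestry proportions; rows sum to 1."""

    accession_ids: list[str]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2 or self.proportions.shape[0] != len(self.accession_ids):
            raise ValidationError("Q matrix shape does not match accession list")
        if self.proportions.shape[1] < 1:
            raise ValidationError("Q matrix needs K >= 1 columns")
        if (self.proportions < 0).any():
            raise ValidationError("Q matrix has negative proportions")
        sums = self.proportions.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValidationError("Q matrix rows must sum to 1 within 1e-6")

    @property
    def k(self) -> int:
        return self.proportions.shape[1]

    def covariate_design(self) -> np.ndarray:
        """Q columns minus the last one, for identifiable regression designs."""
        return self.proportions[:, :-1].copy()


def read_q_matrix(path: str | Path, accession_ids: Sequence[str]) -> QMatrix:
    """Read a whitespace-delimited .Q file whose row order matches ``accession_ids``."""
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape[0] != len(accession_ids):
        raise ValidationError(
            f"Q matrix has {raw.shape[0]} rows but {len(accession_ids)} accessions were supplied"
        )
    sums = raw.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-3)[0]
    if bad.size:
        raise ValidationError(f"Q rows deviate from sum 1 by > 1e-3 at rows {bad[:5].tolist()}")
    raw = raw / sums[:, None]  # exact renormalization after the tolerance check
    return QMatrix(accession_ids=list(accession_ids), proportions=raw)


def write_q_matrix(q: QMatrix, path: str | Path) -> None:
    np.savetxt(path, q.proportions, fmt="%.12f")


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV: accession_id <tab> subpopulation."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        acc, lab = line.split("\t")[:2]
        out[acc] = lab
    return out


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc in labels:
            fh.write(f"{acc}\t{labels[acc]}\n")
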