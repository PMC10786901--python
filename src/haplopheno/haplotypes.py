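"""Per-gene haplotype catalogues from a genotype panel.

A gene's haplotype is the string of SNP alleles (forward genome strand) an
accession carries across the gene's catalogued loci.  Only fully homozygous
accessions contribute a string; heterozygous or missing calls disqualify an
accession for that gene under the default policy, mirroring common practice
in gene-haplotype surveys of inbred crop panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Call, GeneModel, GenotypePanel, Locus, ValidationError

REGION_MODES = ("CODING", "FULL_GENE", "FLANKED")
HET_POLICIES = ("EXCLUDE_ACCESSION", "SITE_DROP")


@dataclass
class Haplotype:
    """One distinct allele string with its carriers and in-panel frequency."""

    hap_id: str
    alleles: str
    carriers: list[str]
    frequency_pct: float
    below_min_carriers: bool = False

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass
class HaplotypeCatalog:
    """All distinct haplotypes of one gene, ranked by carrier count.

    ``excluded`` maps accession -> reason ("HET" or "MISSING").  Frequencies
    are percentages of the assigned (non-excluded) accessions and sum to 100.
    """

    gene_id: str
    loci: list[Locus]
    haplotypes: list[Haplotype]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return sum(h.n_carriers for h in self.haplotypes)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def by_id(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)

    def by_alleles(self, alleles: str) -> Haplotype | None:
        for h in self.haplotypes:
            if h.alleles == alleles:
                return h
        return None

    def carrier_map(self) -> dict[str, str]:
        """accession -> hap_id over all assigned accessions."""
        return {a: h.hap_id for h in self.haplotypes for a in h.carriers}


def extract_gene_snps(
    panel: GenotypePanel,
    gene: GeneModel,
    region_mode: str,
    flank_bp: int = 2000,
) -> GenotypePanel:
    """Restrict a panel to the SNPs of one gene's scan region.

    ``CODING`` keeps SNPs inside the coding intervals, ``FULL_GENE`` the gene
    span, ``FLANKED`` the span padded by ``flank_bp`` on both sides.  An empty
    result is allowed.
    """
    if region_mode not in REGION_MODES:
        raise ValueError(f"region_mode must be one of {REGION_MODES}")
    if region_mode == "CODING":
        intervals = list(gene.coding_intervals)
    elif region_mode == "FULL_GENE":
        intervals = [(gene.start, gene.end)]
    else:
        intervals = [(max(0, gene.start - flank_bp), gene.end + flank_bp)]
    keep: list[int] = []
    for s, e in intervals:
        keep.extend(panel.loci_in_interval(gene.chrom, s, e))
    keep = sorted(set(keep))
    return panel.subset_loci(keep)


def build_haplotypes(
    gene_snps: GenotypePanel,
    gene_id: str = "gene",
    het_policy: str = "EXCLUDE_ACCESSION",
    min_carriers: int = 3,
    max_site_het_frac: float = 0.05,
) -> HaplotypeCatalog:
    """Group fully homozygous accessions into haplotypes over a gene's SNPs.

    Haplotypes are ranked by descending carrier count (ties broken by the
    earliest carrier's panel index) and named H1..Hn.  Haplotypes with fewer
    than ``min_carriers`` carriers stay in the catalogue but are flagged
    ``below_min_carriers`` so downstream haplo-pheno analysis skips them.

    het_policy:
      EXCLUDE_ACCESSION (default): any HET or MISSING call at a catalogued
        locus excludes the accession for this gene, with the reason recorded.
      SITE_DROP: loci with heterozygote frequency above ``max_site_het_frac``
        (among non-missing calls) are removed first; remaining het/missing
        accessions are then excluded as above.

    A gene with zero loci is monomorphic by construction: a single
    empty-string haplotype carries every accession.
    """
    if het_policy not in HET_POLICIES:
        raise ValueError(f"het_policy must be one of {HET_POLICIES}")
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")

    panel = gene_snps
    if het_policy == "SITE_DROP" and panel.n_loci:
        het = panel.calls == Call.HET
        non_missing = panel.calls != Call.MISSING
        with np.errstate(invalid="ignore"):
            het_frac = np.where(
                non_missing.sum(axis=0) > 0,
                het.sum(axis=0) / np.maximum(non_missing.sum(axis=0), 1),
                0.0,
            )
        panel = panel.subset_loci(np.where(het_frac <= max_site_het_frac)[0])

    excluded: dict[str, str] = {}
    strings: dict[str, list[str]] = {}
    first_seen: dict[str, int] = {}
    alleles = [(l.ref, l.alt) for l in panel.loci]
    for i, acc in enumerate(panel.accession_ids):
        row = panel.calls[i]
        if panel.n_loci and (row == Call.HET).any():
            excluded[acc] = "HET"
            continue
        if panel.n_loci and (row == Call.MISSING).any():
            excluded[acc] = "MISSING"
            continue
        s = "".join(ref if c == Call.REF_HOM else alt for c, (ref, alt) in zip(row, alleles))
        strings.setdefault(s, []).append(acc)
        first_seen.setdefault(s, i)

    n_assigned = sum(len(v) for v in strings.values())
    ordered = sorted(strings.items(), key=lambda kv: (-len(kv[1]), first_seen[kv[0]]))
    haplotypes = [
        Haplotype(
            hap_id=f"H{rank}",
            alleles=s,
            carriers=carriers,
            frequency_pct=100.0 * len(carriers) / n_assigned if n_assigned else float("nan"),
            below_min_carriers=len(carriers) < min_carriers,
        )
        for rank, (s, carriers) in enumerate(ordered, start=1)
    ]
    return HaplotypeCatalog(
        gene_id=gene_id, loci=list(panel.loci), haplotypes=haplotypes, excluded=excluded
    )


def haplotype_frequency(catalog: HaplotypeCatalog) -> list[tuple[str, float]]:
    """(hap_id, frequency_pct) pairs; frequencies are over assigned accessions."""
    if catalog.n_assigned == 0:
        raise ValidationError(f"{catalog.gene_id}: no assigned accessions, frequencies undefined")
    return [(h.hap_id, h.frequency_pct) for h in catalog.haplotypes]


def subpop_distribution(
    catalog: HaplotypeCatalog, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Carrier counts per haplotype x subpopulation.

    Row sums equal carrier counts; every carrier must be labelled.
    """
    unlabeled = [a for h in catalog.haplotypes for a in h.carriers if a not in labels]
    if unlabeled:
        raise ValidationError(f"carriers without subpopulation label: {unlabeled[:5]}")
    subpops = sorted({labels[a] for h in catalog.haplotypes for a in h.carriers})
    table = pd.DataFrame(
        0, index=[h.hap_id for h in catalog.haplotypes], columns=subpops, dtype=int
    )
    for h in catalog.haplotypes:
        for a in h.carriers:
            table.loc[h.hap_id, labels[a]] += 1
    table.index.name = "hap_id"
    return table


@dataclass
class HaploDiversitySummary:
    """Per-gene haplotype counts and extreme frequencies, with the panel-wide range."""

    per_gene: pd.DataFrame  # gene_id, n_haplotypes, major_hap_frequency, minor_hap_frequency
    hap_count_range: tuple[int, int]


def diversity_summary(catalogs: Sequence[HaplotypeCatalog]) -> HaploDiversitySummary:
    if not catalogs:
        raise ValidationError("diversity_summary needs at least one catalogue")
    rows = []
    for c in catalogs:
        freqs = [h.frequency_pct for h in c.haplotypes]
        rows.append(
            {
                "gene_id": c.gene_id,
                "n_haplotypes": c.n_haplotypes,
                "major_hap_frequency": max(freqs) if freqs else float("nan"),
                "minor_hap_frequency": min(freqs) if freqs else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    counts = df["n_haplotypes"]
    return HaploDiversitySummary(per_gene=df, hap_count_range=(int(counts.min()), int(counts.max())))


# ---------------------------------------------------------------------------
# Serialization: TSV of haplotypes + JSON sidecar of loci and exclusions
# ---------------------------------------------------------------------------


def write_catalogs(catalogs: Sequence[HaplotypeCatalog], tsv_path: str | Path, sidecar_path: str | Path) -> None:
    rows = []
    for c in catalogs:
        for h in c.haplotypes:
            rows.append(
                {
                    "gene_id": c.gene_id,
                    "hap_id": h.hap_id,
                    "allele_string": h.alleles,
                    "n_carriers": h.n_carriers,
                    "frequency_pct": f"{h.frequency_pct:.6g}",
                    "below_min_carriers": int(h.below_min_carriers),
                    "carriers": ";".join(h.carriers),
                }
            )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    sidecar = {
        c.gene_id: {
            "loci": [[l.chrom, l.pos, l.ref, l.alt] for l in c.loci],
            "excluded": c.excluded,
        }
        for c in catalogs
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_catalogs(tsv_path: str | Path, sidecar_path: str | Path) -> list[HaplotypeCatalog]:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"allele_string": str, "carriers": str})
    sidecar = json.loads(Path(sidecar_path).read_text())
    catalogs = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        meta = sidecar[gene_id]
        loci = [Locus(str(c), int(p), r, a) for c, p, r, a in meta["loci"]]
        haps = []
        for _, row in sub.iterrows():
            s = row["allele_string"]
            carriers = [] if pd.isna(row["carriers"]) or row["carriers"] == "" else row["carriers"].split(";")
            haps.append(
                Haplotype(
                    hap_id=row["hap_id"],
                    alleles="" if pd.isna(s) else str(s),
                    carriers=carriers,
                    frequency_pct=float(row["frequency_pct"]),
                    below_min_carriers=bool(row["below_min_carriers"]),
                )
            )
        catalogs.append(
            HaplotypeCatalog(gene_id=gene_id, loci=loci, haplotypes=haps, excluded=dict(meta["excluded"]))
        )
    return catalogs
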