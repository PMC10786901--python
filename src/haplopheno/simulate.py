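"""Structured diversity-panel simulator with planted haplotype effects.

The generator emulates the study system end to end: a panel of inbred
accessions drawn from K subpopulations (Balding-Nichols allele-frequency
divergence at neutral background SNPs), per-gene haplotype spectra realized
as exact carrier counts (largest-remainder rounding, so a configured
3-carrier haplotype in a 399 panel yields exactly 0.75%), and plot-level
single-plant-yield records over seasons x {non-stress, drought} with the
stress condition lowering the mean and inflating the genotypic CV.

Phenotype model per plot:

    y = condition mean + subpopulation shift + planted haplotype effects
        + polygenic value (covariance proportional to realized kinship)
        + season shift + block effect + residual,   clipped at 0 g.

Planted superior-haplotype effects act under the STRESS condition (the genes
being emulated are drought-responsive).  All randomness derives from a
single integer seed; each component draws from its own fixed-key child
stream, so adding a gene does not perturb earlier genes' draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gwas import kinship
from .panel import (
    Call,
    GeneModel,
    GenotypePanel,
    Locus,
    PhenotypeTable,
    QMatrix,
    ValidationError,
    write_gene_models,
    write_labels,
    write_phenotypes,
    write_q_matrix,
    write_vcf,
)

BASES = "ACGT"
DEFAULT_SUBPOPS = ("indica", "aus", "japonica", "basmati", "admix")


@dataclass
class CondSpec:
    """Per-condition phenotype parameters, all in grams."""

    mean_g: float
    residual_sd_g: float
    polygenic_sd_g: float
    subpop_sd_g: float


@dataclass
class GeneSpec:
    """One simulated gene: haplotype frequency spectrum and optional planted effect.

    ``hap_freqs`` must sum to 1; carrier counts are realized exactly.
    Haplotype h (h >= 1) carries the alt allele at SNP h-1 only, so every
    non-reference haplotype has a private tag SNP; the SH's tag SNP is the
    planted causal marker.  ``sh_subpops`` optionally restricts SH carriers
    to the named subpopulation indices.
    """

    gene_id: str
    chrom: str
    start: int  # half-open 0-based gene start
    hap_freqs: tuple[float, ...]
    sh_index: int | None = None
    sh_effect_g: float = 0.0
    n_snps: int | None = None
    spacing_bp: int = 150
    sh_subpops: tuple[int, ...] | None = None

    def resolved_n_snps(self) -> int:
        need = max(len(self.hap_freqs) - 1, 1)
        return max(self.n_snps or 0, need)

    def validate(self) -> None:
        total = float(sum(self.hap_freqs))
        if any(f <= 0 or f > 1 for f in self.hap_freqs):
            raise ValidationError(f"{self.gene_id}: haplotype frequencies must be in (0, 1]")
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"{self.gene_id}: haplotype frequencies sum to {total}, expected 1"
            )
        if self.sh_effect_g != 0.0:
            if self.sh_index is None or not (1 <= self.sh_index < len(self.hap_freqs)):
                raise ValidationError(
                    f"{self.gene_id}: a planted effect needs sh_index in 1..n_haps-1 "
                    "(the reference haplotype has no private tag SNP)"
                )


def default_genes(n_accessions: int = 399) -> list[GeneSpec]:
    """Five genes spanning the observed spectrum shapes: a diverse gene, a
    moderately diverse gene, a monomorphic gene, a gene with a rare
    (<1%) haplotype, and a two-haplotype gene."""
    rare = 3.0 / n_accessions
    return [
        GeneSpec("DRG01", "1", 1_200_000, (0.42, 0.28, 0.15, 0.08, 0.05, 0.02)),
        GeneSpec("DRG02", "3", 2_500_000, (0.60, 0.25, 0.10, 0.05)),
        GeneSpec("DRG03", "6", 1_400_000, (1.0,)),
        GeneSpec("DRG04", "2", 3_100_000, (0.62, 0.25, 0.13 - rare, rare)),
        GeneSpec("DRG05", "10", 1_800_000, (0.8, 0.2)),
    ]


@dataclass
class SimConfig:
    n_accessions: int = 399
    n_subpops: int = 5
    fst: float = 0.15
    genes: list[GeneSpec] = field(default_factory=default_genes)
    n_neutral_snps: int = 150
    seasons: tuple[str, ...] = ("DS2019", "DS2020")
    conditions: dict[str, CondSpec] = field(
        default_factory=lambda: {
            "NONSTRESS": CondSpec(mean_g=15.0, residual_sd_g=3.4, polygenic_sd_g=2.8, subpop_sd_g=1.5),
            "STRESS": CondSpec(mean_g=4.5, residual_sd_g=1.4, polygenic_sd_g=1.8, subpop_sd_g=0.8),
        }
    )
    replicates: int = 3
    het_rate: float = 0.02
    missing_rate: float = 0.005
    block_sd_g: float = 0.3
    season_sd_g: float = 0.2
    q_concentration: float = 40.0
    subpop_props: tuple[float, ...] = (0.35, 0.20, 0.20, 0.15, 0.10)
    subpop_names: tuple[str, ...] = DEFAULT_SUBPOPS
    stress_only_effects: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 2:
            raise ValidationError("need at least two accessions")
        if len(self.subpop_props) != self.n_subpops or len(self.subpop_names) < self.n_subpops:
            raise ValidationError("subpopulation proportions/names do not match n_subpops")
        for g in self.genes:
            g.validate()
        for c, spec in self.conditions.items():
            if min(spec.residual_sd_g, spec.polygenic_sd_g, spec.subpop_sd_g) < 0:
                raise ValidationError(f"{c}: negative standard deviation")


def planted_sh_config(
    sh_effect_g: float = 1.5,
    sh_n: int = 10,
    n_accessions: int = 399,
    residual_sd_g: float = 1.0,
    seed: int = 0,
) -> SimConfig:
    """Study-condition scenario: one gene with a planted superior haplotype.

    The SH group has ``sh_n`` carriers and a +``sh_effect_g`` yield effect
    under drought; background variance is kept small (polygenic sd 0.5 g,
    subpopulation sd 0.3 g) so the plot residual sd dominates.
    """
    f_sh = sh_n / n_accessions
    rest = 1.0 - f_sh
    freqs = tuple(rest * w for w in (0.50, 0.25, 0.15, 0.10)) + (f_sh,)
    gene = GeneSpec(
        "DRG_EFFECT", "1", 1_200_000, freqs, sh_index=4, sh_effect_g=sh_effect_g
    )
    return SimConfig(
        n_accessions=n_accessions,
        genes=[gene],
        conditions={
            "NONSTRESS": CondSpec(mean_g=15.0, residual_sd_g=2.4, polygenic_sd_g=1.2, subpop_sd_g=0.6),
            "STRESS": CondSpec(mean_g=4.5, residual_sd_g=residual_sd_g, polygenic_sd_g=0.5, subpop_sd_g=0.3),
        },
        seed=seed,
    )


@dataclass
class SimTruth:
    """Ground truth of one simulated panel; JSON round-trippable."""

    seed: int
    subpop: dict[str, str]
    genes: dict[str, dict]
    causal_snps: dict[str, str]  # gene_id -> snp_id of the planted SH tag SNP

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class SimResult:
    panel: GenotypePanel
    pheno: PhenotypeTable
    qmatrix: QMatrix
    labels: dict[str, str]
    gene_models: list[GeneModel]
    truth: SimTruth


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _largest_remainder(freqs: Sequence[float], n: int) -> list[int]:
    raw = np.asarray(freqs, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def simulate_panel(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate genotypes, phenotypes, Q matrix, labels and the truth ledger.

    With ``outdir`` set, also writes genotypes.vcf, phenotypes.csv, panel.Q,
    labels.tsv, genes.bed + genes_coding.tsv, and truth.json.  Identical
    configs (including seed) give byte-identical outputs.
    """
    config.validate()
    seed = config.seed
    n = config.n_accessions
    accessions = [f"ACC{i:04d}" for i in range(1, n + 1)]

    # subpopulation membership (deterministic counts) and softened Q matrix
    sub_counts = _largest_remainder(config.subpop_props[: config.n_subpops], n)
    subpop = np.repeat(np.arange(config.n_subpops), sub_counts)
    labels = {a: config.subpop_names[s] for a, s in zip(accessions, subpop)}
    rng_q = _rng(seed, 0)
    alpha = np.full((n, config.n_subpops), 0.5)
    alpha[np.arange(n), subpop] += config.q_concentration
    q_rows = np.vstack([rng_q.dirichlet(alpha[i]) for i in range(n)])
    qmatrix = QMatrix(accession_ids=accessions, proportions=q_rows)

    # neutral background SNPs: Balding-Nichols divergence across subpops
    rng_n = _rng(seed, 1)
    f = config.fst
    neutral_loci: list[Locus] = []
    neutral_calls = np.zeros((n, config.n_neutral_snps), dtype=np.int8)
    chroms = [str(c) for c in range(1, 13)]
    for j in range(config.n_neutral_snps):
        chrom = chroms[j % len(chroms)]
        pos = 10_000_000 + (j // len(chroms)) * 5_000 + 1
        ref, alt = rng_n.choice(list(BASES), size=2, replace=False)
        neutral_loci.append(Locus(chrom, pos, str(ref), str(alt)))
        p_anc = rng_n.uniform(0.1, 0.9)
        if f > 0:
            p_sub = rng_n.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f, size=config.n_subpops)
        else:
            p_sub = np.full(config.n_subpops, p_anc)
        p_sub = np.clip(p_sub, 1e-4, 1 - 1e-4)
        dosage = rng_n.binomial(2, p_sub[subpop])
        neutral_calls[:, j] = dosage  # 0/1/2 maps onto REF_HOM/HET/ALT_HOM

    # gene loci: exact-count haplotype assignment, then het/missing injection
    gene_loci: list[Locus] = []
    gene_calls_cols: list[np.ndarray] = []
    gene_models: list[GeneModel] = []
    truth_genes: dict[str, dict] = {}
    causal_snps: dict[str, str] = {}
    for gi, gene in enumerate(config.genes):
        rng_g = _rng(seed, 2, gi)
        m = gene.resolved_n_snps()
        loci = []
        for sj in range(m):
            ref, alt = rng_g.choice(list(BASES), size=2, replace=False)
            loci.append(Locus(gene.chrom, gene.start + 1 + sj * gene.spacing_bp, str(ref), str(alt)))
        counts = _largest_remainder(gene.hap_freqs, n)
        # haplotype h: alt allele at tag SNP h-1 (reference haplotype: none)
        hap_codes = [np.zeros(m, dtype=np.int8)]
        for h in range(1, len(counts)):
            code = np.zeros(m, dtype=np.int8)
            code[h - 1] = 2
            hap_codes.append(code)
        assignment = np.zeros(n, dtype=int)
        pool = np.arange(n)
        if gene.sh_index is not None and gene.sh_subpops is not None:
            allowed = pool[np.isin(subpop, gene.sh_subpops)]
            if len(allowed) < counts[gene.sh_index]:
                raise ValidationError(f"{gene.gene_id}: not enough accessions in sh_subpops")
            sh_members = rng_g.choice(allowed, size=counts[gene.sh_index], replace=False)
            rest = np.setdiff1d(pool, sh_members)
            rest = rng_g.permutation(rest)
            assignment[sh_members] = gene.sh_index
            cursor = 0
            for h, cnt in enumerate(counts):
                if h == gene.sh_index:
                    continue
                assignment[rest[cursor : cursor + cnt]] = h
                cursor += cnt
        else:
            perm = rng_g.permutation(pool)
            cursor = 0
            for h, cnt in enumerate(counts):
                assignment[perm[cursor : cursor + cnt]] = h
                cursor += cnt
        calls = np.vstack([hap_codes[h] for h in assignment])
        het_mask = rng_g.random(calls.shape) < config.het_rate
        calls[het_mask] = Call.HET
        miss_mask = rng_g.random(calls.shape) < config.missing_rate
        calls[miss_mask] = Call.MISSING

        gene_loci.extend(loci)
        gene_calls_cols.append(calls)
        span_end = gene.start + m * gene.spacing_bp + 100
        gene_models.append(
            GeneModel(
                gene_id=gene.gene_id,
                locus_id=f"Sim{gene.chrom}g{gi:03d}",
                chrom=gene.chrom,
                start=gene.start,
                end=span_end,
                coding_intervals=((gene.start, span_end),),
            )
        )
        alleles_per_hap = [
            "".join(l.ref if c == 0 else l.alt for c, l in zip(code, loci)) for code in hap_codes
        ]
        carriers = {
            str(h): [accessions[i] for i in np.where(assignment == h)[0]]
            for h in range(len(counts))
        }
        truth_genes[gene.gene_id] = {
            "hap_strings": alleles_per_hap,
            "counts": counts,
            "carriers": carriers,
            "sh_index": gene.sh_index,
            "sh_string": alleles_per_hap[gene.sh_index] if gene.sh_index is not None else None,
            "sh_effect_g": gene.sh_effect_g,
        }
        if gene.sh_index is not None and gene.sh_index >= 1:
            causal_snps[gene.gene_id] = loci[gene.sh_index - 1].snp_id

    # assemble the panel, sorted by (chrom, pos)
    all_loci = gene_loci + neutral_loci
    all_calls = np.hstack(gene_calls_cols + [neutral_calls]) if all_loci else np.zeros((n, 0), np.int8)
    order = sorted(range(len(all_loci)), key=lambda j: (all_loci[j].chrom, all_loci[j].pos))
    panel = GenotypePanel(
        accession_ids=accessions,
        loci=[all_loci[j] for j in order],
        calls=all_calls[:, order],
    )

    # polygenic values: covariance proportional to the realized neutral kinship
    rng_p = _rng(seed, 3)
    z = rng_p.standard_normal(n)
    if config.n_neutral_snps >= 2:
        n_order = sorted(
            range(len(neutral_loci)), key=lambda j: (neutral_loci[j].chrom, neutral_loci[j].pos)
        )
        neutral_panel = GenotypePanel(
            accessions, [neutral_loci[j] for j in n_order], neutral_calls[:, n_order]
        )
        K = kinship(neutral_panel).values
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        poly_base = L @ z
        poly_base = poly_base / max(poly_base.std(), 1e-12)
    else:
        poly_base = np.zeros(n)

    # per-accession planted haplotype effect (sum over genes, by true carrier state)
    hap_effect = np.zeros(n)
    for gene, (gene_id, tg) in zip(config.genes, truth_genes.items()):
        if gene.sh_effect_g and gene.sh_index is not None:
            idx = [accessions.index(a) for a in tg["carriers"][str(gene.sh_index)]]
            hap_effect[idx] += gene.sh_effect_g

    # phenotype records
    rng_y = _rng(seed, 4)
    cond_names = sorted(config.conditions)
    shifts = {
        c: config.conditions[c].subpop_sd_g * rng_y.standard_normal(config.n_subpops)
        for c in cond_names
    }
    season_eff = {
        (s, c): config.season_sd_g * rng_y.standard_normal()
        for s in config.seasons
        for c in cond_names
    }
    block_eff = {
        (s, c, r): config.block_sd_g * rng_y.standard_normal()
        for s in config.seasons
        for c in cond_names
        for r in range(1, config.replicates + 1)
    }
    rows = []
    for s in config.seasons:
        for c in cond_names:
            spec = config.conditions[c]
            gvalue = (
                shifts[c][subpop]
                + spec.polygenic_sd_g * poly_base
                + (hap_effect if (c == "STRESS" or not config.stress_only_effects) else 0.0)
            )
            for r in range(1, config.replicates + 1):
                resid = spec.residual_sd_g * rng_y.standard_normal(n)
                y = np.maximum(
                    spec.mean_g + gvalue + season_eff[(s, c)] + block_eff[(s, c, r)] + resid,
                    0.0,
                )
                for i, acc in enumerate(accessions):
                    rows.append((acc, s, c, f"B{r}", r, float(y[i])))
    pheno = PhenotypeTable(
        pd.DataFrame(
            rows, columns=["accession_id", "season", "condition", "block", "replicate", "spy_grams"]
        )
    )

    truth = SimTruth(seed=seed, subpop=labels, genes=truth_genes, causal_snps=causal_snps)
    result = SimResult(
        panel=panel, pheno=pheno, qmatrix=qmatrix, labels=labels,
        gene_models=gene_models, truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(panel, outdir / "genotypes.vcf")
        write_phenotypes(pheno, outdir / "phenotypes.csv")
        write_q_matrix(qmatrix, outdir / "panel.Q")
        write_labels(labels, outdir / "labels.tsv")
        write_gene_models(gene_models, outdir / "genes.bed", outdir / "genes_coding.tsv")
        truth.to_json(outdir / "truth.json")
    return result


def truth_check(
    sh_calls: Mapping[str, str | None],
    mta_hits: Sequence[str],
    truth: SimTruth,
) -> dict:
    """Compare pipeline calls against the simulation truth.

    ``sh_calls`` maps gene_id -> called SH allele string (or None); only
    genes with a planted effect are scored.  ``mta_hits`` is the list of
    significant marker ids; scored against the planted causal tag SNPs.
    """
    effect_genes = {
        g: tg for g, tg in truth.genes.items() if tg["sh_effect_g"] and tg["sh_string"]
    }
    per_gene = {}
    for g, tg in effect_genes.items():
        called = sh_calls.get(g)
        per_gene[g] = {
            "planted_sh": tg["sh_string"],
            "called_sh": called,
            "recovered": bool(called == tg["sh_string"]),
        }
    n_eff = len(effect_genes)
    hits = set(mta_hits)
    causal_found = {
        g: truth.causal_snps[g] in hits for g in effect_genes if g in truth.causal_snps
    }
    return {
        "per_gene": per_gene,
        "sh_recovery_rate": (
            sum(1 for v in per_gene.values() if v["recovered"]) / n_eff if n_eff else float("nan")
        ),
        "causal_snp_found": causal_found,
        "causal_hit_rate": (
            sum(causal_found.values()) / len(causal_found) if causal_found else float("nan")
        ),
    }
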