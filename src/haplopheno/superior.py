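"""Haplo-pheno analysis: the superior-haplotype decision procedure.

Accessions are grouped by the gene haplotype they carry; group means of the
combined stress-season BLUPs are compared with a one-way ANOVA and Duncan's
multiple range test; the highest-mean group is declared the superior
haplotype (SH) when it is significantly separated from other groups.

Two calling policies are offered.  TOP_SEPARATED (default) requires the top
group to be significantly higher than at least one other group, i.e. to
share no letter with some other group — the practice seen in published
haplo-pheno tables, where an SH may still share a letter with the runner-up.
STRICT requires the top group to share no letter with any other group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dmrt import DmrtResult, dmrt
from .haplotypes import HaplotypeCatalog
from .panel import ValidationError

log = logging.getLogger("haplopheno")

SH_POLICIES = ("TOP_SEPARATED", "STRICT")


@dataclass
class HaploGroup:
    hap_id: str
    members: list[str]
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.n > 1 else 0.0


@dataclass
class HaploGroupTable:
    """Haplotype groups of one gene that qualify for mean comparison."""

    gene_id: str
    groups: list[HaploGroup]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (hap_id, reason)

    @property
    def testable(self) -> bool:
        return len(self.groups) >= 2

    def group(self, hap_id: str) -> HaploGroup:
        for g in self.groups:
            if g.hap_id == hap_id:
                return g
        raise KeyError(hap_id)


@dataclass
class HaploPhenoResult:
    gene_id: str
    dmrt: DmrtResult | None
    superior_haplotype: str | None
    policy: str

    @property
    def letters(self) -> dict[str, str]:
        return {} if self.dmrt is None else self.dmrt.letters


def group_by_haplotype(
    catalog: HaplotypeCatalog, blups: pd.Series, min_n: int = 3
) -> HaploGroupTable:
    """Join a haplotype catalogue with accession BLUPs into phenotype groups.

    Haplotypes flagged below the carrier threshold at catalogue build, and
    groups with fewer than ``min_n`` members holding a BLUP, are dropped with
    reason SMALL_N.  A gene with fewer than two surviving groups is marked
    untestable rather than raising.
    """
    groups: list[HaploGroup] = []
    dropped: list[tuple[str, str]] = []
    have = set(blups.index)
    for h in catalog.haplotypes:
        members = [a for a in h.carriers if a in have]
        missing = h.n_carriers - len(members)
        if missing:
            log.debug("%s %s: %d carriers without BLUPs", catalog.gene_id, h.hap_id, missing)
        if h.below_min_carriers or len(members) < min_n:
            dropped.append((h.hap_id, "SMALL_N"))
            continue
        groups.append(
            HaploGroup(hap_id=h.hap_id, members=members, values=blups.loc[members].to_numpy(float))
        )
    return HaploGroupTable(gene_id=catalog.gene_id, groups=groups, dropped=dropped)


def compare_group_means(table: HaploGroupTable, alpha: float = 0.05) -> DmrtResult:
    """One-way ANOVA + Duncan letters over a gene's haplotype groups."""
    if not table.testable:
        raise ValidationError(f"{table.gene_id}: fewer than two testable haplotype groups")
    return dmrt([(g.hap_id, g.values) for g in table.groups], alpha=alpha)


def call_superior_haplotype(result: DmrtResult, policy: str = "TOP_SEPARATED") -> str | None:
    """Designate the superior haplotype from DMRT letters, or None.

    The candidate is the highest-mean group (ties broken by group name).
    TOP_SEPARATED calls it superior when it shares no letter with at least
    one other group; STRICT when it shares no letter with any other group.
    """
    if policy not in SH_POLICIES:
        raise ValueError(f"policy must be one of {SH_POLICIES}")
    names = sorted(result.means, key=lambda g: (-result.means[g], g))
    top, others = names[0], names[1:]
    if not others:
        return None
    separated = [g for g in others if not result.share_letter(top, g)]
    if policy == "STRICT":
        return top if len(separated) == len(others) else None
    return top if separated else None


def analyze_gene(
    catalog: HaplotypeCatalog,
    blups: pd.Series,
    min_n: int = 3,
    alpha: float = 0.05,
    policy: str = "TOP_SEPARATED",
) -> tuple[HaploGroupTable, HaploPhenoResult]:
    """Full haplo-pheno pass for one gene: group, test, call."""
    table = group_by_haplotype(catalog, blups, min_n=min_n)
    if not table.testable:
        return table, HaploPhenoResult(catalog.gene_id, None, None, policy)
    result = compare_group_means(table, alpha=alpha)
    sh = call_superior_haplotype(result, policy=policy)
    return table, HaploPhenoResult(catalog.gene_id, result, sh, policy)


def yield_advantage(table: HaploGroupTable, sh: str) -> pd.DataFrame:
    """Percent yield advantage of the SH group over each comparison basis.

    Bases are every other group's mean and the pooled mean of all non-SH
    values; non-positive bases are skipped with a warning.
    """
    sh_mean = table.group(sh).mean
    rows = []
    pooled = np.concatenate([g.values for g in table.groups if g.hap_id != sh])
    bases: list[tuple[str, float]] = [
        (g.hap_id, g.mean) for g in table.groups if g.hap_id != sh
    ] + [("pooled_non_SH", float(pooled.mean()))]
    for name, m in bases:
        if m <= 0:
            log.warning("%s: skipping non-positive comparison basis %s", table.gene_id, name)
            continue
        rows.append(
            {"basis": name, "basis_mean": m, "advantage_pct": 100.0 * (sh_mean - m) / m}
        )
    return pd.DataFrame(rows)


def find_donors(table: HaploGroupTable, sh: str, k: int = 3) -> list[tuple[str, float]]:
    """Top-k SH-group accessions by BLUP (descending; ties by accession id)."""
    g = table.group(sh)
    pairs = sorted(zip(g.members, g.values), key=lambda p: (-p[1], p[0]))
    return [(a, float(v)) for a, v in pairs[:k]]


def sh_combinations(
    catalogs: Sequence[HaplotypeCatalog], sh_alleles: Mapping[str, str]
) -> pd.DataFrame:
    """Per accession, the set of genes whose superior-haplotype string it carries.

    ``sh_alleles`` maps gene_id -> SH allele string (cross-referencing is by
    allele string so catalogues from different panels can be compared).
    Returns a DataFrame (accession_id, genes, n_genes) sorted so accessions
    carrying the most SH genes come first.
    """
    hits: dict[str, set[str]] = {}
    for cat in catalogs:
        allele = sh_alleles.get(cat.gene_id)
        if allele is None:
            continue
        hap = cat.by_alleles(allele)
        if hap is None:
            continue
        for acc in hap.carriers:
            hits.setdefault(acc, set()).add(cat.gene_id)
    rows = [
        {"accession_id": acc, "genes": ";".join(sorted(genes)), "n_genes": len(genes)}
        for acc, genes in hits.items()
    ]
    df = pd.DataFrame(rows, columns=["accession_id", "genes", "n_genes"])
    return df.sort_values(["n_genes", "accession_id"], ascending=[False, True]).reset_index(drop=True)
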