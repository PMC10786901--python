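"""Haplotype assignment for re-sequenced validation varieties.

Newly sequenced varieties are genotyped at a reference catalogue's loci,
filtered on per-call depth and per-locus call rate, and matched exactly
against the catalogue's allele strings.  A string absent from the catalogue
is NOVEL — information, not an error: validation panels routinely carry
haplotypes unseen in the discovery panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeCatalog
from .panel import Call, GenotypePanel, ValidationError

SIFT_DAMAGING_BELOW = 0.05


@dataclass
class HaplotypeAssignment:
    """Outcome of matching one variety against one gene catalogue."""

    variety: str
    gene_id: str
    status: str  # hap_id | "NOVEL" | "UNASSIGNED"
    allele_string: str | None = None
    missing_loci: list[str] | None = None
    reason: str | None = None

    @property
    def assigned(self) -> bool:
        return self.status not in ("NOVEL", "UNASSIGNED")


def filter_variants(
    panel: GenotypePanel,
    depths: np.ndarray | None = None,
    min_depth: int = 10,
    min_call_rate: float = 0.90,
) -> GenotypePanel:
    """Apply depth and call-rate filters.

    Calls with depth below ``min_depth`` become MISSING; loci whose call rate
    (fraction of non-missing calls) then falls below ``min_call_rate`` are
    removed.  ``depths`` defaults to the panel's own depth matrix.  The
    operation is idempotent.
    """
    if depths is None:
        depths = panel.depths
    calls = panel.calls.copy()
    if depths is not None:
        depths = np.asarray(depths)
        if depths.shape != calls.shape:
            raise ValidationError(
                f"depth matrix shape {depths.shape} does not match calls {calls.shape}"
            )
        calls[depths < min_depth] = Call.MISSING
    call_rate = (calls != Call.MISSING).mean(axis=0) if calls.shape[1] else np.empty(0)
    keep = np.where(call_rate >= min_call_rate)[0]
    filtered = GenotypePanel(
        accession_ids=list(panel.accession_ids),
        loci=[panel.loci[j] for j in keep],
        calls=calls[:, keep],
        depths=None if depths is None else np.asarray(depths)[:, keep],
    )
    return filtered


def assign_haplotype(
    variety_panel: GenotypePanel, variety: str, catalog: HaplotypeCatalog
) -> HaplotypeAssignment:
    """Match one variety's homozygous allele string against a gene catalogue.

    The variety must be genotyped at every catalogue locus; missing loci give
    UNASSIGNED with the missing loci listed, a heterozygous call gives
    UNASSIGNED with reason HET.  An exact string hit returns the haplotype's
    id; a miss returns NOVEL with the observed string.
    """
    i = variety_panel.accession_ids.index(variety)
    locus_index = {(l.chrom, l.pos): j for j, l in enumerate(variety_panel.loci)}
    alleles: list[str] = []
    missing: list[str] = []
    for l in catalog.loci:
        j = locus_index.get((l.chrom, l.pos))
        call = Call.MISSING if j is None else Call(variety_panel.calls[i, j])
        if call == Call.HET:
            return HaplotypeAssignment(variety, catalog.gene_id, "UNASSIGNED", reason="HET")
        if call == Call.MISSING:
            missing.append(l.snp_id)
            continue
        alleles.append(l.ref if call == Call.REF_HOM else l.alt)
    if missing:
        return HaplotypeAssignment(
            variety, catalog.gene_id, "UNASSIGNED", missing_loci=missing, reason="MISSING"
        )
    s = "".join(alleles)
    hit = catalog.by_alleles(s)
    if hit is None:
        return HaplotypeAssignment(variety, catalog.gene_id, "NOVEL", allele_string=s)
    return HaplotypeAssignment(variety, catalog.gene_id, hit.hap_id, allele_string=s)


def presence_matrix(
    assignments: Sequence[HaplotypeAssignment],
    sh_by_gene: Mapping[str, str],
    tolerance_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Variety x gene report of superior-haplotype presence.

    ``sh_by_gene`` maps gene_id -> SH hap_id.  NOVEL and UNASSIGNED are never
    SH-present.  When ``tolerance_labels`` (variety -> TOLERANT|SUSCEPTIBLE)
    is given, a ``tolerance_label`` column is carried and per-gene counts by
    label are available via groupby.
    """
    rows = []
    for a in assignments:
        sh = sh_by_gene.get(a.gene_id)
        rows.append(
            {
                "variety": a.variety,
                "gene_id": a.gene_id,
                "assigned": a.status,
                "allele_string": a.allele_string or "",
                "sh_present": bool(sh is not None and a.status == sh),
                "tolerance_label": (tolerance_labels or {}).get(a.variety, ""),
            }
        )
    return pd.DataFrame(rows)


def classify_sift(score: float) -> str:
    """SIFT substitution-effect class: < 0.05 DAMAGING, otherwise TOLERATED.

    The boundary score 0.05 itself is classed TOLERATED.
    """
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"SIFT score must be in [0, 1], got {score}")
    return "DAMAGING" if score < SIFT_DAMAGING_BELOW else "TOLERATED"
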