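"""Shared fixtures: small hand-built panels and helpers used across modules."""

import numpy as np
import pytest

from haplopheno.panel import Call, GenotypePanel, Locus


def make_panel(calls, chrom="1", start_pos=100, spacing=10, ref="A", alt="G", prefix="ACC"):
    """Panel from an integer call matrix; loci spaced on one chromosome."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    loci = [Locus(chrom, start_pos + j * spacing, ref, alt) for j in range(m)]
    return GenotypePanel(
        accession_ids=[f"{prefix}{i:03d}" for i in range(n)], loci=loci, calls=calls
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240112)


@pytest.fixture
def toy_panel():
    """2 accessions x 3 SNPs covering all four call states."""
    return make_panel(
        [[Call.REF_HOM, Call.HET, Call.ALT_HOM], [Call.ALT_HOM, Call.MISSING, Call.REF_HOM]]
    )


def random_panel(rng, n, m, missing_rate=0.0, het_rate=0.3):
    """Random biallelic panel with configurable het/missing rates."""
    u = rng.random((n, m))
    calls = np.where(u < het_rate, Call.HET, np.where(u < het_rate + (1 - het_rate) / 2,
                                                      Call.REF_HOM, Call.ALT_HOM)).astype(np.int8)
    if missing_rate:
        calls[rng.random((n, m)) < missing_rate] = Call.MISSING
    return make_panel(calls)
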