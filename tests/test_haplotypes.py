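"""Haplotype catalogue construction against brute-force oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haplopheno.haplotypes import (
    build_haplotypes,
    diversity_summary,
    extract_gene_snps,
    haplotype_frequency,
    read_catalogs,
    subpop_distribution,
    write_catalogs,
)
from haplopheno.panel import Call, GeneModel, ValidationError
from conftest import make_panel, random_panel


def brute_force_groups(panel):
    """Independent oracle: dictionary grouping of fully homozygous strings."""
    groups, excluded = {}, {}
    for i, acc in enumerate(panel.accession_ids):
        row = panel.calls[i]
        if (row == Call.HET).any():
            excluded[acc] = "HET"
        elif (row == Call.MISSING).any():
            excluded[acc] = "MISSING"
        else:
            s = "".join(
                l.ref if c == Call.REF_HOM else l.alt for c, l in zip(row, panel.loci)
            )
            groups.setdefault(s, []).append(acc)
    return groups, excluded


class TestExtractGeneSnps:
    GENE = GeneModel("g", "x", "1", 95, 125, ((100, 110),), "+")

    def test_coding_mode_keeps_snp_inside_coding_interval(self):
        panel = make_panel([[0, 0, 0]], start_pos=101, spacing=10)  # pos 101,111,121
        sub = extract_gene_snps(panel, self.GENE, "CODING")
        assert [l.pos for l in sub.loci] == [101]  # 0-based 100 is in [100,110)

    def test_full_gene_half_open_boundary(self):
        # gene span [95, 125): 1-based position 126 (0-based 125) is outside
        panel = make_panel([[0, 0]], start_pos=125, spacing=1)  # pos 125, 126
        sub = extract_gene_snps(panel, self.GENE, "FULL_GENE")
        assert [l.pos for l in sub.loci] == [125]

    def test_flanked_pads_span(self):
        panel = make_panel([[0]], start_pos=90)  # 0-based 89, just before span
        assert extract_gene_snps(panel, self.GENE, "FULL_GENE").n_loci == 0
        assert extract_gene_snps(panel, self.GENE, "FLANKED", flank_bp=10).n_loci == 1

    def test_coding_union_equals_brute_force_position_filter(self, rng):
        gene = GeneModel("g", "x", "1", 0, 400, ((10, 60), (100, 180), (300, 390)))
        panel = random_panel(rng, 5, 40)  # positions 100..490
        sub = extract_gene_snps(panel, gene, "CODING")
        expect = [
            l.pos for l in panel.loci
            if any(s <= l.pos - 1 < e for s, e in gene.coding_intervals)
        ]
        assert [l.pos for l in sub.loci] == expect


class TestBuildHaplotypes:
    def test_two_distinct_strings_get_distinct_ids(self):
        # five-SNP gene, two homozygous strings differing at the last site
        calls = np.array([[2, 0, 0, 0, 2]] * 3 + [[2, 0, 0, 0, 0]] * 2, dtype=np.int8)
        panel = make_panel(calls, ref="A", alt="G")
        cat = build_haplotypes(panel, min_carriers=1)
        strings = {h.alleles for h in cat.haplotypes}
        assert strings == {"GAAAG", "GAAAA"}
        assert cat.haplotypes[0].hap_id == "H1" and cat.haplotypes[0].alleles == "GAAAG"

    def test_monomorphic_gene_single_haplotype_at_100pct(self):
        panel = make_panel(np.zeros((6, 4), dtype=np.int8))
        cat = build_haplotypes(panel)
        assert cat.n_haplotypes == 1
        assert cat.haplotypes[0].frequency_pct == pytest.approx(100.0)

    def test_zero_loci_gives_empty_string_haplotype(self):
        panel = make_panel(np.zeros((4, 0), dtype=np.int8))
        cat = build_haplotypes(panel)
        assert cat.n_haplotypes == 1
        assert cat.haplotypes[0].alleles == ""
        assert cat.haplotypes[0].n_carriers == 4

    def test_het_excludes_accession_with_reason(self):
        panel = make_panel([[0, 1], [0, 0], [-1, 0]])
        cat = build_haplotypes(panel)
        assert cat.excluded == {"ACC000": "HET", "ACC002": "MISSING"}
        assert cat.n_assigned == 1

    def test_site_drop_removes_high_het_locus(self):
        # locus 0: 3/4 het; locus 1: clean
        calls = np.array([[1, 0], [1, 0], [1, 2], [0, 2]], dtype=np.int8)
        panel = make_panel(calls)
        cat = build_haplotypes(panel, het_policy="SITE_DROP", max_site_het_frac=0.5)
        assert len(cat.loci) == 1 and cat.loci[0].pos == 110
        assert cat.n_assigned == 4

    def test_below_min_carriers_flagged_not_removed(self):
        calls = np.array([[0]] * 5 + [[2]] * 2, dtype=np.int8)
        cat = build_haplotypes(make_panel(calls), min_carriers=3)
        flags = {h.alleles: h.below_min_carriers for h in cat.haplotypes}
        assert flags == {"A": False, "G": True}

    def test_matches_brute_force_grouping(self, rng):
        panel = random_panel(rng, 20, 6, missing_rate=0.05, het_rate=0.1)
        cat = build_haplotypes(panel, min_carriers=1)
        groups, excluded = brute_force_groups(panel)
        assert cat.excluded == excluded
        assert {h.alleles: sorted(h.carriers) for h in cat.haplotypes} == {
            s: sorted(a) for s, a in groups.items()
        }

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.data())
    def test_accession_permutation_preserves_membership(self, seed, data):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, 12, 4, het_rate=0.15)
        perm = data.draw(st.permutations(list(range(12))))
        shuffled = panel.subset_accessions([panel.accession_ids[i] for i in perm])
        a = build_haplotypes(panel, min_carriers=1)
        b = build_haplotypes(shuffled, min_carriers=1)
        assert {h.alleles: frozenset(h.carriers) for h in a.haplotypes} == {
            h.alleles: frozenset(h.carriers) for h in b.haplotypes
        }

    def test_carrier_partition_and_frequency_sum(self, rng):
        panel = random_panel(rng, 30, 5, het_rate=0.1, missing_rate=0.05)
        cat = build_haplotypes(panel, min_carriers=1)
        all_carriers = [a for h in cat.haplotypes for a in h.carriers]
        assert len(all_carriers) == len(set(all_carriers))
        assert len(all_carriers) + len(cat.excluded) == 30
        if cat.n_assigned:
            assert sum(h.frequency_pct for h in cat.haplotypes) == pytest.approx(100.0, abs=1e-9)


class TestFrequencies:
    def test_three_of_399_is_0p75_pct(self):
        calls = np.array([[2]] * 3 + [[0]] * 396, dtype=np.int8)
        cat = build_haplotypes(make_panel(calls), min_carriers=1)
        freqs = dict(haplotype_frequency(cat))
        assert freqs["H2"] == pytest.approx(0.75, abs=5e-3)

    def test_fixed_haplotype_is_100_pct(self):
        cat = build_haplotypes(make_panel(np.zeros((399, 2), dtype=np.int8)))
        assert haplotype_frequency(cat) == [("H1", pytest.approx(100.0))]

    def test_single_accession_panel(self):
        cat = build_haplotypes(make_panel([[0, 2]]), min_carriers=1)
        assert haplotype_frequency(cat)[0][1] == pytest.approx(100.0)

    def test_no_assigned_accessions_errors(self):
        cat = build_haplotypes(make_panel([[1], [1]]))
        with pytest.raises(ValidationError):
            haplotype_frequency(cat)


class TestSubpopDistribution:
    def test_single_subpop_single_column(self):
        cat = build_haplotypes(make_panel([[0], [0], [2]]), min_carriers=1)
        table = subpop_distribution(cat, {a: "indica" for a in ["ACC000", "ACC001", "ACC002"]})
        assert list(table.columns) == ["indica"]
        assert table["indica"].sum() == 3

    def test_absent_subpop_cell_is_zero(self):
        cat = build_haplotypes(make_panel([[0], [0], [2]]), min_carriers=1)
        labels = {"ACC000": "indica", "ACC001": "indica", "ACC002": "aus"}
        table = subpop_distribution(cat, labels)
        assert table.loc["H1", "aus"] == 0  # major hap absent from aus

    def test_unlabeled_carrier_errors(self):
        cat = build_haplotypes(make_panel([[0], [0]]), min_carriers=1)
        with pytest.raises(ValidationError, match="ACC001"):
            subpop_distribution(cat, {"ACC000": "indica"})

    def test_matches_pandas_crosstab(self, rng):
        panel = random_panel(rng, 25, 4, het_rate=0.1)
        cat = build_haplotypes(panel, min_carriers=1)
        labels = {a: f"P{rng.integers(0, 3)}" for a in panel.accession_ids}
        table = subpop_distribution(cat, labels)
        cmap = cat.carrier_map()
        df = pd.DataFrame(
            [(cmap[a], labels[a]) for a in cmap], columns=["hap", "sub"]
        )
        oracle = pd.crosstab(df["hap"], df["sub"])
        for hap in table.index:
            for sub in table.columns:
                expect = oracle.loc[hap, sub] if hap in oracle.index and sub in oracle.columns else 0
                assert table.loc[hap, sub] == expect


class TestDiversitySummary:
    def test_monomorphic_gene(self):
        cat = build_haplotypes(make_panel(np.zeros((5, 2), dtype=np.int8)), gene_id="g1")
        s = diversity_summary([cat])
        row = s.per_gene.iloc[0]
        assert row["n_haplotypes"] == 1
        assert row["major_hap_frequency"] == row["minor_hap_frequency"] == pytest.approx(100.0)

    def test_range_over_genes(self, rng):
        mono = build_haplotypes(make_panel(np.zeros((10, 1), dtype=np.int8)), gene_id="a")
        rich = build_haplotypes(random_panel(rng, 40, 6, het_rate=0.0), gene_id="b", min_carriers=1)
        s = diversity_summary([mono, rich])
        assert s.hap_count_range == (1, rich.n_haplotypes)

    def test_summary_equals_recount(self, rng):
        cats = [
            build_haplotypes(random_panel(rng, 15, 3), gene_id=f"g{i}", min_carriers=1)
            for i in range(4)
        ]
        s = diversity_summary(cats)
        for cat, (_, row) in zip(cats, s.per_gene.iterrows()):
            freqs = [h.frequency_pct for h in cat.haplotypes]
            assert row["n_haplotypes"] == len(freqs)
            assert row["major_hap_frequency"] == pytest.approx(max(freqs))
            assert row["minor_hap_frequency"] == pytest.approx(min(freqs))

    def test_empty_list_errors(self):
        with pytest.raises(ValidationError):
            diversity_summary([])


def test_catalog_tsv_round_trip(tmp_path, rng):
    panel = random_panel(rng, 20, 5, het_rate=0.1)
    cats = [build_haplotypes(panel, gene_id="g1"),
            build_haplotypes(make_panel(np.zeros((20, 0), dtype=np.int8)), gene_id="g2")]
    write_catalogs(cats, tmp_path / "c.tsv", tmp_path / "c.json")
    back = read_catalogs(tmp_path / "c.tsv", tmp_path / "c.json")
    for a, b in zip(cats, back):
        assert a.gene_id == b.gene_id and a.loci == b.loci and a.excluded == b.excluded
        assert [(h.hap_id, h.alleles, h.carriers, h.below_min_carriers) for h in a.haplotypes] == [
            (h.hap_id, h.alleles, h.carriers, h.below_min_carriers) for h in b.haplotypes
        ]
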