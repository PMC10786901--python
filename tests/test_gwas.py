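"""Mixed-model association: kinship/LD oracles, OLS equivalence, model variants."""

import numpy as np
import pandas as pd
import pytest

from haplopheno.gwas import (
    KinshipMatrix,
    annotate_candidates,
    cmlm_scan,
    compress_kinship,
    kinship,
    ld_decay,
    mlm_scan,
    mlmm_scan,
    reml_loglik_rotated,
    select_mtas,
)
from haplopheno.panel import Call, GeneModel, ValidationError
from conftest import make_panel, random_panel


def dosage_panel(rng, n, m, maf_low=0.1, maf_high=0.5):
    """Random panel with binomial dosages at random allele frequencies."""
    p = rng.uniform(maf_low, maf_high, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return make_panel(calls)


def ols_pvalues(y, G, covar=None):
    """Independent OLS F-test oracle per SNP (statsmodels)."""
    import statsmodels.api as sm

    n = len(y)
    base = np.ones((n, 1)) if covar is None else np.column_stack([np.ones(n), covar])
    out = []
    for j in range(G.shape[1]):
        X = np.column_stack([base, G[:, j]])
        if np.var(G[:, j]) == 0:
            out.append(np.nan)
            continue
        fit = sm.OLS(y, X).fit()
        out.append(fit.pvalues[-1])
    return np.array(out)


class TestKinship:
    def test_identical_clones_give_constant_matrix(self, rng):
        row = rng.binomial(2, 0.4, 10).astype(np.int8)
        row[0] = 1  # keep at least one polymorphic-looking site across clones? no:
        calls = np.tile(row, (5, 1))
        calls[:, 0] = [0, 0, 0, 0, 2]  # one polymorphic locus so K is defined
        k = kinship(make_panel(calls)).values
        # clones 0-3 are identical: their mutual entries all equal
        block = k[:4, :4]
        assert np.allclose(block, block[0, 0])

    def test_duplicated_accessions_have_identical_rows(self, rng):
        panel = dosage_panel(rng, 6, 8)
        calls = np.vstack([panel.calls, panel.calls[2]])
        k = kinship(make_panel(calls)).values
        assert np.allclose(k[2], k[6])
        assert np.allclose(k, k.T)

    def test_vanraden_matches_brute_force(self, rng):
        panel = dosage_panel(rng, 6, 8)
        k = kinship(panel, method="VANRADEN").values
        d = panel.calls.astype(float)
        p = d.mean(axis=0) / 2
        w = d - 2 * p
        denom = 2 * np.sum(p * (1 - p))
        expect = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                expect[i, j] = np.dot(w[i], w[j]) / denom
        assert np.allclose(k, expect)

    def test_ibs_matches_brute_force(self, rng):
        panel = dosage_panel(rng, 5, 10)
        k = kinship(panel, method="IBS").values
        d = panel.calls.astype(float)
        for i in range(5):
            for j in range(5):
                assert k[i, j] == pytest.approx(1 - np.abs(d[i] - d[j]).mean() / 2)

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValidationError):
            kinship(make_panel(np.zeros((4, 3), dtype=np.int8)))


class TestLdDecay:
    def test_allele_flipped_copy_has_r2_one(self):
        g = np.array([0, 0, 1, 2, 2, 1, 0, 2], dtype=np.int8)
        calls = np.column_stack([g, 2 - g])
        pairs, _ = ld_decay(make_panel(calls))
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_identical_copy_has_r2_one(self):
        g = np.array([0, 1, 2, 0, 2], dtype=np.int8)
        pairs, _ = ld_decay(make_panel(np.column_stack([g, g])))
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_pairs_skipped(self):
        g = np.array([0, 1, 2, 0], dtype=np.int8)
        calls = np.column_stack([g, np.zeros(4, dtype=np.int8)])
        pairs, _ = ld_decay(make_panel(calls))
        assert len(pairs) == 0

    def test_r2_matches_brute_force_correlation(self, rng):
        panel = dosage_panel(rng, 20, 6)
        pairs, _ = ld_decay(panel, max_dist_bp=1000)
        d = panel.calls.astype(float)
        for _, row in pairs.iterrows():
            i = [l.snp_id for l in panel.loci].index(row["snp_a"])
            j = [l.snp_id for l in panel.loci].index(row["snp_b"])
            r = np.corrcoef(d[:, i], d[:, j])[0, 1]
            assert row["r2"] == pytest.approx(r * r)

    def test_decay_distance_is_first_bin_below_threshold(self, rng):
        panel = dosage_panel(rng, 40, 30)  # independent SNPs: r2 ~ 1/n, low
        _, decay = ld_decay(panel, max_dist_bp=500, bin_bp=50, r2_threshold=0.2)
        assert decay is not None and decay <= 500


class TestMlmScan:
    def test_identity_kinship_matches_ols(self, rng):
        """Acceptance-grade oracle: K = I reduces the mixed model to OLS."""
        for _ in range(10):
            n, m = 50, 12
            panel = dosage_panel(rng, n, m)
            y_v = rng.normal(5, 1, n) + 0.5 * panel.calls[:, 0]
            y = pd.Series(y_v, index=panel.accession_ids)
            K = KinshipMatrix(panel.accession_ids, np.eye(n))
            res = mlm_scan(y, panel, K)
            expect = ols_pvalues(y_v, panel.calls.astype(float))
            assert np.allclose(res["p"].to_numpy(), expect, atol=1e-8, equal_nan=True)

    def test_monomorphic_snp_flagged_na(self, rng):
        panel = make_panel(np.column_stack([
            rng.binomial(2, 0.4, 30), np.zeros(30, dtype=int)]).astype(np.int8))
        y = pd.Series(rng.normal(0, 1, 30), index=panel.accession_ids)
        K = KinshipMatrix(panel.accession_ids, np.eye(30))
        res = mlm_scan(y, panel, K)
        assert np.isnan(res["p"].iloc[1]) and np.isfinite(res["p"].iloc[0])

    def test_effect_recovery_with_structured_noise(self):
        """Median estimated effect within 10% of the planted 0.8 over seeds."""
        est = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            panel = dosage_panel(rng, 200, 25)
            K = kinship(panel)
            L = np.linalg.cholesky(K.values + 1e-6 * np.eye(200))
            u = 0.5 * (L @ rng.standard_normal(200))
            y_v = 0.8 * panel.calls[:, 3] + u + rng.normal(0, 1, 200)
            y = pd.Series(y_v, index=panel.accession_ids)
            est.append(mlm_scan(y, panel, K)["beta"].iloc[3])
        assert np.median(est) == pytest.approx(0.8, rel=0.10)

    def test_affine_rescaling_of_y_preserves_p(self, rng):
        panel = dosage_panel(rng, 40, 8)
        K = kinship(panel)
        y_v = rng.normal(4, 1, 40)
        y1 = pd.Series(y_v, index=panel.accession_ids)
        y2 = pd.Series(3.0 * y_v + 7.0, index=panel.accession_ids)
        p1 = mlm_scan(y1, panel, K)["p"].to_numpy()
        p2 = mlm_scan(y2, panel, K)["p"].to_numpy()
        assert np.allclose(p1, p2, atol=1e-9, equal_nan=True)

    def test_allele_relabeling_flips_sign_keeps_p(self, rng):
        panel = dosage_panel(rng, 40, 6)
        flipped_calls = panel.calls.copy()
        hom = np.isin(flipped_calls, [0, 2])
        flipped_calls[hom] = 2 - flipped_calls[hom]
        flipped = make_panel(flipped_calls)
        y = pd.Series(rng.normal(0, 1, 40) + panel.calls[:, 0], index=panel.accession_ids)
        K = kinship(panel)
        a = mlm_scan(y, panel, K)
        b = mlm_scan(y, flipped, K)
        assert np.allclose(a["p"].to_numpy(), b["p"].to_numpy(), atol=1e-8, equal_nan=True)
        assert np.allclose(a["beta"].to_numpy(), -b["beta"].to_numpy(), atol=1e-8, equal_nan=True)

    def test_rotated_reml_equals_dense(self, rng):
        """Eigen-rotated REML log-likelihood == direct dense-matrix REML."""
        n = 30
        panel = dosage_panel(rng, n, 40)
        K = kinship(panel).values
        y = rng.normal(0, 1, n) + 0.3 * panel.calls[:, 0]
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        for lam in (0.1, 1.0, 5.0):
            rot = reml_loglik_rotated(y, X, K, lam)
            V = np.eye(n) + lam * K
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            rss = r @ Vi @ r
            s2 = rss / (n - 2)
            dense = -0.5 * ((n - 2) * (np.log(2 * np.pi * s2) + 1)
                            + np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1])
            assert rot == pytest.approx(dense, abs=1e-6)


class TestCmlm:
    def test_no_compression_identical_to_mlm(self, rng):
        panel = dosage_panel(rng, 30, 10)
        K = kinship(panel)
        y = pd.Series(rng.normal(0, 1, 30) + panel.calls[:, 1], index=panel.accession_ids)
        a = mlm_scan(y, panel, K)
        b = cmlm_scan(y, panel, K, n_groups=30)
        assert np.allclose(a["p"].to_numpy(), b["p"].to_numpy(), atol=1e-10, equal_nan=True)

    def test_single_group_degenerates_to_ols(self, rng):
        panel = dosage_panel(rng, 30, 8)
        K = kinship(panel)
        y_v = rng.normal(0, 1, 30)
        y = pd.Series(y_v, index=panel.accession_ids)
        res = cmlm_scan(y, panel, K, n_groups=1)
        expect = ols_pvalues(y_v, panel.calls.astype(float))
        assert np.allclose(res["p"].to_numpy(), expect, atol=1e-6, equal_nan=True)

    def test_zero_groups_errors(self, rng):
        panel = dosage_panel(rng, 10, 4)
        K = kinship(panel)
        y = pd.Series(rng.normal(0, 1, 10), index=panel.accession_ids)
        with pytest.raises(ValidationError):
            cmlm_scan(y, panel, K, n_groups=0)

    def test_group_kinship_equals_block_average(self, rng):
        panel = dosage_panel(rng, 12, 10)
        K = kinship(panel)
        K_c, groups = compress_kinship(K, 3)
        for i in range(12):
            for j in range(12):
                ia, ib = groups == groups[i], groups == groups[j]
                assert K_c.values[i, j] == pytest.approx(K.values[np.ix_(ia, ib)].mean())


class TestMlmm:
    def test_single_causal_snp_selected_first(self):
        rng = np.random.default_rng(7)
        panel = dosage_panel(rng, 150, 20)
        y_v = 1.5 * panel.calls[:, 5] + rng.normal(0, 1, 150)
        y = pd.Series(y_v, index=panel.accession_ids)
        K = kinship(panel)
        res = mlmm_scan(y, panel, K, max_steps=3)
        assert res["p"].idxmin() == 5

    def test_zero_threshold_equals_single_scan(self, rng):
        panel = dosage_panel(rng, 40, 8)
        K = kinship(panel)
        y = pd.Series(rng.normal(0, 1, 40), index=panel.accession_ids)
        a = mlmm_scan(y, panel, K, add_threshold=0.0)
        b = mlm_scan(y, panel, K)
        assert np.allclose(a["p"].to_numpy(), b["p"].to_numpy(), atol=1e-12, equal_nan=True)

    def test_two_independent_causals_recovered(self):
        found = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            panel = dosage_panel(rng, 200, 30, maf_low=0.2)
            y_v = 1.2 * panel.calls[:, 4] + 1.2 * panel.calls[:, 20] + rng.normal(0, 1, 200)
            y = pd.Series(y_v, index=panel.accession_ids)
            res = mlmm_scan(y, panel, kinship(panel), max_steps=2, add_threshold=0.005)
            top2 = set(res["p"].nsmallest(2).index)
            if top2 == {4, 20}:
                found += 1
        assert found >= 27  # >= 90% of seeds


class TestMtaSelection:
    def _result(self, ids, pvals, model):
        return pd.DataFrame({
            "snp_id": ids, "chrom": "1", "pos": range(1, len(ids) + 1),
            "model": model, "beta": 0.1, "se": 0.1, "p": pvals, "pve_pct": 1.0,
        })

    def test_threshold_and_intersection_logic(self):
        ids = ["s1", "s2", "s3"]
        r1 = self._result(ids, [0.004, 0.004, 0.5], "MLM")
        r2 = self._result(ids, [0.004, 0.02, 0.001], "MLMM")
        mtas = select_mtas([r1, r2], threshold=0.005)
        assert mtas.snp_ids == ["s1"]  # s2 fails in MLMM, s3 in MLM

    def test_na_p_fails_intersection(self):
        r1 = self._result(["s1"], [np.nan], "MLM")
        assert select_mtas([r1]).snp_ids == []

    def test_matches_brute_force_set_intersection(self, rng):
        ids = [f"s{i}" for i in range(50)]
        results = [self._result(ids, rng.uniform(0, 0.02, 50), m) for m in ("MLM", "CMLM", "MLMM")]
        mtas = select_mtas(results, threshold=0.005)
        expect = set(ids)
        for r in results:
            expect &= set(r.loc[r["p"] <= 0.005, "snp_id"])
        assert set(mtas.snp_ids) == expect

    def test_chromosome_tally(self):
        r = self._result(["a", "b"], [0.001, 0.002], "MLM")
        r.loc[1, "chrom"] = "2"
        tally = select_mtas([r]).chromosome_tally()
        assert tally.to_dict() == {"1": 1, "2": 1}


class TestAnnotateCandidates:
    GENES = [GeneModel("g1", "x1", "1", 100_000, 120_000),
             GeneModel("g2", "x2", "2", 500_000, 510_000)]

    def _mtas(self, positions, chrom="1"):
        df = pd.DataFrame({
            "snp_id": [f"s{p}" for p in positions], "chrom": chrom,
            "pos": positions, "model": "MLM", "beta": 0.1, "se": 0.1,
            "p": 0.001, "pve_pct": 1.0,
        })
        return select_mtas([df], threshold=0.005)

    def test_upstream_snp_assigned_flanking(self):
        out = annotate_candidates(self._mtas([90_001]), self.GENES)  # 10 kb upstream
        assert out.table["candidate_genes"].iloc[0] == "g1"
        assert out.table["status"].iloc[0] == "flanking"

    def test_genic_snp_status(self):
        out = annotate_candidates(self._mtas([110_000]), self.GENES)
        assert out.table["status"].iloc[0] == "genic"

    def test_past_window_boundary_not_assigned(self):
        # gene start 100000 (0-based); 1-based 50001 bp upstream => 0-based 49999
        out = annotate_candidates(self._mtas([50_000]), self.GENES, window_bp=50_000)
        assert out.table["candidate_genes"].iloc[0] == ""
        inside = annotate_candidates(self._mtas([50_001]), self.GENES, window_bp=50_000)
        assert inside.table["candidate_genes"].iloc[0] == "g1"

    def test_matches_brute_force_containment(self, rng):
        positions = rng.integers(1, 700_000, 60).tolist()
        out = annotate_candidates(self._mtas(positions), self.GENES, window_bp=50_000)
        for _, row in out.table.iterrows():
            pos0 = row["pos"] - 1
            expect = [g.gene_id for g in self.GENES
                      if g.chrom == "1" and g.start - 50_000 <= pos0 < g.end + 50_000]
            assert row["candidate_genes"].split(";") == (expect or [""])
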