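"""Protein-level statistics: quantification, moderated t, tests, enrichment."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteorelapse.quantprot import (
    bh_adjust,
    complete_case_filter,
    fit_variance_prior,
    gene_centric_quant,
    geneset_enrichment,
    moderated_t,
    mtdna_ratio,
    paired_differences,
    pca_overview,
    spearman_corr,
    wilcoxon_paired,
)


class TestGeneCentricQuant:
    def _matrix(self):
        mat = pd.DataFrame(
            {"s1": [-1.0, 0.0, 5.0, 2.0], "s2": [1.0, 1.0, 1.0, 3.0]},
            index=["p1", "p2", "p3", "p4"],
        )
        genes = pd.Series({"p1": "G1", "p2": "G1", "p3": "G1", "p4": "G1;G2"})
        return mat, genes

    def test_median_of_unique_peptides(self):
        mat, genes = self._matrix()
        out = gene_centric_quant(mat, genes)
        assert out.loc["G1", "s1"] == 0.0  # median of {-1, 0, 5}; shared p4 dropped
        assert out.loc["G1", "s2"] == 1.0
        assert "G2" not in out.index

    def test_single_peptide_passthrough(self):
        out = gene_centric_quant(
            pd.DataFrame({"s1": [0.7]}, index=["p1"]), pd.Series({"p1": "G9"})
        )
        assert out.loc["G9", "s1"] == 0.7

    def test_matches_brute_force_median_oracle(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            rng.normal(size=(50, 4)), index=[f"p{i}" for i in range(50)],
            columns=list("abcd"),
        )
        genes = pd.Series(
            {f"p{i}": f"G{i % 7}" for i in range(50)}
        )
        out = gene_centric_quant(mat, genes)
        for g in out.index:
            members = [p for p in mat.index if genes[p] == g]
            assert np.allclose(out.loc[g], np.median(mat.loc[members], axis=0))

    def test_column_scaling_adds_constant_log_ratio(self):
        rng = np.random.default_rng(1)
        linear = pd.DataFrame(rng.lognormal(size=(20, 3)), columns=list("xyz"),
                              index=[f"p{i}" for i in range(20)])
        genes = pd.Series({f"p{i}": f"G{i % 5}" for i in range(20)})
        base = gene_centric_quant(np.log2(linear), genes)
        scaled = linear.copy()
        scaled["y"] *= 8.0
        shifted = gene_centric_quant(np.log2(scaled), genes)
        assert np.allclose(shifted["y"] - base["y"], 3.0)
        assert np.allclose(shifted["x"], base["x"])


class TestCompleteCase:
    def test_row_with_any_missing_dropped(self):
        mat = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]}, index=["g1", "g2"])
        out = complete_case_filter(mat, ["a", "b"])
        assert list(out.index) == ["g1"]

    def test_missing_outside_cohort_ignored(self):
        mat = pd.DataFrame({"a": [1.0], "b": [np.nan]}, index=["g1"])
        assert list(complete_case_filter(mat, ["a"]).index) == ["g1"]


class TestModeratedT:
    def test_prior_df_zero_equals_classical_paired_t(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 8))
        res = moderated_t(pd.DataFrame(x), prior_df=0)
        t, p = stats.ttest_1samp(x, 0.0, axis=1)
        assert np.allclose(res["t"], t)
        assert np.allclose(res["p_value"], p)

    def test_infinite_prior_pools_variances(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 6))
        res = moderated_t(pd.DataFrame(x), prior_df=np.inf)
        pooled = x.var(axis=1, ddof=1).mean()
        expect_t = x.mean(axis=1) / np.sqrt(pooled / 6)
        assert np.allclose(res["t"], expect_t)
        assert np.allclose(res["p_value"], 2 * stats.norm.sf(np.abs(expect_t)))

    def test_row_reorder_invariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(60, 10)), index=[f"g{i}" for i in range(60)])
        a = moderated_t(df).set_index("gene")
        b = moderated_t(df.sample(frac=1.0, random_state=5)).set_index("gene")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_shift_equivariance_of_paired_design(self):
        rng = np.random.default_rng(6)
        pairs = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(6)],
             "diagnosis": [f"D{i}" for i in range(6)],
             "relapse": [f"R{i}" for i in range(6)]}
        )
        mat = pd.DataFrame(
            rng.normal(size=(30, 12)),
            columns=pairs["diagnosis"].tolist() + pairs["relapse"].tolist(),
            index=[f"g{i}" for i in range(30)],
        )
        d1 = paired_differences(mat, pairs)
        d2 = paired_differences(mat + 5.0, pairs)  # constant added to both mates
        pd.testing.assert_frame_equal(d1, d2)

    def test_variance_prior_recovers_simulation_parameters(self):
        rng = np.random.default_rng(7)
        d0_true, s0_true, dg = 8.0, 0.25, 15
        s2 = s0_true * d0_true / stats.chi2.rvs(d0_true, size=4000, random_state=8)
        sample_var = s2 * stats.chi2.rvs(dg, size=4000, random_state=9) / dg
        d0, s0 = fit_variance_prior(sample_var, dg)
        assert 0.7 * d0_true <= d0 <= 1.4 * d0_true
        assert 0.9 * s0_true <= s0 <= 1.1 * s0_true


class TestWilcoxon:
    def test_identical_vectors_p_one(self):
        with pytest.warns(UserWarning):
            w, p = wilcoxon_paired([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == 1.0

    def test_n6_all_positive_exact(self):
        x = [10, 11, 12, 13, 14, 15]
        y = [1.0, 2.5, 3.1, 4.7, 5.3, 6.8]  # distinct positive differences
        _w, p = wilcoxon_paired(x, y)
        assert p == pytest.approx(2 / 2**6)

    @pytest.mark.parametrize("n", [8, 12])
    def test_exact_path_matches_full_enumeration(self, n):
        """Brute-force enumeration over all sign assignments of the ranks."""
        rng = np.random.default_rng(10 + n)
        d = rng.normal(size=n)
        while len(np.unique(np.abs(d))) < n:
            d = rng.normal(size=n)
        w_obs, p = wilcoxon_paired(d, np.zeros(n))
        ranks = stats.rankdata(np.abs(d))
        w_plus_all = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        mean_w = n * (n + 1) / 4
        dev = abs(w_obs - mean_w)
        p_exact = np.mean([abs(w - mean_w) >= dev - 1e-9 for w in w_plus_all])
        assert p == pytest.approx(p_exact)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_corr(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])
        rho, _ = spearman_corr(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning):
            rho, p = spearman_corr([1.0] * 5, [1, 2, 3, 4, 5])
        assert np.isnan(rho)


class TestPca:
    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(11)
        mat = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        mat["f"] = mat["a"]
        scores, _ = pca_overview(mat, k=3)
        assert np.allclose(scores.loc["a"], scores.loc["f"])

    def test_full_reconstruction(self):
        rng = np.random.default_rng(12)
        mat = pd.DataFrame(rng.normal(size=(20, 6)))
        x = mat.to_numpy()
        centered = x - x.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        assert np.allclose(u @ np.diag(s) @ vt, centered, atol=1e-8)

    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, size=(100, 6))
        b = rng.normal(0, 1, size=(100, 6)) + 6.0
        mat = pd.DataFrame(np.concatenate([a, b], axis=1),
                           columns=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)])
        scores, explained = pca_overview(mat, k=1)
        pc1_a = scores.iloc[:6, 0].to_numpy()
        pc1_b = scores.iloc[6:, 0].to_numpy()
        assert max(pc1_a) < min(pc1_b) or min(pc1_a) > max(pc1_b)
        assert explained[0] > 0.5


class TestEnrichment:
    def test_whole_background_set_is_null(self):
        genes = {f"g{i}" for i in range(50)}
        out = geneset_enrichment(genes, genes, {"all": sorted(genes)})
        assert out.loc[0, "score"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_closed_form_example(self):
        """N=6840, n=321, K=100, k=30: score ~6.39, P equals brute-force
        hypergeometric tail sum."""
        background = {f"g{i}" for i in range(6840)}
        hits = {f"g{i}" for i in range(321)}
        members = [f"g{i}" for i in range(30)] + [f"g{i}" for i in range(1000, 1070)]
        out = geneset_enrichment(hits, background, {"s": members})
        assert out.loc[0, "overlap"] == 30
        assert out.loc[0, "score"] == pytest.approx((30 / 321) / (100 / 6840))
        brute = sum(
            stats.hypergeom.pmf(k, 6840, 100, 321) for k in range(30, 101)
        )
        assert out.loc[0, "p_value"] == pytest.approx(brute, rel=1e-8)

    def test_disjoint_set_scores_zero(self):
        background = {f"g{i}" for i in range(100)}
        out = geneset_enrichment({"g1"}, background, {"s": ["g50", "g51"]})
        assert out.loc[0, "score"] == 0.0

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment({"x"}, {"y"}, {"s": ["y"]})


class TestBhAdjustment:
    def _brute(self, p):
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        return adj

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=200)
        assert np.allclose(bh_adjust(p), self._brute(p), atol=1e-12)


class TestMtdnaRatio:
    def _depth(self, rows):
        return pd.DataFrame(rows)

    def _pairs(self, n=1):
        return pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)],
             "diagnosis": [f"P{i}-D" for i in range(n)],
             "relapse": [f"P{i}-R" for i in range(n)]}
        )

    def test_identical_depths_give_100_and_p_one(self):
        rows = []
        for i in range(6):
            rows.append({"sample_id": f"P{i}-D", "mt_depth": 3000.0, "nuclear_depth": 30.0})
            rows.append({"sample_id": f"P{i}-R", "mt_depth": 3000.0, "nuclear_depth": 30.0})
        table, p = mtdna_ratio(self._depth(rows), self._pairs(6))
        assert np.allclose(table["ratio_pct"], 100.0)
        assert p == 1.0

    def test_doubled_mt_depth_gives_200(self):
        rows = [
            {"sample_id": "P0-D", "mt_depth": 3000.0, "nuclear_depth": 30.0},
            {"sample_id": "P0-R", "mt_depth": 6000.0, "nuclear_depth": 30.0},
        ]
        table, _ = mtdna_ratio(self._depth(rows), self._pairs(1))
        assert table["ratio_pct"].iloc[0] == pytest.approx(200.0)

    def test_missing_mate_skipped(self):
        rows = [
            {"sample_id": "P0-D", "mt_depth": 3000.0, "nuclear_depth": 30.0},
            {"sample_id": "P0-R", "mt_depth": 3300.0, "nuclear_depth": 30.0},
        ]
        table, _ = mtdna_ratio(self._depth(rows), self._pairs(2))
        assert len(table) == 1

    def test_nonpositive_depth_rejected(self):
        rows = [
            {"sample_id": "P0-D", "mt_depth": 0.0, "nuclear_depth": 30.0},
            {"sample_id": "P0-R", "mt_depth": 3300.0, "nuclear_depth": 30.0},
        ]
        with pytest.raises(ValueError):
            mtdna_ratio(self._depth(rows), self._pairs(1))
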