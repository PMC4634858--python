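"""Welch test, fold-changes, correlations, rank-sum, SD filter, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tmtflow as tf


class TestWelch:
    def test_identical_groups(self):
        r = tf.welch_t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_fixed_example_closed_form(self):
        r = tf.welch_t_test([10, 11, 12], [13, 14, 15])
        assert r.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert r.statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.df == pytest.approx(4.0, abs=1e-12)
        ref = sps.ttest_ind([10, 11, 12], [13, 14, 15], equal_var=False)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_scipy_on_random_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            nx, ny = rng.integers(2, 12, 2)
            x = rng.normal(0, rng.uniform(0.5, 3), nx)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), ny)
            mine = tf.welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.df == pytest.approx(ref.df, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_antisymmetric_in_group_order(self):
        x, y = [1.0, 2.5, 2.0], [4.0, 3.5, 5.0, 4.2]
        a, b = tf.welch_t_test(x, y), tf.welch_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_single_value_group_is_undefined(self):
        r = tf.welch_t_test([1.0], [1, 2, 3])
        assert r.undefined and np.isnan(r.p)

    def test_zero_variance_conventions(self):
        eq = tf.welch_t_test([2, 2, 2], [2, 2, 2])
        assert eq.p == 1.0 and eq.degenerate
        ne = tf.welch_t_test([2, 2, 2], [3, 3, 3])
        assert ne.p == 0.0 and ne.degenerate


class TestFoldChangeAndCalls:
    def test_log2_fold_change_values(self):
        assert tf.log2_fold_change(10.0, 10.0) == 0.0
        assert tf.log2_fold_change(10.0 + np.log2(1.5), 10.0) == \
            pytest.approx(0.585, abs=1e-3)
        assert tf.log2_fold_change(11.88, 10.0) == pytest.approx(1.88)

    @pytest.mark.parametrize("p,lfc,expected", [
        (0.03, 1.0, True),    # linear FC 2.0
        (0.03, 0.5, False),   # linear FC 1.414 < 1.5
        (0.06, 2.0, False),   # p over threshold
        (0.03, -1.0, True),   # linear FC 0.5 < 0.6667
    ])
    def test_published_threshold_rule(self, p, lfc, expected):
        table = pd.DataFrame({"p": [p], "log2fc": [lfc]})
        assert tf.call_significant(table)["called"].iloc[0] == expected

    def test_p_only_mode(self):
        table = pd.DataFrame({"p": [0.03], "log2fc": [0.1]})
        assert tf.call_significant(table, use_fc=False)["called"].iloc[0]

    def test_counts_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"p": rng.uniform(0, 1, 500),
                              "log2fc": rng.normal(0, 1.5, 500)})
        for _ in range(50):
            p1, p2 = sorted(rng.uniform(0.001, 0.2, 2))
            f1, f2 = sorted(rng.uniform(1.05, 3.0, 2))
            n = lambda p, f: tf.call_significant(table, p, f)["called"].sum()
            assert n(p1, f2) <= n(p1, f1) <= n(p2, f1)
            assert n(p1, f2) <= n(p2, f2) <= n(p2, f1)


class TestCorrelation:
    def test_perfect_linear_and_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert tf.correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert tf.correlation(x, x**3, "spearman").r == pytest.approx(1.0)

    def test_rank_formula_example(self):
        # 1 - 6*4/(5*24) = 0.8 by the d^2 formula (no ties)
        c = tf.correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], "spearman")
        assert c.r == pytest.approx(0.8, abs=1e-12)
        ref = sps.spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert c.r == pytest.approx(ref.statistic, abs=1e-12)

    def test_affine_invariance_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = tf.correlation(x, y).r
        assert tf.correlation(3 * x + 2, 0.5 * y - 7).r == pytest.approx(base)

    def test_matches_scipy_with_ties_and_missing(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 6, n).astype(float)  # plenty of ties
            y = x + rng.normal(0, 1.5, n)
            x[rng.random(n) < 0.1] = np.nan
            ok = ~np.isnan(x)
            if ok.sum() < 3:
                continue
            mine = tf.correlation(x, y, "spearman")
            ref = sps.spearmanr(x[ok], y[ok])
            assert mine.r == pytest.approx(ref.statistic, abs=1e-10)
            mine_p = tf.correlation(x, y, "pearson")
            ref_p = sps.pearsonr(x[ok], y[ok])
            assert mine_p.r == pytest.approx(ref_p.statistic, abs=1e-10)

    def test_constant_vector_undefined(self):
        c = tf.correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert c.undefined and np.isnan(c.r)


def exact_ranksum_p(x, y):
    """Exhaustive permutation two-sided p for the Mann-Whitney U."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(idx):
        ranks = sps.rankdata(pooled)
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    mu = n1 * len(y) / 2.0
    observed = abs(u_of(range(n1)) - mu)
    total = hits = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(combo) - mu) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_identical_multisets_p_one(self):
        r = tf.rank_sum_test([1, 2, 3], [1, 2, 3])
        assert r.p == pytest.approx(1.0, abs=1e-9)

    def test_complete_separation_u_zero(self):
        r = tf.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0

    def test_within_enumerated_worst_case_of_exact(self):
        # the continuity-corrected normal approximation's true worst-case
        # deviation from the exhaustive permutation p (enumerated over every
        # possible U) is 0.0375 / 0.0305 / 0.0172 for 3v3 / 4v4 / 5v5
        rng = np.random.default_rng(4)
        bounds = {3: 0.0376, 4: 0.0306, 5: 0.0173}
        for n, bound in bounds.items():
            for _ in range(10):
                x = rng.normal(0, 1, n)
                y = rng.normal(0.8, 1, n)
                approx = tf.rank_sum_test(x, y).p
                assert abs(approx - exact_ranksum_p(x, y)) <= bound + 1e-9

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x = rng.normal(0, 1, int(rng.integers(3, 15)))
            y = rng.normal(0.5, 1, int(rng.integers(3, 15)))
            mine = tf.rank_sum_test(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestSdFilter:
    def test_hand_computed_sds(self):
        samples = [f"s{i}" for i in range(5)]
        rows = {}
        for sd in (0.2, 0.9, 1.0, 1.1, 3.0):
            # five values m-sd, m-sd, m+sd, m+sd, m have variance sd^2 exactly
            rows[f"sd{sd}"] = [10 - sd, 10 - sd, 10 + sd, 10 + sd, 10.0]
        m = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        np.testing.assert_allclose(m.std(axis=1, ddof=1),
                                   [0.2, 0.9, 1.0, 1.1, 3.0], atol=1e-12)
        kept = tf.sd_filter(m, 1.0)
        assert set(kept.index) == {"sd1.1", "sd3.0"}  # strict >: sd 1.0 removed

    def test_constant_probe_removed(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [5.0, 6.0, 9.0]],
                         index=["const", "varies"], columns=["a", "b", "c"])
        kept = tf.sd_filter(m, 1.0)
        assert "const" not in kept.index


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(0)
        col = rng.normal(10, 2, 20)
        m = pd.DataFrame({"a": col, "b": col, "c": -col})
        res = tf.hierarchical_cluster(m)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_correlated_pair_merges_first(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        m = pd.DataFrame({"x": a, "y": 2 * a + 1, "z": -a})
        res = tf.hierarchical_cluster(m)
        first = {int(res.linkage[0, 0]), int(res.linkage[0, 1])}
        assert first == {0, 1}  # x and y (r=1) merge before anything with z

    def test_two_cut_recovers_histology_on_synthetic_data(self):
        params = tf.tmt_like(n_proteins=300, frac_de=0.1, de_log2fc=2.0,
                             channel_noise_sd=0.25, seed=17)
        truth = tf.generate_ground_truth(params)
        table = tf.simulate_peptide_table(truth)
        res = tf.run_pipeline(tf.RunConfig(), truth.design, table)
        labels = res.protein_cluster.labels
        groups = dict(zip(truth.design.sample_ids, truth.design.groups))
        by_label = {}
        for s, lab in labels.items():
            by_label.setdefault(lab, set()).add(groups[s])
        assert all(len(gs) == 1 for gs in by_label.values())

    def test_too_few_complete_features_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, np.nan]})
        with pytest.raises(ValueError, match="complete features"):
            tf.hierarchical_cluster(m)

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(0, 1, (30, 6)),
                         columns=[f"s{i}" for i in range(6)])
        res = tf.hierarchical_cluster(m)
        for s in m.columns:
            assert s in res.newick
        assert res.newick.endswith(";")
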