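"""Probe matching, concordance, overlaps, cross-study comparison."""

import numpy as np
import pandas as pd
import pytest

import tmtflow as tf


def _mats(n_prot=4, samples=("s1", "s2", "s3", "s4", "s5", "s6"), seed=0):
    rng = np.random.default_rng(seed)
    prot = pd.DataFrame(rng.normal(12, 1, (n_prot, len(samples))),
                        index=[f"P{i}" for i in range(n_prot)],
                        columns=list(samples))
    prot.index.name = "protein"
    return prot


class TestProbeMatching:
    def test_highest_average_probe_wins(self):
        prot = _mats(1)
        exprs = pd.DataFrame([[8.0] * 6, [9.0] * 6], index=["pA", "pB"],
                             columns=prot.columns)
        mapping = pd.DataFrame({"probe_id": ["pA", "pB"], "protein_id": ["P0", "P0"]})
        matched = tf.match_probes_to_proteins(exprs, mapping, prot)
        assert matched.pairs.loc["P0", "probe_id"] == "pB"

    def test_tie_prefers_lexicographically_smaller(self):
        prot = _mats(1)
        exprs = pd.DataFrame([[8.0] * 6, [8.0] * 6], index=["pB", "pA"],
                             columns=prot.columns)
        mapping = pd.DataFrame({"probe_id": ["pB", "pA"], "protein_id": ["P0", "P0"]})
        matched = tf.match_probes_to_proteins(exprs, mapping, prot)
        assert matched.pairs.loc["P0", "probe_id"] == "pA"

    def test_probe_row_order_invariance(self):
        prot = _mats(3, seed=2)
        rng = np.random.default_rng(3)
        exprs = pd.DataFrame(rng.normal(8, 1, (6, 6)),
                             index=[f"p{i}" for i in range(6)],
                             columns=prot.columns)
        mapping = pd.DataFrame({
            "probe_id": ["p0", "p1", "p2", "p3", "p4", "p5"],
            "protein_id": ["P0", "P0", "P1", "P1", "P2", "P2"]})
        m1 = tf.match_probes_to_proteins(exprs, mapping, prot)
        m2 = tf.match_probes_to_proteins(exprs.iloc[::-1], mapping.iloc[::-1], prot)
        pd.testing.assert_frame_equal(m1.pairs, m2.pairs)

    def test_protein_without_probe_excluded_and_empty_errors(self):
        prot = _mats(2)
        exprs = pd.DataFrame([[8.0] * 6], index=["pA"], columns=prot.columns)
        mapping = pd.DataFrame({"probe_id": ["pA"], "protein_id": ["P0"]})
        matched = tf.match_probes_to_proteins(exprs, mapping, prot)
        assert list(matched.pairs.index) == ["P0"]
        bad_map = pd.DataFrame({"probe_id": ["zz"], "protein_id": ["P0"]})
        with pytest.raises(ValueError, match="intersection"):
            tf.match_probes_to_proteins(exprs, bad_map, prot)


class TestConcordance:
    def _matched_identical(self, n=5):
        prot = _mats(n, seed=4)
        gene = prot.copy()
        pairs = pd.DataFrame({"probe_id": [f"g{i}" for i in range(n)]},
                             index=prot.index)
        return tf.MatchedPairs(pairs, gene, prot)

    def test_identical_profiles_give_r_one(self):
        matched = self._matched_identical()
        gc = tf.global_concordance(matched)
        assert gc["pearson"].r == pytest.approx(1.0)
        assert gc["spearman"].r == pytest.approx(1.0)
        report = tf.per_pair_concordance(matched)
        assert report.mean_r["pearson"] == pytest.approx(1.0)
        assert report.n_significant["pearson"] == len(matched.pairs)

    def test_single_pair_reduces_to_plain_correlation(self):
        prot = _mats(1, seed=5)
        rng = np.random.default_rng(6)
        gene = prot + rng.normal(0, 0.5, prot.shape)
        pairs = pd.DataFrame({"probe_id": ["g0"]}, index=prot.index)
        matched = tf.MatchedPairs(pairs, gene, prot)
        gc = tf.global_concordance(matched)
        direct = tf.correlation(gene.iloc[0], prot.iloc[0])
        assert gc["pearson"].r == pytest.approx(direct.r)

    def test_constant_profile_excluded_with_count(self):
        prot = _mats(2, seed=7)
        gene = prot.copy()
        gene.iloc[1] = 5.0  # constant gene profile: undefined correlation
        pairs = pd.DataFrame({"probe_id": ["g0", "g1"]}, index=prot.index)
        report = tf.per_pair_concordance(tf.MatchedPairs(pairs, gene, prot))
        assert report.n_undefined == 1
        assert report.mean_r["pearson"] == pytest.approx(1.0)

    def test_moderate_r_at_n6_not_significant(self):
        # r just above 0.5 at n=6 has p > 0.05, so the joint rule rejects it
        x = np.array([0.0, 1, 2, 3, 4, 5])
        zx = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
        e = np.array([1.0, -1, 1, -1, 1, -1])
        e = e - e.mean() - zx * (zx * (e - e.mean())).sum()
        ze = e / np.sqrt((e**2).sum())
        r_target = 0.55
        y = r_target * zx + np.sqrt(1 - r_target**2) * ze
        c = tf.correlation(x, y)
        assert c.r == pytest.approx(0.55, abs=1e-9)
        assert c.p > 0.05
        prot = pd.DataFrame([x], index=["P0"], columns=[f"s{i}" for i in range(6)])
        prot.index.name = "protein"
        gene = pd.DataFrame([y], index=["P0"], columns=prot.columns)
        pairs = pd.DataFrame({"probe_id": ["g0"]}, index=prot.index)
        report = tf.per_pair_concordance(tf.MatchedPairs(pairs, gene, prot))
        assert report.n_significant["pearson"] == 0

    def test_recovers_generator_latent_correlation(self):
        # many genes, many samples: mean per-pair r tracks rho (attenuated by
        # array noise); direct oracle interval computed from the construction
        rho, n_genes, n_samples = 0.6, 300, 20
        params = tf.SimParams(
            n_proteins=n_genes, frac_de=1.0, n_samples_per_group=n_samples // 2,
            peptides_per_protein=(4.0, 0.0), frac_shared_peptides=0.0,
            channel_noise_sd=0.0, peptide_efficiency_sd=0.0,
            missingness=(-np.inf, 0.0), frac_decoy=0.0, frac_contaminant=0.0,
            gene_protein_corr=rho, array_noise_sd=0.25,
            n_probes_per_gene=(1.0, 0.0), seed=23).validate()
        truth = tf.generate_ground_truth(params)
        exprs, mapping = tf.simulate_microarray(truth)
        matched = tf.match_probes_to_proteins(exprs, mapping, truth.abundance)
        report = tf.per_pair_concordance(matched)
        # independent oracle: r between rho*z + sqrt(1-rho^2)*e + noise and z
        rng = np.random.default_rng(99)
        means = []
        for _ in range(200):
            z = rng.standard_normal((n_genes, n_samples))
            z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
            g = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(z.shape) \
                + rng.normal(0, 0.25, z.shape)
            rs = [np.corrcoef(g[i], z[i])[0, 1] for i in range(n_genes)]
            means.append(np.mean(rs))
        lo, hi = np.quantile(means, [0.005, 0.995])
        # widen slightly: the pipeline profiles are two-level, not gaussian
        assert lo - 0.05 <= report.mean_r["pearson"] <= hi + 0.05


class TestOverlaps:
    def test_two_set_regions(self):
        rep = tf.overlap_sets({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert rep.regions[("A", "B")] == 2
        assert rep.regions[("A",)] == 1 and rep.regions[("B",)] == 1
        assert rep.union_size == 4

    def test_three_identical_sets(self):
        s = {"x", "y", "z"}
        rep = tf.overlap_sets({"A": set(s), "B": set(s), "C": set(s)})
        assert rep.regions[("A", "B", "C")] == 3
        assert all(rep.regions[k] == 0 for k in rep.regions
                   if len(k) < 3)

    def test_direction_counts(self):
        signs = {"A": {"x": 1.2, "y": 0.8}, "B": {"x": 0.3, "y": -0.4}}
        rep = tf.overlap_sets({"A": {"x", "y"}, "B": {"x", "y"}}, signs)
        assert rep.same_direction == 1 and rep.opposite_direction == 1

    def test_region_counts_sum_to_union_randomized(self):
        rng = np.random.default_rng(10)
        universe = [f"e{i}" for i in range(50)]
        for _ in range(200):
            k = int(rng.integers(2, 4))
            sets = {f"S{j}": {e for e in universe if rng.random() < 0.4}
                    for j in range(k)}
            rep = tf.overlap_sets(sets)
            assert sum(rep.regions.values()) == rep.union_size


class TestCrossStudy:
    def _study(self, name, seed, missing_preset=tf.tmt_like):
        params = missing_preset(n_proteins=40, seed=seed)
        truth = tf.generate_ground_truth(params)
        table = tf.simulate_peptide_table(truth)
        return tf.Study(name, table, truth.design), truth

    def test_study_vs_itself(self):
        s, _ = self._study("self", 31)
        report = tf.cross_study_compare([s, tf.Study("copy", s.peptides.copy(),
                                                     s.design)])
        pair = report["pairwise"][0]
        assert pair["shared_peptides"] == report["studies"][0]["n_peptides_retained"]
        assert pair["mean_intensity_pearson_r"] == pytest.approx(1.0)
        assert pair["peptide_length_ranksum_p"] == pytest.approx(1.0, abs=1e-9)

    def test_same_truth_different_noise_presets(self):
        params_a = tf.tmt_like(n_proteins=60, seed=41)
        truth = tf.generate_ground_truth(params_a)
        table_a = tf.simulate_peptide_table(truth)
        params_b = tf.labelfree_like(n_proteins=60, seed=43,
                                     channel_noise_sd=0.5)
        table_b = tf.simulate_peptide_table(truth, params_b)
        report = tf.cross_study_compare([
            tf.Study("tmt", table_a, truth.design),
            tf.Study("lf", table_b, truth.design)])
        pair = report["pairwise"][0]
        assert pair["mean_intensity_pearson_r"] > 0.5  # same underlying truth
        for s in report["studies"]:
            de = s["de_counts"]
            assert de["p<0.001"] <= de["p<0.01"] <= de["p<0.05"]

    def test_direction_agreement_symmetric_in_order(self):
        a, _ = self._study("a", 51)
        b, _ = self._study("b", 53)
        r1 = tf.cross_study_compare([a, b])["pairwise"][0]["de_overlap"]
        r2 = tf.cross_study_compare([b, a])["pairwise"][0]["de_overlap"]
        assert r1["same_direction"] == r2["same_direction"]
        assert r1["opposite_direction"] == r2["opposite_direction"]

    def test_fewer_than_two_studies_rejected(self):
        s, _ = self._study("solo", 61)
        with pytest.raises(ValueError, match="two studies"):
            tf.cross_study_compare([s])
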