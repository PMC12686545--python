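"""Trend DE, size factors, clustering, overlap and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import linregress
from sklearn.metrics import adjusted_rand_score

import dauerclock as dc
from dauerclock.trend import choose_elbow


class TestPrefilter:
    def test_boundary_gene_retained(self):
        counts = pd.DataFrame([[10, 10, 10, 0]], index=["g"], columns=list("abcd"))
        assert len(dc.prefilter(counts)) == 1

    def test_below_threshold_dropped(self):
        counts = pd.DataFrame([[9, 9, 9, 9]], index=["g"], columns=list("abcd"))
        with pytest.warns(UserWarning):
            out = dc.prefilter(counts)
        assert len(out) == 0

    def test_exact_count_on_toy_matrix(self):
        counts = pd.DataFrame(
            [
                [10, 10, 10, 0],  # pass: three samples at 10
                [100, 100, 5, 5],  # fail: only two samples >= 10
                [50, 60, 70, 80],  # pass
                [9, 9, 9, 9],  # fail
                [10, 11, 12, 13],  # pass
            ],
            index=[f"g{i}" for i in range(5)],
            columns=list("abcd"),
        )
        out = dc.prefilter(counts)
        assert list(out.index) == ["g0", "g2", "g4"]


class TestNormalizeCounts:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "b": [10, 20, 30]}, index=["g1", "g2", "g3"]
        )
        _, factors = dc.normalize_counts(counts)
        assert np.allclose(factors, 1.0)

    def test_doubled_sample_has_double_factor(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "b": [20, 40, 60]}, index=["g1", "g2", "g3"]
        )
        norm, factors = dc.normalize_counts(counts)
        assert factors["b"] / factors["a"] == pytest.approx(2.0)
        pd.testing.assert_series_equal(
            norm["a"], norm["b"], check_names=False
        )

    def test_factors_have_geometric_mean_one(self, timecourse):
        cfg, counts, meta, truth = timecourse
        _, factors = dc.normalize_counts(dc.prefilter(counts))
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)

    def test_all_genes_with_zero_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            dc.normalize_counts(counts)


class TestTrendTest:
    def test_noiseless_doubling_slope(self):
        """100 -> 200 -> 400 -> 800 over days 0..3 is 1 log2/day; the
        0.5 pseudocount biases the slope by < 0.5% at these magnitudes
        and not at all when disabled."""
        counts = pd.DataFrame(
            [[100.0, 200.0, 400.0, 800.0]], index=["g"], columns=list("abcd")
        )
        res = dc.trend_test(counts, [0.0, 1.0, 2.0, 3.0])
        assert res.loc["g", "slope"] == pytest.approx(1.0, abs=5e-3)
        exact = dc.trend_test(counts, [0.0, 1.0, 2.0, 3.0], pseudocount=0.0)
        assert exact.loc["g", "slope"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_gene_not_significant(self):
        counts = pd.DataFrame(
            [[50.0] * 6, [10, 80, 20, 70, 30, 60]],
            index=["flat", "noisy"],
            columns=list("abcdef"),
        )
        res = dc.trend_test(counts, [0, 0, 1, 1, 2, 2])
        assert res.loc["flat", "slope"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["flat", "direction"] == "ns"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e5), min_size=6, max_size=12))
    def test_slope_matches_ols_oracle(self, values):
        """Per-gene slope/p equal an independent OLS fit on the same
        transformed values for arbitrary inputs."""
        n = len(values)
        times = np.arange(n, dtype=float)
        counts = pd.DataFrame([values], index=["g"], columns=[f"s{i}" for i in range(n)])
        res = dc.trend_test(counts, times)
        y = np.log2(np.asarray(values) + 0.5)
        oracle = linregress(times, y)
        assert res.loc["g", "slope"] == pytest.approx(oracle.slope, abs=1e-9)
        if np.ptp(y) > 0:
            assert res.loc["g", "p"] == pytest.approx(oracle.pvalue, rel=1e-6)

    def test_requires_three_distinct_times(self):
        counts = pd.DataFrame([[1, 2, 3, 4]], index=["g"], columns=list("abcd"))
        with pytest.raises(ValueError):
            dc.trend_test(counts, [0, 0, 1, 1])

    def test_bh_q_monotone_in_p_and_bounded(self, trend_fixture):
        norm, days, truth = trend_fixture
        res = dc.trend_test(norm, days)
        ordered = res.sort_values("p")
        assert (ordered["q"].diff().dropna() >= -1e-12).all()
        assert (res["q"] <= 1.0).all()
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_direction_consistent_with_slope_and_q(self, trend_fixture):
        norm, days, truth = trend_fixture
        res = dc.trend_test(norm, days, alpha=0.05)
        up = res["direction"] == "up"
        down = res["direction"] == "down"
        assert ((res.loc[up, "q"] <= 0.05) & (res.loc[up, "slope"] > 0)).all()
        assert ((res.loc[down, "q"] <= 0.05) & (res.loc[down, "slope"] < 0)).all()

    def test_planted_effect_recovery(self, trend_fixture):
        """Sensitivity >= 0.8 at observed FDR <= 0.1 on the planted fixture."""
        norm, days, truth = trend_fixture
        res = dc.trend_test(norm, days)
        tab = truth.table.set_index("gene_id").loc[res.index]
        true_up = tab["program"] == "up"
        true_down = tab["program"] == "down"
        called_up = res["direction"] == "up"
        called_down = res["direction"] == "down"
        hits = (called_up & true_up) | (called_down & true_down)
        sens = hits.sum() / (true_up | true_down).sum()
        called = called_up | called_down
        false = called & ~hits
        fdr = false.sum() / max(int(called.sum()), 1)
        assert sens >= 0.8
        assert fdr <= 0.1

    def test_null_fixture_fdr_controlled(self, null_fixture):
        norm, days = null_fixture
        res = dc.trend_test(norm, days)
        rate = (res["q"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert rate <= 0.05 + 2 * se


class TestTwoGroupTest:
    def test_planted_shift_detected_with_sign(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(50, 500, size=30)
        a = base[:, None] * rng.lognormal(0, 0.05, size=(30, 4))
        b = a.copy()
        b[0] *= 4.0  # up in group B
        b[1] /= 4.0  # down in group B
        frame = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"g{i}" for i in range(30)],
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        res = dc.two_group_test(frame, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)])
        assert res.loc["g0", "direction"] == "up"
        assert res.loc["g1", "direction"] == "down"


class TestClustering:
    def test_wcss_non_increasing_in_k(self, archetype_profiles):
        norm, times, labels = archetype_profiles
        out = dc.cluster_profiles(norm, times, k_range=range(1, 9), seed=0)
        assert (out.wcss.diff().dropna() <= 1e-9).all()

    def test_archetype_recovery_at_k4(self, archetype_profiles):
        norm, times, labels = archetype_profiles
        out = dc.cluster_profiles(norm, times, k_range=[4], seed=0, k=4)
        ari = adjusted_rand_score(labels, out.labels.loc[norm.index])
        assert ari >= 0.9

    def test_every_gene_assigned_exactly_once(self, archetype_profiles):
        norm, times, labels = archetype_profiles
        out = dc.cluster_profiles(norm, times, k_range=[4], seed=0, k=4)
        assert sorted(out.labels.index) == sorted(norm.index)
        assert out.labels.between(1, 4).all()

    def test_single_cluster_k_range(self, archetype_profiles):
        norm, times, labels = archetype_profiles
        out = dc.cluster_profiles(norm, times, k_range=[1], seed=0)
        assert out.chosen_k == 1
        assert (out.labels == 1).all()

    def test_zero_variance_gene_excluded_with_warning(self, archetype_profiles):
        norm, times, labels = archetype_profiles
        with_flat = pd.concat(
            [norm, pd.DataFrame([[100.0] * norm.shape[1]], index=["flatgene"],
                                columns=norm.columns)]
        )
        with pytest.warns(UserWarning, match="zero variance"):
            out = dc.cluster_profiles(with_flat, times, k_range=[4], seed=0, k=4)
        assert "flatgene" not in out.labels.index

    def test_elbow_rule_on_synthetic_curve(self):
        wcss = pd.Series({1: 100.0, 2: 60.0, 3: 30.0, 4: 25.0, 5: 22.0})
        # second differences peak at k=3 (drop flattens after 3)
        assert choose_elbow(wcss) == 3

    def test_determinism_under_seed(self, archetype_profiles):
        norm, times, labels = archetype_profiles
        a = dc.cluster_profiles(norm, times, k_range=[4], seed=3, k=4)
        b = dc.cluster_profiles(norm, times, k_range=[4], seed=3, k=4)
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestExitOverlap:
    def test_identical_signed_sets(self):
        sets = {"a": {"g1": 1, "g2": -1}, "b": {"g1": 1, "g2": -1}}
        out = dc.exit_overlap(sets).set_index(["set_a", "set_b"])
        row = out.loc[("a", "b")]
        assert row["n_shared"] == 2 and row["frac_same_direction"] == 1.0

    def test_flipped_signs_give_zero_fraction(self):
        sets = {"a": {"g1": 1, "g2": -1}, "b": {"g1": -1, "g2": 1}}
        out = dc.exit_overlap(sets).set_index(["set_a", "set_b"])
        assert out.loc[("a", "b"), "frac_same_direction"] == 0.0

    def test_disjoint_sets_reported_na(self):
        sets = {"a": {"g1": 1}, "b": {"g2": 1}}
        out = dc.exit_overlap(sets).set_index(["set_a", "set_b"])
        assert out.loc[("a", "b"), "n_shared"] == 0
        assert np.isnan(out.loc[("a", "b"), "frac_same_direction"])

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        sets = {
            name: {f"g{i}": int(s) for i, s in zip(
                rng.choice(50, size=20, replace=False),
                rng.choice([-1, 1], size=20))}
            for name in ("x", "y", "z")
        }
        out = dc.exit_overlap(sets).set_index(["set_a", "set_b"])
        for a in sets:
            for b in sets:
                assert out.loc[(a, b), "n_shared"] == out.loc[(b, a), "n_shared"]
                fa = out.loc[(a, b), "frac_same_direction"]
                fb = out.loc[(b, a), "frac_same_direction"]
                assert (np.isnan(fa) and np.isnan(fb)) or fa == fb


class TestPca:
    def test_two_duplicated_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(4, 1, size=100)
        b = a * np.exp(rng.normal(0, 2, size=100))
        cols = {f"a{i}": a for i in range(3)} | {f"b{i}": b for i in range(3)}
        norm = pd.DataFrame(cols, index=[f"g{i}" for i in range(100)])
        emb = dc.pca_embed(norm, n_components=2)
        pc1 = emb.scores["PC1"].to_numpy()
        assert len(np.unique(np.sign(pc1[:3]))) == 1
        assert (np.sign(pc1[:3]) != np.sign(pc1[3:])).all()
        assert emb.explained_variance_ratio["PC1"] > 0.99

    def test_variance_fractions_sum_below_one(self, trend_fixture):
        norm, days, truth = trend_fixture
        emb = dc.pca_embed(norm, n_components=3)
        assert emb.explained_variance_ratio.sum() <= 1.0 + 1e-9

    def test_orientation_convention(self, trend_fixture):
        norm, days, truth = trend_fixture
        emb = dc.pca_embed(norm, n_components=2)
        for pc in emb.loadings:
            col = emb.loadings[pc]
            assert col.loc[col.abs().idxmax()] > 0

    def test_component_truncation_warns(self):
        norm = pd.DataFrame(
            np.random.default_rng(0).lognormal(3, 1, size=(20, 3)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abc"),
        )
        with pytest.warns(UserWarning, match="truncated"):
            emb = dc.pca_embed(norm, n_components=10)
        assert emb.scores.shape[1] == 3
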