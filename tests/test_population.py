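"""Quadrant gating, proportions, outlier removal and distance profiling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synaptoscope.population import (QuadrantGates, classify_quadrants,
                                     conditional_proportion, distance_profile,
                                     enrichment_ratio, estimate_gate,
                                     estimate_gates, frame_proportions,
                                     remove_outliers, subpop_intensity_compare)


class TestGates:
    def test_bimodal_mixture_separates_classes(self):
        mis = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            neg = rng.normal(0.0, 200.0, 250)
            pos = rng.lognormal(8.5, 0.3, 250)
            t, method = estimate_gate(np.concatenate([neg, pos]))
            assert method == "kde_valley"
            mis.append(((neg > t).sum() + (pos <= t).sum()) / 500.0)
        assert np.mean(mis) < 0.02

    def test_all_background_calls_few_positives(self):
        rng = np.random.default_rng(3)
        neg = rng.normal(0.0, 200.0, 400)
        t, method = estimate_gate(neg)
        assert method == "unimodal_fallback"
        assert (neg > t).mean() <= 0.01

    def test_manual_override(self):
        gates = estimate_gates({"intensity_ch1": np.array([1.0, 2.0, 3.0])},
                               overrides={"intensity_ch1": 42.0})
        assert gates.thresholds["intensity_ch1"] == 42.0
        assert gates.method["intensity_ch1"] == "manual_override"

    def test_too_few_events(self):
        with pytest.raises(ValueError):
            estimate_gate([1.0])


class TestClassifyQuadrants:
    def _df(self, i1, i2, frames=None):
        n = len(i1)
        return pd.DataFrame({
            "frame_id": frames if frames is not None else ["f0"] * n,
            "intensity_ch1": i1, "intensity_ch2": i2})

    def test_all_below_both_gates(self):
        df = self._df([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        counts = classify_quadrants(df, QuadrantGates(
            {"intensity_ch1": 10.0, "intensity_ch2": 10.0}))
        assert counts.loc["f0"].tolist() == [0, 0, 0, 3]

    def test_threshold_tie_is_negative(self):
        df = self._df([10.0], [10.0])
        counts = classify_quadrants(df, QuadrantGates(
            {"intensity_ch1": 10.0, "intensity_ch2": 10.0}))
        assert counts.loc["f0", "n_nn"] == 1

    def test_each_event_in_exactly_one_quadrant(self):
        rng = np.random.default_rng(4)
        df = self._df(rng.normal(size=200), rng.normal(size=200),
                      frames=rng.choice(["f0", "f1"], 200))
        counts = classify_quadrants(df, QuadrantGates(
            {"intensity_ch1": 0.0, "intensity_ch2": 0.0}))
        assert counts.sum().sum() == 200

    def test_ground_truth_quadrant_accuracy(self):
        # planted separated intensity laws: accuracy >= 98%
        rng = np.random.default_rng(5)
        n = 400
        klass = rng.choice(["pp", "pn", "np", "nn"], n)
        def draw(positive):
            return np.where(positive, rng.lognormal(8.5, 0.3, n),
                            rng.normal(0, 200, n))
        i1 = draw(np.isin(klass, ["pp", "pn"]))
        i2 = draw(np.isin(klass, ["pp", "np"]))
        df = self._df(i1, i2)
        gates = estimate_gates({"intensity_ch1": i1, "intensity_ch2": i2})
        t1, t2 = gates.thresholds["intensity_ch1"], gates.thresholds["intensity_ch2"]
        pred = np.where((i1 > t1) & (i2 > t2), "pp",
                        np.where(i1 > t1, "pn", np.where(i2 > t2, "np", "nn")))
        assert (pred == klass).mean() >= 0.98


class TestFrameProportions:
    def _counts(self, rows, index=None):
        return pd.DataFrame(rows, columns=["n_pp", "n_pn", "n_np", "n_nn"],
                            index=index or [f"f{i}" for i in range(len(rows))])

    def test_single_frame_equal_quadrants(self):
        s = frame_proportions(self._counts([[1, 1, 1, 1]]))
        assert s.frame_percentages.iloc[0].tolist() == [25.0] * 4
        assert not s.sem_defined
        assert (s.sem_pct == 0).all()

    def test_two_point_sem(self):
        s = frame_proportions(self._counts([[5, 0, 0, 0], [0, 0, 0, 7]]))
        assert s.mean_pct["pct_pp"] == 50.0
        # SD of {100, 0} is 100/sqrt(2); SEM = SD/sqrt(2) = 50
        assert s.sem_pct["pct_pp"] == pytest.approx(50.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(6)
        s = frame_proportions(self._counts(rng.integers(1, 30, size=(8, 4))))
        np.testing.assert_allclose(s.frame_percentages.sum(axis=1), 100.0,
                                   atol=1e-9)

    def test_zero_event_frame_excluded(self):
        with pytest.warns(UserWarning, match="zero events"):
            s = frame_proportions(self._counts([[1, 1, 1, 1], [0, 0, 0, 0]]))
        assert s.n_frames == 1
        assert s.excluded_frames == ["f1"]

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(7)
        counts = self._counts(rng.integers(0, 50, size=(6, 4)) + 1)
        s = frame_proportions(counts)
        direct = 100.0 * counts.to_numpy() / counts.sum(axis=1).to_numpy()[:, None]
        np.testing.assert_allclose(s.frame_percentages.to_numpy(), direct)
        np.testing.assert_allclose(s.mean_pct.to_numpy(), direct.mean(axis=0))


class TestHeadlineArithmetic:
    def test_conditional_proportion_worked_examples(self):
        assert round(conditional_proportion(29, 28)) == 51
        assert round(conditional_proportion(53, 15)) == 78
        assert conditional_proportion(0, 10) == 0.0

    def test_conditional_proportion_scale_invariance(self):
        assert conditional_proportion(29, 28) == pytest.approx(
            conditional_proportion(2.9, 2.8))

    def test_conditional_proportion_errors(self):
        with pytest.raises(ValueError):
            conditional_proportion(0, 0)

    def test_enrichment_ratio_worked_examples(self):
        assert round(enrichment_ratio(48.9, 3.9), 1) == 12.5
        assert enrichment_ratio(7.0, 7.0) == 1.0
        assert enrichment_ratio(28.6, 3.2) == pytest.approx(8.94, abs=0.005)
        with pytest.raises(ValueError):
            enrichment_ratio(10.0, 0.0)


class TestSubpopCompare:
    def test_identical_groups(self):
        x = np.arange(20.0)
        out = subpop_intensity_compare(x, x)
        assert out["ks_d"] == 0.0
        assert out["mannwhitney_p"] > 0.9

    def test_strong_shift_detected(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(5, 1, 100)
        out = subpop_intensity_compare(a, b)
        assert out["mannwhitney_p"] < 1e-10
        assert out["ks_p"] < 1e-10

    def test_mw_agrees_with_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(1.0, 1.0, 8)
        out = subpop_intensity_compare(a, b)

        def u_stat(x, y):
            return stats.mannwhitneyu(x, y, alternative="two-sided").statistic

        perm = stats.permutation_test(
            (a, b), u_stat, permutation_type="independent",
            n_resamples=20000, alternative="two-sided",
            random_state=np.random.default_rng(0))
        assert out["mannwhitney_p"] == pytest.approx(perm.pvalue, abs=0.03)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            subpop_intensity_compare([1.0], [1.0, 2.0])


class TestRemoveOutliers:
    def test_pure_normal_low_removal(self):
        removed_frac = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=1000)
            kept, removed = remove_outliers(x, q=1.0)
            removed_frac.append(len(removed) / 1000.0)
        assert max(removed_frac) <= 0.02

    def test_gross_outlier_removed(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(size=200), [10.0]])
        kept, removed = remove_outliers(x, q=1.0)
        assert 10.0 in removed
        assert len(removed) <= 3

    def test_constant_values_untouched(self):
        x = np.full(50, 3.3)
        kept, removed = remove_outliers(x)
        assert len(removed) == 0 and len(kept) == 50

    def test_small_sample_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            kept, removed = remove_outliers(np.arange(5.0))
        assert len(removed) == 0

    def test_partition_is_total(self, rng):
        x = rng.normal(size=300)
        kept, removed = remove_outliers(x)
        assert len(kept) + len(removed) == 300


class TestDistanceProfile:
    def test_single_marker_no_omnibus(self, rng):
        profiles, omni = distance_profile({"Th": rng.normal(0.2, 0.05, 100)})
        assert omni is None
        assert profiles[0].n + len(profiles[0].removed_um) == 100

    def test_ordering_and_omnibus_power(self, rng):
        near = np.abs(rng.normal(0.2, 0.1, 150))
        far = np.abs(rng.normal(0.5, 0.1, 150))
        profiles, omni = distance_profile({"near": near, "far": far})
        means = {p.marker: p.mean_um for p in profiles}
        assert means["near"] < means["far"]
        assert omni["kruskal_p"] < 1e-6
        dunn = omni["dunn"]
        assert dunn.loc[0, "p_adjusted"] < 1e-6

    def test_null_calibration(self):
        # markers drawn from one distribution: KW p approximately uniform
        rejections = 0
        reps = 120
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            groups = {f"m{i}": rng.normal(0.3, 0.1, 30) for i in range(3)}
            _, omni = distance_profile(groups)
            rejections += omni["kruskal_p"] < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 3 * se

    def test_small_marker_flagged_unfiltered(self, rng):
        profiles, _ = distance_profile({"a": rng.normal(0.3, 0.1, 5),
                                        "b": rng.normal(0.3, 0.1, 50)})
        small = next(p for p in profiles if p.marker == "a")
        assert not small.outlier_removal
        assert small.n == 5
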