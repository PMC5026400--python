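import numpy as np
import pandas as pd
import pytest

from sowmotion import errors
from sowmotion.behaviour_profiles import (
    ecdf,
    profile,
    time_budget,
    transition_frequency,
)
from sowmotion.transition_features import FEATURE_NAMES


def tf_table(rng, n, duration_scale=1.0, span=86400.0):
    """Random transition-feature table with points spread over the span."""
    return pd.DataFrame(
        {
            "point_s": np.sort(rng.uniform(0, span, n)),
            "duration_s": duration_scale * rng.gamma(4.0, 2.0, n),
            "peak_accel": 1.0 + rng.gamma(2.0, 0.5, n),
            "accel_range": rng.gamma(2.0, 0.4, n),
            "jerk": rng.gamma(2.0, 3.0, n),
            "pitch_rate": rng.gamma(2.0, 2.0, n),
            "roll_rate": rng.gamma(2.0, 5.0, n),
        }
    )


class TestTimeBudget:
    def test_half_left_half_right(self):
        budget = time_budget(["LL"] * 50 + ["RL"] * 50)
        assert budget.tolist() == [0.0, 0.0, 0.5, 0.5, 0.0]

    def test_all_standing(self):
        assert time_budget(["ST"] * 7).tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]

    def test_sums_to_one_and_permutation_invariant(self, rng):
        labels = rng.choice(["ST", "S", "LL", "RL", "SL"], 500)
        b1 = time_budget(labels)
        b2 = time_budget(rng.permutation(labels))
        assert b1.sum() == pytest.approx(1.0, abs=1e-9)
        pd.testing.assert_series_equal(b1, b2)

    def test_empty_rejected(self):
        with pytest.raises(errors.EmptyInputError):
            time_budget([])

    def test_budget_matches_truth_interval_proportions(self, sim_2h, sim_2h_frames):
        from sowmotion.posture_classification import label_frames

        ls = label_frames(sim_2h_frames, sim_2h.truth)
        budget = time_budget(ls.labels)
        durations = {}
        for s, e, lab in sim_2h.truth.posture_intervals:
            durations[lab] = durations.get(lab, 0.0) + (e - s)
        total = sum(durations.values())
        for lab, share in budget.items():
            assert share == pytest.approx(durations.get(lab, 0.0) / total, abs=0.02)


class TestTransitionFrequency:
    def test_no_transitions_all_zero(self):
        tf = transition_frequency([], 86400.0)
        assert (tf["count"] == 0).all()
        assert len(tf) == int((86400 - 7200) / 720) + 1

    def test_cluster_counted_by_covering_windows_only(self):
        # 10 transitions inside hour 5 of a 24-h span
        pts = np.linspace(5 * 3600 + 100, 6 * 3600 - 100, 10)
        tf = transition_frequency(pts, 86400.0)
        # brute-force oracle
        for center, count in zip(tf["window_center_s"], tf["count"]):
            lo, hi = center - 3600, center + 3600
            assert count == int(np.sum((pts >= lo) & (pts < hi)))
        covering = tf[(tf["window_center_s"] - 3600 <= 5 * 3600)
                      & (tf["window_center_s"] + 3600 >= 6 * 3600)]
        assert (covering["count"] == 10).all()
        outside = tf[(tf["window_center_s"] + 3600 <= 5 * 3600)
                     | (tf["window_center_s"] - 3600 >= 6 * 3600)]
        assert (outside["count"] == 0).all()

    def test_disjoint_windows_conserve_total(self, rng):
        pts = rng.uniform(0, 86400, 200)
        tf = transition_frequency(pts, 86400.0, window_s=7200.0, step_s=7200.0)
        assert tf["count"].sum() == len(pts)  # 12 disjoint windows tile the span

    def test_short_span_truncated_window(self):
        with pytest.warns(UserWarning, match="truncated"):
            tf = transition_frequency([10.0, 20.0], 100.0)
        assert len(tf) == 1 and tf["count"].iloc[0] == 2 and tf["truncated"].iloc[0]

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            transition_frequency([], 100.0, window_s=0.0)


class TestEcdf:
    def test_basic_values(self):
        F = ecdf([1.0, 2.0, 3.0])
        assert F(2.0) == pytest.approx(2 / 3)
        assert F(0.5) == 0.0
        assert F(3.0) == 1.0

    def test_monotone_right_continuous(self, rng):
        F = ecdf(rng.normal(0, 1, 200))
        xs = np.linspace(-4, 4, 500)
        vals = F(xs)
        assert np.all(np.diff(vals) >= 0)
        assert vals.min() >= 0 and vals.max() == 1.0

    def test_dkw_bound_on_uniform(self):
        rng = np.random.default_rng(5)
        u = rng.uniform(0, 1, 10_000)
        F = ecdf(u)
        xs = np.linspace(0, 1, 2001)
        assert np.max(np.abs(F(xs) - xs)) < 0.025

    def test_matches_statsmodels(self, rng):
        from statsmodels.distributions.empirical_distribution import ECDF as SmECDF

        vals = rng.gamma(2.0, 1.0, 137)
        F = ecdf(vals)
        G = SmECDF(vals)
        xs = np.concatenate([vals, rng.uniform(0, 10, 50)])
        np.testing.assert_allclose(F(xs), G(xs))

    def test_empty_rejected(self):
        with pytest.raises(errors.EmptyInputError):
            ecdf([])


class TestProfile:
    def _animals(self, rng, sizes, **kwargs):
        return {
            f"sow{k}": {
                "labels": rng.choice(["ST", "LL", "RL"], 50),
                "transition_features": tf_table(rng, n, **kwargs.get(f"sow{k}", {})),
                "span_s": 86400.0,
            }
            for k, n in enumerate(sizes)
        }

    def test_single_animal_baseline_identity(self, rng):
        animals = self._animals(rng, [40])
        prof = profile(animals)["sow0"]
        for own, base in prof.ecdf_per_feature.values():
            np.testing.assert_array_equal(own.values, base.values)

    def test_baseline_is_count_weighted_mixture(self, rng):
        animals = self._animals(rng, [30, 70])
        profs = profile(animals)
        xs = np.linspace(0, 50, 200)
        for name in FEATURE_NAMES:
            own0, base = profs["sow0"].ecdf_per_feature[name]
            own1, _ = profs["sow1"].ecdf_per_feature[name]
            mixture = (30 * own0(xs) + 70 * own1(xs)) / 100
            np.testing.assert_allclose(base(xs), mixture, atol=1e-12)

    def test_zero_transition_animal_flagged(self, rng):
        animals = self._animals(rng, [40])
        animals["empty"] = {
            "labels": np.array(["ST"] * 10),
            "transition_features": tf_table(rng, 0),
            "span_s": 86400.0,
        }
        profs = profile(animals)
        assert profs["empty"].flags and not profs["empty"].ecdf_per_feature

    def test_short_duration_sow_lies_above_baseline(self, rng):
        # one sow with systematically shorter transitions: its duration ECDF
        # dominates (lies above) the pooled baseline
        animals = self._animals(
            rng, [300, 300, 300], sow0={"duration_scale": 0.4}
        )
        profs = profile(animals)
        own, base = profs["sow0"].ecdf_per_feature["duration_s"]
        xs = np.quantile(base.values, np.linspace(0.05, 0.95, 19))
        assert np.all(own(xs) >= base(xs))
        assert own(np.median(base.values)) > base(np.median(base.values)) + 0.1

    def test_shared_distribution_converges_to_baseline(self, rng):
        animals = self._animals(rng, [5000, 5000])
        profs = profile(animals)
        own, base = profs["sow0"].ecdf_per_feature["jerk"]
        xs = np.linspace(0, 40, 400)
        assert np.max(np.abs(own(xs) - base(xs))) < 0.05

    def test_leave_one_out_baseline_excludes_self(self, rng):
        animals = self._animals(rng, [30, 50])
        profs = profile(animals, leave_one_out_baseline=True)
        own0, base0 = profs["sow0"].ecdf_per_feature["jerk"]
        own1, _ = profs["sow1"].ecdf_per_feature["jerk"]
        np.testing.assert_array_equal(base0.values, own1.values)
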