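import numpy as np
import pandas as pd
import pytest

from sowmotion import errors
from sowmotion.features import extract_features
from sowmotion.sensor_io import SignalTrace
from sowmotion.synthetic_data import SimConfig, invert_orientation, simulate
from sowmotion.transition_detection import (
    DetectionConfig,
    TransitionSegment,
    build_extended_frames,
    circular_diff_deg,
    detect_and_segment,
    detect_transition_points,
    segment_transition,
)


def make_frames(p, r=None, a=None, frame_s=2.0, t0=0.0):
    """Feature-frame DataFrame from per-frame pitch/roll arrays."""
    p = np.asarray(p, dtype=float)
    r = np.zeros_like(p) if r is None else np.asarray(r, dtype=float)
    a = np.zeros_like(p) if a is None else np.asarray(a, dtype=float)
    starts = t0 + np.arange(len(p)) * frame_s
    g = invert_orientation(p, r)
    return pd.DataFrame(
        {
            "start_s": starts,
            "end_s": starts + frame_s,
            "p": p,
            "r": r,
            "a": a,
            "gx": g[:, 0],
            "gy": g[:, 1],
            "gz": g[:, 2],
            "m_mean": np.ones_like(p),
        }
    )


def brute_force_points(ext, cfg):
    """Literal re-implementation of the detection rule: enumerate every pair,
    apply the threshold rule, require confirming neighbour pairs, collapse
    runs to the first pair's midpoint."""
    p = ext["p"].to_numpy()
    r = ext["r"].to_numpy()
    centers = ((ext["start_s"] + ext["end_s"]) / 2.0).to_numpy()
    exceed = []
    for i in range(1, len(p)):
        dp = abs(p[i] - p[i - 1])
        dr = abs(r[i] - r[i - 1])
        dr = 360 - dr if dr > 180 else dr
        exceed.append(dp > cfg.theta_p or dr > cfg.theta_r)
    confirmed = []
    for i, ex in enumerate(exceed):
        if not ex:
            confirmed.append(False)
            continue
        n_adj = sum(
            1
            for j in (i - 1, i + 1)
            if 0 <= j < len(exceed) and exceed[j]
        )
        confirmed.append(n_adj >= cfg.confirm_adjacent)
    points = []
    for i, c in enumerate(confirmed):
        if c and not (i > 0 and confirmed[i - 1]):
            points.append((centers[i] + centers[i + 1]) / 2.0)
    return np.array(points)


class TestExtendedFrames:
    def test_twelve_frames_give_four_extended(self):
        frames = make_frames(np.zeros(12))
        ext = build_extended_frames(frames, DetectionConfig())
        assert len(ext) == 4
        np.testing.assert_allclose(ext["start_s"], [0, 4, 8, 12])
        np.testing.assert_allclose(ext["end_s"], [12, 16, 20, 24])

    def test_identity_configuration(self):
        frames = make_frames(np.linspace(0, 30, 8))
        ext = build_extended_frames(frames, DetectionConfig(group_size=1, overlap_fraction=0.0))
        pd.testing.assert_frame_equal(ext, frames)

    def test_constant_orientation_preserved(self):
        frames = make_frames(np.full(20, 25.0), np.full(20, -40.0))
        ext = build_extended_frames(frames, DetectionConfig())
        np.testing.assert_allclose(ext["p"], 25.0, atol=1e-9)
        np.testing.assert_allclose(ext["r"], -40.0, atol=1e-9)

    def test_works_without_gravity_columns(self):
        frames = make_frames(np.full(12, 10.0), np.full(12, 20.0))
        bare = frames[["start_s", "end_s", "p", "r", "a"]].copy()
        ext = build_extended_frames(bare, DetectionConfig())
        np.testing.assert_allclose(ext["p"], 10.0, atol=1e-9)
        np.testing.assert_allclose(ext["r"], 20.0, atol=1e-9)

    def test_too_few_frames(self):
        with pytest.raises(errors.EmptyInputError):
            build_extended_frames(make_frames(np.zeros(3)), DetectionConfig())


class TestDetectPoints:
    def test_constant_orientation_no_points(self):
        ext = make_frames(np.full(30, 5.0), frame_s=4.0)
        assert len(detect_transition_points(ext, DetectionConfig())) == 0

    def test_pitch_ramp_single_point_matches_brute_force(self):
        # pitch ramps 0 -> 40 degrees over 8 s (two 4-s extended frames):
        # one transition, at the midpoint of the first exceeding pair
        p = np.concatenate([np.zeros(10), [20.0], np.full(10, 40.0)])
        ext = make_frames(p, frame_s=4.0)
        cfg = DetectionConfig(theta_p=10.0, theta_r=10.0, confirm_adjacent=1)
        pts = detect_transition_points(ext, cfg)
        np.testing.assert_allclose(pts, brute_force_points(ext, cfg))
        assert len(pts) == 1
        # first exceeding pair is frames 9 and 10, centred at 38 s and 42 s
        assert pts[0] == pytest.approx(40.0)

    def test_single_pair_spike_rejected(self):
        # a temporary adjustment of position: the threshold is exceeded in
        # exactly one pair while both neighbouring pairs stay stable, so the
        # confirmation rule must reject it
        p = np.zeros(20)
        p[10:] = 16.0  # step: exactly one exceeding pair
        ext = make_frames(p, frame_s=4.0)
        pts = detect_transition_points(
            ext, DetectionConfig(theta_p=15.0, confirm_adjacent=1)
        )
        assert len(pts) == 0  # no confirming neighbour pair

    def test_agrees_with_brute_force_on_random_walks(self, rng):
        cfg = DetectionConfig(theta_p=12.0, theta_r=12.0)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            p = np.clip(np.cumsum(rng.normal(0, 8, n)), -85, 85)
            r = np.clip(np.cumsum(rng.normal(0, 8, n)), -175, 175)
            ext = make_frames(p, r, frame_s=4.0)
            np.testing.assert_allclose(
                detect_transition_points(ext, cfg), brute_force_points(ext, cfg)
            )

    def test_roll_wraparound_uses_circular_difference(self):
        assert circular_diff_deg(179.0, -179.0) == pytest.approx(2.0)
        r = np.concatenate([np.full(8, 175.0), np.full(8, -175.0)])
        ext = make_frames(np.zeros(16), r, frame_s=4.0)
        assert len(detect_transition_points(ext, DetectionConfig(theta_r=15.0))) == 0

    def test_translation_equivariance(self):
        p = np.concatenate([np.zeros(10), np.linspace(0, 60, 4), np.full(10, 60.0)])
        ext0 = make_frames(p, frame_s=4.0)
        ext1 = make_frames(p, frame_s=4.0, t0=123.0)
        cfg = DetectionConfig()
        np.testing.assert_allclose(
            detect_transition_points(ext1, cfg),
            detect_transition_points(ext0, cfg) + 123.0,
        )


class TestSegmentation:
    def test_step_between_plateaus_is_tightly_bracketed(self):
        p = np.concatenate([np.zeros(50), np.full(50, 60.0)])
        frames = make_frames(p)  # step at t = 100 s
        seg = segment_transition(frames, 100.0, DetectionConfig())
        assert seg.start_s < 100.0 < seg.end_s
        assert 100.0 - seg.start_s <= 3.5 and seg.end_s - 100.0 <= 3.5
        assert not seg.truncated

    def test_linear_ramp_boundaries(self):
        # pitch 0 at t<=10, ramps to 40 during [10, 16], constant after
        edges = np.arange(0, 41, 2.0)
        p = np.interp((edges[:-1] + edges[1:]) / 2.0, [10, 16], [0, 40])
        frames = make_frames(p)
        seg = segment_transition(frames, 13.0, DetectionConfig())
        assert 8.0 <= seg.start_s <= 11.0
        assert 15.0 <= seg.end_s <= 18.0

    def test_edge_transition_is_truncated(self):
        p = np.concatenate([np.linspace(0, 60, 5), np.full(10, 60.0)])
        frames = make_frames(p)
        seg = segment_transition(frames, 2.0, DetectionConfig())
        assert seg.truncated and seg.start_s == 0.0

    def test_point_outside_coverage_rejected(self):
        frames = make_frames(np.zeros(10))
        with pytest.raises(errors.IntervalError):
            segment_transition(frames, 99.0, DetectionConfig())

    def test_segment_invariant_enforced(self):
        with pytest.raises(errors.IntervalError):
            TransitionSegment(point_s=5.0, start_s=6.0, end_s=7.0)


class TestDetectAndSegment:
    def test_planted_transitions_all_recovered(self):
        # clean geometry: only large-orientation-change moves
        pref = {
            "ST": {"LL": 0.5, "RL": 0.5},
            "S": {"LL": 0.5, "RL": 0.5},
            "LL": {"ST": 0.4, "RL": 0.3, "SL": 0.3},
            "RL": {"ST": 0.4, "LL": 0.3, "SL": 0.3},
            "SL": {"LL": 0.5, "RL": 0.5},
        }
        out = simulate(SimConfig(seed=3, duration_h=3.0, preference=pref))
        segs = detect_and_segment(out.trace)
        truth = out.truth.transition_intervals
        assert len(segs) == len(truth)
        for seg, (ts, te) in zip(segs, truth):
            assert seg.start_s <= te and seg.end_s >= ts  # overlap

    def test_motionless_trace_empty(self):
        trace = SignalTrace(np.tile([0.0, 0.0, 1.0], (60000, 1)), 100.0)
        assert detect_and_segment(trace) == []

    def test_gradual_drift_below_threshold_not_detected(self):
        # 30 degrees of pitch drift spread over 5 minutes: every
        # extended-frame pair changes far less than theta_p
        n = 30000
        p = np.linspace(0, 30, n)
        g = invert_orientation(p, np.zeros(n))
        trace = SignalTrace(g, 100.0)
        assert detect_and_segment(trace) == []

    def test_segments_sorted_and_disjoint(self, sim_2h):
        segs = detect_and_segment(sim_2h.trace)
        for a, b in zip(segs, segs[1:]):
            assert a.end_s <= b.start_s
            assert a.start_s <= a.point_s <= a.end_s


class TestThresholdMonotonicity:
    def test_detection_count_nonincreasing_in_thresholds(self, sim_2h):
        frames = extract_features(sim_2h.trace)
        counts = []
        for theta in (5.0, 10.0, 15.0, 20.0, 30.0, 45.0):
            cfg = DetectionConfig(theta_p=theta, theta_r=theta)
            ext = build_extended_frames(frames, cfg)
            counts.append(len(detect_transition_points(ext, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] > 0
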