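"""Synthetic sow-motion simulator.

Generates tri-axial accelerometer traces with exact ground-truth posture and
transition annotations, so that every pipeline stage can be tested without
animal data.  The behavioural model is a semi-Markov chain over the five
postures (truncated-exponential dwell times, next posture drawn from a fixed
preference matrix that favours stand<->lie and lie<->lie moves, as in crated
sows).  Between postures the sensor orientation follows a sigmoid in pitch
and roll over a drawn transition duration, producing the stabilisation
plateaus the segmentation search relies on.  An additive impact spike along
the post-transition gravity direction models the hind-end striking the floor
("flopping"); its amplitude is the planted *abruptness* and is the ground
truth for jerk/peak-acceleration recovery checks.

Movement jitter is band-limited (~0.8 Hz correlation, i.e. body sway rather
than white noise) and scaled per posture: standing is high-activity, lying
low-activity, which is what separates standing from sternal lying (identical
orientation).  Sitting is deliberately confusable: brief, scarce,
orientation-intermediate and with wide per-bout variability in both posture
angle and activity.  White sensor noise (MEMS noise floor) is added last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .errors import ConfigError
from .sensor_io import POSTURE_LABELS, SENSOR_RANGE_G, AnnotationTrack, SignalTrace

__all__ = ["SimConfig", "SimOutput", "simulate", "invert_orientation"]


def _default_orientations() -> dict:
    # (pitch deg, roll deg) of the mean gravity vector per posture.
    return {
        "ST": (0.0, 0.0),
        "S": (-35.0, 0.0),
        "LL": (0.0, -90.0),
        "RL": (0.0, 90.0),
        "SL": (0.0, 0.0),
    }


def _default_dwell_means() -> dict:
    return {"ST": 300.0, "S": 90.0, "LL": 1200.0, "RL": 1200.0, "SL": 600.0}


def _default_activity_sd() -> dict:
    # Within-posture movement jitter amplitude (g0); standing is restless,
    # lying nearly still.  Standing vs sternal lying differ only here.
    return {"ST": 0.12, "S": 0.035, "LL": 0.010, "RL": 0.010, "SL": 0.012}


def _default_activity_spread() -> dict:
    # Log-normal sigma of the per-bout activity multiplier: sitting bouts
    # range from nearly still to stand-like, driving its confusability.
    return {"ST": 0.15, "S": 0.6, "LL": 0.3, "RL": 0.3, "SL": 0.3}


def _default_orientation_jitter() -> dict:
    # Per-bout (pitch, roll) jitter SDs in degrees: a sow never reassumes
    # exactly the same pose.  Sitting is poorly defined and wobbles widely.
    return {"ST": (3.0, 3.0), "S": (15.0, 5.0), "LL": (3.0, 5.0), "RL": (3.0, 5.0), "SL": (3.0, 3.0)}


def _default_preference() -> dict:
    # Next-posture probabilities.  Crated sows mostly alternate between
    # standing and lying and roll between lies; direct stand<->sternal and
    # sit-adjacent moves (small orientation change) are rare.
    return {
        "ST": {"LL": 0.48, "RL": 0.48, "S": 0.02, "SL": 0.02},
        "S": {"LL": 0.47, "RL": 0.47, "ST": 0.03, "SL": 0.03},
        "LL": {"ST": 0.35, "RL": 0.25, "SL": 0.28, "S": 0.12},
        "RL": {"ST": 0.35, "LL": 0.25, "SL": 0.28, "S": 0.12},
        "SL": {"LL": 0.47, "RL": 0.47, "ST": 0.03, "S": 0.03},
    }


def _default_initial() -> dict:
    return {"ST": 0.18, "S": 0.02, "LL": 0.30, "RL": 0.30, "SL": 0.20}


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the package's study conditions."""

    seed: int = 0
    duration_h: float = 24.0
    rate_hz: float = 100.0
    animal_id: str = "sim"
    posture_orientations: dict = field(default_factory=_default_orientations)
    dwell_mean_s: dict = field(default_factory=_default_dwell_means)
    min_dwell_s: float = 45.0
    transition_duration_range_s: tuple = (8.0, 16.0)
    abruptness_range: tuple = (0.2, 2.5)
    spike_width_s: float = 0.08
    noise_sd: float = 0.005
    activity_sd: dict = field(default_factory=_default_activity_sd)
    activity_spread: dict = field(default_factory=_default_activity_spread)
    orientation_jitter_deg: dict = field(default_factory=_default_orientation_jitter)
    transition_activity_sd: float = 0.04
    jitter_corr_s: float = 0.2
    preference: dict = field(default_factory=_default_preference)
    initial_probs: dict = field(default_factory=_default_initial)
    farrowing_surge: Optional[tuple] = None  # (start_h, end_h, rate_multiplier)

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ConfigError("duration_h must be positive")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        lo, hi = self.transition_duration_range_s
        if not (0 < lo <= hi):
            raise ConfigError("transition_duration_range_s must satisfy 0 < lo <= hi")
        for post, mean in self.dwell_mean_s.items():
            if mean <= hi:
                raise ConfigError(
                    f"dwell mean for {post} ({mean}s) must exceed the longest transition ({hi}s)"
                )
        if self.farrowing_surge is not None:
            s, e, m = self.farrowing_surge
            if not (0 <= s < e) or m <= 0:
                raise ConfigError("farrowing_surge must be (start_h, end_h, multiplier>0)")


@dataclass
class SimOutput:
    """Trace plus exact ground truth for one simulated sow."""

    trace: SignalTrace
    truth: AnnotationTrack
    transition_params: pd.DataFrame  # start_s,end_s,duration_s,abruptness,from_label,to_label


def invert_orientation(pitch_deg, roll_deg) -> np.ndarray:
    """Unit gravity vector with the given pitch and roll.

    Inverse of the pitch/roll feature equations:
    ``g = (-cos p sin r, sin p, cos p cos r)``.  Accepts scalars (returns a
    (3,) vector) or equal-length arrays (returns (n, 3)).
    """
    p = np.asarray(pitch_deg, dtype=float)
    r = np.asarray(roll_deg, dtype=float)
    if np.any(np.abs(p) >= 90.0):
        raise ConfigError("pitch must lie strictly within (-90, 90) degrees")
    if np.any((r <= -180.0) | (r > 180.0)):
        raise ConfigError("roll must lie within (-180, 180] degrees")
    pr, rr = np.radians(p), np.radians(r)
    g = np.stack(
        [-np.cos(pr) * np.sin(rr), np.sin(pr), np.cos(pr) * np.cos(rr)], axis=-1
    )
    return g


def _draw_schedule(cfg: SimConfig, rng: np.random.Generator):
    """Draw the semi-Markov bout/transition schedule covering [0, T]."""
    T = cfg.duration_h * 3600.0
    surge = cfg.farrowing_surge
    labels = list(POSTURE_LABELS)
    init_p = np.array([cfg.initial_probs[l] for l in labels])
    posture = rng.choice(labels, p=init_p / init_p.sum())
    pref = {
        k: (list(v.keys()), np.array(list(v.values())) / sum(v.values()))
        for k, v in cfg.preference.items()
    }
    td_lo, td_hi = cfg.transition_duration_range_s
    ab_lo, ab_hi = cfg.abruptness_range

    bouts = []  # (label, start, end)
    trans = []  # dict rows
    t = 0.0
    while True:
        mean = cfg.dwell_mean_s[posture]
        if surge is not None and surge[0] * 3600.0 <= t < surge[1] * 3600.0:
            mean = mean / surge[2]
        dwell = max(rng.exponential(mean), cfg.min_dwell_s)
        bout_end = t + dwell
        if bout_end + td_hi >= T:
            bouts.append((posture, t, T))
            break
        nxt_labels, nxt_p = pref[posture]
        nxt = rng.choice(nxt_labels, p=nxt_p)
        td = rng.uniform(td_lo, td_hi)
        ab = rng.uniform(ab_lo, ab_hi)
        bouts.append((posture, t, bout_end))
        trans.append(
            {
                "start_s": bout_end,
                "end_s": bout_end + td,
                "duration_s": td,
                "abruptness": ab,
                "from_label": posture,
                "to_label": nxt,
            }
        )
        t = bout_end + td
        posture = nxt
    return bouts, trans


def simulate(cfg: SimConfig) -> SimOutput:
    """Run one simulation; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate_hz
    n = int(round(cfg.duration_h * 3600.0 * rate))
    bouts, trans = _draw_schedule(cfg, rng)

    # Per-bout realised orientation and activity level.
    bout_p = np.empty(len(bouts))
    bout_r = np.empty(len(bouts))
    bout_act = np.empty(len(bouts))
    for k, (label, _s, _e) in enumerate(bouts):
        p0, r0 = cfg.posture_orientations[label]
        sd_p, sd_r = cfg.orientation_jitter_deg[label]
        jp = np.clip(rng.normal(0.0, sd_p), -2.0 * sd_p, 2.0 * sd_p) if sd_p > 0 else 0.0
        jr = np.clip(rng.normal(0.0, sd_r), -2.0 * sd_r, 2.0 * sd_r) if sd_r > 0 else 0.0
        bout_p[k] = np.clip(p0 + jp, -89.0, 89.0)
        bout_r[k] = np.clip(r0 + jr, -179.0, 179.0)
        bout_act[k] = cfg.activity_sd[label] * rng.lognormal(
            0.0, cfg.activity_spread[label]
        )

    # Per-sample pitch/roll and jitter-amplitude arrays.
    p_arr = np.empty(n)
    r_arr = np.empty(n)
    act_arr = np.empty(n)
    for k, (label, s, e) in enumerate(bouts):
        i0, i1 = int(round(s * rate)), int(round(e * rate)) if e < cfg.duration_h * 3600.0 else n
        p_arr[i0:i1] = bout_p[k]
        r_arr[i0:i1] = bout_r[k]
        act_arr[i0:i1] = bout_act[k]
    for k, tr in enumerate(trans):
        i0, i1 = int(round(tr["start_s"] * rate)), int(round(tr["end_s"] * rate))
        if i1 <= i0:
            continue
        # Sigmoid ramp between bout orientations; steepness d/8 gives flat
        # tails at both ends (stabilisation plateaus).
        tt = (np.arange(i1 - i0) / rate) - tr["duration_s"] / 2.0
        w = expit(tt / (tr["duration_s"] / 8.0))
        p_arr[i0:i1] = bout_p[k] + (bout_p[k + 1] - bout_p[k]) * w
        r_arr[i0:i1] = bout_r[k] + (bout_r[k + 1] - bout_r[k]) * w
        act_arr[i0:i1] = cfg.transition_activity_sd

    g = invert_orientation(p_arr, r_arr)

    # Impact spikes along the post-transition gravity direction.
    spike = np.zeros(n)
    half = int(round(4 * cfg.spike_width_s * rate))
    for k, tr in enumerate(trans):
        c = int(round((tr["start_s"] + 0.8 * tr["duration_s"]) * rate))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        if hi <= lo:
            continue
        tt = (np.arange(lo, hi) - c) / rate
        spike[lo:hi] += tr["abruptness"] * np.exp(-0.5 * (tt / cfg.spike_width_s) ** 2)
    signal = g * (1.0 + spike)[:, None]

    # Band-limited movement jitter (body sway, ~1/(2*pi*corr) Hz bandwidth).
    corr = max(cfg.jitter_corr_s * rate, 1.0)
    jitter = gaussian_filter1d(
        rng.standard_normal((n, 3)), sigma=corr, axis=0, mode="nearest"
    )
    jitter *= np.sqrt(2.0 * corr * np.sqrt(np.pi))  # renormalise to unit SD
    signal = signal + jitter * act_arr[:, None]

    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=(n, 3))
    np.clip(signal, -SENSOR_RANGE_G, SENSOR_RANGE_G, out=signal)

    truth = AnnotationTrack(
        animal_id=cfg.animal_id,
        posture_intervals=[(s, e, label) for label, s, e in bouts],
        transition_intervals=[(tr["start_s"], tr["end_s"]) for tr in trans],
    )
    params = pd.DataFrame(
        trans,
        columns=["start_s", "end_s", "duration_s", "abruptness", "from_label", "to_label"],
    )
    trace = SignalTrace(signal, rate, animal_id=cfg.animal_id)
    return SimOutput(trace=trace, truth=truth, transition_params=params)
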