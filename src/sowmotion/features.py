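"""Static-acceleration estimation and per-frame posture features.

A tri-axial accelerometer mounted on the sow's hind end measures the sum of
gravity (the *static* component, which encodes sensor orientation) and
movement acceleration.  The static component is isolated with a first-order
recursive low-pass filter and summarised per 2-s frame by three features:

* ``p`` — pitch in degrees, ``arctan(gy / sqrt(gx^2 + gz^2))``;
* ``r`` — roll in degrees, the two-argument arctangent of ``(-gx, gz)``;
* ``a`` — activity, the population standard deviation of the per-sample
  acceleration-magnitude series within the frame.

Frames are returned as a :class:`pandas.DataFrame` with one row per frame and
columns ``start_s, end_s, p, r, a`` plus the frame-mean gravity vector
(``gx, gy, gz``) and frame-mean magnitude ``m_mean``, which downstream code
uses to recombine frames exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigError, EmptyInputError, OrientationError

__all__ = [
    "FilterConfig",
    "FrameConfig",
    "FRAME_COLUMNS",
    "estimate_static_acceleration",
    "pitch",
    "roll",
    "magnitude",
    "activity",
    "extract_features",
]

#: Columns of a feature-frame DataFrame (auxiliary columns may follow).
FRAME_COLUMNS = ["start_s", "end_s", "p", "r", "a"]


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the recursive gravity (static acceleration) filter.

    Parameters
    ----------
    alpha : float
        Weighting component in (0, 1].  Small values track gravity slowly
        and suppress movement; ``alpha=1`` passes the raw signal through.
        The default 0.01 at 100 Hz corresponds to a ~1.6 s time constant,
        slow enough to suppress gait and fast enough to follow posture
        changes.
    initial_state : str
        ``"first_sample"`` seeds the recursion with the first sample (no
        start-up transient for a stationary animal); ``"zero"`` seeds with 0.
    literal_sign : bool
        Reproduce the non-converging recursion
        ``g(t) = alpha*s(t) - (1-alpha)*g(t-1)`` for auditability.  The
        default uses the standard exponential moving average
        ``g(t) = alpha*s(t) + (1-alpha)*g(t-1)``.
    """

    alpha: float = 0.01
    initial_state: str = "first_sample"
    literal_sign: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigError(f"filter alpha must be in (0, 1], got {self.alpha}")
        if self.initial_state not in ("first_sample", "zero"):
            raise ConfigError(
                f"initial_state must be 'first_sample' or 'zero', got {self.initial_state!r}"
            )


@dataclass(frozen=True)
class FrameConfig:
    """Framing parameters: 2-s frames, i.e. 200 samples at 100 Hz."""

    frame_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.frame_seconds <= 0:
            raise ConfigError("frame_seconds must be positive")

    def frame_samples(self, rate_hz: float) -> int:
        n = int(round(self.frame_seconds * rate_hz))
        if n < 2:
            raise ConfigError(
                f"frame of {self.frame_seconds}s at {rate_hz}Hz has {n} samples (< 2)"
            )
        return n


def estimate_static_acceleration(samples: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Low-pass the raw signal to estimate per-sample gravity.

    Parameters
    ----------
    samples : (n, 3) array
        Raw acceleration in g0 units.
    cfg : FilterConfig

    Returns
    -------
    (n, 3) array of the gravity estimate, same length as the input.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3:
        raise ValueError(f"expected (n, 3) samples, got shape {s.shape}")
    if s.shape[0] == 0:
        raise EmptyInputError("cannot estimate static acceleration of an empty trace")
    a = cfg.alpha
    # g(t) - c*g(t-1) = a*s(t): one-pole IIR filter per axis.
    c = -(1.0 - a) if cfg.literal_sign else (1.0 - a)
    b_coef = np.array([a])
    a_coef = np.array([1.0, -c])
    g0 = s[0] if cfg.initial_state == "first_sample" else np.zeros(3)
    # zi such that the first output equals a*s[0] + c*g0.
    zi = (c * g0)[np.newaxis, :]
    out, _ = lfilter(b_coef, a_coef, s, axis=0, zi=zi)
    return out


def _as_triple(g) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.shape != (3,):
        raise ValueError(f"expected a gravity triple, got shape {g.shape}")
    return g


def pitch(g) -> float:
    """Pitch angle in degrees from a gravity triple.

    ``p = arctan(gy / sqrt(gx^2 + gz^2))`` in [-90, 90]; the boundary
    values are returned when the horizontal component vanishes.
    """
    gx, gy, gz = _as_triple(g)
    horiz = np.hypot(gx, gz)
    if horiz == 0.0 and gy == 0.0:
        raise OrientationError("pitch undefined for the zero gravity vector")
    return float(np.degrees(np.arctan2(gy, horiz)))


def roll(g) -> float:
    """Roll angle in degrees from a gravity triple, in (-180, 180].

    Quadrant-aware arctangent of ``(-gx, gz)``; the two-argument form is
    needed to span the full circle.
    """
    gx, _gy, gz = _as_triple(g)
    if gx == 0.0 and gz == 0.0:
        raise OrientationError("roll undefined when gx = gz = 0")
    val = float(np.degrees(np.arctan2(-gx, gz)))
    return 180.0 if val == -180.0 else val


def magnitude(samples) -> np.ndarray | float:
    """Euclidean norm of one sample triple or of each row of an (n, 3) array."""
    s = np.asarray(samples, dtype=float)
    if s.ndim == 1:
        return float(np.linalg.norm(s))
    return np.linalg.norm(s, axis=1)


def activity(frame_samples: np.ndarray) -> float:
    """Activity of one frame: population SD of the per-sample magnitudes."""
    s = np.asarray(frame_samples, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3:
        raise ValueError(f"expected (n, 3) frame, got shape {s.shape}")
    if s.shape[0] < 2:
        raise EmptyInputError("activity needs at least 2 samples")
    return float(np.std(np.linalg.norm(s, axis=1)))


def _angles_from_gravity(gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pitch/roll (degrees) from (n, 3) mean-gravity rows."""
    gx, gy, gz = gm[:, 0], gm[:, 1], gm[:, 2]
    horiz = np.hypot(gx, gz)
    if np.any((horiz == 0.0) & (gy == 0.0)):
        raise OrientationError("zero mean-gravity vector in a frame")
    p = np.degrees(np.arctan2(gy, horiz))
    # Roll is undefined on the pitch boundary; report 0 there (gx=gz=0).
    with np.errstate(invalid="ignore"):
        r = np.degrees(np.arctan2(-gx, gz))
    r = np.where(horiz == 0.0, 0.0, r)
    r = np.where(r == -180.0, 180.0, r)  # range is (-180, 180]
    return p, r


def extract_features(
    trace,
    fcfg: FilterConfig | None = None,
    wcfg: FrameConfig | None = None,
) -> pd.DataFrame:
    """Divide a trace into consecutive non-overlapping frames and featurise.

    Per frame, pitch and roll are computed from the frame-mean of the
    per-sample gravity estimate (mean-gravity-then-angle avoids angle
    wrapping), and activity from the raw samples.  A trailing partial frame
    is dropped.

    Parameters
    ----------
    trace : SignalTrace
    fcfg, wcfg : filter and framing configuration (defaults used if None).

    Returns
    -------
    pandas.DataFrame with columns ``start_s, end_s, p, r, a, gx, gy, gz,
    m_mean`` and one row per frame (frame index as the row index).
    """
    fcfg = fcfg or FilterConfig()
    wcfg = wcfg or FrameConfig()
    s = trace.samples
    rate = trace.sample_rate_hz
    L = wcfg.frame_samples(rate)
    n = s.shape[0] // L
    if n < 1:
        raise EmptyInputError(
            f"trace of {s.shape[0]} samples is shorter than one {L}-sample frame"
        )
    g = estimate_static_acceleration(s, fcfg)
    gm = g[: n * L].reshape(n, L, 3).mean(axis=1)
    p, r = _angles_from_gravity(gm)
    m = np.linalg.norm(s[: n * L], axis=1).reshape(n, L)
    a = m.std(axis=1)
    starts = np.arange(n) * (L / rate)
    return pd.DataFrame(
        {
            "start_s": starts,
            "end_s": starts + L / rate,
            "p": p,
            "r": r,
            "a": a,
            "gx": gm[:, 0],
            "gy": gm[:, 1],
            "gz": gm[:, 2],
            "m_mean": m.mean(axis=1),
        }
    )
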