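"""Run configuration: nested sections mirroring each stage's config type.

YAML layout::

    seed: 0
    log_level: INFO
    filter:   {alpha: 0.01, initial_state: first_sample, literal_sign: false}
    frame:    {frame_seconds: 2.0}
    detect:   {theta_p: 15.0, theta_r: 15.0, group_size: 6, overlap_fraction: 0.6, ...}
    classify: {grid_subsample: 1500, fit_subsample: 4000, class_weight: null}
    evaluate: {tolerance_s: 2.0}
    simulate: {duration_h: 24.0, rate_hz: 100.0, ...}

Every field is validated against its module's invariants at load time (the
dataclass ``__post_init__`` checks fire while building the sections).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .features import FilterConfig, FrameConfig
from .synthetic_data import SimConfig
from .transition_detection import DetectionConfig

__all__ = ["ClassifyConfig", "EvaluateConfig", "RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class ClassifyConfig:
    grid_subsample: int = 1500
    fit_subsample: int = 4000
    class_weight: object = None  # None or "balanced"

    def __post_init__(self) -> None:
        if self.grid_subsample < 10 or self.fit_subsample < 10:
            raise ConfigError("subsample sizes must be >= 10")


@dataclass(frozen=True)
class EvaluateConfig:
    tolerance_s: float = 2.0

    def __post_init__(self) -> None:
        if self.tolerance_s < 0:
            raise ConfigError("tolerance_s must be >= 0")


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    filter: FilterConfig = field(default_factory=FilterConfig)
    frame: FrameConfig = field(default_factory=FrameConfig)
    detect: DetectionConfig = field(default_factory=DetectionConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    simulate: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "log_level": self.log_level}
        for name in ("filter", "frame", "detect", "classify", "evaluate", "simulate"):
            section = getattr(self, name)
            d = dataclasses.asdict(section)
            out[name] = d
        return out


_SECTIONS = {
    "filter": FilterConfig,
    "frame": FrameConfig,
    "detect": DetectionConfig,
    "classify": ClassifyConfig,
    "evaluate": EvaluateConfig,
    "simulate": SimConfig,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    # YAML lists become tuples where tuples are expected.
    kwargs = {}
    for k, v in data.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML; ``overrides`` maps section -> {key: value}."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for section, kv in (overrides or {}).items():
        data.setdefault(section, {}).update(kv)
    cfg = RunConfig(
        seed=int(data.get("seed", 0)), log_level=str(data.get("log_level", "INFO"))
    )
    for name, cls in _SECTIONS.items():
        if name in data and data[name] is not None:
            section_data = dict(data[name])
            if name == "simulate":
                section_data.setdefault("seed", cfg.seed)
            setattr(cfg, name, _build(cls, section_data))
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the full configuration (for run manifests)."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
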