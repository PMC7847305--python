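"""Pipeline configuration: one YAML-serializable object holding every knob."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import defaults
from .contacts import MorphThresholds
from .synthetic import PhotometryParams, SceneParams, TraceParams

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All stage settings and the master seed for a reproducible run.

    Every decision constant (0.95/1.75 um overlap thresholds, 0.4 um bouton
    minimum, mean+2SD response rule, 5% drift limit, 10%-of-max event rule)
    defaults to the canonical value in :mod:`kisspulse.defaults`.
    """

    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["exm", "calcium", "photometry"]
    )
    scene: SceneParams = field(default_factory=SceneParams)
    traces: TraceParams = field(default_factory=TraceParams)
    photometry: PhotometryParams = field(default_factory=PhotometryParams)
    thresholds: MorphThresholds = field(default_factory=MorphThresholds)
    drift_limit: float = defaults.DRIFT_LIMIT_PCT
    se_fraction_of_max: float = defaults.SE_FRACTION_OF_MAX
    coincidence_window: float = defaults.COINCIDENCE_WINDOW_MIN

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        cfg.seed = seed
        cfg.scene = dataclasses.replace(self.scene, seed=seed)
        cfg.traces = dataclasses.replace(self.traces, seed=seed + 1)
        cfg.photometry = dataclasses.replace(self.photometry, seed=seed + 2)
        return cfg


_SUB = {
    "scene": SceneParams,
    "traces": TraceParams,
    "photometry": PhotometryParams,
    "thresholds": MorphThresholds,
}


def save_config(cfg: PipelineConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    # YAML-friendly: tuples -> lists handled by asdict already via repr? ensure plain types
    Path(path).write_text(yaml.safe_dump(_plain(data), sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    kwargs = {}
    for key, value in data.items():
        cls = _SUB.get(key)
        if cls is not None:
            value = _from_plain(cls, value)
        kwargs[key] = value
    return PipelineConfig(**kwargs)


def _from_plain(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown field {k!r} for {cls.__name__}")
        if isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
            # gap_distribution is a list of tuples; scalar tuples stay tuples
            if k == "gap_distribution":
                v = list(v)
        kwargs[k] = v
    return cls(**kwargs)
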