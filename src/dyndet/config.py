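"""YAML run configuration: schema, defaults and validation.

A run config has four blocks — ``data`` (phantom generation), ``detector``
(architecture, optimizer, loss and schedule settings), ``training`` (batch
size, split ratios, whether to oversample the training split) and
``evaluation`` (IoU thresholds) — plus a top-level ``seed``. Every field has
a documented default; unknown keys are rejected with their full key path so
typos fail fast rather than silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from dyndet.data_synth import PhantomConfig
from dyndet.detector import DetectorConfig
from dyndet.exceptions import ConfigError

__all__ = ["RunConfig", "TrainingOptions", "EvaluationOptions", "load_config"]


@dataclass(frozen=True)
class TrainingOptions:
    batch_size: int = 4
    split: tuple = (0.7, 0.15, 0.15)
    oversample: bool = True

    def validate(self):
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        if len(self.split) != 3 or abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigError(f"split must be 3 ratios summing to 1, got {self.split}")


@dataclass(frozen=True)
class EvaluationOptions:
    thresholds: tuple = (0.5, 0.75)

    def validate(self):
        if not all(0 < t < 1 for t in self.thresholds):
            raise ConfigError(f"thresholds must lie in (0, 1), got {self.thresholds}")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    data: PhantomConfig = field(default_factory=PhantomConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    training: TrainingOptions = field(default_factory=TrainingOptions)
    evaluation: EvaluationOptions = field(default_factory=EvaluationOptions)

    def validate(self):
        self.data.validate()
        self.detector.validate()
        self.training.validate()
        self.evaluation.validate()

    def to_yaml(self) -> str:
        return yaml.safe_dump(_to_plain(dataclasses.asdict(self)), sort_keys=False)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


_BLOCKS = {
    "data": PhantomConfig,
    "detector": DetectorConfig,
    "training": TrainingOptions,
    "evaluation": EvaluationOptions,
}


def _build_block(cls, values: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in values.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key: {path}.{key}")
        f = fields[key]
        if isinstance(val, list) and (f.type == "tuple" or isinstance(f.default, tuple)):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid block {path}: {exc}") from exc


def load_config(path, seed_override: int | None = None) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    kwargs = {}
    for key, val in raw.items():
        if key == "seed":
            kwargs["seed"] = int(val)
        elif key in _BLOCKS:
            if not isinstance(val, dict):
                raise ConfigError(f"block {key} must be a mapping")
            kwargs[key] = _build_block(_BLOCKS[key], val, key)
        else:
            raise ConfigError(f"unknown configuration key: {key}")
    cfg = RunConfig(**kwargs)
    if seed_override is not None:
        data = dataclasses.replace(cfg.data, seed=seed_override)
        det = dataclasses.replace(cfg.detector, seed=seed_override)
        cfg = dataclasses.replace(cfg, seed=seed_override, data=data, detector=det)
    cfg.validate()
    return cfg
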