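"""Pipeline configuration: one YAML file drives every stage.

Defaults reproduce the pipeline's printed constants: 50 Hz simulator
output, 100 ms bins, 30-frame windows, 8x8x12 spectrogram tensors, the
published layer sizes, and the 70/11/19 split.  Unknown keys are
rejected with did-you-mean suggestions; one master seed
deterministically derives every stage seed.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from kneeadl.filters import FilterSpec
from kneeadl.metrics import SplitSpec
from kneeadl.model import ModelConfig
from kneeadl.simulate import SimulationConfig
from kneeadl.spectrogram import StftParams


class ConfigError(ValueError):
    """Aggregated, human-readable configuration errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class SyncConfig:
    bin_ms: int = 100
    max_gap: int = 3
    stride: int = 30
    window_frames: int = 30


@dataclass(frozen=True)
class FiltersConfig:
    accel: FilterSpec = field(
        default_factory=lambda: FilterSpec("low_pass", 2.0, 4))
    gyro: FilterSpec = field(
        default_factory=lambda: FilterSpec("high_pass", 0.1, 2))
    per_window: bool = False   # default: filter whole segments before cutting
    spectrogram_from_raw: bool = False  # default: both branches see filtered data


@dataclass(frozen=True)
class PipelineConfig:
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    sync: SyncConfig = field(default_factory=SyncConfig)
    filters: FiltersConfig = field(default_factory=FiltersConfig)
    features: StftParams = field(default_factory=StftParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    seed: int = 42
    classes: tuple[str, ...] | None = None  # optional class restriction

    def stage_seeds(self) -> dict[str, int]:
        """Derive per-stage seeds from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return {
            "simulate": int(state[0]),
            "split": int(state[1]),
            "model": int(state[2]),
        }

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-seed every stochastic stage from a new master seed."""
        cfg = replace(self, seed=seed)
        seeds = cfg.stage_seeds()
        return replace(
            cfg,
            simulate=replace(cfg.simulate, seed=seeds["simulate"]),
            split=replace(cfg.split, seed=seeds["split"]),
            model=replace(cfg.model, seed=seeds["model"]),
        )


_SECTION_TYPES = {
    "simulate": SimulationConfig,
    "sync": SyncConfig,
    "filters": FiltersConfig,
    "features": StftParams,
    "model": ModelConfig,
    "split": SplitSpec,
}

_TUPLE_FIELDS = {"lstm_units", "lstm_dropout", "fractions", "window_shape",
                 "tensor_shape", "classes"}


def _build_section(cls, payload: dict, section: str, errors: list[str]):
    allowed = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"{section}: unknown key {key!r}{suffix}")
            continue
        if key in ("accel", "gyro") and isinstance(value, dict):
            value = _build_section(FilterSpec, value, f"{section}.{key}", errors)
            if value is None:
                continue
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def config_from_dict(payload: dict) -> PipelineConfig:
    """Build and validate a :class:`PipelineConfig` from plain data."""
    errors: list[str] = []
    if not isinstance(payload, dict):
        raise ConfigError(["top level must be a mapping"])
    kwargs = {}
    top_allowed = set(_SECTION_TYPES) | {"seed", "classes"}
    for key, value in payload.items():
        if key not in top_allowed:
            hint = difflib.get_close_matches(key, top_allowed, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown section {key!r}{suffix}")
            continue
        if key == "seed":
            kwargs["seed"] = int(value)
        elif key == "classes":
            kwargs["classes"] = tuple(value) if value is not None else None
        else:
            section = _build_section(_SECTION_TYPES[key], value or {}, key, errors)
            if section is not None:
                kwargs[key] = section
    # cross-field checks
    sync = kwargs.get("sync", SyncConfig())
    if sync.bin_ms <= 0:
        errors.append("sync.bin_ms: must be > 0")
    if sync.window_frames < 1:
        errors.append("sync.window_frames: must be >= 1")
    if sync.stride < 1:
        errors.append("sync.stride: must be >= 1")
    if errors:
        raise ConfigError(errors)
    cfg = PipelineConfig(**kwargs)
    if "seed" in payload:
        # derive stage seeds from the master, but respect explicit ones
        derived = cfg.with_seed(int(payload["seed"]))
        def explicit(section: str) -> bool:
            sect = payload.get(section)
            return isinstance(sect, dict) and "seed" in sect
        cfg = replace(
            derived,
            simulate=cfg.simulate if explicit("simulate") else derived.simulate,
            split=cfg.split if explicit("split") else derived.split,
            model=cfg.model if explicit("model") else derived.model,
        )
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, validate and normalize a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return config_from_dict(payload)


def default_config(seed: int = 42) -> PipelineConfig:
    """Shipped default configuration, re-seeded from ``seed``."""
    return PipelineConfig().with_seed(seed)


def benchmark_config(seed: int = 42) -> PipelineConfig:
    """Desk-scale benchmark configuration: defaults capped at 50 epochs."""
    cfg = PipelineConfig(
        model=ModelConfig(max_epochs=50, early_stop_patience=8),
        split=SplitSpec(group_by_recording=True),
    )
    return cfg.with_seed(seed)
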