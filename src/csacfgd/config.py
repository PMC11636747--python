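"""Experiment configuration: YAML/JSON loading, defaulting and validation.

An experiment file has optional blocks ``fractional``, ``csa``, ``step``,
``train``, ``generator``, ``augment`` plus top-level keys ``mode``,
``optimizers``, ``n_repeats``, ``output_dir`` and ``seed``.  Missing keys
fall back to the full-scale defaults; every invariant violation is reported
with its field path.  Two presets bundle coherent scales: ``paper``
(population 50, 6 x 400 iterations, 20 repeats) and ``desk`` (population 10,
1 x 50 iterations, 3 repeats) for quick runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .baselines import StepConfig
from .cuckoo import CSAConfig
from .fractional import FractionalConfig
from .head import OPTIMIZERS, TrainConfig
from .synth import AugmentConfig, GeneratorConfig

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "apply_preset",
    "PRESETS",
]

MODES = ("optimize", "train", "compare", "sweep", "generate-data")

PRESETS: dict[str, dict] = {
    "paper": {
        "n_repeats": 20,
        "train": {"epochs": 6, "iterations_per_epoch": 400, "batch_size": 32},
        "csa": {"pop_size": 50},
        "generator": {"n_per_class": 200},
    },
    "desk": {
        "n_repeats": 3,
        "train": {"epochs": 1, "iterations_per_epoch": 50, "batch_size": 32},
        "csa": {"pop_size": 10},
        "generator": {"n_per_class": 50},
    },
}


class ConfigError(ValueError):
    """Invalid experiment configuration; message lists every violation."""


@dataclass
class ExperimentConfig:
    mode: str = "compare"
    optimizers: tuple[str, ...] = ("csa", "csa-cfgd")
    n_repeats: int = 20
    output_dir: str = "results"
    seed: int = 0
    fractional: FractionalConfig = field(default_factory=FractionalConfig)
    csa: CSAConfig = field(default_factory=CSAConfig)
    step: StepConfig = field(default_factory=StepConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def to_dict(self) -> dict:
        def as_plain(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: as_plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (tuple, list)):
                return [as_plain(v) for v in obj]
            return obj

        return as_plain(self)


_BLOCKS = {
    "fractional": FractionalConfig,
    "csa": CSAConfig,
    "step": StepConfig,
    "train": TrainConfig,
    "generator": GeneratorConfig,
    "augment": AugmentConfig,
}


def _build_block(cls, data: dict, path: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    clean = {}
    for key, value in data.items():
        if key not in known:
            errors.append(f"{path}.{key}: unknown field")
            continue
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        clean[key] = value
    try:
        return cls(**clean)
    except (ValueError, TypeError) as exc:
        field_hint = path if not clean else f"{path} ({', '.join(clean)})"
        errors.append(f"{field_hint}: {exc}")
        return cls()


def _from_mapping(data: dict) -> ExperimentConfig:
    errors: list[str] = []
    data = dict(data or {})

    preset = data.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            errors.append(f"preset: unknown preset {preset!r}")
        else:
            data = _merge_preset(data, PRESETS[preset])

    kwargs: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        block = data.pop(name, {}) or {}
        if not isinstance(block, dict):
            errors.append(f"{name}: expected a mapping")
            block = {}
        kwargs[name] = _build_block(cls, block, name, errors)

    mode = data.pop("mode", "compare")
    if mode not in MODES:
        errors.append(f"mode: {mode!r} is not one of {MODES}")
    optimizers = tuple(data.pop("optimizers", ("csa", "csa-cfgd")))
    for opt in optimizers:
        if opt not in OPTIMIZERS:
            errors.append(f"optimizers: unknown optimizer {opt!r}")
    n_repeats = data.pop("n_repeats", 20)
    if not isinstance(n_repeats, int) or n_repeats < 1:
        errors.append("n_repeats: must be a positive integer")
    output_dir = data.pop("output_dir", "results")
    seed = data.pop("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
    for leftover in data:
        errors.append(f"{leftover}: unknown field")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return ExperimentConfig(
        mode=mode,
        optimizers=optimizers,
        n_repeats=n_repeats,
        output_dir=output_dir,
        seed=seed,
        **kwargs,
    )


def _merge_preset(data: dict, preset: dict) -> dict:
    merged = dict(preset)
    for key, value in data.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key] = {**merged[key], **value}
        else:
            merged[key] = value
    return merged


def apply_preset(name: str) -> ExperimentConfig:
    """Experiment config for a named preset ('paper' or 'desk')."""
    return _from_mapping({"preset": name})


def load_config(path) -> ExperimentConfig:
    """Parse, default and validate a YAML or JSON experiment file.

    An empty file yields the all-defaults configuration.  All invariant
    violations are collected and reported together as :class:`ConfigError`.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return _from_mapping(data)


def dump_config(cfg: ExperimentConfig, path) -> None:
    """Write a config back to YAML; load_config(dump) round-trips."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
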