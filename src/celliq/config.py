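"""Run configuration: YAML loading, strict validation, resolved-config dumps.

Unknown keys are rejected (fail fast); every command writes the resolved
configuration next to its outputs so any run is reproducible from the
emitted file plus its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .backbone import BackboneConfig
from .celli import CelliConfig
from .dynamics import MDConfig
from .model import LossWeights, TrainSchedule

__all__ = ["RunConfig", "ElectrostaticsConfig", "TrainingConfig",
           "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class ElectrostaticsConfig:
    boundary: str = "open"          # "open" | "ewald"
    ewald_accuracy: float = 1e-8
    splitting_width: Optional[float] = None

    def __post_init__(self):
        if self.boundary not in ("open", "ewald"):
            raise ConfigError(f"unknown boundary {self.boundary!r}")


@dataclass
class TrainingConfig:
    gamma_U: float = 1.0
    gamma_F: float = 10.0
    gamma_Q: float = 1.0
    learning_rate: float = 5e-3
    epochs: int = 40
    batch_size: int = 32
    kappa: float = 1.0
    weight_decay: float = 1e-6
    clip_norm: float = 100.0

    def weights(self) -> LossWeights:
        return LossWeights(self.gamma_U, self.gamma_F, self.gamma_Q)

    def schedule(self) -> TrainSchedule:
        return TrainSchedule(self.learning_rate, self.epochs, self.batch_size,
                             self.kappa, self.weight_decay, self.clip_norm)


@dataclass
class RunConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    celli: Optional[CelliConfig] = field(default_factory=CelliConfig)
    electrostatics: ElectrostaticsConfig = field(
        default_factory=ElectrostaticsConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    md: MDConfig = field(default_factory=MDConfig)
    seed: int = 0
    version: str = __version__


def _build(cls, mapping, section):
    if mapping is None:
        return cls()
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in section {section!r}: {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def load_config(path=None, overrides: dict = None) -> RunConfig:
    """Load a YAML run configuration; CLI overrides win over file values."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top-level config must be a mapping")
    if overrides:
        for key, val in overrides.items():
            sect, _, name = key.partition(".")
            if name:
                raw.setdefault(sect, {})[name] = val
            else:
                raw[sect] = val

    known = {"backbone", "celli", "electrostatics", "training", "md",
             "seed", "version"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    if "backbone" in raw and isinstance(raw["backbone"], dict) \
            and "species" in raw["backbone"]:
        raw["backbone"]["species"] = tuple(raw["backbone"]["species"])
    celli_raw = raw.get("celli", {})
    celli = None if celli_raw is None else _build(CelliConfig, celli_raw, "celli")
    try:
        return RunConfig(
            backbone=_build(BackboneConfig, raw.get("backbone"), "backbone"),
            celli=celli,
            electrostatics=_build(ElectrostaticsConfig,
                                  raw.get("electrostatics"), "electrostatics"),
            training=_build(TrainingConfig, raw.get("training"), "training"),
            md=_build(MDConfig, raw.get("md"), "md"),
            seed=int(raw.get("seed", 0)),
            version=str(raw.get("version", __version__)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration as YAML."""
    out = {
        "backbone": dataclasses.asdict(cfg.backbone),
        "celli": None if cfg.celli is None else dataclasses.asdict(cfg.celli),
        "electrostatics": dataclasses.asdict(cfg.electrostatics),
        "training": dataclasses.asdict(cfg.training),
        "md": dataclasses.asdict(cfg.md),
        "seed": cfg.seed,
        "version": cfg.version,
    }
    out["backbone"]["species"] = list(out["backbone"]["species"])
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
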