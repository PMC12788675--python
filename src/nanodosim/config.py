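"""Experiment configuration: schema, defaults, validation, provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from nanodosim.xsec import ConfigurationError

__all__ = ["ExperimentConfig", "load_config", "config_hash"]

_STUDY_ENERGIES = (20.0, 50.0, 100.0, 300.0, 600.0, 1000.0, 5000.0, 10000.0)


def _default_diameters() -> dict[float, float]:
    return {e: (8.0 if e < 5000.0 else 100.0) for e in _STUDY_ENERGIES}


def _default_world_radii() -> dict[float, float]:
    # 1 um world for 8 nm targets, 3 um for 100 nm targets
    return {e: (1000.0 if e < 5000.0 else 3000.0) for e in _STUDY_ENERGIES}


@dataclass
class ExperimentConfig:
    """Full-experiment parameters with study defaults."""

    energies: tuple[float, ...] = _STUDY_ENERGIES
    diameters: dict[float, float] = field(default_factory=_default_diameters)
    world_radii: dict[float, float] = field(default_factory=_default_world_radii)
    n_histories: int = 100_000
    cutoff_energy: float = 10.0
    master_seed: int = 1
    n_members: int = 7
    family_dir: str | None = None
    spread_amplitude_low: float = 0.6931471805599453
    spread_amplitude_high: float = 0.05
    spread_correlation_scale: float = 1.0
    grid_points_per_decade: int = 10
    initial_direction: str = "fixed_z"

    _KEYS = (
        "energies", "diameters", "world_radii", "n_histories", "cutoff_energy",
        "master_seed", "n_members", "family_dir", "spread_amplitude_low",
        "spread_amplitude_high", "spread_correlation_scale",
        "grid_points_per_decade", "initial_direction",
    )

    def __post_init__(self) -> None:
        self.energies = tuple(float(e) for e in self.energies)
        self.diameters = {float(k): float(v) for k, v in self.diameters.items()}
        self.world_radii = {float(k): float(v) for k, v in self.world_radii.items()}
        self.validate()

    def validate(self) -> None:
        if not self.energies:
            raise ConfigurationError("at least one energy is required")
        for e in self.energies:
            if e not in self.diameters:
                raise ConfigurationError(f"no scoring diameter configured for E = {e:g} eV")
        if self.n_histories < 1:
            raise ConfigurationError("n_histories must be >= 1")
        if self.n_members < 2 and self.family_dir is None:
            raise ConfigurationError("a synthetic family needs at least 2 members")

    def world_radius_for(self, energy: float) -> float:
        return self.world_radii.get(energy, 1000.0)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ExperimentConfig":
        unknown = set(mapping) - set(cls._KEYS)
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["energies"] = list(self.energies)
        d["diameters"] = {str(k): v for k, v in self.diameters.items()}
        d["world_radii"] = {str(k): v for k, v in self.world_radii.items()}
        return d


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    return ExperimentConfig.from_mapping(data)


def config_hash(config: ExperimentConfig) -> str:
    """Stable content hash identifying a configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
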