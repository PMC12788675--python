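"""Synthetic cross-section families and ICSD families for end-to-end testing.

The published per-code datasets are not redistributable, so this module
fabricates (a) a plausible base cross-section dataset from simple
thresholded analytic shapes and (b) families of multiplicatively perturbed
variants whose mutual spread is large at the lowest energies and shrinks
with energy, mimicking the observed inter-code behavior.  It also draws
cluster-size histogram families directly, so the statistics layer can be
exercised without any transport.

None of the shapes below is a physics claim; they only need to satisfy the
dataset invariants and produce realistic orders of magnitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from nanodosim.scoring import ClusterSizeDistribution
from nanodosim.xsec import (
    ChannelKind,
    ChannelTable,
    ConfigurationError,
    CrossSectionDataset,
    EnergyGrid,
    InteractionChannel,
    Provenance,
    ValidationError,
    write_dataset,
)

__all__ = [
    "SpreadProfile",
    "BaseModelParams",
    "default_grid",
    "base_dataset",
    "perturbed_family",
    "default_family",
    "synthetic_icsd_family",
    "write_family",
    "load_family",
]

#: (binding energy eV, magnitude eV^2 nm^2) per ionization shell;
#: sigma(E) = C ln(E/B) / (E B) above threshold.
_DEFAULT_IONIZATION = ((10.79, 6.0), (13.39, 5.0), (16.05, 4.0), (32.30, 1.5), (539.0, 0.1))

#: (excitation energy eV, magnitude nm^2, shape constant) per excitation;
#: sigma(E) = D (E/W - 1) / ((E/W)^2 + c) above threshold.
_DEFAULT_EXCITATION = ((8.22, 0.02, 1.0), (10.0, 0.015, 1.0), (11.24, 0.012, 1.0),
                       (12.61, 0.010, 1.0), (13.77, 0.008, 1.0))

#: elastic sigma(E) = a / (E (E + b)), (a eV^2 nm^2, b eV).
_DEFAULT_ELASTIC = (210.0, 15.0)


@dataclass(frozen=True)
class SpreadProfile:
    """Log-normal perturbation profile for a synthetic dataset family.

    ``amplitude_low``/``amplitude_high`` are the pointwise standard
    deviations of ln(sigma) at the 20 eV and 10 keV anchor energies; the
    amplitude interpolates linearly in log10(E) between them (clamped
    outside).  ``correlation_scale`` is the node spacing of the smooth
    random perturbation, in decades.
    """

    amplitude_low: float = math.log(2.0)
    amplitude_high: float = 0.05
    correlation_scale: float = 1.0
    seed: int = 0
    anchor_low_ev: float = 20.0
    anchor_high_ev: float = 1e4

    def __post_init__(self) -> None:
        if self.amplitude_low < 0 or self.amplitude_high < 0:
            raise ValidationError("spread amplitudes must be >= 0")
        if self.amplitude_low < self.amplitude_high:
            raise ValidationError("spread must not grow with energy (amplitude_low >= amplitude_high)")
        if self.correlation_scale <= 0:
            raise ValidationError("correlation scale must be positive")

    def amplitude(self, energy: float | np.ndarray) -> np.ndarray:
        lo = math.log10(self.anchor_low_ev)
        hi = math.log10(self.anchor_high_ev)
        t = (np.log10(np.asarray(energy, dtype=float)) - lo) / (hi - lo)
        t = np.clip(t, 0.0, 1.0)
        return self.amplitude_low + (self.amplitude_high - self.amplitude_low) * t


@dataclass(frozen=True)
class BaseModelParams:
    ionization: tuple[tuple[float, float], ...] = _DEFAULT_IONIZATION
    excitation: tuple[tuple[float, float, float], ...] = _DEFAULT_EXCITATION
    elastic: tuple[float, float] = _DEFAULT_ELASTIC

    def __post_init__(self) -> None:
        if len(self.ionization) != 5 or len(self.excitation) != 5:
            raise ValidationError("need 5 ionization and 5 excitation channel parameter sets")
        for b, c in self.ionization:
            if b <= 0 or c <= 0:
                raise ValidationError("ionization parameters must be positive")
        for w, d, c in self.excitation:
            if w <= 0 or d <= 0 or c <= 0:
                raise ValidationError("excitation parameters must be positive")
        if self.elastic[0] <= 0 or self.elastic[1] <= 0:
            raise ValidationError("elastic parameters must be positive")


def default_grid(points_per_decade: int = 10, emin: float = 8.0, emax: float = 1e6) -> EnergyGrid:
    """Log-spaced template grid (>= 9 points per decade by default)."""
    decades = math.log10(emax / emin)
    n = int(math.ceil(decades * points_per_decade))
    return EnergyGrid(np.geomspace(emin, emax, n + 1))


def base_dataset(params: BaseModelParams | None = None, grid: EnergyGrid | None = None,
                 name: str = "base") -> CrossSectionDataset:
    """Analytic stand-in dataset satisfying all template invariants."""
    params = params or BaseModelParams()
    grid = grid or default_grid()
    energies = grid.energies

    tables: list[ChannelTable] = []
    ion_e = energies[energies >= 10.0]
    ion_grid = EnergyGrid(ion_e)
    for i, (b, c) in enumerate(params.ionization, start=1):
        sigma = np.where(ion_e > b, c * np.log(np.maximum(ion_e / b, 1.0)) / (ion_e * b), 0.0)
        tables.append(ChannelTable(InteractionChannel(ChannelKind.IONIZATION, i, b), ion_grid, sigma))
    for i, (w, d, c) in enumerate(params.excitation, start=1):
        x = energies / w
        sigma = np.where(energies > w, d * (x - 1.0) / (x * x + c), 0.0)
        tables.append(ChannelTable(InteractionChannel(ChannelKind.EXCITATION, i, w), grid, sigma))
    a, b = params.elastic
    tables.append(ChannelTable(InteractionChannel(ChannelKind.ELASTIC), grid,
                               a / (energies * (energies + b))))
    return CrossSectionDataset(name, tuple(tables), Provenance.SYNTHETIC)


def _smooth_unit_noise(rng: np.random.Generator, log_e: np.ndarray,
                       scale_decades: float, lo: float, hi: float) -> np.ndarray:
    """Smooth random function of log10(E) with unit pointwise standard deviation.

    Independent standard-normal node values at ``scale_decades`` spacing are
    linearly interpolated, then renormalized by the interpolation variance
    so the pointwise s.d. is exactly 1 everywhere.
    """
    nodes = np.arange(lo - scale_decades, hi + 2 * scale_decades, scale_decades)
    z = rng.standard_normal(len(nodes))
    idx = np.clip(np.searchsorted(nodes, log_e, side="right") - 1, 0, len(nodes) - 2)
    w = (log_e - nodes[idx]) / scale_decades
    val = (1.0 - w) * z[idx] + w * z[idx + 1]
    return val / np.sqrt(w**2 + (1.0 - w) ** 2)


def perturbed_family(base: CrossSectionDataset, n_members: int = 7,
                     profile: SpreadProfile | None = None) -> list[CrossSectionDataset]:
    """Multiplicative log-normal perturbations of a base dataset.

    Member k's sigma_c(E) = base sigma_c(E) * exp(g_{k,c}(log10 E)) with g a
    smooth random function whose pointwise s.d. follows the spread profile;
    thresholds and grids are unchanged and the family is reproducible from
    the profile seed.
    """
    if n_members < 2:
        raise ConfigurationError("a family needs at least 2 members")
    profile = profile or SpreadProfile()
    rng = np.random.default_rng(profile.seed)
    lo = math.log10(min(t.grid.energies[0] for t in base.channels))
    hi = math.log10(max(t.grid.energies[-1] for t in base.channels))

    members: list[CrossSectionDataset] = []
    for k in range(n_members):
        tables: list[ChannelTable] = []
        for tab in base.channels:
            log_e = np.log10(tab.grid.energies)
            g = _smooth_unit_noise(rng, log_e, profile.correlation_scale, lo, hi)
            g = g * profile.amplitude(tab.grid.energies)
            sigma = tab.sigma * np.exp(g)
            sigma = np.where(tab.sigma == 0.0, 0.0, sigma)  # keep thresholds exact
            tables.append(ChannelTable(tab.channel, tab.grid, sigma))
        members.append(
            CrossSectionDataset(f"{base.name}-m{k + 1}", tuple(tables), Provenance.SYNTHETIC)
        )
    return members


def default_family(n_members: int = 7, seed: int = 0,
                   points_per_decade: int = 10) -> list[CrossSectionDataset]:
    """Seven-member family with the default base shapes and spread profile."""
    base = base_dataset(grid=default_grid(points_per_decade))
    return perturbed_family(base, n_members, SpreadProfile(seed=seed))


def synthetic_icsd_family(
    n_members: int,
    energy_label: float,
    mean_range: tuple[float, float],
    n_histories: int,
    seed: int = 0,
    thinning: float = 0.7,
) -> list[ClusterSizeDistribution]:
    """Directly synthesized ICSD family (binomial-thinned Poisson draws).

    Each member gets a mean drawn uniformly from ``mean_range``; cluster
    sizes are Poisson draws at mean/thinning thinned binomially, so the
    marginal is Poisson with the drawn mean.  ``energy_label`` is metadata
    only (the nominal energy the family emulates).
    """
    if n_members < 2:
        raise ConfigurationError("a family needs at least 2 members")
    lo, hi = mean_range
    if lo < 0 or hi < lo:
        raise ValidationError("mean_range must be a non-negative interval")
    if not 0 < thinning <= 1:
        raise ValidationError("thinning must be in (0, 1]")
    rng = np.random.default_rng(seed)
    family = []
    for _ in range(n_members):
        mu = float(rng.uniform(lo, hi))
        raw = rng.poisson(mu / thinning, n_histories)
        nu = rng.binomial(raw, thinning)
        family.append(ClusterSizeDistribution(np.bincount(nu), n_histories))
    return family


def write_family(family: Sequence[CrossSectionDataset], out_dir: str | Path,
                 manifest_extra: dict | None = None) -> Path:
    """One template TSV per member plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for ds in family:
        write_dataset(ds, out_dir / f"{ds.name}.tsv")
        names.append(ds.name)
    manifest = {"members": names, **(manifest_extra or {})}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def load_family(in_dir: str | Path) -> list[CrossSectionDataset]:
    """Load a family written by :func:`write_family`."""
    from nanodosim.xsec import load_dataset

    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    return [
        load_dataset(in_dir / f"{name}.tsv", name=name, provenance=Provenance.SYNTHETIC)
        for name in manifest["members"]
    ]
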