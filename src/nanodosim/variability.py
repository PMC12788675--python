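"""Inter-dataset variability: earth-mover distances, GUM dispersion, driver.

The Wasserstein-1 (earth-mover) distance between two discrete histograms is
computed as the sum of absolute cumulative differences,

    W1 = sum_i |delta_i|,   delta_0 = 0,  delta_{i+1} = delta_i + x_i - y_i.

Dispersion across datasets reports MV (mean), SD (sample standard
deviation, n-1 denominator) and RSD = SD/MV with GUM-propagated
uncertainties:

    u(SD)  = sqrt(sum_k (x_k - MV)^2 u(x_k)^2) / (n_c * SD)
    u(RSD) = sqrt(sum_k (x_k/MV - 1 - RSD^2)^2 u(x_k)^2) / (n_c * RSD * MV)
    u(MV)  = sqrt(sum_k u(x_k)^2 / n_c + SD^2 / (n_c - 1))

u(SD) and u(RSD) are implemented exactly as published even though a direct
first-order propagation would place 1/(n_c - 1) rather than 1/n_c in front;
they are reported for completeness and carry no acceptance weight.

The uncertainty of W1 uses first-order propagation treating the two
histograms as statistically independent; when one argument is the mean
over members this correlates with each member and the result overestimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from nanodosim import stats as _stats
from nanodosim.scoring import ClusterSizeDistribution, ScoringSphere, build_icsd
from nanodosim.xsec import (
    ConfigurationError,
    CrossSectionDataset,
    MaterialModel,
    ValidationError,
    average_datasets,
)

__all__ = [
    "DispersionSummary",
    "VariabilityRecord",
    "wasserstein1",
    "wasserstein1_uncertainty",
    "mean_distribution",
    "variability_record",
    "dispersion",
    "HarmonizationReport",
    "PhaseResult",
    "harmonization_experiment",
]

_NORMALIZATION_TOL = 1e-9


def _as_probabilities(dist) -> tuple[np.ndarray, np.ndarray | None, int | None]:
    """Return (probabilities, binomial u(P) or None, N or None)."""
    if isinstance(dist, ClusterSizeDistribution):
        return dist.probabilities, dist.uncertainties(), dist.n_histories
    arr = np.asarray(dist, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("distribution must be a non-empty 1-d probability list")
    if np.any(arr < 0) or abs(float(arr.sum()) - 1.0) > _NORMALIZATION_TOL:
        raise ValidationError(f"distribution is not normalized (sum = {float(arr.sum())})")
    return arr, None, None


def _padded_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = max(len(x), len(y))
    xp = np.zeros(m)
    yp = np.zeros(m)
    xp[: len(x)] = x
    yp[: len(y)] = y
    return xp, yp


def wasserstein1(x, y) -> float:
    """Earth-mover distance between two normalized histograms, in bins.

    The shorter histogram is zero-padded to the common length.
    """
    px, _, _ = _as_probabilities(x)
    py, _, _ = _as_probabilities(y)
    px, py = _padded_pair(px, py)
    delta = np.cumsum(px - py)
    return float(np.abs(delta).sum())


def wasserstein1_uncertainty(x, y, ux=None, uy=None) -> float:
    """First-order propagated u(W1) assuming independent histograms.

    ``ux``/``uy`` default to the binomial bin uncertainties when the inputs
    are :class:`ClusterSizeDistribution` objects, else to zero.
    """
    px, bux, _ = _as_probabilities(x)
    py, buy, _ = _as_probabilities(y)
    ux = np.asarray(ux, dtype=float) if ux is not None else (bux if bux is not None else np.zeros_like(px))
    uy = np.asarray(uy, dtype=float) if uy is not None else (buy if buy is not None else np.zeros_like(py))
    m = max(len(px), len(py))
    pxp, pyp = _padded_pair(px, py)
    uxp, uyp = _padded_pair(ux, uy)
    delta = np.cumsum(pxp - pyp)
    sgn = np.where(np.abs(delta) < 1e-12, 0.0, np.sign(delta))  # flat at delta ~ 0
    # dW1/dx_j = sum_{i >= j} sign(delta_i)
    tail = np.cumsum(sgn[::-1])[::-1]
    return float(math.sqrt(float(np.sum(tail**2 * (uxp**2 + uyp**2)))))


def mean_distribution(dists: Sequence) -> np.ndarray:
    """Per-bin arithmetic mean after zero-padding to the longest member."""
    if len(dists) < 2:
        raise ConfigurationError("mean distribution needs at least 2 members")
    probs = [_as_probabilities(d)[0] for d in dists]
    m = max(len(p) for p in probs)
    out = np.zeros(m)
    for p in probs:
        out[: len(p)] += p
    return out / len(probs)


def _mean_of(dist) -> float:
    p, _, _ = _as_probabilities(dist)
    return float(np.dot(np.arange(len(p), dtype=float), p))


@dataclass(frozen=True)
class VariabilityRecord:
    """Per-member W1 distances to the mean histogram plus normalized summary."""

    flavor: str
    w1: np.ndarray
    mean_w1: float
    mean_m1: float
    w1_over_m1: float

    def __post_init__(self) -> None:
        if np.any(self.w1 < 0):
            raise ValidationError("W1 distances must be >= 0")


def variability_record(dists: Sequence, flavor: str = "initial") -> VariabilityRecord:
    """W1 of each member to the per-bin mean; mean W1; and mean W1 / mean M1."""
    if len(dists) < 2:
        raise ConfigurationError("variability record needs at least 2 members")
    ref = mean_distribution(dists)
    w1 = np.array([wasserstein1(d, ref) for d in dists])
    mean_w1 = float(w1.mean())
    mean_m1 = float(np.mean([_mean_of(d) for d in dists]))
    return VariabilityRecord(flavor, w1, mean_w1, mean_m1, mean_w1 / mean_m1)


@dataclass(frozen=True)
class DispersionSummary:
    """MV / SD / RSD of per-dataset values with GUM uncertainties."""

    values: np.ndarray
    uncertainties: np.ndarray
    mv: float
    sd: float
    rsd: float
    u_mv: float
    u_sd: float
    u_rsd: float

    @property
    def n(self) -> int:
        return len(self.values)


def dispersion(values: Sequence[float], uncertainties: Sequence[float] | None = None) -> DispersionSummary:
    """Dispersion of per-dataset scalars (sample SD, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ConfigurationError("dispersion needs at least 2 values")
    u = np.zeros_like(x) if uncertainties is None else np.asarray(uncertainties, dtype=float)
    if u.shape != x.shape or np.any(u < 0):
        raise ValidationError("uncertainties must be non-negative and match values")
    n_c = len(x)
    mv = float(x.mean())
    sd = float(x.std(ddof=1))
    if mv == 0.0:
        raise ArithmeticError("MV = 0: RSD undefined")
    rsd = sd / mv
    u_mv = math.sqrt(float(np.sum(u**2)) / n_c + sd * sd / (n_c - 1))
    if sd > 0:
        u_sd = math.sqrt(float(np.sum((x - mv) ** 2 * u**2))) / (n_c * sd)
        u_rsd = math.sqrt(float(np.sum((x / mv - 1.0 - rsd * rsd) ** 2 * u**2))) / (n_c * rsd * mv)
    else:
        u_sd = 0.0
        u_rsd = 0.0
    return DispersionSummary(x, u, mv, sd, rsd, u_mv, u_sd, u_rsd)


# ---------------------------------------------------------------------------
# harmonization experiment driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseResult:
    """One phase (member or common cross sections) at one energy."""

    phase: str
    icsds: tuple[ClusterSizeDistribution, ...]
    summaries: tuple[_stats.NanodosimetricSummary, ...]
    dispersion_m1: DispersionSummary
    dispersion_f2: DispersionSummary | None
    dispersion_f3: DispersionSummary | None
    variability: VariabilityRecord


@dataclass(frozen=True)
class EnergyReport:
    energy: float
    diameter: float
    initial: PhaseResult
    final: PhaseResult
    cross_w1: np.ndarray  # per member, original vs modified


@dataclass(frozen=True)
class HarmonizationReport:
    member_names: tuple[str, ...]
    energies: tuple[float, ...]
    n_histories: int
    master_seed: int
    by_energy: Mapping[float, EnergyReport]

    def __iter__(self) -> Iterator[EnergyReport]:
        return iter(self.by_energy.values())


def _phase_dispersion(values, uncerts):
    try:
        return dispersion(values, uncerts)
    except ArithmeticError:
        return None  # e.g. F2 identically zero at 20 eV


def _run_phase(
    phase: str,
    datasets: Sequence[CrossSectionDataset],
    energy: float,
    sphere: ScoringSphere,
    material: MaterialModel,
    n_histories: int,
    master_seed: int,
    phase_id: int,
    base_config,
    record: str,
) -> PhaseResult:
    from nanodosim.transport import TransportConfig, TransportEngine, substream_rng

    icsds = []
    for k, ds in enumerate(datasets):
        seed = ((master_seed * 1_000_003 + phase_id) * 1_000_003 + k) * 1_000_003 + int(energy * 1000)
        cfg = TransportConfig(
            cutoff_energy=base_config.cutoff_energy,
            world_radius=base_config.world_radius,
            initial_direction=base_config.initial_direction,
            seed=seed,
            elastic_model=base_config.elastic_model,
            ionization_model=base_config.ionization_model,
        )
        engine = TransportEngine(ds, material, cfg)
        icsds.append(build_icsd(engine.run(energy, n_histories, record=record), sphere))
    summaries = tuple(_stats.summarize(icsd) for icsd in icsds)
    m1 = [s.m1 for s in summaries]
    u_m1 = [s.u_m1 for s in summaries]
    f2 = [s.f2 for s in summaries]
    u_f2 = [s.u_f2 for s in summaries]
    f3 = [s.f3 for s in summaries]
    u_f3 = [s.u_f3 for s in summaries]
    return PhaseResult(
        phase=phase,
        icsds=tuple(icsds),
        summaries=summaries,
        dispersion_m1=dispersion(m1, u_m1),
        dispersion_f2=_phase_dispersion(f2, u_f2) if any(v > 0 for v in f2) else None,
        dispersion_f3=_phase_dispersion(f3, u_f3) if any(v > 0 for v in f3) else None,
        variability=variability_record(icsds, flavor=phase),
    )


def harmonization_experiment(
    family: Sequence[CrossSectionDataset],
    energies: Sequence[float],
    diameter_map: Mapping[float, float],
    n_histories: int,
    config=None,
    material: MaterialModel | None = None,
    elastic_extra: Sequence[CrossSectionDataset] | None = None,
    record: str = "ionization",
) -> HarmonizationReport:
    """Run the two-phase intercomparison on a family of datasets.

    Phase "initial" transports with each member's own cross sections, phase
    "final" with their channel-wise arithmetic mean (identical dataset for
    every member; differential models as configured).  ``elastic_extra``
    optionally appends further datasets to the elastic averaging member
    list.  Per-(phase, member, energy) seeds are derived from the config
    seed, so the report is deterministic and order-independent.
    """
    from nanodosim.transport import TransportConfig

    family = list(family)
    if len(family) < 2:
        raise ConfigurationError("harmonization experiment needs at least 2 datasets")
    config = config or TransportConfig()
    material = material or MaterialModel()
    elastic_members = family + list(elastic_extra) if elastic_extra else None
    common = average_datasets(family, elastic_datasets=elastic_members)

    by_energy: dict[float, EnergyReport] = {}
    for energy in energies:
        if energy not in diameter_map:
            raise ConfigurationError(f"no scoring diameter configured for E = {energy:g} eV")
        sphere = ScoringSphere(diameter_map[energy])
        initial = _run_phase(
            "initial", family, energy, sphere, material, n_histories,
            config.seed, 0, config, record,
        )
        final = _run_phase(
            "final", [common] * len(family), energy, sphere, material, n_histories,
            config.seed, 1, config, record,
        )
        cross = np.array(
            [wasserstein1(a, b) for a, b in zip(initial.icsds, final.icsds)]
        )
        by_energy[energy] = EnergyReport(energy, sphere.diameter, initial, final, cross)

    return HarmonizationReport(
        member_names=tuple(ds.name for ds in family),
        energies=tuple(energies),
        n_histories=n_histories,
        master_seed=config.seed,
        by_energy=by_energy,
    )
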