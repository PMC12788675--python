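"""Total interaction cross-section datasets: model, I/O, interpolation, averaging.

A dataset holds total (channel-integrated) cross sections for electron
interactions in liquid water on a tabulated energy grid:

* 5 ionization shells (binding energies ``B``),
* 5 discrete electronic excitations (excitation energies ``W``),
* 1 total elastic channel.

Units are fixed throughout the package: eV for energies, nm^2 for cross
sections, nm for lengths.

The on-disk template is a tab-separated table with two header rows::

    # optional comment lines
    E_eV  ion1 .. ion5  exc1 .. exc5  elastic
    transition_eV  B1 .. B5  W1 .. W5  -
    8.0   0 ... 1.14
    ...

The first header row carries the fixed channel labels, the second the
channel transition energies (binding/excitation energies; ``-`` for
elastic).  Data rows list the kinetic energy followed by the eleven cross
sections.  Blank cells are read as 0.  Rows below 10 eV must carry zero
ionization cross sections; ionization channels are stored on the sub-grid
restricted to E >= 10 eV.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ChannelKind",
    "InteractionChannel",
    "EnergyGrid",
    "ChannelTable",
    "CrossSectionDataset",
    "MaterialModel",
    "WATER_NUMBER_DENSITY",
    "ValidationError",
    "RangeError",
    "DegenerateMediumError",
    "ConfigurationError",
    "load_dataset",
    "write_dataset",
    "interpolate_sigma",
    "sigma_at",
    "channel_probabilities",
    "ChannelProbabilities",
    "average_datasets",
    "mean_free_path",
    "IONIZATION_GRID_FLOOR_EV",
]

#: Liquid water molecular number density, molecules / nm^3
#: (rho = 1.0 g/cm^3, M = 18.0153 g/mol).
WATER_NUMBER_DENSITY = 33.43

#: Ionization tables start at or above this energy; the liquid-water
#: ionization threshold slightly exceeds 10 eV.
IONIZATION_GRID_FLOOR_EV = 10.0

N_IONIZATION_CHANNELS = 5
N_EXCITATION_CHANNELS = 5


class ValidationError(ValueError):
    """A dataset or file violates a structural invariant."""


class RangeError(ValueError):
    """Requested energy lies outside a channel's tabulated span."""


class DegenerateMediumError(ValueError):
    """Total cross section vanished where an interaction was required."""


class ConfigurationError(ValueError):
    """Invalid operation configuration (e.g. empty member list)."""


class ChannelKind(str, Enum):
    IONIZATION = "ionization"
    EXCITATION = "excitation"
    ELASTIC = "elastic"


@dataclass(frozen=True)
class InteractionChannel:
    """One interaction channel of the water molecule.

    ``transition_energy`` is the binding energy B for ionization shells and
    the excitation energy W for electronic excitations; the elastic channel
    carries none.
    """

    kind: ChannelKind
    index: int | None = None
    transition_energy: float | None = None

    def __post_init__(self) -> None:
        if self.kind is ChannelKind.ELASTIC:
            if self.index is not None or self.transition_energy is not None:
                raise ValidationError("elastic channel carries no index or transition energy")
        else:
            if self.index is None or not 1 <= self.index <= 5:
                raise ValidationError(f"{self.kind.value} channel index must be in 1..5, got {self.index}")
            if self.transition_energy is None or self.transition_energy <= 0:
                raise ValidationError(
                    f"{self.kind.value} channel {self.index} needs a positive transition energy"
                )

    @property
    def label(self) -> str:
        if self.kind is ChannelKind.ELASTIC:
            return "elastic"
        prefix = "ion" if self.kind is ChannelKind.IONIZATION else "exc"
        return f"{prefix}{self.index}"

    @property
    def key(self) -> tuple[str, int | None]:
        return (self.kind.value, self.index)


class EnergyGrid:
    """Strictly increasing grid of kinetic energies (eV)."""

    __slots__ = ("_energies",)

    def __init__(self, energies: Sequence[float] | np.ndarray):
        arr = np.asarray(energies, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValidationError("energy grid needs at least 2 points")
        if not np.all(np.isfinite(arr)) or arr[0] <= 0:
            raise ValidationError("energy grid values must be finite and positive")
        if not np.all(np.diff(arr) > 0):
            bad = int(np.flatnonzero(np.diff(arr) <= 0)[0]) + 1
            raise ValidationError(f"energy grid not strictly increasing at row {bad}")
        arr.setflags(write=False)
        self._energies = arr

    @property
    def energies(self) -> np.ndarray:
        return self._energies

    @property
    def span(self) -> tuple[float, float]:
        return float(self._energies[0]), float(self._energies[-1])

    def points_per_decade(self) -> float:
        lo, hi = self.span
        return (len(self) - 1) / math.log10(hi / lo)

    def __len__(self) -> int:
        return len(self._energies)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EnergyGrid) and np.array_equal(self._energies, other._energies)

    def __repr__(self) -> str:
        lo, hi = self.span
        return f"EnergyGrid({len(self)} points, {lo:g}..{hi:g} eV)"


@dataclass(frozen=True)
class ChannelTable:
    """Tabulated total cross section sigma(E) of one channel."""

    channel: InteractionChannel
    grid: EnergyGrid
    sigma: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigma, dtype=float)
        sig.setflags(write=False)
        object.__setattr__(self, "sigma", sig)
        if sig.shape != self.grid.energies.shape:
            raise ValidationError(
                f"channel {self.channel.label}: sigma length {sig.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(sig)) or np.any(sig < 0):
            bad = int(np.flatnonzero(~np.isfinite(sig) | (sig < 0))[0])
            raise ValidationError(f"channel {self.channel.label}: negative or non-finite sigma at row {bad}")
        if self.channel.kind is ChannelKind.IONIZATION:
            below = self.grid.energies <= self.channel.transition_energy
            if np.any(sig[below] != 0.0):
                bad = int(np.flatnonzero(below & (sig != 0.0))[0])
                raise ValidationError(
                    f"channel {self.channel.label}: sigma > 0 at E = {self.grid.energies[bad]:g} eV "
                    f"below binding energy {self.channel.transition_energy:g} eV (row {bad})"
                )


class Provenance(str, Enum):
    ORIGINAL = "original"
    COMMON = "common"
    SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class CrossSectionDataset:
    """A named collection of channel tables (one dataset = one 'code')."""

    name: str
    channels: tuple[ChannelTable, ...]
    provenance: Provenance = Provenance.ORIGINAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "provenance", Provenance(self.provenance))
        counts = {kind: 0 for kind in ChannelKind}
        seen: set[tuple[str, int | None]] = set()
        for tab in self.channels:
            counts[tab.channel.kind] += 1
            if tab.channel.key in seen:
                raise ValidationError(f"duplicate channel {tab.channel.label}")
            seen.add(tab.channel.key)
        if counts[ChannelKind.IONIZATION] != N_IONIZATION_CHANNELS:
            raise ValidationError(f"expected {N_IONIZATION_CHANNELS} ionization channels, got {counts[ChannelKind.IONIZATION]}")
        if counts[ChannelKind.EXCITATION] != N_EXCITATION_CHANNELS:
            raise ValidationError(f"expected {N_EXCITATION_CHANNELS} excitation channels, got {counts[ChannelKind.EXCITATION]}")
        if counts[ChannelKind.ELASTIC] != 1:
            raise ValidationError("expected exactly one elastic channel")

    def table(self, channel: InteractionChannel) -> ChannelTable:
        return self.table_for(channel.kind, channel.index)

    def table_for(self, kind: ChannelKind, index: int | None = None) -> ChannelTable:
        for tab in self.channels:
            if tab.channel.kind is kind and tab.channel.index == index:
                return tab
        raise KeyError(f"no channel ({kind.value}, {index}) in dataset {self.name!r}")

    @property
    def elastic(self) -> ChannelTable:
        return self.table_for(ChannelKind.ELASTIC)

    def inelastic_tables(self) -> list[ChannelTable]:
        return [t for t in self.channels if t.channel.kind is not ChannelKind.ELASTIC]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossSectionDataset):
            return NotImplemented
        if self.name != other.name or self.provenance != other.provenance:
            return False
        if len(self.channels) != len(other.channels):
            return False
        for a, b in zip(self.channels, other.channels):
            if a.channel != b.channel or a.grid != b.grid or not np.array_equal(a.sigma, b.sigma):
                return False
        return True


@dataclass(frozen=True)
class MaterialModel:
    """Homogeneous medium defined by its molecular number density (nm^-3)."""

    number_density: float = WATER_NUMBER_DENSITY

    def __post_init__(self) -> None:
        if not self.number_density > 0:
            raise ValidationError("number density must be positive")


# ---------------------------------------------------------------------------
# template I/O
# ---------------------------------------------------------------------------

_TEMPLATE_LABELS = (
    ["E_eV"]
    + [f"ion{i}" for i in range(1, 6)]
    + [f"exc{i}" for i in range(1, 6)]
    + ["elastic"]
)


def _parse_cell(cell: str, row: int, col: str) -> float:
    cell = cell.strip()
    if cell == "":
        return 0.0
    try:
        return float(cell)
    except ValueError as exc:
        raise ValidationError(f"row {row}, column {col}: cannot parse {cell!r}") from exc


def load_dataset(path: str | Path, name: str | None = None,
                 provenance: Provenance | str = Provenance.ORIGINAL) -> CrossSectionDataset:
    """Read a cross-section dataset from the TSV template.

    Violated invariants (missing columns, non-monotone grid, negative sigma,
    sigma > 0 below an ionization threshold) raise :class:`ValidationError`
    naming the offending row and channel; nothing is silently repaired.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with path.open(newline="") as fh:
        for raw in csv.reader(fh, delimiter="\t"):
            if not raw or (raw[0].lstrip().startswith("#")):
                continue
            rows.append(raw)
    if len(rows) < 3:
        raise ValidationError(f"{path}: need 2 header rows and at least 1 data row")
    labels = [c.strip() for c in rows[0]]
    if labels != _TEMPLATE_LABELS:
        raise ValidationError(
            f"{path}: header labels {labels} do not match template {_TEMPLATE_LABELS}"
        )
    trans_row = rows[1]
    if len(trans_row) != 12 or trans_row[0].strip() != "transition_eV":
        raise ValidationError(f"{path}: second header row must start with 'transition_eV' and have 12 columns")
    transition = []
    for i, cell in enumerate(trans_row[1:11], start=1):
        transition.append(_parse_cell(cell, 2, _TEMPLATE_LABELS[i]))

    data = np.empty((len(rows) - 2, 12), dtype=float)
    for r, raw in enumerate(rows[2:], start=3):
        if len(raw) != 12:
            raise ValidationError(f"{path}: row {r} has {len(raw)} columns, expected 12")
        for c, cell in enumerate(raw):
            data[r - 3, c] = _parse_cell(cell, r, _TEMPLATE_LABELS[c])

    energies = data[:, 0]
    grid = EnergyGrid(energies)  # validates monotonicity

    channels: list[ChannelTable] = []
    ion_mask = energies >= IONIZATION_GRID_FLOOR_EV
    if not np.any(ion_mask):
        raise ValidationError(f"{path}: grid contains no points at or above {IONIZATION_GRID_FLOOR_EV} eV")
    for i in range(5):
        col = data[:, 1 + i]
        if np.any(col[~ion_mask] != 0.0):
            bad = int(np.flatnonzero(~ion_mask & (col != 0.0))[0]) + 3
            raise ValidationError(
                f"{path}: channel ion{i + 1}: sigma > 0 at row {bad} below the "
                f"{IONIZATION_GRID_FLOOR_EV:g} eV ionization grid floor"
            )
        ch = InteractionChannel(ChannelKind.IONIZATION, i + 1, transition[i])
        channels.append(ChannelTable(ch, EnergyGrid(energies[ion_mask]), col[ion_mask]))
    for i in range(5):
        ch = InteractionChannel(ChannelKind.EXCITATION, i + 1, transition[5 + i])
        channels.append(ChannelTable(ch, grid, data[:, 6 + i]))
    channels.append(ChannelTable(InteractionChannel(ChannelKind.ELASTIC), grid, data[:, 11]))

    return CrossSectionDataset(name or path.stem, tuple(channels), Provenance(provenance))


def write_dataset(ds: CrossSectionDataset, path: str | Path) -> None:
    """Write a dataset in the TSV template (inverse of :func:`load_dataset`).

    All channels must live on sub-grids of a common union grid; grid points
    missing from an inelastic channel's table must lie below its first
    tabulated point (they are written as 0).
    """
    path = Path(path)
    union = ds.elastic.grid.energies
    for tab in ds.inelastic_tables():
        union = np.union1d(union, tab.grid.energies)

    columns: list[np.ndarray] = []
    order: list[ChannelTable] = [
        *(ds.table_for(ChannelKind.IONIZATION, i) for i in range(1, 6)),
        *(ds.table_for(ChannelKind.EXCITATION, i) for i in range(1, 6)),
        ds.elastic,
    ]
    for tab in order:
        col = np.zeros_like(union)
        idx = np.searchsorted(union, tab.grid.energies)
        if not np.array_equal(union[idx], tab.grid.energies):
            raise ValidationError(f"channel {tab.channel.label}: grid is not aligned with the union grid")
        col[idx] = tab.sigma
        missing = np.setdiff1d(union, tab.grid.energies)
        if missing.size and (tab.channel.kind is ChannelKind.ELASTIC or missing.max() > tab.grid.energies[0]):
            raise ValidationError(
                f"channel {tab.channel.label}: cannot serialize, grid misses interior union points"
            )
        columns.append(col)

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TEMPLATE_LABELS)
        writer.writerow(
            ["transition_eV"]
            + [f"{t.channel.transition_energy:.17g}" for t in order[:10]]
            + ["-"]
        )
        for j, e in enumerate(union):
            writer.writerow([f"{e:.17g}"] + [f"{col[j]:.17g}" for col in columns])


# ---------------------------------------------------------------------------
# interpolation and channel probabilities
# ---------------------------------------------------------------------------

def _interp_segment(e1: float, s1: float, e2: float, s2: float, e: float, mode: str) -> float:
    if mode == "linear" or s1 <= 0.0 or s2 <= 0.0:
        # log-log is undefined across zero values (thresholds); fall back
        return s1 + (s2 - s1) * (e - e1) / (e2 - e1)
    t = math.log(e / e1) / math.log(e2 / e1)
    return math.exp(math.log(s1) + t * (math.log(s2) - math.log(s1)))


def interpolate_sigma(ds: CrossSectionDataset, channel: InteractionChannel, energy: float,
                      mode: str = "log-log") -> float:
    """Interpolate the tabulated sigma(E) of one channel. Extrapolation is forbidden."""
    if mode not in ("log-log", "linear"):
        raise ConfigurationError(f"unknown interpolation mode {mode!r}")
    tab = ds.table(channel)
    grid = tab.grid.energies
    if not grid[0] <= energy <= grid[-1]:
        raise RangeError(
            f"channel {channel.label}: E = {energy:g} eV outside tabulated span "
            f"[{grid[0]:g}, {grid[-1]:g}] eV"
        )
    j = int(np.searchsorted(grid, energy))
    if j < len(grid) and grid[j] == energy:
        return float(tab.sigma[j])
    return _interp_segment(grid[j - 1], float(tab.sigma[j - 1]), grid[j], float(tab.sigma[j]), energy, mode)


def sigma_at(ds: CrossSectionDataset, channel: InteractionChannel, energy: float,
             mode: str = "log-log") -> float:
    """Like :func:`interpolate_sigma` but closed inelastic channels contribute 0.

    An inelastic channel is closed below its tabulated span and at or below
    its transition energy (interpolation across the threshold node must not
    leak probability into the closed region).
    """
    tab = ds.table(channel)
    if channel.kind is not ChannelKind.ELASTIC:
        if energy < tab.grid.energies[0]:
            return 0.0
        if channel.transition_energy is not None and energy <= channel.transition_energy:
            return 0.0
    return interpolate_sigma(ds, channel, energy, mode)


class ChannelProbabilities(NamedTuple):
    probabilities: dict[InteractionChannel, float]
    sigma_total: float
    sigma_inelastic: float


def channel_probabilities(ds: CrossSectionDataset, energy: float,
                          mode: str = "log-log") -> ChannelProbabilities:
    """Relative interaction probabilities sigma_c / sigma_tot at ``energy``."""
    sigmas: dict[InteractionChannel, float] = {}
    for tab in ds.channels:
        sigmas[tab.channel] = sigma_at(ds, tab.channel, energy, mode)
    total = math.fsum(sigmas.values())
    if total <= 0.0:
        raise DegenerateMediumError(f"total cross section vanishes at E = {energy:g} eV")
    inel = math.fsum(s for ch, s in sigmas.items() if ch.kind is not ChannelKind.ELASTIC)
    probs = {ch: s / total for ch, s in sigmas.items()}
    return ChannelProbabilities(probs, total, inel)


def mean_free_path(ds: CrossSectionDataset, material: MaterialModel, energy: float,
                   mode: str = "log-log") -> float:
    """Mean free path lambda = 1 / (n * sigma_tot), in nm."""
    cp = channel_probabilities(ds, energy, mode)
    return 1.0 / (material.number_density * cp.sigma_total)


# ---------------------------------------------------------------------------
# averaging ("common" dataset construction)
# ---------------------------------------------------------------------------

def _overlap_union_grid(tables: Sequence[ChannelTable]) -> EnergyGrid:
    lo = max(t.grid.energies[0] for t in tables)
    hi = min(t.grid.energies[-1] for t in tables)
    if not lo < hi:
        raise ConfigurationError("member grids do not overlap")
    union = tables[0].grid.energies
    for t in tables[1:]:
        union = np.union1d(union, t.grid.energies)
    union = union[(union >= lo) & (union <= hi)]
    return EnergyGrid(union)


def average_datasets(datasets: Sequence[CrossSectionDataset],
                     target_grid: EnergyGrid | None = None,
                     elastic_datasets: Sequence[CrossSectionDataset] | None = None,
                     name: str = "common",
                     mode: str = "log-log") -> CrossSectionDataset:
    """Channel-wise unweighted arithmetic mean of member datasets.

    The member list for the elastic channel may differ from the inelastic
    one (``elastic_datasets``); by default the same members are used for
    every channel kind.  Each channel is averaged on ``target_grid`` if
    given, otherwise on the union of the member grids restricted to their
    common overlap.  The averaged channel keeps the smallest member
    transition energy so that the below-threshold zero invariant holds.
    """
    datasets = list(datasets)
    if len(datasets) < 2:
        raise ConfigurationError("averaging needs at least 2 member datasets")
    elastic_members = list(datasets if elastic_datasets is None else elastic_datasets)
    if not elastic_members:
        raise ConfigurationError("empty member list for the elastic channel")

    out: list[ChannelTable] = []
    for kind, indices, members in (
        (ChannelKind.IONIZATION, range(1, 6), datasets),
        (ChannelKind.EXCITATION, range(1, 6), datasets),
        (ChannelKind.ELASTIC, (None,), elastic_members),
    ):
        for index in indices:
            tables = [m.table_for(kind, index) for m in members]
            grid = target_grid if target_grid is not None else _overlap_union_grid(tables)
            if kind is ChannelKind.IONIZATION:
                gridE = grid.energies[grid.energies >= IONIZATION_GRID_FLOOR_EV]
                grid = EnergyGrid(gridE)
            values = np.empty(len(grid))
            for j, e in enumerate(grid.energies):
                values[j] = math.fsum(sigma_at(m, t.channel, float(e), mode)
                                      for m, t in zip(members, tables)) / len(members)
            if kind is ChannelKind.ELASTIC:
                channel = InteractionChannel(ChannelKind.ELASTIC)
            else:
                thr = min(t.channel.transition_energy for t in tables)
                channel = InteractionChannel(kind, index, thr)
                if kind is ChannelKind.IONIZATION:
                    values[grid.energies <= thr] = 0.0
            out.append(ChannelTable(channel, grid, values))

    return CrossSectionDataset(name, tuple(out), Provenance.COMMON)
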