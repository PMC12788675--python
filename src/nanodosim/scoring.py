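"""Reduce simulated tracks to ionization cluster size distributions (ICSDs).

The cluster size nu of one primary history is the number of ionization
events whose interaction point lies strictly inside the centered scoring
sphere (boundary rule: |r| < d/2).  Excitation and elastic events are never
counted.  ICSDs are stored as raw per-size counts plus the number of
histories N so that every downstream uncertainty can be recomputed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from nanodosim.transport import Track

__all__ = [
    "ScoringSphere",
    "ClusterSizeDistribution",
    "count_ionizations",
    "build_icsd",
    "merge_icsds",
    "read_icsd",
    "write_icsd",
]


@dataclass(frozen=True)
class ScoringSphere:
    """Scoring sphere centered at the origin; 8 or 100 nm diameter in the study."""

    diameter: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("sphere diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


class ClusterSizeDistribution:
    """Normalized histogram P_nu of ionization counts with history count N."""

    __slots__ = ("_counts", "_n")

    def __init__(self, counts: Iterable[int] | np.ndarray, n_histories: int):
        arr = np.asarray(counts)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("counts must be a non-empty 1-d sequence")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=1e-9):
                raise ValueError("counts must be integers")
            arr = rounded.astype(np.int64)
        arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError(f"negative count at nu = {int(np.flatnonzero(arr < 0)[0])}")
        if n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if int(arr.sum()) != int(n_histories):
            raise ValueError(f"counts sum to {int(arr.sum())}, expected N = {n_histories}")
        # trim trailing zero bins so nu_max indexes the largest populated size
        last = int(np.max(np.flatnonzero(arr))) if np.any(arr) else 0
        arr = arr[: last + 1].copy()
        arr.setflags(write=False)
        self._counts = arr
        self._n = int(n_histories)

    @property
    def counts(self) -> np.ndarray:
        return self._counts

    @property
    def n_histories(self) -> int:
        return self._n

    @property
    def probabilities(self) -> np.ndarray:
        return self._counts / self._n

    @property
    def nu_max(self) -> int:
        return len(self._counts) - 1

    def uncertainties(self) -> np.ndarray:
        """Binomial one-sigma uncertainty of each P_nu: sqrt(P(1-P)/N)."""
        p = self.probabilities
        return np.sqrt(p * (1.0 - p) / self._n)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ClusterSizeDistribution)
            and self._n == other._n
            and np.array_equal(self._counts, other._counts)
        )

    def __repr__(self) -> str:
        return f"ClusterSizeDistribution(nu_max={self.nu_max}, N={self._n})"


def count_ionizations(track: "Track", sphere: ScoringSphere) -> int:
    """Number of ionization events strictly inside the sphere."""
    pos = track.ionization_positions
    if pos.size == 0:
        return 0
    r2 = np.einsum("ij,ij->i", pos, pos)
    return int(np.count_nonzero(r2 < sphere.radius**2))


def build_icsd(tracks: Iterable["Track"], sphere: ScoringSphere) -> ClusterSizeDistribution:
    """Histogram per-history cluster sizes over a stream of tracks."""
    sizes = [count_ionizations(t, sphere) for t in tracks]
    if not sizes:
        raise ValueError("build_icsd needs at least one track")
    counts = np.bincount(sizes)
    return ClusterSizeDistribution(counts, len(sizes))


def merge_icsds(a: ClusterSizeDistribution, b: ClusterSizeDistribution) -> ClusterSizeDistribution:
    """ICSD of the concatenated track sets (count additivity)."""
    m = max(len(a), len(b))
    counts = np.zeros(m, dtype=np.int64)
    counts[: len(a)] += a.counts
    counts[: len(b)] += b.counts
    return ClusterSizeDistribution(counts, a.n_histories + b.n_histories)


def write_icsd(icsd: ClusterSizeDistribution, path: str | Path) -> None:
    """Write an ICSD as TSV with columns [nu, count, P, u(P)]."""
    path = Path(path)
    p = icsd.probabilities
    u = icsd.uncertainties()
    with path.open("w", newline="") as fh:
        fh.write(f"# n_histories\t{icsd.n_histories}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["nu", "count", "P", "u_P"])
        for nu in range(len(icsd)):
            writer.writerow([nu, int(icsd.counts[nu]), f"{p[nu]:.17g}", f"{u[nu]:.17g}"])


def read_icsd(path: str | Path) -> ClusterSizeDistribution:
    """Read an ICSD TSV; validates normalization and the stored u(P) column."""
    path = Path(path)
    n_histories = None
    rows: list[list[str]] = []
    with path.open(newline="") as fh:
        for raw in csv.reader(fh, delimiter="\t"):
            if not raw:
                continue
            if raw[0].startswith("#"):
                if raw[0].strip("# ").startswith("n_histories"):
                    n_histories = int(raw[1])
                continue
            rows.append(raw)
    if n_histories is None:
        raise ValueError(f"{path}: missing '# n_histories' header")
    if not rows or rows[0][:2] != ["nu", "count"]:
        raise ValueError(f"{path}: missing column header row")
    counts = np.zeros(len(rows) - 1, dtype=np.int64)
    stored_p = np.zeros(len(rows) - 1)
    stored_u = np.zeros(len(rows) - 1)
    for i, raw in enumerate(rows[1:]):
        if len(raw) != 4:
            raise ValueError(f"{path}: malformed row {i}")
        nu, count = int(raw[0]), int(raw[1])
        if nu != i:
            raise ValueError(f"{path}: rows must list nu = 0..nu_max contiguously (row {i})")
        if count < 0:
            raise ValueError(f"{path}: negative count at nu = {nu}")
        counts[i] = count
        stored_p[i] = float(raw[2])
        stored_u[i] = float(raw[3])
    icsd = ClusterSizeDistribution(counts, n_histories)
    if not np.allclose(stored_p, icsd.probabilities, atol=1e-12, rtol=0.0):
        raise ValueError(f"{path}: stored P column inconsistent with counts/N")
    if not np.allclose(stored_u, icsd.uncertainties(), atol=1e-12, rtol=0.0):
        raise ValueError(f"{path}: stored u(P) column inconsistent with binomial recomputation")
    if abs(float(icsd.probabilities.sum()) - 1.0) > 1e-12:
        raise ValueError(f"{path}: probabilities do not sum to 1")
    return icsd
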