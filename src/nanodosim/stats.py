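"""Nanodosimetric quantities of an ICSD and their statistical uncertainties.

Moments M_k = sum_nu nu^k P_nu, complementary cumulative probabilities
F_k = sum_{nu>=k} P_nu, binomial one-sigma uncertainties for probabilities
u(x) = sqrt(x (1-x) / N), and the propagated moment uncertainty
u(M1) = sqrt((M2 - M1^2) / N).  Reported uncertainties are one standard
deviation (coverage factor 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from nanodosim.scoring import ClusterSizeDistribution

__all__ = [
    "NanodosimetricSummary",
    "moment",
    "cumulative",
    "u_binomial",
    "u_mean_cluster",
    "summarize",
]


def moment(icsd: ClusterSizeDistribution, k: int) -> float:
    """k-th raw moment M_k of the cluster-size distribution."""
    if k < 1:
        raise ValueError("moment order k must be >= 1")
    nu = np.arange(len(icsd), dtype=float)
    return float(np.dot(nu**k, icsd.probabilities))


def cumulative(icsd: ClusterSizeDistribution, k: int) -> float:
    """Complementary cumulative probability F_k = P(nu >= k)."""
    if k < 1:
        raise ValueError("cumulative order k must be >= 1")
    if k > icsd.nu_max:
        return 0.0
    return float(icsd.probabilities[k:].sum())


def u_binomial(x: float, n_histories: int) -> float:
    """Binomial sampling uncertainty sqrt(x (1-x) / N) of a probability."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"probability {x} outside [0, 1]")
    if n_histories < 1:
        raise ValueError("N must be >= 1")
    return math.sqrt(x * (1.0 - x) / n_histories)


def u_mean_cluster(icsd: ClusterSizeDistribution) -> float:
    """Propagated uncertainty of M1: sqrt((M2 - M1^2) / N)."""
    n = icsd.n_histories
    if n < 2:
        raise ValueError("u(M1) needs N >= 2")
    m1 = moment(icsd, 1)
    m2 = moment(icsd, 2)
    var = m2 - m1 * m1
    if var < -1e-9 * max(1.0, m2):
        raise ArithmeticError(f"M2 - M1^2 = {var} negative beyond rounding")
    return math.sqrt(max(0.0, var) / n)


@dataclass(frozen=True)
class NanodosimetricSummary:
    """M1, M2, F2, F3 with one-sigma uncertainties for one ICSD."""

    m1: float
    m2: float
    f2: float
    f3: float
    u_m1: float
    u_f2: float
    u_f3: float
    n_histories: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.f3 <= self.f2 <= 1.0:
            raise ValueError("need 0 <= F3 <= F2 <= 1")
        if min(self.u_m1, self.u_f2, self.u_f3) < 0:
            raise ValueError("uncertainties must be >= 0")


def summarize(icsd: ClusterSizeDistribution) -> NanodosimetricSummary:
    """Compute the standard summary of one ICSD."""
    n = icsd.n_histories
    f2 = cumulative(icsd, 2)
    f3 = cumulative(icsd, 3)
    return NanodosimetricSummary(
        m1=moment(icsd, 1),
        m2=moment(icsd, 2),
        f2=f2,
        f3=f3,
        u_m1=u_mean_cluster(icsd),
        u_f2=u_binomial(f2, n),
        u_f3=u_binomial(f3, n),
        n_histories=n,
    )
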