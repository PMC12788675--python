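"""Published benchmark values from a seven-code nanodosimetric intercomparison.

These per-code nanodosimetric quantities (with one-sigma uncertainties) for
monoenergetic electrons in liquid-water spheres were published by a
multi-laboratory comparison of seven track-structure codes, each run once
with its original total interaction cross sections ("original") and once
with a channel-wise averaged common dataset ("modified").  They serve as
desk-scale validation inputs for the statistics and variability layers:
feeding the printed per-code values through :func:`nanodosim.variability.dispersion`
and the two-bin earth-mover construction must reproduce the printed
MV/SD/RSD and mean-W1 summary cells.

All simulations behind these numbers used N = 100,000 primary electrons;
sphere diameters were 8 nm below 5 keV and 100 nm at 5 and 10 keV.
"""

from __future__ import annotations

__all__ = [
    "CODES",
    "N_HISTORIES",
    "ORIGINAL_M1",
    "ORIGINAL_F2",
    "MODIFIED_M1",
    "MODIFIED_F2",
    "ORIGINAL_SUMMARY",
    "ORIGINAL_F2_SUMMARY",
    "MODIFIED_SUMMARY",
    "MODIFIED_F2_SUMMARY",
    "MEAN_W1_ORIGINAL",
    "MEAN_W1_MODIFIED",
]

CODES = ("G4DNA-2", "G4DNA-4", "G4DNA-6", "PARTRAC", "MCwater", "PTra", "PHITS")

N_HISTORIES = 100_000

# Per-code mean ionization number M1 (value, one-sigma u), original cross
# sections; energies in eV, code order as in CODES.
ORIGINAL_M1: dict[float, tuple[tuple[float, float], ...]] = {
    20.0: ((0.7680, 0.0013), (0.4370, 0.0016), (0.8330, 0.0012), (0.2080, 0.0013),
           (0.2970, 0.0014), (0.6220, 0.0015), (0.4550, 0.0016)),
    50.0: ((2.206, 0.002), (1.771, 0.002), (2.429, 0.002), (1.212, 0.002),
           (1.419, 0.002), (1.8426, 0.0020), (1.9027, 0.0016)),
    100.0: ((4.303, 0.004), (3.648, 0.004), (4.829, 0.003), (2.808, 0.003),
            (3.167, 0.003), (3.723, 0.003), (4.093, 0.002)),
    300.0: ((5.344, 0.013), (4.545, 0.011), (6.655, 0.015), (4.437, 0.010),
            (5.215, 0.012), (5.015, 0.012), (6.040, 0.012)),
    600.0: ((2.905, 0.010), (2.541, 0.009), (3.587, 0.011), (2.498, 0.008),
            (2.989, 0.010), (2.768, 0.009), (3.759, 0.011)),
    1000.0: ((1.826, 0.007), (1.668, 0.007), (2.261, 0.008), (1.572, 0.006),
             (1.873, 0.007), (1.761, 0.007), (2.198, 0.007)),
    5000.0: ((7.119, 0.017), (6.575, 0.016), (8.112, 0.017), (6.470, 0.016),
             (6.500, 0.016), (6.529, 0.016), (7.304, 0.013)),
    10000.0: ((4.024, 0.014), (3.976, 0.013), (4.532, 0.014), (3.606, 0.013),
              (3.709, 0.013), (3.593, 0.012), (4.063, 0.011)),
}

# Per-code probability of >= 2 ionizations F2, original cross sections.
# 20 eV is absent: that energy produces at most one ionization, so F2 = 0.
ORIGINAL_F2: dict[float, tuple[tuple[float, float], ...]] = {
    50.0: ((0.8893, 0.0010), (0.6859, 0.0015), (0.9332, 0.0008), (0.3140, 0.0015),
           (0.4401, 0.0016), (0.7408, 0.0014), (0.8202, 0.0012)),
    100.0: ((0.9621, 0.0006), (0.9506, 0.0007), (0.9886, 0.0003), (0.9151, 0.0009),
            (0.9549, 0.0007), (0.9633, 0.0006), (0.9961, 0.0002)),
    300.0: ((0.8140, 0.0012), (0.7807, 0.0013), (0.8861, 0.0010), (0.8124, 0.0012),
            (0.8184, 0.0012), (0.8154, 0.0012), (0.9245, 0.0008)),
    600.0: ((0.5900, 0.0016), (0.5550, 0.0016), (0.6840, 0.0015), (0.5650, 0.0016),
            (0.5920, 0.0016), (0.5830, 0.0016), (0.7494, 0.0014)),
    1000.0: ((0.4170, 0.0016), (0.3930, 0.0015), (0.5020, 0.0016), (0.3810, 0.0015),
             (0.4280, 0.0016), (0.4090, 0.0016), (0.5380, 0.0016)),
    5000.0: ((0.9033, 0.0009), (0.9016, 0.0009), (0.9541, 0.0007), (0.9018, 0.0009),
             (0.8906, 0.0010), (0.9082, 0.0009), (0.9768, 0.0005)),
    10000.0: ((0.6880, 0.0015), (0.7100, 0.0014), (0.7745, 0.0013), (0.6660, 0.0015),
              (0.6720, 0.0015), (0.6750, 0.0015), (0.8246, 0.0012)),
}

# Per-code M1 with the common (channel-wise averaged) cross sections.
MODIFIED_M1: dict[float, tuple[tuple[float, float], ...]] = {
    20.0: ((0.5975, 0.0016), (0.6123, 0.0015), (0.6088, 0.0015), (0.6208, 0.0015),
           (0.6035, 0.0015), (0.6085, 0.0015), (0.6223, 0.0015)),
    50.0: ((1.824, 0.002), (1.836, 0.002), (1.936, 0.002), (1.857, 0.002),
           (1.696, 0.003), (1.760, 0.002), (1.973, 0.002)),
    100.0: ((3.751, 0.003), (3.701, 0.004), (3.882, 0.004), (3.826, 0.003),
            (3.376, 0.004), (3.473, 0.004), (4.002, 0.004)),
    300.0: ((5.710, 0.012), (5.258, 0.012), (5.235, 0.013), (5.257, 0.012),
            (5.465, 0.012), (4.577, 0.011), (5.150, 0.012)),
    600.0: ((3.374, 0.010), (3.234, 0.009), (2.841, 0.008), (2.856, 0.010),
            (3.376, 0.011), (2.503, 0.009), (3.641, 0.012)),
    1000.0: ((2.308, 0.008), (2.290, 0.007), (2.040, 0.007), (1.793, 0.007),
             (2.288, 0.008), (1.575, 0.006), (2.111, 0.008)),
    5000.0: ((7.208, 0.016), (7.285, 0.016), (6.364, 0.014), (7.103, 0.017),
             (7.614, 0.017), (6.073, 0.015), (7.316, 0.015)),
    10000.0: ((4.344, 0.013), (4.352, 0.013), (3.908, 0.012), (4.045, 0.014),
              (4.587, 0.014), (3.402, 0.012), (4.143, 0.013)),
}

# Per-code F2 with the common cross sections.
MODIFIED_F2: dict[float, tuple[tuple[float, float], ...]] = {
    50.0: ((0.7021, 0.0014), (0.6982, 0.0015), (0.7398, 0.0014), (0.7186, 0.0014),
           (0.6152, 0.0015), (0.6809, 0.0015), (0.7657, 0.0013)),
    100.0: ((0.9703, 0.0005), (0.9614, 0.0006), (0.9630, 0.0006), (0.9760, 0.0005),
            (0.8985, 0.0010), (0.9449, 0.0007), (0.9729, 0.0005)),
    300.0: ((0.8688, 0.0011), (0.8528, 0.0011), (0.8138, 0.0012), (0.8151, 0.0012),
            (0.8350, 0.0012), (0.7911, 0.0013), (0.8410, 0.0012)),
    600.0: ((0.6780, 0.0015), (0.6779, 0.0015), (0.6447, 0.0015), (0.5846, 0.0016),
            (0.6454, 0.0015), (0.5486, 0.0016), (0.6621, 0.0015)),
    1000.0: ((0.5238, 0.0016), (0.5262, 0.0016), (0.4966, 0.0016), (0.4155, 0.0016),
             (0.5058, 0.0016), (0.3735, 0.0015), (0.4654, 0.0016)),
    5000.0: ((0.9329, 0.0008), (0.9345, 0.0008), (0.9278, 0.0008), (0.9059, 0.0009),
             (0.9246, 0.0008), (0.8902, 0.0010), (0.9459, 0.0007)),
    10000.0: ((0.7706, 0.0013), (0.7764, 0.0013), (0.7615, 0.0013), (0.6934, 0.0015),
              (0.7568, 0.0014), (0.6554, 0.0015), (0.7565, 0.0014)),
}

# Printed summary cells (MV, SD, RSD) per energy, for cross-checks.
ORIGINAL_SUMMARY: dict[float, tuple[float, float, float]] = {
    20.0: (0.52, 0.2338, 0.4521),
    50.0: (1.83, 0.4202, 0.2301),
    100.0: (3.8, 0.6846, 0.1804),
    300.0: (5.3, 0.794, 0.1493),
    600.0: (3.0, 0.491, 0.1633),
    1000.0: (1.88, 0.259, 0.1380),
    5000.0: (6.9, 0.613, 0.0883),
    10000.0: (3.93, 0.331, 0.0843),
}

ORIGINAL_F2_SUMMARY: dict[float, tuple[float, float, float]] = {
    50.0: (0.69, 0.2317, 0.3363),
    100.0: (0.962, 0.0266, 0.0277),
    300.0: (0.84, 0.0503, 0.0602),
    600.0: (0.62, 0.0720, 0.1167),
    1000.0: (0.44, 0.0588, 0.1342),
    5000.0: (0.919, 0.0325, 0.0353),
    10000.0: (0.72, 0.0608, 0.0849),
}

MODIFIED_SUMMARY: dict[float, tuple[float, float, float]] = {
    20.0: (0.611, 0.0089, 0.0145),
    50.0: (1.84, 0.0953, 0.0518),
    100.0: (3.72, 0.2224, 0.0599),
    300.0: (5.24, 0.346, 0.0661),
    600.0: (3.12, 0.396, 0.1271),
    1000.0: (2.06, 0.281, 0.1368),
    5000.0: (7.0, 0.559, 0.0800),
    10000.0: (4.11, 0.385, 0.0936),
}

MODIFIED_F2_SUMMARY: dict[float, tuple[float, float, float]] = {
    50.0: (0.703, 0.0479, 0.0681),
    100.0: (0.955, 0.0271, 0.0283),
    300.0: (0.831, 0.0263, 0.0317),
    600.0: (0.63, 0.0494, 0.0778),
    1000.0: (0.47, 0.0582, 0.1231),
    5000.0: (0.923, 0.0189, 0.0205),
    10000.0: (0.739, 0.0458, 0.0620),
}

# Published mean W1 to the mean histogram and its M1-normalized value,
# per energy: (mean W1, mean W1 / mean M1).
MEAN_W1_ORIGINAL: dict[float, tuple[float, float]] = {
    20.0: (0.19, 0.37), 50.0: (0.35, 0.19), 100.0: (0.56, 0.15), 300.0: (0.66, 0.12),
    600.0: (0.39, 0.13), 1000.0: (0.23, 0.12), 5000.0: (0.70, 0.103), 10000.0: (0.40, 0.103),
}

MEAN_W1_MODIFIED: dict[float, tuple[float, float]] = {
    20.0: (0.007, 0.011), 50.0: (0.08, 0.045), 100.0: (0.18, 0.049), 300.0: (0.32, 0.061),
    600.0: (0.37, 0.12), 1000.0: (0.26, 0.13), 5000.0: (0.62, 0.09), 10000.0: (0.40, 0.10),
}


def two_bin_icsd(m1: float) -> tuple[float, float]:
    """At 20 eV only 0 or 1 ionizations occur, so an ICSD is {1 - M1, M1}."""
    if not 0.0 <= m1 <= 1.0:
        raise ValueError("a two-bin construction needs 0 <= M1 <= 1")
    return (1.0 - m1, m1)
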