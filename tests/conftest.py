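import numpy as np
import pytest

from nanodosim.scoring import ClusterSizeDistribution
from nanodosim.synthetic import base_dataset, default_grid
from nanodosim.xsec import (
    ChannelKind,
    ChannelTable,
    CrossSectionDataset,
    EnergyGrid,
    InteractionChannel,
    MaterialModel,
)

TEMPLATE_HEADER = (
    "E_eV\tion1\tion2\tion3\tion4\tion5\texc1\texc2\texc3\texc4\texc5\telastic\n"
    "transition_eV\t10.79\t13.39\t16.05\t32.3\t539\t8.22\t10\t11.24\t12.61\t13.77\t-\n"
)


def make_toy_file(path, rows=None):
    """Three-row template file with simple hand-checkable values."""
    if rows is None:
        rows = [
            "8\t0\t0\t0\t0\t0\t0.01\t0\t0\t0\t0\t1.0",
            "100\t0.02\t0.015\t0.01\t0.004\t0\t0.005\t0.004\t0.003\t0.002\t0.001\t0.1",
            "1000\t0.004\t0.003\t0.002\t0.001\t0.0005\t0.001\t0.0008\t0.0006\t0.0004\t0.0002\t0.01",
        ]
    path.write_text(TEMPLATE_HEADER + "\n".join(rows) + "\n")
    return path


def random_dataset(rng, name="random", n_grid=12):
    """Structurally valid dataset with random positive cross sections."""
    energies = np.geomspace(8.0, 1e6, n_grid)
    ion_e = energies[energies >= 10.0]
    tables = []
    bindings = [10.79, 13.39, 16.05, 32.30, 539.0]
    for i, b in enumerate(bindings, start=1):
        sigma = rng.uniform(0.001, 0.1, len(ion_e))
        sigma[ion_e <= b] = 0.0
        tables.append(
            ChannelTable(InteractionChannel(ChannelKind.IONIZATION, i, b), EnergyGrid(ion_e), sigma)
        )
    for i, w in enumerate([8.22, 10.0, 11.24, 12.61, 13.77], start=1):
        tables.append(
            ChannelTable(
                InteractionChannel(ChannelKind.EXCITATION, i, w),
                EnergyGrid(energies),
                rng.uniform(0.001, 0.05, len(energies)),
            )
        )
    tables.append(
        ChannelTable(
            InteractionChannel(ChannelKind.ELASTIC),
            EnergyGrid(energies),
            rng.uniform(0.01, 1.0, len(energies)),
        )
    )
    return CrossSectionDataset(name, tuple(tables))


def random_icsd(rng, n_bins=None, n_histories=1000):
    n_bins = n_bins or rng.integers(2, 9)
    counts = rng.multinomial(n_histories, rng.dirichlet(np.ones(n_bins)))
    return ClusterSizeDistribution(counts, n_histories)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_file(tmp_path):
    return make_toy_file(tmp_path / "toy.tsv")


@pytest.fixture
def material():
    return MaterialModel()


@pytest.fixture(scope="session")
def base_ds():
    return base_dataset(grid=default_grid(10))
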