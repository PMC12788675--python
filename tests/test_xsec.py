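import math

import numpy as np
import pytest

from nanodosim import xsec
from nanodosim.xsec import (
    ChannelKind,
    ChannelTable,
    ConfigurationError,
    CrossSectionDataset,
    DegenerateMediumError,
    EnergyGrid,
    InteractionChannel,
    MaterialModel,
    RangeError,
    ValidationError,
    average_datasets,
    channel_probabilities,
    interpolate_sigma,
    load_dataset,
    mean_free_path,
    write_dataset,
)

from .conftest import TEMPLATE_HEADER, make_toy_file, random_dataset


class TestTypes:
    def test_elastic_channel_has_no_transition_energy(self):
        ch = InteractionChannel(ChannelKind.ELASTIC)
        assert ch.transition_energy is None and ch.label == "elastic"

    @pytest.mark.parametrize("index", [0, 6, None])
    def test_inelastic_index_out_of_range(self, index):
        with pytest.raises(ValidationError):
            InteractionChannel(ChannelKind.IONIZATION, index, 10.79)

    def test_grid_must_increase(self):
        with pytest.raises(ValidationError, match="increasing"):
            EnergyGrid([10.0, 20.0, 20.0])

    def test_grid_points_per_decade(self):
        grid = EnergyGrid(np.geomspace(10, 1000, 21))
        assert grid.points_per_decade() == pytest.approx(10.0)

    def test_sigma_above_binding_rejected(self):
        ch = InteractionChannel(ChannelKind.IONIZATION, 1, 12.0)
        with pytest.raises(ValidationError, match="below binding"):
            ChannelTable(ch, EnergyGrid([10.0, 11.0, 20.0]), [0.0, 0.1, 0.2])

    def test_negative_sigma_rejected(self):
        ch = InteractionChannel(ChannelKind.EXCITATION, 1, 8.0)
        with pytest.raises(ValidationError, match="negative"):
            ChannelTable(ch, EnergyGrid([10.0, 20.0]), [0.1, -0.1])

    def test_material_density_positive(self):
        with pytest.raises(ValidationError):
            MaterialModel(number_density=0.0)


class TestLoadDataset:
    def test_toy_file_parses(self, toy_file):
        ds = load_dataset(toy_file)
        assert len(ds.channels) == 11
        # ionization grids dropped the 8 eV row, excitation/elastic keep it
        assert len(ds.table_for(ChannelKind.IONIZATION, 1).grid) == 2
        assert len(ds.elastic.grid) == 3
        assert ds.table_for(ChannelKind.IONIZATION, 1).channel.transition_energy == 10.79

    def test_threshold_violation_names_channel(self, tmp_path):
        rows = [
            "8\t0\t0\t0\t0\t0\t0\t0\t0\t0\t0\t1.0",
            "10.5\t0.1\t0\t0\t0\t0\t0\t0\t0\t0\t0\t0.5",  # 10.5 eV < B1 = 10.79
            "100\t0.02\t0\t0\t0\t0\t0\t0\t0\t0\t0\t0.1",
        ]
        with pytest.raises(ValidationError, match="ion1"):
            load_dataset(make_toy_file(tmp_path / "bad.tsv", rows))

    def test_sub_floor_ionization_rejected(self, tmp_path):
        rows = [
            "8\t0.1\t0\t0\t0\t0\t0\t0\t0\t0\t0\t1.0",
            "100\t0.02\t0\t0\t0\t0\t0\t0\t0\t0\t0\t0.1",
        ]
        with pytest.raises(ValidationError, match="ion1"):
            load_dataset(make_toy_file(tmp_path / "bad.tsv", rows))

    def test_non_monotone_grid_rejected(self, tmp_path):
        rows = [
            "100\t0\t0\t0\t0\t0\t0\t0\t0\t0\t0\t1.0",
            "50\t0\t0\t0\t0\t0\t0\t0\t0\t0\t0\t0.5",
        ]
        with pytest.raises(ValidationError, match="increasing"):
            load_dataset(make_toy_file(tmp_path / "bad.tsv", rows))

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(TEMPLATE_HEADER + "8\t0\t0\t1.0\n")
        with pytest.raises(ValidationError, match="columns"):
            load_dataset(path)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("E\tsigma\nfoo\tbar\n1\t2\n")
        with pytest.raises(ValidationError):
            load_dataset(path)

    def test_round_trip_identity(self, tmp_path, rng):
        ds = random_dataset(rng)
        write_dataset(ds, tmp_path / "ds.tsv")
        again = xsec.load_dataset(tmp_path / "ds.tsv", name="random")
        assert again == ds

    def test_comments_ignored(self, toy_file, tmp_path):
        commented = tmp_path / "commented.tsv"
        commented.write_text("# a comment\n" + toy_file.read_text())
        assert load_dataset(commented, name="toy") == load_dataset(toy_file, name="toy")


class TestInterpolation:
    def test_node_identity(self, rng):
        ds = random_dataset(rng)
        tab = ds.elastic
        e = float(tab.grid.energies[3])
        assert interpolate_sigma(ds, tab.channel, e) == tab.sigma[3]

    def test_loglog_power_law(self):
        # sigma ~ 1/E through (10, 1) and (1000, 0.01) gives 0.1 at 100 eV
        grid = EnergyGrid([10.0, 1000.0])
        tables = list(random_dataset(np.random.default_rng(0)).channels)
        tables[-1] = ChannelTable(InteractionChannel(ChannelKind.ELASTIC), grid, [1.0, 0.01])
        ds = CrossSectionDataset("p", tuple(tables))
        assert interpolate_sigma(ds, tables[-1].channel, 100.0, "log-log") == pytest.approx(0.1, rel=1e-12)

    def test_linear_midpoint(self):
        grid = EnergyGrid([10.0, 20.0])
        tables = list(random_dataset(np.random.default_rng(0)).channels)
        tables[-1] = ChannelTable(InteractionChannel(ChannelKind.ELASTIC), grid, [1.0, 3.0])
        ds = CrossSectionDataset("p", tuple(tables))
        assert interpolate_sigma(ds, tables[-1].channel, 15.0, "linear") == pytest.approx(2.0)

    def test_extrapolation_forbidden(self, rng):
        ds = random_dataset(rng)
        with pytest.raises(RangeError):
            interpolate_sigma(ds, ds.elastic.channel, 1e7)

    def test_bounded_between_nodes(self, rng):
        ds = random_dataset(rng)
        tab = ds.elastic
        for j in range(len(tab.grid) - 1):
            e = math.sqrt(tab.grid.energies[j] * tab.grid.energies[j + 1])
            v = interpolate_sigma(ds, tab.channel, e)
            lo, hi = sorted([tab.sigma[j], tab.sigma[j + 1]])
            assert lo <= v <= hi


class TestChannelProbabilities:
    def _single_channel_ds(self, sig_ion, sig_exc, sig_el):
        energies = np.array([8.0, 50.0, 1e6])
        ion_e = energies[energies >= 10.0]
        tables = []
        for i, b in enumerate([10.79, 13.39, 16.05, 32.30, 539.0], start=1):
            s = sig_ion if i == 1 else 0.0
            sigma = np.where(ion_e > b, s, 0.0)
            tables.append(ChannelTable(InteractionChannel(ChannelKind.IONIZATION, i, b), EnergyGrid(ion_e), sigma))
        for i, w in enumerate([8.22, 10.0, 11.24, 12.61, 13.77], start=1):
            s = sig_exc if i == 1 else 0.0
            sigma = np.where(energies > w, s, 0.0)
            tables.append(ChannelTable(InteractionChannel(ChannelKind.EXCITATION, i, w), EnergyGrid(energies), sigma))
        tables.append(ChannelTable(InteractionChannel(ChannelKind.ELASTIC), EnergyGrid(energies), np.full(3, sig_el)))
        return CrossSectionDataset("probe", tuple(tables))

    def test_simple_ratio(self):
        ds = self._single_channel_ds(2.0, 1.0, 7.0)
        cp = channel_probabilities(ds, 50.0)
        by_label = {ch.label: p for ch, p in cp.probabilities.items()}
        assert by_label["ion1"] == pytest.approx(0.2)
        assert by_label["exc1"] == pytest.approx(0.1)
        assert by_label["elastic"] == pytest.approx(0.7)
        assert cp.sigma_total == pytest.approx(10.0)
        assert cp.sigma_inelastic == pytest.approx(3.0)

    def test_below_all_thresholds_elastic_only(self):
        ds = self._single_channel_ds(2.0, 1.0, 7.0)
        cp = channel_probabilities(ds, 8.1)  # below exc1 W = 8.22
        by_label = {ch.label: p for ch, p in cp.probabilities.items()}
        assert by_label["elastic"] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        ds = random_dataset(rng)
        for e in rng.uniform(20.0, 1e5, 20):
            cp = channel_probabilities(ds, float(e))
            # independent renormalization oracle
            sigmas = {t.channel: xsec.sigma_at(ds, t.channel, float(e)) for t in ds.channels}
            total = sum(sigmas.values())
            for ch, p in cp.probabilities.items():
                assert p == pytest.approx(sigmas[ch] / total, abs=1e-12)
            assert abs(sum(cp.probabilities.values()) - 1.0) < 1e-12

    def test_degenerate_medium(self):
        ds = self._single_channel_ds(0.0, 0.0, 0.0)
        with pytest.raises(DegenerateMediumError):
            channel_probabilities(ds, 50.0)


class TestAveraging:
    def _scaled(self, ds, factor, name):
        tables = tuple(
            ChannelTable(t.channel, t.grid, t.sigma * factor) for t in ds.channels
        )
        return CrossSectionDataset(name, tables)

    def test_constant_members_mean(self, rng):
        ds = random_dataset(rng)
        avg = average_datasets([ds, self._scaled(ds, 3.0, "b")])
        for t in avg.channels:
            ref = ds.table(t.channel)
            expect = np.array([2.0 * xsec.sigma_at(ds, t.channel, float(e)) for e in t.grid.energies])
            np.testing.assert_allclose(t.sigma, expect, rtol=1e-12)

    def test_idempotence(self, rng):
        ds = random_dataset(rng)
        avg = average_datasets([ds, ds, ds])
        for t in avg.channels:
            np.testing.assert_allclose(
                t.sigma,
                [xsec.sigma_at(ds, t.channel, float(e)) for e in t.grid.energies],
                rtol=1e-12,
            )

    def test_elementwise_oracle(self, rng):
        members = [random_dataset(rng, name=f"m{i}") for i in range(3)]
        avg = average_datasets(members)
        for t in avg.channels:
            for j, e in enumerate(t.grid.energies):
                expect = np.mean([xsec.sigma_at(m, t.channel, float(e)) for m in members])
                assert t.sigma[j] == pytest.approx(expect, rel=1e-12)

    def test_linearity(self, rng):
        members = [random_dataset(rng, name=f"m{i}") for i in range(3)]
        scaled = [self._scaled(m, 2.5, m.name) for m in members]
        a = average_datasets(members)
        b = average_datasets(scaled)
        for ta, tb in zip(a.channels, b.channels):
            np.testing.assert_allclose(tb.sigma, 2.5 * ta.sigma, rtol=1e-12)

    def test_needs_two_members(self, rng):
        with pytest.raises(ConfigurationError):
            average_datasets([random_dataset(rng)])

    def test_empty_elastic_member_list(self, rng):
        members = [random_dataset(rng, name=f"m{i}") for i in range(2)]
        with pytest.raises(ConfigurationError):
            average_datasets(members, elastic_datasets=[])

    def test_provenance_common(self, rng):
        members = [random_dataset(rng, name=f"m{i}") for i in range(2)]
        assert average_datasets(members).provenance == xsec.Provenance.COMMON


class TestMeanFreePath:
    def _uniform_elastic(self, sigma):
        energies = np.array([8.0, 1e6])
        ion_e = np.array([10.0, 1e6])
        tables = []
        for i, b in enumerate([10.79, 13.39, 16.05, 32.30, 539.0], start=1):
            tables.append(ChannelTable(InteractionChannel(ChannelKind.IONIZATION, i, b), EnergyGrid(ion_e), [0.0, 0.0]))
        for i, w in enumerate([8.22, 10.0, 11.24, 12.61, 13.77], start=1):
            tables.append(ChannelTable(InteractionChannel(ChannelKind.EXCITATION, i, w), EnergyGrid(energies), [0.0, 0.0]))
        tables.append(ChannelTable(InteractionChannel(ChannelKind.ELASTIC), EnergyGrid(energies), np.full(2, sigma)))
        return CrossSectionDataset("mfp", tuple(tables))

    def test_hand_value(self):
        ds = self._uniform_elastic(0.01)
        lam = mean_free_path(ds, MaterialModel(33.43), 100.0)
        assert lam == pytest.approx(2.991, abs=5e-4)

    def test_doubling_sigma_halves_lambda(self):
        lam1 = mean_free_path(self._uniform_elastic(0.01), MaterialModel(), 100.0)
        lam2 = mean_free_path(self._uniform_elastic(0.02), MaterialModel(), 100.0)
        assert lam1 == pytest.approx(2 * lam2, rel=1e-12)

    def test_unit_case(self):
        lam = mean_free_path(self._uniform_elastic(1.0), MaterialModel(1.0), 100.0)
        assert lam == pytest.approx(1.0, rel=1e-12)
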