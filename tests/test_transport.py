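import math

import numpy as np
import pytest
from scipy import stats as sps

from nanodosim import transport
from nanodosim.scoring import ScoringSphere, build_icsd
from nanodosim.stats import summarize
from nanodosim.transport import (
    ElectronState,
    InteractionEvent,
    LorentzianSecondarySpectrum,
    ScreenedRutherfordElastic,
    Track,
    TransportConfig,
    TransportEngine,
    apply_elastic,
    apply_inelastic,
    sample_free_path,
    select_channel,
    simulate_history,
    substream_rng,
)
from nanodosim.xsec import (
    ChannelKind,
    ChannelTable,
    CrossSectionDataset,
    DegenerateMediumError,
    EnergyGrid,
    InteractionChannel,
    MaterialModel,
    ValidationError,
)


def _uniform_ds(sig_ion=0.0, sig_exc=0.0, sig_el=1.0, w1=9.0, b1=10.79):
    """Dataset with constant cross sections in selected channels only."""
    energies = np.array([8.0, 1e6])
    tables = []
    for i, b in enumerate([b1, 13.39, 16.05, 32.30, 539.0], start=1):
        s = sig_ion if i == 1 else 0.0
        grid = np.array([max(b, 10.0), 2 * max(b, 10.0), 1e6])
        tables.append(
            ChannelTable(
                InteractionChannel(ChannelKind.IONIZATION, i, b), EnergyGrid(grid), [0.0, s, s]
            )
        )
    for i, w in enumerate([w1, 10.0, 11.24, 12.61, 13.77], start=1):
        # constant sigma over the whole grid; thresholds below 8 eV stay open
        s = sig_exc if i == 1 else 0.0
        tables.append(
            ChannelTable(InteractionChannel(ChannelKind.EXCITATION, i, w), EnergyGrid(energies), [s, s])
        )
    tables.append(ChannelTable(InteractionChannel(ChannelKind.ELASTIC), EnergyGrid(energies), [sig_el, sig_el]))
    return CrossSectionDataset("uniform", tuple(tables))


class TestSampleFreePath:
    def test_mean(self):
        rng = substream_rng(1, 0)
        n = 100_000
        samples = [sample_free_path(0.5, rng) for _ in range(n)]
        assert abs(np.mean(samples) - 2.0) < 3 * 2.0 / math.sqrt(n)

    def test_non_negative_and_error(self):
        rng = substream_rng(1, 1)
        assert all(sample_free_path(2.0, rng) >= 0 for _ in range(100))
        with pytest.raises(DegenerateMediumError):
            sample_free_path(0.0, rng)

    def test_reproducible(self):
        a = [sample_free_path(1.0, substream_rng(3, 5)) for _ in range(1)]
        b = [sample_free_path(1.0, substream_rng(3, 5)) for _ in range(1)]
        assert a == b

    def test_exponential_ks(self):
        rng = substream_rng(2, 0)
        samples = [sample_free_path(0.25, rng) for _ in range(20_000)]
        p = sps.kstest(samples, "expon", args=(0, 4.0)).pvalue
        assert p > 1e-3


class TestSelectChannel:
    def test_degenerate(self):
        ch = InteractionChannel(ChannelKind.ELASTIC)
        rng = substream_rng(0, 0)
        assert all(select_channel({ch: 1.0}, rng) is ch for _ in range(50))

    def test_frequencies(self):
        chans = {
            InteractionChannel(ChannelKind.IONIZATION, 1, 10.79): 0.2,
            InteractionChannel(ChannelKind.EXCITATION, 1, 8.22): 0.1,
            InteractionChannel(ChannelKind.ELASTIC): 0.7,
        }
        rng = substream_rng(4, 0)
        n = 100_000
        counts = {ch: 0 for ch in chans}
        for _ in range(n):
            counts[select_channel(chans, rng)] += 1
        for ch, p in chans.items():
            assert abs(counts[ch] / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            select_channel({InteractionChannel(ChannelKind.ELASTIC): 0.5}, substream_rng(0, 0))


class TestApplyElastic:
    def test_energy_unchanged_unit_norm(self):
        state = ElectronState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 100.0)
        rng = substream_rng(5, 0)
        for _ in range(200):
            state = apply_elastic(state, ScreenedRutherfordElastic(), rng)
            assert state.kinetic_energy == 100.0
            assert np.linalg.norm(state.direction) == pytest.approx(1.0, abs=1e-9)

    def test_large_eta_limit_uniform(self):
        # eta -> inf: P(cos t) tends to uniform on [-1, 1]
        model = ScreenedRutherfordElastic()
        rng = substream_rng(6, 0)
        energy = 1.0e-2  # tau tiny => eta huge
        cos_samples = [model.sample_cos_theta(energy, rng.random()) for _ in range(20_000)]
        p = sps.kstest(cos_samples, sps.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > 1e-3

    def test_small_eta_forward_peaked(self):
        model = ScreenedRutherfordElastic()
        rng = substream_rng(7, 0)
        cos_samples = [model.sample_cos_theta(1.0e4, rng.random()) for _ in range(5000)]
        assert np.mean(cos_samples) > 0.9


class TestApplyInelastic:
    def test_excitation(self):
        ch = InteractionChannel(ChannelKind.EXCITATION, 1, 8.4)
        state = ElectronState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 50.0)
        primary, secondary, event = apply_inelastic(state, ch, None, substream_rng(8, 0))
        assert secondary is None
        assert event.energy_deposit == pytest.approx(8.4)
        assert primary.kinetic_energy == pytest.approx(50.0 - 8.4)
        np.testing.assert_array_equal(primary.direction, state.direction)

    def test_ionization_20ev_interval(self):
        # E = 20, B = 10.79: eps <= (20 - 10.79)/2 = 4.605 and both outgoing
        # energies stay below B, so no further ionization is possible
        ch = InteractionChannel(ChannelKind.IONIZATION, 1, 10.79)
        rng = substream_rng(9, 0)
        for _ in range(500):
            state = ElectronState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 20.0)
            primary, secondary, event = apply_inelastic(state, ch, LorentzianSecondarySpectrum(), rng)
            assert 0.0 <= event.secondary_energy <= 4.605 + 1e-12
            assert primary.kinetic_energy < 10.79
            assert secondary.kinetic_energy < 10.79

    def test_energy_conservation_exact(self):
        ch = InteractionChannel(ChannelKind.IONIZATION, 2, 13.39)
        state = ElectronState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 312.5)
        primary, secondary, event = apply_inelastic(state, ch, LorentzianSecondarySpectrum(), substream_rng(10, 0))
        total = primary.kinetic_energy + secondary.kinetic_energy + event.energy_deposit
        assert total == pytest.approx(312.5, abs=1e-12)

    def test_closed_channel_rejected(self):
        ch = InteractionChannel(ChannelKind.IONIZATION, 1, 10.79)
        state = ElectronState(np.zeros(3), np.array([0.0, 0.0, 1.0]), 9.0)
        with pytest.raises(ValidationError, match="not open"):
            apply_inelastic(state, ch, None, substream_rng(0, 0))


class TestSimulateHistory:
    def test_20ev_at_most_one_ionization(self, base_ds, material):
        cfg = TransportConfig(seed=11)
        engine = TransportEngine(base_ds, material, cfg)
        for i in range(2000):
            track = engine.history(20.0, substream_rng(cfg.seed, i))
            assert track.n_ionizations in (0, 1)

    def test_zero_inelastic_pure_elastic_walk(self, material):
        ds = _uniform_ds(sig_el=0.05)
        cfg = TransportConfig(seed=12, world_radius=50.0)
        engine = TransportEngine(ds, material, cfg)
        track = engine.history(100.0, substream_rng(cfg.seed, 0))
        assert track.n_ionizations == 0
        assert track.escaped_energy == pytest.approx(100.0)
        assert track.deposited_energy == 0.0

    def test_energy_bookkeeping_closes(self, base_ds, material):
        cfg = TransportConfig(seed=13)
        engine = TransportEngine(base_ds, material, cfg)
        rng = np.random.default_rng(99)
        for i in range(1000):
            e0 = float(rng.uniform(15.0, 300.0))
            track = engine.history(e0, substream_rng(cfg.seed, i))
            assert abs(track.energy_residual()) < 1e-6

    def test_single_excitation_channel_closed_form(self, material):
        # no elastic, one always-open excitation with W = 7.9: the track is
        # exactly ceil((E0 - cutoff)/W) deposits of W, then local termination
        ds = _uniform_ds(sig_exc=0.1, sig_el=0.0, w1=7.9)
        cfg = TransportConfig(seed=14, world_radius=1e6)
        engine = TransportEngine(ds, material, cfg)
        e0, w, cutoff = 100.0, 7.9, 10.0
        expected = math.ceil((e0 - cutoff) / w)
        track = engine.history(e0, substream_rng(cfg.seed, 0))
        n_exc = track.n_events  # record='all': every event recorded
        assert n_exc == expected
        assert track.deposited_energy == pytest.approx(expected * w)
        assert track.terminated_energy == pytest.approx(e0 - expected * w)

    def test_first_collision_channel_fraction(self, base_ds, material):
        from nanodosim.xsec import channel_probabilities

        e0 = 20.0
        cp = channel_probabilities(base_ds, e0)
        p_ion = sum(p for ch, p in cp.probabilities.items() if ch.kind is ChannelKind.IONIZATION)
        cfg = TransportConfig(seed=15)
        engine = TransportEngine(base_ds, material, cfg)
        n = 20_000
        first_ion = 0
        for i in range(n):
            track = engine.history(e0, substream_rng(cfg.seed, i))
            chans = track.event_channels
            if chans and chans[0].kind is ChannelKind.IONIZATION:
                first_ion += 1
        assert abs(first_ion / n - p_ion) < 4 * math.sqrt(p_ion * (1 - p_ion) / n)

    def test_cutoff_range_enforced(self):
        with pytest.raises(ValidationError):
            TransportConfig(cutoff_energy=0.5)
        with pytest.raises(ValidationError):
            TransportConfig(cutoff_energy=11.0)


class TestRunSimulation:
    def test_n1_reduces_to_simulate_history(self, base_ds, material):
        cfg = TransportConfig(seed=16)
        track_run = next(iter(transport.run_simulation(100.0, base_ds, material, cfg, 1)))
        track_single = simulate_history(100.0, base_ds, material, cfg)
        assert track_run.n_events == track_single.n_events
        np.testing.assert_array_equal(track_run.ionization_positions, track_single.ionization_positions)

    def test_same_seed_identical_icsd(self, base_ds, material):
        cfg = TransportConfig(seed=17)
        sphere = ScoringSphere(8.0)
        a = build_icsd(transport.run_simulation(100.0, base_ds, material, cfg, 500, record="ionization"), sphere)
        b = build_icsd(transport.run_simulation(100.0, base_ds, material, cfg, 500, record="ionization"), sphere)
        assert a == b

    def test_fast_and_reference_paths_agree_statistically(self, base_ds, material):
        cfg = TransportConfig(seed=18)
        engine = TransportEngine(base_ds, material, cfg)
        sphere = ScoringSphere(8.0)
        n = 4000
        fast = summarize(build_icsd(engine.run(100.0, n, record="ionization"), sphere))
        ref = summarize(
            build_icsd((engine.history(100.0, substream_rng(cfg.seed, i)) for i in range(n)), sphere)
        )
        tol = 4 * math.hypot(fast.u_m1, ref.u_m1)
        assert abs(fast.m1 - ref.m1) < tol

    def test_spherical_symmetry_fixed_vs_isotropic(self, base_ds, material):
        sphere = ScoringSphere(8.0)
        n = 5000
        res = {}
        for mode in ("fixed_z", "isotropic"):
            cfg = TransportConfig(seed=19, initial_direction=mode)
            engine = TransportEngine(base_ds, material, cfg)
            res[mode] = summarize(build_icsd(engine.run(50.0, n, record="ionization"), sphere))
        tol = 4 * math.hypot(res["fixed_z"].u_m1, res["isotropic"].u_m1)
        assert abs(res["fixed_z"].m1 - res["isotropic"].m1) < tol


class TestTrack:
    def test_from_events_round_trip(self):
        ch_ion = InteractionChannel(ChannelKind.IONIZATION, 1, 10.79)
        ch_exc = InteractionChannel(ChannelKind.EXCITATION, 1, 8.22)
        events = [
            InteractionEvent(np.array([1.0, 0.0, 0.0]), ch_exc, 8.22, None),
            InteractionEvent(np.array([2.0, 0.0, 0.0]), ch_ion, 10.79, 3.0),
        ]
        track = Track.from_events(50.0, events, terminated_energy=50.0 - 8.22 - 10.79 - 3.0,
                                  escaped_energy=3.0)
        assert track.n_ionizations == 1
        assert abs(track.energy_residual()) < 1e-9
        rebuilt = track.events
        assert rebuilt[1].secondary_energy == pytest.approx(3.0)

    def test_event_invariant(self):
        ch_exc = InteractionChannel(ChannelKind.EXCITATION, 1, 8.22)
        with pytest.raises(ValidationError):
            InteractionEvent(np.zeros(3), ch_exc, 8.22, 1.0)  # excitation with secondary
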