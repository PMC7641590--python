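import numpy as np
import pytest

from domainfold.coordinates import drms_series, q_fraction, q_series
from domainfold.hamiltonian import ForceField, PackedSystem
from domainfold.model_builder import ContactSet
from domainfold.sampler import (
    SimulationProtocol,
    run_langevin,
    run_langevin_1d,
    run_metadynamics,
    run_metadynamics_1d,
    run_remd,
    run_umbrella,
    run_umbrella_1d,
)
from domainfold.synthetic_data import DoubleWell, make_harmonic_chain


@pytest.fixture(scope="module")
def harmonic_setup():
    chain = make_harmonic_chain(8, stiffness=100.0)
    ff = ForceField(electrostatics=False)
    cs = ContactSet([])
    return chain, cs, ff, PackedSystem(chain, cs, ff, include_excluded_volume=False)


class TestLangevin:
    def test_equipartition_per_bond_mode(self, harmonic_setup):
        """Mean harmonic-bond potential energy matches kT/2 per mode."""
        chain, cs, ff, packed = harmonic_setup
        kT = 1.0
        means = []
        for k in range(10):
            proto = SimulationProtocol(
                n_steps=80_000, timestep=0.003, temperature=kT,
                record_interval=100, seed=100 + k,
            )
            rec = run_langevin(chain, cs, ff, proto, system=packed)
            burn = rec.n_frames // 5
            means.append(rec.energies[burn:, 0].mean() / (chain.n_beads - 1))
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - kT / 2) < 3 * se

    def test_bond_length_variance_closed_form(self, harmonic_setup):
        chain, cs, ff, packed = harmonic_setup
        proto = SimulationProtocol(
            n_steps=200_000, timestep=0.003, temperature=1.0,
            record_interval=50, seed=7,
        )
        rec = run_langevin(chain, cs, ff, proto, system=packed)
        burn = rec.n_frames // 5
        d = np.linalg.norm(
            rec.positions[burn:, chain.bonds[:, 0], :]
            - rec.positions[burn:, chain.bonds[:, 1], :], axis=2,
        )
        var = np.mean((d - 1.0) ** 2)
        assert var == pytest.approx(1.0 / 200.0, rel=0.10)

    def test_zero_temperature_quench_recovers_native(self, fold_toy, fold_packed, rng):
        ff, packed = fold_packed
        start = fold_toy.model.positions + rng.normal(
            0, 0.05, fold_toy.model.positions.shape
        )
        proto = SimulationProtocol(
            n_steps=50_000, timestep=0.001, temperature=0.0,
            record_interval=5000, seed=3,
        )
        rec = run_langevin(
            fold_toy.model, fold_toy.contacts, ff, proto,
            start_coords=start, system=packed,
        )
        assert q_fraction(rec.positions[-1], fold_toy.contacts) > 0.99

    def test_seeded_determinism(self, fold_toy, fold_packed):
        ff, packed = fold_packed
        proto = SimulationProtocol(
            n_steps=5_000, timestep=0.001, temperature=0.9,
            record_interval=100, seed=42,
        )
        a = run_langevin(fold_toy.model, fold_toy.contacts, ff, proto, system=packed)
        b = run_langevin(fold_toy.model, fold_toy.contacts, ff, proto, system=packed)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.energies, b.energies)

    def test_frozen_beads_never_move(self, binding_toy):
        ff = ForceField()
        proto = SimulationProtocol(
            n_steps=5_000, timestep=0.001, temperature=1.0,
            record_interval=500, seed=5,
        )
        rec = run_langevin(binding_toy.model, binding_toy.contacts, ff, proto)
        frozen = binding_toy.model.frozen
        for frame in rec.positions:
            np.testing.assert_array_equal(
                frame[frozen], binding_toy.model.positions[frozen]
            )

    def test_frame_times_strictly_increasing(self, fold_toy, fold_packed):
        ff, packed = fold_packed
        proto = SimulationProtocol(
            n_steps=3_000, timestep=0.002, temperature=0.8,
            record_interval=100, seed=9,
        )
        rec = run_langevin(fold_toy.model, fold_toy.contacts, ff, proto, system=packed)
        assert np.all(np.diff(rec.times) > 0)


class TestREMD:
    def test_identical_temperature_pair_always_swaps(self, harmonic_setup):
        chain, cs, ff, packed = harmonic_setup
        proto = SimulationProtocol(
            n_steps=20_000, timestep=0.003, ladder=(1.0, 1.0),
            exchange_interval=1000, record_interval=500, seed=21,
        )
        recs = run_remd(chain, cs, ff, proto, system=packed)
        assert recs[0].cv["acceptance_rates"][0] == pytest.approx(1.0)

    def test_mean_energy_linear_in_temperature(self, harmonic_setup):
        """Each rung equilibrates to equipartition: <PE> = (n-1) T / 2."""
        chain, cs, ff, packed = harmonic_setup
        ladder = (0.6, 0.8, 1.0, 1.2)
        proto = SimulationProtocol(
            n_steps=150_000, timestep=0.003, ladder=ladder,
            exchange_interval=1500, record_interval=150, seed=22,
        )
        recs = run_remd(chain, cs, ff, proto, system=packed)
        n_modes = chain.n_beads - 1
        for rec in recs:
            burn = rec.n_frames // 4
            pe = rec.energies[burn:, 0].mean()
            assert pe == pytest.approx(n_modes * rec.temperature / 2, rel=0.12)

    def test_exchange_log_and_rates_recorded(self, harmonic_setup):
        chain, cs, ff, packed = harmonic_setup
        proto = SimulationProtocol(
            n_steps=10_000, timestep=0.003, ladder=(0.8, 1.0, 1.2),
            exchange_interval=1000, record_interval=500, seed=23,
        )
        recs = run_remd(chain, cs, ff, proto, system=packed)
        assert len(recs) == 3
        assert recs[0].exchange_log
        rates = recs[0].cv["acceptance_rates"]
        assert np.all((rates >= 0) & (rates <= 1))


class TestUmbrella:
    def test_stiff_spring_pins_the_cv(self, binding_toy):
        ff = ForceField()
        proto = SimulationProtocol(
            n_steps=30_000, timestep=0.001, temperature=0.7,
            record_interval=100, seed=31,
        )
        recs = run_umbrella(
            binding_toy.model, binding_toy.contacts, ff,
            [(1.0, 400.0)], proto, n_equil=10_000,
        )
        mean_drms = recs[0].cv["dRMS"][len(recs[0].cv["dRMS"]) // 2:].mean()
        assert mean_drms == pytest.approx(1.0, abs=0.15)

    def test_bias_energy_column_matches_recomputation(self, binding_toy):
        ff = ForceField()
        proto = SimulationProtocol(
            n_steps=10_000, timestep=0.001, temperature=0.7,
            record_interval=100, seed=32,
        )
        recs = run_umbrella(
            binding_toy.model, binding_toy.contacts, ff, [(0.8, 50.0)], proto,
        )
        rec = recs[0]
        expected = 0.5 * 50.0 * (rec.cv["dRMS"] - 0.8) ** 2
        np.testing.assert_allclose(rec.bias, expected, rtol=1e-9)
        d = drms_series(rec.positions, binding_toy.contacts.by_class("binding"))
        np.testing.assert_allclose(rec.cv["dRMS"], d, rtol=1e-9)


class TestMetadynamics:
    def test_zero_hill_height_reduces_to_langevin(self, binding_toy):
        ff = ForceField()
        proto = SimulationProtocol(
            n_steps=5_000, timestep=0.001, temperature=0.7,
            record_interval=100, seed=41,
        )
        plain = run_langevin(binding_toy.model, binding_toy.contacts, ff, proto)
        metad = run_metadynamics(
            binding_toy.model, binding_toy.contacts, ff, proto,
            hill_height=0.0, target=(np.inf, np.inf),
        )
        np.testing.assert_allclose(plain.positions, metad.positions)

    def test_deposited_bias_nonnegative_and_growing(self):
        out = run_metadynamics_1d(
            3.0, 200_000, target=(np.inf, np.inf), seed=42,
            hill_height=0.3, hill_stride=500, adaptive=False,
        )
        heights = out["hills"]["heights"]
        assert len(heights) > 10
        assert np.all(heights > 0)
        # accumulated bias at a fixed point is non-decreasing in hill count
        centers = out["hills"]["centers"]
        width = out["hills"]["width"]
        at_point = np.cumsum(
            heights * np.exp(-((centers - (-1.0)) ** 2) / (2 * width**2))
        )
        assert np.all(np.diff(at_point) >= 0)

    def test_double_well_rate_within_factor_three(self):
        """Rescaled metadynamics transition times track the unbiased MFPT."""
        from domainfold.synthetic_data import brute_force_mfpt_1d, make_double_well

        well = make_double_well(4.0)
        mfpt, censored = brute_force_mfpt_1d(
            well, n_runs=50, n_steps=1_000_000, dt=0.005, seed=43,
        )
        assert censored == 0
        times = []
        for k in range(16):
            out = run_metadynamics_1d(
                well.barrier, 2_000_000, (0.9, 1.3), dt=0.005, seed=500 + k,
                hill_height=0.25, hill_width=0.15, hill_stride=1000,
                bias_factor=8.0,
            )
            if not out["censored"]:
                times.append(out["t_rescaled"])
        assert len(times) >= 12
        ratio = np.mean(times) / mfpt
        assert 1 / 3 < ratio < 3


class TestOneD:
    def test_boltzmann_statistics_on_double_well(self):
        well = DoubleWell(1.5)
        xs = run_langevin_1d(well.barrier, 1_500_000, dt=0.005, seed=4, record_every=20)
        edges = np.linspace(-2, 2, 41)
        h, _ = np.histogram(xs, bins=edges, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        ref = well.boltzmann_density(centers)
        mask = ref > 0.02
        dF = -np.log(h[mask] / ref[mask])
        assert np.abs(dF).max() < 0.25

    def test_umbrella_windows_cover_their_centers(self):
        recs = run_umbrella_1d(3.0, [(-1.0, 30.0), (0.0, 30.0), (1.0, 30.0)], 50_000, seed=5)
        for rec in recs:
            assert np.mean(rec["x"]) == pytest.approx(rec["center"], abs=0.3)


class TestTrajectorySerialization:
    def test_xyz_and_energy_table_round_trip_frames(self, fold_toy, fold_packed):
        ff, packed = fold_packed
        proto = SimulationProtocol(
            n_steps=2_000, timestep=0.002, temperature=0.8,
            record_interval=500, seed=13,
        )
        rec = run_langevin(fold_toy.model, fold_toy.contacts, ff, proto, system=packed)
        xyz = rec.to_xyz()
        frames = xyz.strip().split("\n")
        assert frames[0] == str(fold_toy.model.n_beads)
        assert xyz.count(f"\n{fold_toy.model.n_beads}\n") == rec.n_frames - 1
        table = rec.energy_table()
        assert list(table["time"]) == list(rec.times)
        np.testing.assert_allclose(table["total"], rec.total_energy)
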