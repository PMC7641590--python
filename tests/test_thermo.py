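import numpy as np
import pytest
from scipy.special import logsumexp

from domainfold import thermo
from domainfold.synthetic_data import (
    make_double_well,
    make_synthetic_melting_set,
)
from domainfold.sampler import run_umbrella_1d
from domainfold.thermo import (
    FreeEnergySurface,
    MeltingCurve,
    WhamError,
    kd_from_pmf,
    melting_curves,
    mtci,
    reweight_rho,
    state_stabilities,
    tci,
    wham_temperature,
    wham_umbrella,
    weighted_fes,
)


def two_level_samples(eps, g_excited, temps, n, seed):
    """Exact Boltzmann draws from a two-level system (E=0 or eps)."""
    rng = np.random.default_rng(seed)
    out = []
    for T in temps:
        p1 = g_excited * np.exp(-eps / T) / (1 + g_excited * np.exp(-eps / T))
        e = np.where(rng.random(n) < p1, eps, 0.0)
        # jitter within a narrow band so histogram bins resolve the levels
        e = e + rng.normal(0, 0.01, n)
        out.append((T, e, None))
    return out


def schottky_cv(T, eps, g):
    b = eps / T
    z = 1 + g * np.exp(-b)
    return g * b**2 * np.exp(-b) / z**2


class TestWhamTemperature:
    def test_two_level_heat_capacity_matches_schottky(self):
        eps, g = 2.0, 3.0
        temps = [0.5, 0.7, 0.9, 1.2, 1.6]
        samples = two_level_samples(eps, g, temps, 40_000, seed=1)
        res = wham_temperature(samples, n_energy_bins=60)
        grid = np.linspace(0.55, 1.5, 25)
        cv_est = []
        for T in grid:
            w = res.dos.log_n - res.dos.e_centers / T
            p = np.exp(w - logsumexp(w))
            e1 = np.sum(p * res.dos.e_centers)
            e2 = np.sum(p * res.dos.e_centers**2)
            cv_est.append((e2 - e1**2) / T**2)
        ref = schottky_cv(grid, eps, g)
        assert np.abs(np.array(cv_est) - ref).max() < 0.06

    def test_single_temperature_reduces_to_histogram(self, rng):
        e = rng.normal(5.0, 1.0, 20_000)
        res = wham_temperature([(1.0, e, None)], n_energy_bins=40)
        h, edges = np.histogram(e, bins=40)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # recovered density of states must reproduce the sampled distribution
        logp = res.dos.log_n - centers / 1.0
        logp -= logsumexp(logp)
        mask = h > 200
        np.testing.assert_allclose(
            np.exp(logp[mask]) * len(e), h[mask], rtol=0.2,
        )

    def test_non_overlapping_histograms_rejected(self):
        with pytest.raises(WhamError, match="overlap"):
            wham_temperature([
                (0.5, np.zeros(100), None), (2.0, np.full(100, 50.0), None),
            ])


class TestWhamUmbrella:
    def test_double_well_pmf_recovered(self):
        well = make_double_well(3.0)
        windows = [(c, 20.0) for c in np.linspace(-1.6, 1.6, 17)]
        recs = run_umbrella_1d(well.barrier, windows, 150_000, seed=5)
        pmf = wham_umbrella(recs, grid=np.linspace(-1.8, 1.8, 73))
        x = pmf.axes[0]
        ref = well.analytic_pmf(x)
        mask = np.isfinite(pmf.values) & (np.abs(x) < 1.5)
        assert np.abs(pmf.values[mask] - ref[mask]).max() < 0.2

    def test_single_unbiased_window_is_minus_log_histogram(self, rng):
        x = rng.normal(0.0, 0.5, 50_000)
        grid = np.linspace(-1.5, 1.5, 31)
        pmf = wham_umbrella([{"x": x, "center": 0.0, "spring": 0.0}], grid=grid)
        h, _ = np.histogram(x, bins=grid)
        ref = -np.log(h / h.max())
        mask = h > 100
        np.testing.assert_allclose(pmf.values[mask], ref[mask], atol=1e-6)

    def test_shifting_all_centers_preserves_pmf_shape(self):
        well = make_double_well(2.0)
        windows = [(c, 15.0) for c in np.linspace(-1.5, 1.5, 13)]
        grid = np.linspace(-1.7, 1.7, 69)
        recs = run_umbrella_1d(well.barrier, windows, 60_000, seed=6)
        pmf_a = wham_umbrella(recs, grid=grid)
        shifted = [
            {"x": r["x"], "center": r["center"] + 0.0, "spring": r["spring"]}
            for r in recs
        ]
        pmf_b = wham_umbrella(shifted, grid=grid)
        mask = np.isfinite(pmf_a.values)
        np.testing.assert_allclose(pmf_a.values[mask], pmf_b.values[mask], atol=1e-9)


class TestReweighting:
    def test_identity_at_reference_rho(self, rng):
        e = np.zeros((500, 8))
        e[:, 2] = rng.normal(-3, 0.5, 500)
        w, ess = reweight_rho(e, 1.0, 1.0, 1.0)
        np.testing.assert_allclose(w, 1.0 / 500)
        assert ess == pytest.approx(500)

    def test_two_level_occupancies_match_direct_boltzmann(self, rng):
        # state A: E_intra=-2, E_inter=-1; state B: both 0; kT=1, rho0=1
        T = 1.0
        pA = np.exp(3.0) / (np.exp(3.0) + 1.0)
        n = 200_000
        is_a = rng.random(n) < pA
        e = np.zeros((n, 8))
        e[is_a, 1] = -2.0
        e[is_a, 2] = -1.0
        for rho in (0.5, 1.5):
            w, _ = reweight_rho(e, 1.0, rho, T)
            occ_a = w[is_a].sum()
            expected = np.exp(2.0 + rho) / (np.exp(2.0 + rho) + 1.0)
            assert occ_a == pytest.approx(expected, abs=0.01)

    def test_missing_decomposition_rejected(self):
        with pytest.raises(ValueError):
            reweight_rho(np.zeros(10), 1.0, 0.8, 1.0)

    def test_weighted_fes_normalized(self, rng):
        q = rng.uniform(0, 1, 1000)
        fes = weighted_fes(q, None, np.linspace(0, 1, 11))
        assert np.isfinite(fes.values).all()


class TestMeltingAndCoupling:
    def test_parameters_recovered_from_synthetic_curves(self):
        grid = np.linspace(0.6, 1.4, 33)
        curves_in = make_synthetic_melting_set([0.9, 1.1], [0.05, 0.08], grid)
        fitted = melting_curves(
            {c.element: c.p_folded for c in curves_in}, grid,
            presupplied_probabilities=True,
        )
        for fit, ref in zip(fitted, curves_in):
            assert fit.tm == pytest.approx(ref.tm, rel=0.02)
            assert fit.width == pytest.approx(ref.width, rel=0.02)

    def test_always_folded_element_flagged(self):
        grid = np.linspace(0.6, 1.4, 20)
        out = melting_curves(
            {"stuck": np.ones(20)}, grid, presupplied_probabilities=True,
        )
        assert out[0].flagged

    def test_fitted_sigmoid_vanishes_at_high_temperature(self):
        grid = np.linspace(0.6, 1.4, 33)
        fit = melting_curves(
            {"el": 1 / (1 + np.exp((grid - 1.0) / 0.05))}, grid,
            presupplied_probabilities=True,
        )[0]
        assert fit.fitted(np.array([3.0]))[0] < 1e-3

    def test_tci_log_identity(self):
        grid = np.linspace(0, 1, 11)
        a = MeltingCurve("a", grid, np.full(11, 0.5))
        b = MeltingCurve("b", grid, np.full(11, 0.5 - np.exp(-2.0)))
        assert tci(a, b) == pytest.approx(2.0)

    def test_identical_curves_capped(self):
        grid = np.linspace(0, 1, 11)
        a = MeltingCurve("a", grid, np.linspace(0, 1, 11))
        assert tci(a, a) == pytest.approx(np.log(10 * 11))

    def test_mtci_decreases_with_tm_spread(self):
        grid = np.linspace(0.5, 1.5, 41)
        vals = []
        for spread in (0.02, 0.1, 0.25):
            curves = make_synthetic_melting_set(
                [1.0 - spread, 1.0, 1.0 + spread], [0.05] * 3, grid,
            )
            vals.append(mtci(curves))
        assert vals[0] > vals[1] > vals[2]

    def test_mtci_bounded_by_pairwise_extremes(self):
        grid = np.linspace(0.5, 1.5, 41)
        curves = make_synthetic_melting_set(
            [0.8, 1.0, 1.2], [0.04, 0.07, 0.05], grid,
        )
        pair_vals = [
            tci(curves[i], curves[j])
            for i in range(3) for j in range(i + 1, 3)
        ]
        assert min(pair_vals) <= mtci(curves) <= max(pair_vals)

    def test_grid_mismatch_rejected(self):
        a = MeltingCurve("a", np.linspace(0, 1, 5), np.zeros(5))
        b = MeltingCurve("b", np.linspace(0, 2, 5), np.zeros(5))
        with pytest.raises(ValueError):
            tci(a, b)


def _two_basin_surface(depth_n=4.0, depth_u=0.0):
    q = np.linspace(0.025, 0.975, 20)
    F = np.full_like(q, 6.0)
    F[q < 0.3] = depth_u
    F[q > 0.7] = depth_n
    return FreeEnergySurface(axes=(q,), values=F, temperature=1.0)


class TestStateStabilities:
    def test_reference_rho_has_zero_shift(self):
        surfaces = {0.8: _two_basin_surface(3.0), 1.0: _two_basin_surface(4.0)}
        table = state_stabilities(
            surfaces, {"N": (0.7, 1.0), "U": (0.0, 0.3)}, rho0=1.0,
        )
        i0 = table.rhos.index(1.0)
        np.testing.assert_allclose(table.delta_delta_f[i0], 0.0, atol=1e-12)

    def test_hand_set_depths_match_quadrature(self):
        surf = _two_basin_surface(depth_n=2.0)
        table = state_stabilities(
            {1.0: surf}, {"N": (0.7, 1.0), "U": (0.0, 0.3)}, rho0=1.0,
        )
        q, F = surf.axes[0], surf.values
        n_mask = (q >= 0.7) & (q <= 1.0)
        u_mask = (q >= 0.0) & (q <= 0.3)
        expected = -(
            logsumexp(-F[n_mask]) - logsumexp(-F[u_mask])
        )
        assert table.delta_f[0, 0] == pytest.approx(expected)

    def test_deepening_a_basin_lowers_its_free_energy_linearly(self):
        t1 = state_stabilities(
            {1.0: _two_basin_surface(4.0)}, {"N": (0.7, 1.0), "U": (0.0, 0.3)},
        )
        t2 = state_stabilities(
            {1.0: _two_basin_surface(3.0)}, {"N": (0.7, 1.0), "U": (0.0, 0.3)},
        )
        assert t2.delta_f[0, 0] == pytest.approx(t1.delta_f[0, 0] - 1.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            state_stabilities(
                {1.0: _two_basin_surface()}, {"N": (2.0, 3.0), "U": (0.0, 0.3)},
            )


class TestBindingAffinity:
    @staticmethod
    def _pmf(bound_depth=0.0):
        x = np.linspace(0.05, 12.0, 240)
        F = np.full_like(x, 8.0)
        F[x < 0.5] = bound_depth
        F[x > 10.0] = 0.0
        return FreeEnergySurface(axes=(x,), values=F, temperature=1.0)

    def test_symmetric_basins_at_single_molecule_volume_give_one_molar(self):
        x = np.linspace(0.05, 12.0, 2400)
        F = np.where((x < 0.5) | (x > 10.0), 0.0, 12.0)
        # equalize integration measure: bound window 0.05-0.5, unbound 10-12;
        # shift the unbound plateau so both Boltzmann integrals match exactly
        dx = np.gradient(x)
        lb = logsumexp(-F[x < 0.5], b=dx[x < 0.5])
        lu = logsumexp(-F[x > 10.0], b=dx[x > 10.0])
        F[x > 10.0] += lu - lb
        pmf = FreeEnergySurface(axes=(x,), values=F, temperature=1.0)
        box = 1e24 / 6.02214076e23  # nm^3 holding one molecule at 1 M
        aff = kd_from_pmf(pmf, box_volume_nm3=box)
        assert aff.kd_nm == pytest.approx(1e9, rel=1e-6)

    def test_deepening_bound_basin_by_one_kt_divides_kd_by_e(self):
        a = kd_from_pmf(self._pmf(0.0))
        b = kd_from_pmf(self._pmf(-1.0))
        assert a.kd_nm / b.kd_nm == pytest.approx(np.e, rel=1e-6)

    def test_populations_sum_to_one_and_windows_echoed(self):
        aff = kd_from_pmf(self._pmf())
        assert sum(aff.populations.values()) == pytest.approx(1.0)
        assert set(aff.windows) == {"BS", "IS", "EC", "US"}

    def test_missing_unbound_plateau_rejected(self):
        x = np.linspace(0.05, 5.0, 100)
        pmf = FreeEnergySurface(axes=(x,), values=np.zeros_like(x), temperature=1.0)
        with pytest.raises(ValueError, match="plateau"):
            kd_from_pmf(pmf)

    def test_occupancy_counting_oracle(self, rng):
        """Kd from the PMF agrees with direct occupancy counting of samples
        drawn from the same Boltzmann distribution."""
        pmf = self._pmf(-1.0)
        x, F = pmf.axes[0], pmf.values
        p = np.exp(-F)
        p /= p.sum()
        draws = rng.choice(x, size=400_000, p=p)
        f_bound = np.mean(draws < 0.5)
        f_unbound = np.mean(draws > 10.0)
        box = 1000.0
        c_box = 1e24 / 6.02214076e23 / box
        kd_counted = c_box * f_unbound / f_bound * 1e9
        aff = kd_from_pmf(pmf, box_volume_nm3=box)
        assert aff.kd_nm == pytest.approx(kd_counted, rel=0.05)

    def test_four_state_classifier_thresholds(self):
        assert thermo.classify_binding_state(0.1) == "BS"
        assert thermo.classify_binding_state(1.5) == "IS"
        assert thermo.classify_binding_state(5.0) == "EC"
        assert thermo.classify_binding_state(12.0) == "US"
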