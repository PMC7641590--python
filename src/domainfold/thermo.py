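"""Equilibrium analyses: WHAM, rho-reweighting, melting curves, stabilities.

Temperature WHAM combines replica-exchange samples into a density of states
n(E) (optionally jointly with a collective variable), from which heat
capacity curves, the folding temperature (Cv peak), and free-energy surfaces
at any temperature follow. Umbrella WHAM unbiases harmonic-window samples
into a potential of mean force. Because the potential is linear in rho,
samples generated at rho0 can be reweighted exactly to any other rho from
the stored energy decomposition, without re-simulation.

Free energies are in kT at the stated temperature throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import logsumexp

from .sampler import TrajectoryRecord

AVOGADRO = 6.02214076e23
#: mol/L concentration of a single molecule in a 1 nm^3 box
_CONC_PER_NM3 = 1.0e24 / AVOGADRO

# dRMS windows of the four-state binding classifier (nm)
BS_MAX_DRMS = 0.5
IS_MAX_DRMS = 2.5
US_MIN_DRMS = 10.0


class WhamError(RuntimeError):
    pass


@dataclass
class DensityOfStates:
    e_centers: np.ndarray
    log_n: np.ndarray                       # up to an additive constant
    cv_centers: np.ndarray | None = None
    log_n_joint: np.ndarray | None = None   # (E, cv)


@dataclass
class FreeEnergySurface:
    axes: tuple[np.ndarray, ...]
    values: np.ndarray        # kT; min over sampled bins = 0
    temperature: float
    residuals: np.ndarray | None = None

    def interp(self, x: float) -> float:
        return float(np.interp(x, self.axes[0], self.values))

    def to_frame(self):
        import pandas as pd

        if len(self.axes) == 1:
            return pd.DataFrame({"cv": self.axes[0], "F_kT": self.values})
        g0, g1 = np.meshgrid(self.axes[0], self.axes[1], indexing="ij")
        return pd.DataFrame({
            "cv1": g0.ravel(), "cv2": g1.ravel(), "F_kT": self.values.ravel()
        })


@dataclass
class WhamResult:
    dos: DensityOfStates
    temperatures: np.ndarray
    heat_capacity: np.ndarray
    tf: float                   # Cv-peak temperature
    replica_free_energies: np.ndarray

    def mean_energy(self, T: float) -> float:
        w = self.dos.log_n - self.dos.e_centers / T
        p = np.exp(w - logsumexp(w))
        return float(np.sum(p * self.dos.e_centers))

    def fes_at(self, T: float) -> FreeEnergySurface:
        if self.dos.log_n_joint is None:
            raise WhamError("no collective variable was histogrammed")
        w = self.dos.log_n_joint - self.dos.e_centers[:, None] / T
        logp = logsumexp(w, axis=0)
        finite = np.isfinite(logp)
        F = np.full_like(logp, np.inf)
        F[finite] = -(logp[finite] - logp[finite].max())
        return FreeEnergySurface(
            axes=(self.dos.cv_centers,), values=F, temperature=T
        )


def _as_temp_samples(records) -> list[tuple[float, np.ndarray, np.ndarray | None]]:
    out = []
    for rec in records:
        if isinstance(rec, TrajectoryRecord):
            cv = rec.cv.get("Q_total")
            out.append((rec.temperature, rec.total_energy, cv))
        else:
            T, E, cv = rec if len(rec) == 3 else (*rec, None)
            out.append((float(T), np.asarray(E, float),
                        None if cv is None else np.asarray(cv, float)))
    return out


def wham_temperature(
    remd_records,
    n_energy_bins: int = 80,
    cv_bins: np.ndarray | int = 40,
    temperature_grid: np.ndarray | None = None,
    tol: float = 1.0e-10,
    max_iter: int = 50_000,
) -> WhamResult:
    """Multiple-histogram WHAM over temperatures.

    ``remd_records`` is a list of TrajectoryRecord (with cv['Q_total'] set for
    joint histogramming) or of (temperature, energies, cv) tuples. Requires
    overlapping energy histograms between neighboring temperatures.
    """
    samples = sorted(_as_temp_samples(remd_records), key=lambda s: s[0])
    if len(samples) < 1:
        raise WhamError("no samples given")
    for (t1, e1, _), (t2, e2, _) in zip(samples, samples[1:]):
        if e1.max() < e2.min() or e2.max() < e1.min():
            raise WhamError(
                f"energy histograms at T={t1:g} and T={t2:g} do not overlap"
            )
    all_e = np.concatenate([s[1] for s in samples])
    edges = np.linspace(all_e.min(), all_e.max() + 1e-12, n_energy_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    betas = np.array([1.0 / s[0] for s in samples])
    counts = np.array([len(s[1]) for s in samples], dtype=float)
    hist = np.array([np.histogram(s[1], bins=edges)[0] for s in samples], float)
    total = hist.sum(axis=0)

    g = np.zeros(len(samples))  # g_k = -ln Z_k
    log_counts = np.log(counts)
    with np.errstate(divide="ignore"):
        log_total = np.log(total)
    for _ in range(max_iter):
        # log denominator per energy bin
        denom = logsumexp(
            log_counts[:, None] + g[:, None] - betas[:, None] * centers[None, :],
            axis=0,
        )
        log_n = np.where(total > 0, log_total - denom, -np.inf)
        g_new = -logsumexp(
            log_n[None, :] - betas[:, None] * centers[None, :], axis=1
        )
        g_new -= g_new[0]
        if np.max(np.abs(g_new - g)) < tol:
            g = g_new
            break
        g = g_new

    denom = logsumexp(
        log_counts[:, None] + g[:, None] - betas[:, None] * centers[None, :],
        axis=0,
    )
    dos = DensityOfStates(e_centers=centers, log_n=np.where(total > 0, log_total - denom, -np.inf))

    have_cv = all(s[2] is not None for s in samples)
    if have_cv:
        all_cv = np.concatenate([s[2] for s in samples])
        if np.isscalar(cv_bins) or isinstance(cv_bins, int):
            cv_edges = np.linspace(all_cv.min(), all_cv.max() + 1e-12, int(cv_bins) + 1)
        else:
            cv_edges = np.asarray(cv_bins, float)
        joint = np.zeros((len(centers), len(cv_edges) - 1))
        for s in samples:
            h2, _, _ = np.histogram2d(s[1], s[2], bins=(edges, cv_edges))
            joint += h2
        with np.errstate(divide="ignore"):
            log_joint = np.where(joint > 0, np.log(joint) - denom[:, None], -np.inf)
        dos.cv_centers = 0.5 * (cv_edges[:-1] + cv_edges[1:])
        dos.log_n_joint = log_joint

    t_lo, t_hi = samples[0][0], samples[-1][0]
    if temperature_grid is None:
        pad = 0.02 * (t_hi - t_lo if t_hi > t_lo else t_lo)
        temperature_grid = np.linspace(t_lo - pad, t_hi + pad, 201)
    cv_curve = np.zeros_like(temperature_grid)
    for i, T in enumerate(temperature_grid):
        w = dos.log_n - centers / T
        p = np.exp(w - logsumexp(w))
        e1 = np.sum(p * centers)
        e2 = np.sum(p * centers**2)
        cv_curve[i] = (e2 - e1**2) / T**2
    tf = float(temperature_grid[np.argmax(cv_curve)])
    return WhamResult(
        dos=dos,
        temperatures=np.asarray(temperature_grid, float),
        heat_capacity=cv_curve,
        tf=tf,
        replica_free_energies=g,
    )


# ---------------------------------------------------------------------------
# umbrella WHAM


def _as_window_samples(window_records) -> list[tuple[np.ndarray, float, float, float]]:
    out = []
    for rec in window_records:
        if isinstance(rec, TrajectoryRecord):
            if rec.window is None:
                raise WhamError("trajectory has no umbrella window parameters")
            out.append((rec.cv["dRMS"], rec.window[0], rec.window[1], rec.temperature))
        else:
            out.append((
                np.asarray(rec["x"], float), float(rec["center"]),
                float(rec["spring"]), float(rec.get("kT", 1.0)),
            ))
    return out


def wham_umbrella(
    window_records,
    grid: np.ndarray | int = 80,
    tol: float = 1.0e-10,
    max_iter: int = 50_000,
) -> FreeEnergySurface:
    """Unbiased PMF over the umbrella CV from harmonic-window samples.

    A single window with zero spring reduces to -ln(histogram). Per-window
    consistency residuals (mean |F_unbiased - F_window-implied| over the
    window's well-sampled bins, kT) are attached to the surface.
    """
    samples = _as_window_samples(window_records)
    kT = samples[0][3]
    all_x = np.concatenate([s[0] for s in samples])
    if np.isscalar(grid) or isinstance(grid, int):
        edges = np.linspace(all_x.min(), all_x.max() + 1e-12, int(grid) + 1)
    else:
        edges = np.asarray(grid, float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.array([np.histogram(s[0], bins=edges)[0] for s in samples], float)
    total = hist.sum(axis=0)
    if not np.any(total > 0):
        raise WhamError("no samples fall on the requested grid")
    counts = hist.sum(axis=1)
    bias = np.array([
        0.5 * s[2] * (centers - s[1]) ** 2 / kT for s in samples
    ])  # (K, X) in kT

    f = np.zeros(len(samples))
    log_counts = np.where(counts > 0, np.log(counts), -np.inf)
    with np.errstate(divide="ignore"):
        log_total = np.log(total)
    for _ in range(max_iter):
        denom = logsumexp(log_counts[:, None] + f[:, None] - bias, axis=0)
        logp = np.where(total > 0, log_total - denom, -np.inf)
        f_new = -logsumexp(logp[None, :] - bias, axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    denom = logsumexp(log_counts[:, None] + f[:, None] - bias, axis=0)
    logp = np.where(total > 0, log_total - denom, -np.inf)
    F = np.full_like(logp, np.inf)
    finite = np.isfinite(logp)
    F[finite] = -(logp[finite] - logp[finite].max())
    F[finite] -= F[finite].min()

    residuals = np.zeros(len(samples))
    for k, s in enumerate(samples):
        hk = hist[k]
        good = hk > max(5, 0.01 * hk.max())
        if not np.any(good):
            residuals[k] = np.nan
            continue
        with np.errstate(divide="ignore"):
            f_win = -np.log(np.where(hk > 0, hk, np.nan)) - bias[k]
        diff = F[good] - f_win[good]
        residuals[k] = float(np.nanstd(diff))
    return FreeEnergySurface(
        axes=(centers,), values=F, temperature=kT, residuals=residuals
    )


# ---------------------------------------------------------------------------
# rho reweighting


def reweight_rho(
    energies_decomposed: np.ndarray,
    rho0: float,
    rho_target: float,
    temperature: float,
    ess_warn_fraction: float = 0.10,
) -> tuple[np.ndarray, float]:
    """Sample weights mapping a rho0 ensemble onto rho_target.

    ``energies_decomposed`` is the (F, 8) per-frame energy decomposition in
    kernel layout. E(rho) - E(rho0) = (rho - rho0)(V_inter + V_linker) with
    the raw sums recovered from the stored rho0-scaled components. Returns
    (normalized weights, effective sample size).
    """
    e = np.asarray(energies_decomposed, float)
    if e.ndim != 2 or e.shape[1] != 8:
        raise ValueError(
            "reweighting requires the (F, 8) decomposed energy table"
        )
    raw_inter = (e[:, 2] + e[:, 3] + e[:, 4]) / rho0
    delta = (rho_target - rho0) * raw_inter
    logw = -delta / temperature
    logw -= logsumexp(logw)
    w = np.exp(logw)
    ess = float(1.0 / np.sum(w**2))
    if ess < ess_warn_fraction * len(w):
        import logging

        logging.getLogger(__name__).warning(
            "reweighting ESS %.1f is below %.0f%% of %d samples",
            ess, 100 * ess_warn_fraction, len(w),
        )
    return w, ess


def weighted_fes(
    cv_values: np.ndarray,
    weights: np.ndarray | None,
    bins: np.ndarray,
    temperature: float = 1.0,
) -> FreeEnergySurface:
    """F(cv) = -ln of the (weighted, normalized) histogram, in kT."""
    hist, edges = np.histogram(cv_values, bins=bins, weights=weights, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        F = -np.log(hist)
    return FreeEnergySurface(axes=(centers,), values=F, temperature=temperature)


# ---------------------------------------------------------------------------
# melting curves and thermodynamic coupling


@dataclass
class MeltingCurve:
    element: str
    temperatures: np.ndarray
    p_folded: np.ndarray
    tm: float = np.nan
    width: float = np.nan
    flagged: bool = False

    def fitted(self, T: np.ndarray | None = None) -> np.ndarray:
        T = self.temperatures if T is None else T
        return _sigmoid(T, self.tm, self.width)


def _sigmoid(T, tm, width):
    return 1.0 / (1.0 + np.exp((T - tm) / width))


def melting_curves(
    per_element_q: dict[str, np.ndarray],
    temperatures: np.ndarray,
    threshold: float = 0.5,
    presupplied_probabilities: bool = False,
) -> list[MeltingCurve]:
    """Folding probability P_I(T) per element, fitted by a two-parameter sigmoid.

    ``per_element_q`` maps element name -> (n_T, n_frames) Q series per
    temperature (or directly P_I(T) when ``presupplied_probabilities``).
    Elements that never change state across the ladder are flagged and their
    fit parameters left NaN.
    """
    temperatures = np.asarray(temperatures, float)
    curves = []
    for name, q in per_element_q.items():
        if presupplied_probabilities:
            p = np.asarray(q, float)
        else:
            p = np.array([np.mean(np.asarray(qt) >= threshold) for qt in q])
        curve = MeltingCurve(element=name, temperatures=temperatures, p_folded=p)
        if p.max() - p.min() < 0.05:
            curve.flagged = True
        else:
            try:
                span = temperatures.max() - temperatures.min()
                popt, _ = curve_fit(
                    _sigmoid, temperatures, p,
                    p0=(float(np.median(temperatures)), max(span / 10, 1e-3)),
                    bounds=(
                        (temperatures.min() - span, 1e-6),
                        (temperatures.max() + span, 10 * span + 1.0),
                    ),
                    maxfev=10_000,
                )
                curve.tm, curve.width = float(popt[0]), float(popt[1])
            except RuntimeError:
                curve.flagged = True
        curves.append(curve)
    return curves


def tci(
    curve_i: MeltingCurve, curve_j: MeltingCurve, cap: float | None = None
) -> float:
    """Thermodynamic coupling index: -ln <|P_I(T) - P_J(T)|> over the grid.

    Identical curves diverge by the formula; the value is capped at
    -ln(1 / (10 * grid size)) so they stay finite and comparable.
    """
    if len(curve_i.temperatures) != len(curve_j.temperatures) or not np.allclose(
        curve_i.temperatures, curve_j.temperatures
    ):
        raise ValueError("melting curves must share a temperature grid")
    g = len(curve_i.temperatures)
    cap = np.log(10.0 * g) if cap is None else cap
    mad = float(np.mean(np.abs(curve_i.p_folded - curve_j.p_folded)))
    if mad <= 0:
        return cap
    return min(-np.log(mad), cap)


def mtci(curves: list[MeltingCurve], cap: float | None = None) -> float:
    """-ln of the pair-averaged mean absolute melting-curve difference."""
    if len(curves) < 2:
        raise ValueError("MTCI needs at least two melting curves")
    g = len(curves[0].temperatures)
    cap = np.log(10.0 * g) if cap is None else cap
    mads = []
    for a in range(len(curves)):
        for b in range(a + 1, len(curves)):
            mads.append(
                np.mean(np.abs(curves[a].p_folded - curves[b].p_folded))
            )
    mean_mad = float(np.mean(mads))
    if mean_mad <= 0:
        return cap
    return min(-np.log(mean_mad), cap)


# ---------------------------------------------------------------------------
# state stabilities


@dataclass
class StabilityTable:
    states: list[str]
    rhos: list[float]
    delta_f: np.ndarray      # (n_rho, n_state) kT, relative to U
    delta_delta_f: np.ndarray

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, rho in enumerate(self.rhos):
            for j, s in enumerate(self.states):
                rows.append((rho, s, self.delta_f[i, j], self.delta_delta_f[i, j]))
        return pd.DataFrame(rows, columns=["rho", "state", "dF_kT", "ddF_kT"])


def state_stabilities(
    surface_per_rho: dict[float, FreeEnergySurface],
    state_definitions: dict[str, tuple[float, float]],
    rho0: float = 1.0,
    unfolded_state: str = "U",
) -> StabilityTable:
    """dF(rho)^S = F_S - F_U by Boltzmann integration over each CV window."""
    if unfolded_state not in state_definitions:
        raise ValueError(f"state definitions lack the unfolded state {unfolded_state!r}")
    if rho0 not in surface_per_rho:
        raise ValueError("surfaces must include the reference rho0")
    states = [s for s in state_definitions if s != unfolded_state]
    rhos = sorted(surface_per_rho)
    dF = np.zeros((len(rhos), len(states)))
    for i, rho in enumerate(rhos):
        surf = surface_per_rho[rho]
        x, F = surf.axes[0], surf.values
        f_u = _window_free_energy(x, F, state_definitions[unfolded_state])
        for j, s in enumerate(states):
            dF[i, j] = _window_free_energy(x, F, state_definitions[s]) - f_u
    i0 = rhos.index(rho0)
    ddF = dF - dF[i0][None, :]
    return StabilityTable(states=states, rhos=rhos, delta_f=dF, delta_delta_f=ddF)


def _window_free_energy(x, F, window) -> float:
    lo, hi = window
    mask = (x >= lo) & (x <= hi) & np.isfinite(F)
    if not np.any(mask):
        raise ValueError(f"state window {window} contains no sampled bins")
    return float(-logsumexp(-F[mask]))


# ---------------------------------------------------------------------------
# binding affinity


@dataclass
class BindingAffinity:
    delta_g_bind: float          # kT, bound relative to unbound
    box_volume_nm3: float
    kd_nm: float                 # nanomolar
    populations: dict[str, float] = field(default_factory=dict)
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)


def classify_binding_state(
    drms_value: float,
    bs_max: float = BS_MAX_DRMS,
    is_max: float = IS_MAX_DRMS,
    us_min: float = US_MIN_DRMS,
) -> str:
    """Four-state classifier on dRMS: BS / IS / EC / US."""
    if drms_value < bs_max:
        return "BS"
    if drms_value < is_max:
        return "IS"
    if drms_value <= us_min:
        return "EC"
    return "US"


def kd_from_pmf(
    pmf: FreeEnergySurface,
    bound_window: tuple[float, float] = (0.0, BS_MAX_DRMS),
    unbound_min: float = US_MIN_DRMS,
    box_volume_nm3: float = 1000.0,
    state_windows: dict[str, tuple[float, float]] | None = None,
) -> BindingAffinity:
    """Dissociation constant from a dRMS potential of mean force.

    The bound/unbound Boltzmann integrals give the bound fraction at the
    single-molecule box concentration C_box = 1/(N_A V_box); the standard
    1 M state then yields Kd = C_box * I_unbound / I_bound.
    """
    x, F = pmf.axes[0], pmf.values
    if x.max() < unbound_min:
        raise ValueError(
            f"PMF grid ends at {x.max():.2f} nm, before the unbound plateau "
            f"({unbound_min:g} nm)"
        )
    finite = np.isfinite(F)
    lb = _log_integral(x, F, finite & (x >= bound_window[0]) & (x <= bound_window[1]))
    lu = _log_integral(x, F, finite & (x > unbound_min))
    delta_g = -(lb - lu)
    c_box_molar = _CONC_PER_NM3 / box_volume_nm3
    kd_molar = c_box_molar * np.exp(lu - lb)
    windows = state_windows or {
        "BS": (0.0, BS_MAX_DRMS),
        "IS": (BS_MAX_DRMS, IS_MAX_DRMS),
        "EC": (IS_MAX_DRMS, US_MIN_DRMS),
        "US": (US_MIN_DRMS, float(x.max())),
    }
    logs = {
        s: _log_integral(x, F, finite & (x >= w[0]) & (x < w[1]))
        for s, w in windows.items()
    }
    norm = logsumexp(np.array(list(logs.values())))
    pops = {s: float(np.exp(v - norm)) for s, v in logs.items()}
    return BindingAffinity(
        delta_g_bind=float(delta_g),
        box_volume_nm3=box_volume_nm3,
        kd_nm=float(kd_molar * 1e9),
        populations=pops,
        windows=windows,
    )


def _log_integral(x, F, mask) -> float:
    if not np.any(mask):
        raise ValueError("integration window contains no sampled bins")
    dx = np.gradient(x)
    return float(logsumexp(-F[mask], b=dx[mask]))
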