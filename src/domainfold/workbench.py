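"""Campaign orchestration and command-line interface.

Three campaigns mirror the study design: ``fold`` (replica-exchange
thermodynamics at the reference contact weighting rho0, reweighted free
energy surfaces and melting/coupling analyses across a rho range, plus
constant-temperature kinetic runs), ``bind`` (umbrella-sampling potential of
mean force over dRMS, dissociation constant, diffusion/RMSF of the free
protein, encounter statistics, and metadynamics transition times), and
``build`` (model construction only). Configurations are YAML; every random
draw derives from the single global seed via named streams, and the full
configuration is echoed into the output directory.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import logging

import click
import numpy as np
import pandas as pd
import yaml

_log = logging.getLogger(__name__)

from . import coordinates, kinetics, thermo
from .hamiltonian import ForceField, PackedSystem, rescale_for_temperature
from .model_builder import (
    build_contacts, build_dual_basin, classify_contacts, coarse_grain, parse_pdb,
)
from .sampler import (
    SimulationDivergedError, SimulationProtocol, derive_seed, run_langevin,
    run_metadynamics, run_remd, run_umbrella,
)
from .synthetic_data import ToySpec, make_toy_binding_system, make_toy_multidomain

#: rho grid of the study: 0.5 to 1.5 in steps of 0.1
DEFAULT_RHO_LIST = [round(0.5 + 0.1 * k, 1) for k in range(11)]


def map_temperature(t_exp_kelvin: float, tf_exp_kelvin: float, tf_sim: float) -> float:
    """Map an experimental temperature into reduced simulation units.

    T(sim) = T(exp) * Tf(sim) / Tf(exp): the simulated and experimental
    folding temperatures are aligned and other temperatures scaled linearly.
    """
    if min(t_exp_kelvin, tf_exp_kelvin, tf_sim) <= 0:
        raise ValueError("temperatures must be positive")
    return t_exp_kelvin * tf_sim / tf_exp_kelvin


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "runs"
    toy: dict = field(default_factory=dict)
    structures: dict = field(default_factory=dict)
    rho_list: list = field(default_factory=lambda: [0.8, 1.0, 1.2])
    rho0: float = 1.0
    ladder: list = field(default_factory=lambda: list(np.geomspace(0.75, 1.25, 8)))
    remd_steps: int = 200_000
    timestep: float = 0.001
    exchange_interval: int = 3000
    record_interval: int = 300
    n_kinetic: int = 10
    kinetic_steps: int = 300_000
    kinetic_temperature_factor: float = 0.81   # room-temperature analog
    fpt_threshold: float = 0.75
    umbrella_centers: list = field(default_factory=lambda: list(np.linspace(0.0, 4.0, 17)))
    umbrella_spring: float = 40.0
    umbrella_steps: int = 60_000
    binding_temperature: float = 0.7
    box_volume_nm3: float = 1000.0
    n_encounter: int = 20
    encounter_steps: int = 200_000
    metad_runs: int = 5
    metad_steps: int = 400_000
    # toy-scale four-state thresholds (nm); the full-scale defaults live in thermo
    bs_max_drms: float = 0.3
    is_max_drms: float = 1.0
    us_min_drms: float = 3.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def echo(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), sort_keys=True)
        )


def _toy_spec(config: RunConfig, **overrides) -> ToySpec:
    fields = dict(config.toy)
    fields.pop("kind", None)
    fields.update(overrides)
    if "charge_pattern" in fields and fields["charge_pattern"] is not None:
        fields["charge_pattern"] = tuple(fields["charge_pattern"])
    fields.setdefault("seed", config.seed)
    return ToySpec(**fields)


def cmd_build(config: RunConfig) -> dict:
    """Build models and contact maps; write them under outdir/build."""
    outdir = Path(config.outdir) / "build"
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    artifacts = {}
    if config.structures:
        apo_path = Path(config.structures["apo"])
        if not apo_path.exists():
            raise click.ClickException(f"structure file not found: {apo_path}")
        domains = {
            k: [tuple(iv) for iv in v]
            for k, v in config.structures["domains"].items()
        }
        apo = parse_pdb(apo_path.read_text())
        model = coarse_grain(apo, domains)
        contacts = classify_contacts(build_contacts(apo, model), model)
        if "binary" in config.structures:
            binary_path = Path(config.structures["binary"])
            if not binary_path.exists():
                raise click.ClickException(f"structure file not found: {binary_path}")
            binary = parse_pdb(binary_path.read_text())
            bmodel = coarse_grain(binary, domains, freeze_nucleic=True)
            bcontacts = classify_contacts(build_contacts(binary, bmodel), bmodel)
            contacts = build_dual_basin(contacts, bcontacts)
            model = bmodel
        artifacts["model"], artifacts["contacts"] = model, contacts
    else:
        kind = config.toy.get("kind", "multidomain")
        if kind == "binding":
            system = make_toy_binding_system(_toy_spec(config))
        else:
            system = make_toy_multidomain(_toy_spec(config))
        artifacts["model"], artifacts["contacts"] = system.model, system.contacts
        artifacts["system"] = system
        (outdir / "native.pdb").write_text(system.pdb_text)
    (outdir / "model.json").write_text(artifacts["model"].to_json())
    (outdir / "contacts.csv").write_text(artifacts["contacts"].to_csv())
    return artifacts


def cmd_fold(config: RunConfig) -> dict:
    """Folding campaign: REMD thermodynamics + reweighting + kinetics."""
    outdir = Path(config.outdir) / "fold"
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    system = make_toy_multidomain(_toy_spec(config))
    model, contacts = system.model, system.contacts
    elements = system.element_subsets()

    ff0 = ForceField(rho=config.rho0)
    packed = PackedSystem(model, contacts, ff0)
    proto = SimulationProtocol(
        n_steps=config.remd_steps, timestep=config.timestep,
        ladder=tuple(config.ladder), exchange_interval=config.exchange_interval,
        record_interval=config.record_interval,
        seed=derive_seed(config.seed, 1),
    )
    records = run_remd(model, contacts, ff0, proto, system=packed)
    burn = records[0].n_frames // 4
    for rec in records:
        rec.cv["Q_total"] = coordinates.q_series(rec.positions, contacts)

    wham = thermo.wham_temperature(
        [(r.temperature, r.total_energy[burn:], r.cv["Q_total"][burn:]) for r in records]
    )
    pd.DataFrame({
        "T": wham.temperatures, "Cv": wham.heat_capacity,
    }).to_csv(outdir / "heat_capacity.csv", index=False)

    # per-rho folding temperature from reweighted global melting curves
    ladder = np.array([r.temperature for r in records])
    tf_by_rho, fes_rows = {}, []
    q_bins = np.linspace(0.0, 1.0, 21)
    t_star = ladder[len(ladder) // 2]
    k_star = len(ladder) // 2
    for rho in sorted(set(config.rho_list) | {config.rho0}):
        p_fold = []
        for rec in records:
            w, _ = thermo.reweight_rho(
                rec.energies[burn:], config.rho0, rho, rec.temperature
            )
            p_fold.append(
                float(np.sum(w * (rec.cv["Q_total"][burn:] >= 0.5)) / np.sum(w))
            )
        curve = thermo.melting_curves(
            {"global": np.array(p_fold)}, ladder, presupplied_probabilities=True
        )[0]
        tf_by_rho[rho] = curve.tm if not curve.flagged else float("nan")
        w, _ = thermo.reweight_rho(
            records[k_star].energies[burn:], config.rho0, rho, t_star
        )
        fes = thermo.weighted_fes(
            records[k_star].cv["Q_total"][burn:], w, q_bins, t_star
        )
        for q, f in zip(fes.axes[0], fes.values):
            fes_rows.append((rho, t_star, q, f))
    pd.DataFrame(
        fes_rows, columns=["rho", "T", "Q_total", "F_kT"]
    ).to_csv(outdir / "fes_by_rho.csv", index=False)

    # melting curves and thermodynamic coupling per element
    per_el = {
        name: [coordinates.q_series(r.positions[burn:], sub) for r in records]
        for name, sub in elements.items()
    }
    curves = thermo.melting_curves(per_el, ladder)
    usable = [c for c in curves if not c.flagged]
    mtci_val = thermo.mtci(usable) if len(usable) >= 2 else float("nan")
    pd.DataFrame({
        "element": [c.element for c in curves],
        "Tm": [c.tm for c in curves], "width": [c.width for c in curves],
        "flagged": [c.flagged for c in curves],
    }).to_csv(outdir / "melting.csv", index=False)

    # kinetics per rho at the shared low temperature, with the potential
    # rescaled so every rho folds at the same bath temperature
    tf0 = tf_by_rho.get(config.rho0, wham.tf)
    if not np.isfinite(tf0):
        tf0 = wham.tf
    tf0 = float(np.clip(tf0, ladder.min(), ladder.max()))
    t_kin = config.kinetic_temperature_factor * tf0
    t_hot = min(1.5 * tf0, 1.6)
    kin_rows = []
    op_by_rho = {}
    for rho in config.rho_list:
        ff = ForceField(rho=rho)
        if np.isfinite(tf_by_rho.get(rho, np.nan)):
            ff = rescale_for_temperature(ff, tf0, tf_by_rho[rho])
        packed_rho = PackedSystem(model, contacts, ff)
        fpts, order_events, n_backtrack = [], [], 0
        for run in range(config.n_kinetic):
            # unfolded start: brief hot equilibration
            hot = SimulationProtocol(
                n_steps=40_000, timestep=config.timestep / 2, temperature=t_hot,
                record_interval=40_000, seed=derive_seed(config.seed, 2, run),
            )
            start = run_langevin(
                model, contacts, ff, hot, system=packed_rho
            ).positions[-1]
            proto_k = SimulationProtocol(
                n_steps=config.kinetic_steps, timestep=config.timestep,
                temperature=t_kin, record_interval=config.record_interval,
                seed=derive_seed(config.seed, 3, int(rho * 100), run),
            )
            try:
                rec = run_langevin(
                    model, contacts, ff, proto_k, start_coords=start,
                    system=packed_rho,
                )
            except SimulationDivergedError:
                _log.warning("kinetic run %d at rho %g diverged; discarded", run, rho)
                fpts.append(None)
                continue
            q_tot = coordinates.q_series(rec.positions, contacts)
            inter_like = contacts.subset(
                lambda r: r.contact_class.startswith(("inter", "linker"))
            )
            q_int = coordinates.q_series(rec.positions, inter_like)
            fpts.append(kinetics.first_passage(rec.times, q_tot, config.fpt_threshold))
            n_backtrack += len(kinetics.detect_backtracking(q_tot, q_int))
            q_by_el = {
                name: coordinates.q_series(rec.positions, sub)
                for name, sub in elements.items()
            }
            ev = kinetics.element_folding_steps(
                rec.times, q_by_el, q_tot, config.fpt_threshold
            )
            if ev is not None:
                order_events.append(ev)
        done = [t for t in fpts if t is not None]
        kin_rows.append({
            "rho": rho, "n_runs": config.n_kinetic, "n_folded": len(done),
            "mfpt": float(np.mean(done)) if done else float("nan"),
            "sd_fpt": float(np.std(done)) if done else float("nan"),
            "backtracking_events": n_backtrack,
        })
        if order_events:
            op = kinetics.folding_order(order_events, list(elements))
            op_by_rho[rho] = op
            pd.DataFrame(
                op.matrix, columns=op.elements,
                index=[f"step{k+1}" for k in range(len(op.elements))],
            ).to_csv(outdir / f"op_matrix_rho{rho:g}.csv")
    pd.DataFrame(kin_rows).to_csv(outdir / "mfpt_by_rho.csv", index=False)

    summary = {
        "seed": config.seed,
        "tf_rho0_cv_peak": wham.tf,
        "tf_by_rho": {str(k): v for k, v in tf_by_rho.items()},
        "mtci": mtci_val,
        "kinetic_temperature": t_kin,
        "mfpt_by_rho": {str(r["rho"]): r["mfpt"] for r in kin_rows},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return {
        "wham": wham, "curves": curves, "mtci": mtci_val,
        "kinetics": kin_rows, "op_by_rho": op_by_rho, "summary": summary,
    }


def cmd_bind(config: RunConfig) -> dict:
    """Binding campaign: PMF, Kd, diffusion, encounter, transition times."""
    outdir = Path(config.outdir) / "bind"
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    spec = _toy_spec(
        config, partner_length=config.toy.get("partner_length", 5),
        charge_pattern=tuple(
            config.toy.get("charge_pattern", ("ARG", "GLY", "GLY", "GLY", "GLY", "GLY"))
        ),
        dual_basin=config.toy.get("dual_basin", True),
    )
    system = make_toy_binding_system(spec)
    model, contacts = system.model, system.contacts
    binding = contacts.by_class("binding")
    ff = ForceField(rho=config.rho0)
    packed = PackedSystem(model, contacts, ff)
    T = config.binding_temperature

    proto_u = SimulationProtocol(
        n_steps=config.umbrella_steps, timestep=config.timestep, temperature=T,
        record_interval=config.record_interval // 3 or 50,
        seed=derive_seed(config.seed, 10),
    )
    windows = [(c, config.umbrella_spring) for c in config.umbrella_centers]
    urecs = run_umbrella(
        model, contacts, ff, windows, proto_u,
        n_equil=config.umbrella_steps // 4, system=packed,
    )
    pmf = thermo.wham_umbrella(urecs)
    pmf.to_frame().to_csv(outdir / "pmf_drms.csv", index=False)
    state_windows = {
        "BS": (0.0, config.bs_max_drms),
        "IS": (config.bs_max_drms, config.is_max_drms),
        "EC": (config.is_max_drms, config.us_min_drms),
        "US": (config.us_min_drms, float(pmf.axes[0].max())),
    }
    affinity = thermo.kd_from_pmf(
        pmf, bound_window=(0.0, config.bs_max_drms),
        unbound_min=config.us_min_drms, box_volume_nm3=config.box_volume_nm3,
        state_windows=state_windows,
    )

    # free protein: diffusion and flexibility
    free = make_toy_multidomain(
        ToySpec(
            n_domains=spec.n_domains, beads_per_domain=spec.beads_per_domain,
            linker_length=spec.linker_length, target_ratio=spec.target_ratio,
            seed=spec.seed, charge_pattern=spec.charge_pattern,
        )
    )
    proto_f = SimulationProtocol(
        n_steps=config.encounter_steps, timestep=config.timestep, temperature=T,
        record_interval=config.record_interval, seed=derive_seed(config.seed, 11),
    )
    frec = run_langevin(free.model, free.contacts, ForceField(rho=config.rho0), proto_f)
    n_frames = frec.n_frames
    diff = coordinates.diffusion_coefficient(
        frec.positions, frec.times, lag_window=(max(1, n_frames // 50), n_frames // 5)
    )
    _, mean_rmsf = coordinates.rmsf(frec.positions[n_frames // 4:])

    # encounter statistics: runs from EC-like starts
    outcomes = []
    ec_start = _ec_start_coords(system, config)
    for run in range(config.n_encounter):
        proto_e = SimulationProtocol(
            n_steps=config.encounter_steps, timestep=config.timestep,
            temperature=T, record_interval=config.record_interval // 3 or 50,
            seed=derive_seed(config.seed, 12, run),
        )
        try:
            rec = run_langevin(
                model, contacts, ff, proto_e, start_coords=ec_start,
                system=packed, confine=(50.0, 6.0),
            )
        except SimulationDivergedError:
            _log.warning("encounter run %d diverged; discarded", run)
            continue
        d = rec.cv["dRMS"]
        hit_is = np.nonzero(d < config.is_max_drms)[0]
        hit_us = np.nonzero(d > config.us_min_drms)[0]
        t_is = rec.times[hit_is[0]] if len(hit_is) else np.inf
        t_us = rec.times[hit_us[0]] if len(hit_us) else np.inf
        if np.isinf(t_is) and np.isinf(t_us):
            continue  # undecided within budget
        outcomes.append(
            ("IS", float(t_is)) if t_is < t_us else ("US", float(t_us))
        )
    enc = (
        kinetics.encounter_framework(outcomes) if outcomes else None
    )

    # IS <-> BS transition times by metadynamics
    is_start = _drms_start_coords(system, config, target=0.6 * config.is_max_drms)
    runs = []
    for run in range(config.metad_runs):
        proto_m = SimulationProtocol(
            n_steps=config.metad_steps, timestep=config.timestep, temperature=T,
            record_interval=config.record_interval, seed=derive_seed(config.seed, 13, run),
        )
        try:
            rec = run_metadynamics(
                model, contacts, ff, proto_m,
                hill_height=0.3, hill_width=0.1, hill_stride=1000,
                target=(0.0, config.bs_max_drms), start_coords=is_start,
                system=packed,
            )
        except SimulationDivergedError:
            _log.warning("metadynamics run %d diverged; counted censored", run)
            runs.append({"t_rescaled": None, "censored": True})
            continue
        runs.append({"t_rescaled": rec.t_rescaled, "censored": rec.censored})
    try:
        rate = kinetics.metad_transition_time(runs, seed=derive_seed(config.seed, 14))
        rate_out = {
            "tau_trans": rate.mean, "bootstrap_error": rate.bootstrap_error,
            "n_bootstrap": rate.n_bootstrap, "censored": rate.censored,
        }
    except kinetics.KineticsError:
        rate_out = {"tau_trans": None, "censored": len(runs)}

    summary = {
        "seed": config.seed,
        "kd_nM": affinity.kd_nm,
        "delta_g_bind_kT": affinity.delta_g_bind,
        "populations": affinity.populations,
        "state_windows_nm": {k: list(v) for k, v in state_windows.items()},
        "diffusion_nm2_per_tau": diff,
        "mean_rmsf_nm": mean_rmsf,
        "encounter": None if enc is None else {
            "n_evo": enc.n_evo, "n_dis": enc.n_dis,
            "encounter_time": enc.encounter_time,
        },
        "is_bs_transition": rate_out,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return {"pmf": pmf, "affinity": affinity, "summary": summary}


def _ec_start_coords(system, config: RunConfig) -> np.ndarray:
    """Protein displaced so dRMS sits inside the encounter-complex window."""
    target = 0.5 * (config.is_max_drms + config.us_min_drms)
    return _drms_start_coords(system, config, target)


def _drms_start_coords(system, config: RunConfig, target: float) -> np.ndarray:
    model = system.model
    binding = system.contacts.by_class("binding")
    protein = ~np.array([k != "CA" for k in model.kinds])
    coords = np.array(model.positions)
    direction = np.array([0.0, 1.0, 0.3])
    direction /= np.linalg.norm(direction)
    lo, hi = 0.0, 40.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        trial = np.array(model.positions)
        trial[protein] += mid * direction
        if coordinates.drms(trial, binding) < target:
            lo = mid
        else:
            hi = mid
    coords[protein] += lo * direction
    return coords


# ---------------------------------------------------------------------------
# validation experiments: closed-form / paired-simulation oracles run at
# desk scale; shared by the test suite and the acceptance script


def reweight_validation(
    seed: int = 11,
    rho_target: float = 0.8,
    remd_steps: int = 600_000,
    n_ladder: int = 8,
    min_counts: int = 25,
) -> dict:
    """Reweighted F(Q_total) from rho0 = 1 versus direct replica exchange at
    rho_target, compared bin-by-bin (kT) at a mid-ladder temperature."""
    system = make_toy_multidomain(ToySpec(seed=0))
    model, contacts = system.model, system.contacts
    ladder = tuple(np.geomspace(0.75, 1.25, n_ladder))

    def remd_at(rho, stream):
        ff = ForceField(rho=rho)
        packed = PackedSystem(model, contacts, ff)
        proto = SimulationProtocol(
            n_steps=remd_steps, timestep=0.001, ladder=ladder,
            exchange_interval=3000, record_interval=300,
            seed=derive_seed(seed, stream),
        )
        return run_remd(model, contacts, ff, proto, system=packed)

    recs_ref = remd_at(1.0, 1)
    recs_direct = remd_at(rho_target, 2)
    burn = recs_ref[0].n_frames // 4
    k = n_ladder // 2
    T = ladder[k]
    q_ref = coordinates.q_series(recs_ref[k].positions[burn:], contacts)
    q_dir = coordinates.q_series(recs_direct[k].positions[burn:], contacts)
    w, ess = thermo.reweight_rho(
        recs_ref[k].energies[burn:], 1.0, rho_target, T
    )
    bins = np.linspace(0.0, 1.0, 21)
    h_rw, _ = np.histogram(q_ref, bins=bins, weights=w)
    h_dir, _ = np.histogram(q_dir, bins=bins)
    good = (h_dir >= min_counts) & (h_rw >= min_counts / len(q_dir))
    with np.errstate(divide="ignore", invalid="ignore"):
        f_rw = -np.log(h_rw / h_rw.sum())
        f_dir = -np.log(h_dir / h_dir.sum())
        dev = np.abs(f_rw - f_dir)[good]
    return {
        "temperature": float(T),
        "rho_target": rho_target,
        "ess": ess,
        "n_samples": len(q_ref),
        "n_bins_compared": int(good.sum()),
        "max_dev_kT": float(dev.max()),
        "mean_dev_kT": float(dev.mean()),
    }


def equipartition_validation(seed: int = 100, n_runs: int = 10) -> dict:
    """Per-bond potential energy of a harmonic chain against kT/2."""
    from .model_builder import ContactSet
    from .synthetic_data import make_harmonic_chain

    chain = make_harmonic_chain(8, stiffness=100.0)
    ff = ForceField(electrostatics=False)
    cs = ContactSet([])
    packed = PackedSystem(chain, cs, ff, include_excluded_volume=False)
    kT = 1.0
    means = []
    for k in range(n_runs):
        proto = SimulationProtocol(
            n_steps=80_000, timestep=0.003, temperature=kT,
            record_interval=100, seed=derive_seed(seed, k),
        )
        rec = run_langevin(chain, cs, ff, proto, system=packed)
        burn = rec.n_frames // 5
        means.append(rec.energies[burn:, 0].mean() / (chain.n_beads - 1))
    means = np.array(means)
    se = float(means.std(ddof=1) / np.sqrt(len(means)))
    return {
        "pe_per_mode": float(means.mean()),
        "expected": kT / 2,
        "standard_error": se,
        "deviation_in_se": float(abs(means.mean() - kT / 2) / se),
        "n_runs": n_runs,
    }


def double_well_pmf_validation(seed: int = 5, barrier: float = 3.0) -> dict:
    """Umbrella WHAM on the quartic double well against the analytic PMF."""
    from .sampler import run_umbrella_1d
    from .synthetic_data import make_double_well

    well = make_double_well(barrier)
    windows = [(c, 20.0) for c in np.linspace(-1.6, 1.6, 17)]
    recs = run_umbrella_1d(well.barrier, windows, 150_000, seed=seed)
    pmf = thermo.wham_umbrella(recs, grid=np.linspace(-1.8, 1.8, 73))
    x = pmf.axes[0]
    ref = well.analytic_pmf(x)
    mask = np.isfinite(pmf.values) & (np.abs(x) < 1.5)
    err = np.abs(pmf.values[mask] - ref[mask])
    return {
        "barrier_kT": barrier,
        "n_bins_compared": int(mask.sum()),
        "max_err_kT": float(err.max()),
        "mean_err_kT": float(err.mean()),
    }


def metad_rate_validation(
    seed: int = 43, barrier: float = 4.0, n_unbiased: int = 50, n_metad: int = 16
) -> dict:
    """Rescaled metadynamics transition times against the unbiased MFPT."""
    from .sampler import run_metadynamics_1d
    from .synthetic_data import brute_force_mfpt_1d, make_double_well

    well = make_double_well(barrier)
    mfpt, censored = brute_force_mfpt_1d(
        well, n_runs=n_unbiased, n_steps=1_500_000, dt=0.005,
        seed=derive_seed(seed, 1) % 2_000_000,
    )
    runs = []
    for k in range(n_metad):
        out = run_metadynamics_1d(
            well.barrier, 2_000_000, (0.9, 1.3), dt=0.005,
            seed=derive_seed(seed, 2, k),
            hill_height=0.25, hill_width=0.15, hill_stride=1000,
            bias_factor=8.0,
        )
        runs.append(out)
    est = kinetics.metad_transition_time(
        [{"t_rescaled": r["t_rescaled"], "censored": r["censored"]} for r in runs],
        seed=derive_seed(seed, 3),
    )
    return {
        "barrier_kT": barrier,
        "unbiased_mfpt": mfpt,
        "unbiased_censored": censored,
        "metad_mean": est.mean,
        "metad_bootstrap_error": est.bootstrap_error,
        "metad_censored": est.censored,
        "ratio": est.mean / mfpt,
    }


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli():
    """Coarse-grained multidomain folding and binding workbench."""


def _load_config(config_path, seed, outdir, toy):
    config = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    if seed is not None:
        config.seed = seed
    if outdir is not None:
        config.outdir = outdir
    if toy:
        config.toy.setdefault("kind", toy)
    return config


_shared = [
    click.option("--config", "config_path", type=click.Path(exists=True), default=None),
    click.option("--seed", type=int, default=None),
    click.option("--outdir", type=click.Path(), default=None),
    click.option("--toy", type=click.Choice(["multidomain", "binding"]), default=None),
]


def _with_shared(f):
    for opt in reversed(_shared):
        f = opt(f)
    return f


@cli.command()
@_with_shared
def build(config_path, seed, outdir, toy):
    """Build the coarse model and classified contact map."""
    config = _load_config(config_path, seed, outdir, toy)
    artifacts = cmd_build(config)
    totals = artifacts["contacts"].class_totals()
    click.echo(f"beads: {artifacts['model'].n_beads}  contacts: {totals}")


@cli.command()
@_with_shared
def fold(config_path, seed, outdir, toy):
    """Run the folding campaign (REMD + reweighting + kinetics)."""
    config = _load_config(config_path, seed, outdir, toy)
    out = cmd_fold(config)
    click.echo(json.dumps(out["summary"], indent=1))


@cli.command()
@_with_shared
def bind(config_path, seed, outdir, toy):
    """Run the binding campaign (PMF, Kd, encounter, rates)."""
    config = _load_config(config_path, seed, outdir, toy)
    out = cmd_bind(config)
    click.echo(json.dumps(out["summary"], indent=1))


@cli.command()
@_with_shared
@click.option("--rho", type=float, required=True)
def reweight(config_path, seed, outdir, toy, rho):
    """Reweighted free-energy surface at a single rho (runs fold REMD)."""
    config = _load_config(config_path, seed, outdir, toy)
    config.rho_list = [rho]
    out = cmd_fold(config)
    click.echo(json.dumps(out["summary"], indent=1))


@cli.command("map-temperature")
@click.argument("t_exp", type=float)
@click.argument("tf_exp", type=float)
@click.argument("tf_sim", type=float)
def map_temperature_cmd(t_exp, tf_exp, tf_sim):
    """Map an experimental temperature (K) into reduced units."""
    t = map_temperature(t_exp, tf_exp, tf_sim)
    click.echo(f"{t:.2f} (full precision: {t!r})")


@cli.command()
@click.option("--outdir", type=click.Path(), default="runs")
def report(outdir):
    """Summarize the JSON outputs found under an output directory."""
    root = Path(outdir)
    found = sorted(root.glob("*/summary.json"))
    if not found:
        click.echo(f"no campaign summaries under {root}")
        return
    for p in found:
        click.echo(f"== {p.parent.name} ==")
        click.echo(p.read_text())
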