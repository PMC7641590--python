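"""Trajectory generation in reduced units.

Langevin dynamics uses the BAOAB splitting with unit bead masses, kB = 1 and
time in tau. Temperature replica exchange swaps configurations between
neighboring rungs with the Metropolis criterion; umbrella sampling and
well-tempered metadynamics bias the protein-DNA dRMS coordinate. A
one-dimensional quartic double well with analytic Boltzmann statistics is
available through the ``*_1d`` helpers as an oracle for the thermodynamic
and rate estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .hamiltonian import ForceField, PackedSystem
from .model_builder import CoarseModel, ContactSet

MAX_HILLS = 20000


class SimulationDivergedError(RuntimeError):
    pass


def derive_seed(base: int, *keys: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and stream keys."""
    ss = np.random.SeedSequence(int(base), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


@dataclass
class SimulationProtocol:
    n_steps: int = 100_000
    timestep: float = 0.0005          # tau
    friction: float = 1.0             # 1/tau
    temperature: float = 1.0          # reduced; ignored when ladder given
    ladder: tuple[float, ...] | None = None
    exchange_interval: int = 1000
    record_interval: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.ladder is not None:
            lad = tuple(self.ladder)
            if any(b < a for a, b in zip(lad, lad[1:])):
                raise ValueError("temperature ladder must be non-decreasing")
            self.ladder = lad


@dataclass
class TrajectoryRecord:
    times: np.ndarray                 # tau
    positions: np.ndarray             # (F, N, 3)
    energies: np.ndarray              # (F, 8) decomposed, kernel layout
    temperature: float
    protocol: SimulationProtocol
    seed: int
    cv: dict[str, np.ndarray] = field(default_factory=dict)
    exchange_log: list = field(default_factory=list)
    hill_log: dict | None = None
    bias: np.ndarray | None = None
    window: tuple[float, float] | None = None   # (center, spring) for umbrella
    t_rescaled: float | None = None
    reached: bool = False
    censored: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def total_energy(self) -> np.ndarray:
        return self.energies.sum(axis=1)

    def to_xyz(self, labels: list[str] | None = None) -> str:
        """Multi-frame XYZ text (coordinates in nm)."""
        n = self.positions.shape[1]
        labels = labels if labels is not None else ["C"] * n
        chunks = []
        for t, frame in zip(self.times, self.positions):
            chunks.append(f"{n}\ntime={t:g} tau T={self.temperature:g}")
            for lab, (x, y, z) in zip(labels, frame):
                chunks.append(f"{lab} {x:.6f} {y:.6f} {z:.6f}")
        return "\n".join(chunks) + "\n"

    def energy_table(self):
        """Tidy per-frame table of the decomposed energies and CVs."""
        import pandas as pd

        names = (
            "bonded", "intra", "inter", "linker", "binary_basin",
            "binding", "electrostatic", "excluded",
        )
        data = {"time": self.times}
        data.update({k: self.energies[:, i] for i, k in enumerate(names)})
        data["total"] = self.energies.sum(axis=1)
        for k, v in self.cv.items():
            if len(np.atleast_1d(v)) == len(self.times):
                data[k] = v
        if self.bias is not None and len(self.bias) == len(self.times):
            data["bias"] = self.bias
        return pd.DataFrame(data)

    def concat(self, other: "TrajectoryRecord") -> "TrajectoryRecord":
        return replace(
            self,
            times=np.concatenate([self.times, other.times]),
            positions=np.concatenate([self.positions, other.positions]),
            energies=np.concatenate([self.energies, other.energies]),
            cv={
                k: np.concatenate([v, other.cv[k]])
                for k, v in self.cv.items() if k in other.cv
            },
        )


_NO_BIND = (
    np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64), np.zeros(0),
)
_NO_HILLS = (np.zeros(MAX_HILLS), np.zeros(MAX_HILLS))


def _segment(
    system: PackedSystem,
    pos: np.ndarray,
    vel: np.ndarray,
    n_steps: int,
    dt: float,
    gamma: float,
    kT: float,
    seed: int,
    record_every: int,
    bias_kind: int = _kernels.BIAS_NONE,
    umb: tuple[float, float] = (0.0, 0.0),
    metad: dict | None = None,
    hills: tuple[np.ndarray, np.ndarray] | None = None,
    n_hills: int = 0,
    target: tuple[float, float] = (1.0, 0.0),
    confine: tuple[float, float] = (0.0, 0.0),
):
    md = metad or {}
    hc, hh = hills if hills is not None else (np.zeros(MAX_HILLS), np.zeros(MAX_HILLS))
    out = _kernels.run_md(
        pos, vel, *system.kernel_args(),
        n_steps, dt, gamma, kT, seed, record_every,
        bias_kind, system.bind_i, system.bind_j, system.bind_sigma,
        umb[0], umb[1],
        md.get("height", 0.0), md.get("width", 0.1),
        md.get("stride", 500), md.get("bias_factor", 6.0),
        hc, hh, n_hills,
        target[0], target[1],
        confine[0], confine[1],
        1 if md.get("adaptive", False) else 0,
    )
    if out[8]:
        raise SimulationDivergedError(
            "potential energy exceeded the divergence guard; reduce the "
            "timestep or check the starting structure"
        )
    return out, hc, hh


def run_langevin(
    model: CoarseModel,
    contacts: ContactSet,
    forcefield: ForceField,
    protocol: SimulationProtocol,
    start_coords: np.ndarray | None = None,
    system: PackedSystem | None = None,
    confine: tuple[float, float] = (0.0, 0.0),
) -> TrajectoryRecord:
    """Constant-temperature Langevin trajectory; frozen beads stay immobile."""
    if system is None:
        system = PackedSystem(model, contacts, forcefield)
    pos = np.array(
        start_coords if start_coords is not None else model.positions,
        dtype=np.float64,
    )
    vel = _draw_velocities(model, protocol.temperature, derive_seed(protocol.seed, 7))
    (fp, fc, fcv, fb, *_rest), _, _ = _segment(
        system, pos, vel, protocol.n_steps, protocol.timestep,
        protocol.friction, protocol.temperature, derive_seed(protocol.seed),
        protocol.record_interval, confine=confine,
    )
    times = protocol.timestep * protocol.record_interval * np.arange(1, len(fp) + 1)
    cv = {}
    if system.bind_i.shape[0] > 0:
        cv["dRMS"] = fcv
    return TrajectoryRecord(
        times=times, positions=fp, energies=fc,
        temperature=protocol.temperature, protocol=protocol,
        seed=protocol.seed, cv=cv, bias=fb,
    )


def _draw_velocities(model: CoarseModel, kT: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    vel = rng.normal(0.0, np.sqrt(max(kT, 0.0)), size=(model.n_beads, 3))
    vel[model.frozen] = 0.0
    return vel


def run_remd(
    model: CoarseModel,
    contacts: ContactSet,
    forcefield: ForceField,
    protocol: SimulationProtocol,
    start_coords: np.ndarray | None = None,
    system: PackedSystem | None = None,
) -> list[TrajectoryRecord]:
    """Temperature replica exchange; one record per ladder rung.

    Configurations (with velocity rescaling) are swapped between neighboring
    temperatures every ``exchange_interval`` steps with acceptance
    min(1, exp(dbeta * dE)); each returned trajectory is the continuous
    constant-temperature series at its rung.
    """
    if protocol.ladder is None or len(protocol.ladder) < 2:
        raise ValueError("REMD requires a ladder with at least two temperatures")
    if protocol.exchange_interval % protocol.record_interval != 0:
        raise ValueError("record_interval must divide exchange_interval")
    if system is None:
        system = PackedSystem(model, contacts, forcefield)
    ladder = protocol.ladder
    n_rep = len(ladder)
    x0 = np.array(
        start_coords if start_coords is not None else model.positions,
        dtype=np.float64,
    )
    pos = [x0.copy() for _ in range(n_rep)]
    vel = [
        _draw_velocities(model, T, derive_seed(protocol.seed, 7, k))
        for k, T in enumerate(ladder)
    ]
    replica_id = list(range(n_rep))  # conserved multiset under swaps

    n_rounds = protocol.n_steps // protocol.exchange_interval
    frames = [[] for _ in range(n_rep)]
    comps = [[] for _ in range(n_rep)]
    attempts = np.zeros(n_rep - 1)
    accepts = np.zeros(n_rep - 1)
    exchange_log = []

    rng = np.random.default_rng(derive_seed(protocol.seed, 11))
    for rnd in range(n_rounds):
        energies = np.zeros(n_rep)
        for k in range(n_rep):
            (fp, fc, *_), _, _ = _segment(
                system, pos[k], vel[k], protocol.exchange_interval,
                protocol.timestep, protocol.friction, ladder[k],
                derive_seed(protocol.seed, rnd, k), protocol.record_interval,
            )
            frames[k].append(fp)
            comps[k].append(fc)
            energies[k] = fc[-1].sum() if len(fc) else np.nan
        for k in range((rnd % 2), n_rep - 1, 2):
            beta_a, beta_b = 1.0 / ladder[k], 1.0 / ladder[k + 1]
            delta = (beta_a - beta_b) * (energies[k] - energies[k + 1])
            attempts[k] += 1
            accepted = rng.random() < min(1.0, np.exp(delta))
            if accepted:
                accepts[k] += 1
                pos[k], pos[k + 1] = pos[k + 1], pos[k]
                scale = np.sqrt(ladder[k] / ladder[k + 1])
                vel[k], vel[k + 1] = vel[k + 1] * scale, vel[k] / scale
                energies[k], energies[k + 1] = energies[k + 1], energies[k]
                replica_id[k], replica_id[k + 1] = replica_id[k + 1], replica_id[k]
            exchange_log.append((rnd, k, bool(accepted)))
        assert sorted(replica_id) == list(range(n_rep))

    rates = np.divide(
        accepts, attempts, out=np.ones_like(accepts), where=attempts > 0
    )
    records = []
    dt_rec = protocol.timestep * protocol.record_interval
    for k in range(n_rep):
        fp = np.concatenate(frames[k])
        fc = np.concatenate(comps[k])
        records.append(
            TrajectoryRecord(
                times=dt_rec * np.arange(1, len(fp) + 1),
                positions=fp, energies=fc, temperature=ladder[k],
                protocol=protocol, seed=protocol.seed,
                exchange_log=exchange_log,
            )
        )
        records[k].cv["acceptance_rates"] = rates
    return records


def run_umbrella(
    model: CoarseModel,
    contacts: ContactSet,
    forcefield: ForceField,
    windows: Sequence[tuple[float, float]],
    protocol: SimulationProtocol,
    n_equil: int = 0,
    system: PackedSystem | None = None,
) -> list[TrajectoryRecord]:
    """Umbrella sampling on dRMS; windows = [(center nm, spring eps/nm^2)].

    Windows are seeded sequentially from the previous window's final frame,
    walking outward from the native pose, which keeps neighbor histograms
    overlapping.
    """
    if system is None:
        system = PackedSystem(model, contacts, forcefield)
    if system.bind_i.shape[0] == 0:
        raise ValueError("umbrella sampling requires binding contacts (dRMS CV)")
    records = []
    pos = np.array(model.positions, dtype=np.float64)
    for w, (center, spring) in enumerate(windows):
        vel = _draw_velocities(
            model, protocol.temperature, derive_seed(protocol.seed, 7, w)
        )
        if n_equil > 0:
            (fp, *_), _, _ = _segment(
                system, pos, vel, n_equil, protocol.timestep, protocol.friction,
                protocol.temperature, derive_seed(protocol.seed, w, 999),
                max(n_equil, 1), bias_kind=_kernels.BIAS_UMBRELLA,
                umb=(center, spring),
            )
        (fp, fc, fcv, fb, *_), _, _ = _segment(
            system, pos, vel, protocol.n_steps, protocol.timestep,
            protocol.friction, protocol.temperature,
            derive_seed(protocol.seed, w), protocol.record_interval,
            bias_kind=_kernels.BIAS_UMBRELLA, umb=(center, spring),
        )
        if len(fp) == 0:
            raise RuntimeError(f"umbrella window {w} produced no samples")
        times = protocol.timestep * protocol.record_interval * np.arange(1, len(fp) + 1)
        records.append(
            TrajectoryRecord(
                times=times, positions=fp, energies=fc,
                temperature=protocol.temperature, protocol=protocol,
                seed=protocol.seed, cv={"dRMS": fcv}, bias=fb,
                window=(center, spring),
            )
        )
        pos = fp[-1].copy()
    _warn_on_overlap_gaps(records)
    return records


def _warn_on_overlap_gaps(records):
    import logging

    log = logging.getLogger(__name__)
    for a, b in zip(records, records[1:]):
        lo_a, hi_a = np.min(a.cv["dRMS"]), np.max(a.cv["dRMS"])
        lo_b, hi_b = np.min(b.cv["dRMS"]), np.max(b.cv["dRMS"])
        if hi_a < lo_b or hi_b < lo_a:
            log.warning(
                "umbrella windows at %.3f and %.3f nm do not overlap",
                a.window[0], b.window[0],
            )


def run_metadynamics(
    model: CoarseModel,
    contacts: ContactSet,
    forcefield: ForceField,
    protocol: SimulationProtocol,
    hill_height: float = 0.2,
    hill_width: float = 0.1,
    hill_stride: int = 500,
    bias_factor: float = 6.0,
    adaptive: bool = True,
    target: tuple[float, float] = (1.0, 0.0),
    start_coords: np.ndarray | None = None,
    system: PackedSystem | None = None,
) -> TrajectoryRecord:
    """Well-tempered metadynamics on dRMS with first-arrival stopping.

    The deposition interval doubles each time the running acceleration
    factor <exp(V_bias/kT)> crosses a power of ten (an infrequent-deposition
    schedule). The rescaled transition time sum(dt exp(V_bias/kT)) is
    accumulated for rate estimation; a run that never reaches the target
    window is flagged censored.
    """
    if system is None:
        system = PackedSystem(model, contacts, forcefield)
    if system.bind_i.shape[0] == 0:
        raise ValueError("metadynamics requires binding contacts (dRMS CV)")
    pos = np.array(
        start_coords if start_coords is not None else model.positions,
        dtype=np.float64,
    )
    vel = _draw_velocities(model, protocol.temperature, derive_seed(protocol.seed, 7))
    hills = (np.zeros(MAX_HILLS), np.zeros(MAX_HILLS))
    metad = {
        "height": hill_height, "width": hill_width, "stride": hill_stride,
        "bias_factor": bias_factor, "adaptive": adaptive,
    }
    (fp, fc, fcv, fb, n_hills, t_resc, reached, step_reached, _), hc, hh = _segment(
        system, pos, vel, protocol.n_steps, protocol.timestep, protocol.friction,
        protocol.temperature, derive_seed(protocol.seed), protocol.record_interval,
        bias_kind=_kernels.BIAS_METAD, metad=metad, hills=hills, target=target,
    )
    times = protocol.timestep * protocol.record_interval * np.arange(1, len(fp) + 1)
    return TrajectoryRecord(
        times=times, positions=fp, energies=fc,
        temperature=protocol.temperature, protocol=protocol,
        seed=protocol.seed, cv={"dRMS": fcv}, bias=fb,
        hill_log={
            "centers": hc[:n_hills].copy(),
            "heights": hh[:n_hills].copy(),
            "width": hill_width,
        },
        t_rescaled=t_resc, reached=bool(reached), censored=not bool(reached),
    )


# ---------------------------------------------------------------------------
# 1D double-well reference dynamics


def run_langevin_1d(
    barrier: float, n_steps: int, dt: float = 0.005, friction: float = 1.0,
    kT: float = 1.0, seed: int = 0, record_every: int = 10, x0: float = -1.0,
) -> np.ndarray:
    """Unbiased trajectory on V(x) = barrier (x^2-1)^2; returns x series."""
    xs, *_ = _kernels.run_1d(
        x0, n_steps, dt, friction, kT, derive_seed(seed), record_every,
        barrier, _kernels.BIAS_NONE, 0.0, 0.0,
        0.0, 0.1, 500, 6.0, *_NO_HILLS, 0, 1.0, 0.0, 0,
    )
    return xs


def first_passage_1d(
    barrier: float, target: tuple[float, float], n_steps: int,
    dt: float = 0.005, friction: float = 1.0, kT: float = 1.0,
    seed: int = 0, x0: float = -1.0,
) -> float | None:
    """Unbiased first-passage time into the target window, or None (censored)."""
    hc = np.zeros(8)
    hh = np.zeros(8)
    _, _, _, _, reached, step = _kernels.run_1d(
        x0, n_steps, dt, friction, kT, derive_seed(seed), max(n_steps, 1),
        barrier, _kernels.BIAS_NONE, 0.0, 0.0,
        0.0, 0.1, 500, 6.0, hc, hh, 0, target[0], target[1], 0,
    )
    return step * dt if reached else None


def run_umbrella_1d(
    barrier: float, windows: Sequence[tuple[float, float]], n_steps: int,
    dt: float = 0.005, friction: float = 1.0, kT: float = 1.0,
    seed: int = 0, record_every: int = 10,
) -> list[dict]:
    """Umbrella windows on x; returns [{'x': xs, 'center': c, 'spring': k}]."""
    out = []
    for w, (center, spring) in enumerate(windows):
        xs, *_ = _kernels.run_1d(
            center, n_steps, dt, friction, kT, derive_seed(seed, w),
            record_every, barrier, _kernels.BIAS_UMBRELLA, center, spring,
            0.0, 0.1, 500, 6.0, *_NO_HILLS, 0, 1.0, 0.0, 0,
        )
        out.append({"x": xs, "center": center, "spring": spring})
    return out


def run_metadynamics_1d(
    barrier: float, n_steps: int, target: tuple[float, float],
    dt: float = 0.005, friction: float = 1.0, kT: float = 1.0, seed: int = 0,
    hill_height: float = 0.25, hill_width: float = 0.15, hill_stride: int = 500,
    bias_factor: float = 8.0, adaptive: bool = True, x0: float = -1.0,
    record_every: int = 10,
) -> dict:
    """Well-tempered metadynamics on x with first-arrival stopping."""
    hc = np.zeros(MAX_HILLS)
    hh = np.zeros(MAX_HILLS)
    xs, vb, n_hills, t_resc, reached, step = _kernels.run_1d(
        x0, n_steps, dt, friction, kT, derive_seed(seed), record_every,
        barrier, _kernels.BIAS_METAD, 0.0, 0.0,
        hill_height, hill_width, hill_stride, bias_factor,
        hc, hh, 0, target[0], target[1], 1 if adaptive else 0,
    )
    return {
        "x": xs, "bias": vb,
        "hills": {"centers": hc[:n_hills].copy(), "heights": hh[:n_hills].copy(),
                  "width": hill_width},
        "t_rescaled": t_resc, "reached": bool(reached),
        "wall_time": (step if reached else n_steps) * dt,
        "censored": not bool(reached),
    }
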