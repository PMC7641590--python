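"""Kinetic statistics: first-passage times, backtracking, folding order,
binding-encounter framework, and metadynamics transition times.

A folding event is complete when the total fraction of native contacts Q
first reaches a threshold (0.75 by default); its first passage time (FPT) is
reported in reduced time units tau. The folding order of the K structural
elements (domains and interfaces) within an event is the permutation of
commitment times; accumulated over events it yields the folding-order
probability matrix OP_k^I whose columns are stochastic with mean 1/K.
Backtracking is the transient formation and loss of interdomain contacts on
the way to the folded state, detected as drops of Q_inter binned along
monotonized Q_total progress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FPT_Q_THRESHOLD = 0.75
BACKTRACK_BIN_WIDTH = 0.02
BACKTRACK_DROP = 0.05
COMMITMENT_FRACTION = 0.67

#: default element set: four domains and four interfaces/linker
DPO4_ELEMENTS = ("F", "P", "T", "LF", "F-P", "P-T", "T-LF", "linker")


class KineticsError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# first passage


def first_passage(
    times: np.ndarray, q_total: np.ndarray, q_threshold: float = FPT_Q_THRESHOLD
) -> float | None:
    """Earliest time with Q_total >= threshold, or None when censored."""
    idx = np.nonzero(np.asarray(q_total) >= q_threshold)[0]
    if len(idx) == 0:
        return None
    return float(np.asarray(times)[idx[0]])


def mean_first_passage(fpts: list[float | None]) -> tuple[float, float, int]:
    """(MFPT, SD, censored count) over a set of runs; censored runs excluded."""
    done = [t for t in fpts if t is not None]
    censored = len(fpts) - len(done)
    if not done:
        raise KineticsError("all runs censored; no MFPT defined")
    return float(np.mean(done)), float(np.std(done)), censored


# ---------------------------------------------------------------------------
# backtracking


@dataclass
class BacktrackEvent:
    q_total_position: float
    drop: float
    implicated: list[str] = field(default_factory=list)


def detect_backtracking(
    q_total: np.ndarray,
    q_inter: np.ndarray,
    bin_width: float = BACKTRACK_BIN_WIDTH,
    drop_threshold: float = BACKTRACK_DROP,
    per_domain_q: dict[str, np.ndarray] | None = None,
    implicated_threshold: float = 0.6,
) -> list[BacktrackEvent]:
    """Backtracking events: local maxima of Q_inter along Q_total progress.

    Frames are binned by the running maximum of Q_total (so only forward
    progress opens a new bin); an event is a drop of the binned Q_inter by at
    least ``drop_threshold`` from its running local peak before further
    progress. Implicated domains are those with per-domain Q >=
    ``implicated_threshold`` at the peak.
    """
    q_total = np.asarray(q_total, float)
    q_inter = np.asarray(q_inter, float)
    if len(q_total) < 3:
        raise KineticsError("trajectory too short to bin")
    progress = np.maximum.accumulate(q_total)
    bins = np.floor(progress / bin_width).astype(int)
    # mean Q_inter (and frame index of peak) per progress bin, in order
    uniq = np.unique(bins)
    binned = np.array([q_inter[bins == b].mean() for b in uniq])
    rep_frame = np.array([np.argmax(bins == b) for b in uniq])

    events: list[BacktrackEvent] = []
    peak_val = binned[0]
    peak_idx = 0
    for k in range(1, len(binned)):
        if binned[k] > peak_val:
            peak_val = binned[k]
            peak_idx = k
        elif peak_val - binned[k] >= drop_threshold:
            implicated = []
            if per_domain_q is not None:
                f = rep_frame[peak_idx]
                implicated = [
                    name for name, q in per_domain_q.items()
                    if np.asarray(q)[f] >= implicated_threshold
                ]
            events.append(
                BacktrackEvent(
                    q_total_position=float(uniq[peak_idx] * bin_width),
                    drop=float(peak_val - binned[k]),
                    implicated=implicated,
                )
            )
            peak_val = binned[k]
            peak_idx = k
    return events


# ---------------------------------------------------------------------------
# folding order


@dataclass
class OPMatrix:
    elements: list[str]
    matrix: np.ndarray          # (K steps, K elements): OP_k^I
    sigma_per_step: np.ndarray  # sigma_OPk
    n_events: int

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def element_folding_steps(
    times: np.ndarray,
    q_by_element: dict[str, np.ndarray],
    q_total: np.ndarray,
    q_threshold: float = FPT_Q_THRESHOLD,
    commitment_fraction: float = COMMITMENT_FRACTION,
) -> dict[str, float] | None:
    """Commitment time per element within one successful folding event.

    An element commits at its first crossing of ``q_threshold`` after which
    its Q never falls below commitment_fraction * q_threshold before global
    folding completes. Returns None when the event is unsuccessful or some
    element never commits.
    """
    fpt = first_passage(times, q_total, q_threshold)
    if fpt is None:
        return None
    end = int(np.searchsorted(times, fpt, side="right"))
    floor = commitment_fraction * q_threshold
    out = {}
    for name, q in q_by_element.items():
        q = np.asarray(q, float)[:end]
        t_commit = None
        above = np.nonzero(q >= q_threshold)[0]
        for idx in above:
            if np.all(q[idx:] >= floor):
                t_commit = float(np.asarray(times)[idx])
                break
        if t_commit is None:
            return None
        out[name] = t_commit
    return out


def folding_order(
    events: list[dict[str, float]],
    elements: list[str] | None = None,
) -> OPMatrix:
    """OP_k^I from per-event element commitment times.

    ``events`` is a list of {element: commitment time} dictionaries (see
    :func:`element_folding_steps`); ties are broken by element order.
    """
    if not events:
        raise KineticsError("no successful folding events")
    if elements is None:
        elements = list(events[0].keys())
    K = len(elements)
    counts = np.zeros((K, K))
    for ev in events:
        if set(ev) != set(elements):
            raise KineticsError("event elements do not match the configured set")
        order = sorted(elements, key=lambda e: (ev[e], elements.index(e)))
        for step, name in enumerate(order):
            counts[step, elements.index(name)] += 1
    op = counts / len(events)
    sigma = np.sqrt(np.mean((op - 1.0 / K) ** 2, axis=1))
    return OPMatrix(
        elements=list(elements), matrix=op, sigma_per_step=sigma,
        n_events=len(events),
    )


# ---------------------------------------------------------------------------
# encounter framework


@dataclass
class EncounterStats:
    n_evo: int
    n_dis: int
    total_time: float
    k_evo: float
    k_dis: float
    encounter_time: float | None
    undefined: bool = False


def encounter_framework(outcomes: list[tuple[str, float]]) -> EncounterStats:
    """Encounter statistics from (outcome, duration) pairs.

    outcome is 'IS' (the encounter complex evolved to the intermediate
    binding state) or 'US' (complete dissociation). The encounter time
    kDis/kEvo + 1 is the expected number of encounter attempts per
    successful evolution.
    """
    n_evo = sum(1 for o, _ in outcomes if o == "IS")
    n_dis = sum(1 for o, _ in outcomes if o == "US")
    if n_evo + n_dis != len(outcomes):
        raise KineticsError("outcomes must be labeled 'IS' or 'US'")
    total_time = float(sum(t for _, t in outcomes))
    k_evo = n_evo / total_time if total_time > 0 else 0.0
    k_dis = n_dis / total_time if total_time > 0 else 0.0
    if n_evo == 0:
        return EncounterStats(
            n_evo, n_dis, total_time, k_evo, k_dis, None, undefined=True
        )
    return EncounterStats(
        n_evo, n_dis, total_time, k_evo, k_dis, n_dis / n_evo + 1.0
    )


# ---------------------------------------------------------------------------
# metadynamics transition times


@dataclass
class RateEstimate:
    times: np.ndarray            # per-run rescaled transition times, tau
    mean: float
    bootstrap_error: float
    n_bootstrap: int
    censored: int
    barrier_correlation: float | None = None


def metad_transition_time(
    runs: list[dict],
    n_bootstrap: int = 50,
    seed: int = 0,
    barrier_heights: np.ndarray | None = None,
) -> RateEstimate:
    """Mean rescaled IS<->BS transition time with bootstrap error.

    Each run dict carries 't_rescaled' and 'censored' (the output of
    :func:`domainfold.sampler.run_metadynamics` or its 1D analog). Censored
    runs are excluded from the mean but counted. When barrier heights from
    umbrella PMFs are supplied (one per run group), the Pearson correlation
    of log times against barriers is reported.
    """
    done = np.array([r["t_rescaled"] for r in runs if not r.get("censored")])
    censored = sum(1 for r in runs if r.get("censored"))
    if len(done) == 0:
        raise KineticsError("all metadynamics runs censored")
    rng = np.random.default_rng(seed)
    means = np.array([
        rng.choice(done, size=len(done), replace=True).mean()
        for _ in range(n_bootstrap)
    ])
    corr = None
    if barrier_heights is not None and len(barrier_heights) == len(done) and len(done) > 2:
        corr = float(np.corrcoef(np.log(done), barrier_heights)[0, 1])
    return RateEstimate(
        times=done, mean=float(done.mean()),
        bootstrap_error=float(means.std()), n_bootstrap=n_bootstrap,
        censored=censored, barrier_correlation=corr,
    )
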