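"""Collective variables and structural statistics.

Q is the fraction of a native-contact subset formed (a contact counts as
formed when r_ij < formed_tolerance * sigma_ij); dRMS is the
root-mean-square deviation of the protein-DNA native-contact distances from
their native values (0 nm at the bound native pose). RMSF is computed after
optimal superposition onto the mean structure; the diffusion coefficient
comes from a linear fit of the center-of-mass MSD to 6 D t.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model_builder import ContactSet

FORMED_TOLERANCE = 1.2


def q_fraction(
    coords: np.ndarray,
    contact_subset: ContactSet | Sequence,
    formed_tolerance: float = FORMED_TOLERANCE,
) -> float:
    """Fraction of the given native contacts formed at these coordinates."""
    records = list(contact_subset)
    if not records:
        raise ValueError("contact subset is empty")
    i = np.array([r.i for r in records])
    j = np.array([r.j for r in records])
    sigma = np.array([r.sigma for r in records])
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    return float(np.mean(r < formed_tolerance * sigma))


def q_series(
    positions: np.ndarray,
    contact_subset: ContactSet | Sequence,
    formed_tolerance: float = FORMED_TOLERANCE,
) -> np.ndarray:
    """Q for every frame of a (F, N, 3) trajectory."""
    records = list(contact_subset)
    if not records:
        raise ValueError("contact subset is empty")
    i = np.array([r.i for r in records])
    j = np.array([r.j for r in records])
    sigma = np.array([r.sigma for r in records])
    r = np.linalg.norm(positions[:, i, :] - positions[:, j, :], axis=2)
    return np.mean(r < formed_tolerance * sigma, axis=1)


def drms(coords: np.ndarray, binding_contacts: ContactSet | Sequence) -> float:
    """sqrt(mean (r_ij - sigma_ij)^2) over binding contacts, in nm."""
    records = list(binding_contacts)
    if not records:
        raise ValueError("binding contact set is empty")
    i = np.array([r.i for r in records])
    j = np.array([r.j for r in records])
    sigma = np.array([r.sigma for r in records])
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    return float(np.sqrt(np.mean((r - sigma) ** 2)))


def drms_series(
    positions: np.ndarray, binding_contacts: ContactSet | Sequence
) -> np.ndarray:
    records = list(binding_contacts)
    if not records:
        raise ValueError("binding contact set is empty")
    i = np.array([r.i for r in records])
    j = np.array([r.j for r in records])
    sigma = np.array([r.sigma for r in records])
    r = np.linalg.norm(positions[:, i, :] - positions[:, j, :], axis=2)
    return np.sqrt(np.mean((r - sigma) ** 2, axis=1))


def rmsf(
    positions: np.ndarray, selection: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Per-bead RMSF (nm) about the mean structure, after superposition.

    Frames are iteratively aligned (two passes) onto the running mean
    structure with the optimal rotation/translation before deviations are
    accumulated. Returns (per-bead RMSF, mean RMSF).
    """
    if positions.shape[0] < 2:
        raise ValueError("RMSF requires at least two frames")
    sel = (
        np.asarray(selection, dtype=int)
        if selection is not None
        else np.arange(positions.shape[1])
    )
    frames = positions[:, sel, :].astype(float)
    ref = frames[0] - frames[0].mean(axis=0)
    for _ in range(2):
        aligned = np.array([_superpose(f, ref) for f in frames])
        ref = aligned.mean(axis=0)
    dev = aligned - ref
    per_bead = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return per_bead, float(per_bead.mean())


def _superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    mob = mobile - mobile.mean(axis=0)
    if np.allclose(mob, 0) or np.allclose(ref, 0):
        return mob
    rot, _ = Rotation.align_vectors(ref, mob)
    return rot.apply(mob)


def diffusion_coefficient(
    positions: np.ndarray,
    times: np.ndarray,
    selection: np.ndarray | None = None,
    lag_window: tuple[int, int] = (10, 100),
) -> float:
    """D (nm^2/tau) from MSD(t) = 6 D t of the selection's center of mass."""
    sel = (
        np.asarray(selection, dtype=int)
        if selection is not None
        else np.arange(positions.shape[1])
    )
    com = positions[:, sel, :].mean(axis=1)
    lo, hi = lag_window
    if hi >= len(com):
        raise ValueError(
            f"lag window {lag_window} exceeds trajectory length {len(com)}"
        )
    lags = np.arange(lo, hi + 1)
    msd = np.array([
        np.mean(np.sum((com[lag:] - com[:-lag]) ** 2, axis=1)) for lag in lags
    ])
    dt = float(np.mean(np.diff(times)))
    slope = np.polyfit(lags * dt, msd, 1)[0]
    return float(slope / 6.0)


def cv_series_frame(times: np.ndarray, series: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tidy (frame, time, name, value) table for a set of CV series."""
    rows = []
    for name, vals in series.items():
        for f, (t, v) in enumerate(zip(times, vals)):
            rows.append((f, t, name, v))
    return pd.DataFrame(rows, columns=["frame", "time", "name", "value"])
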