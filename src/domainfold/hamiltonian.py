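"""The rho-parameterized structure-based energy function.

The potential is

    V = V_bonded + eps_intra * V_intra + eps_inter * (V_inter + V_linker)
        [+ V_binary + V_binding + V_elec + V_excluded]

with eps_inter = rho * eps_intra: a single dimensionless ratio rho controls
the relative weight of interdomain (and linker) native contacts against
intradomain ones. Contacts unique to the ligand-bound basin sit at a domain
interface and are therefore scaled like interdomain contacts; protein-DNA
binding contacts carry unit strength. Native contacts use the 12-10 form
V = eps [5 (sigma/r)^12 - 6 (sigma/r)^10], minimum -eps at r = sigma.

Because V depends on rho linearly,

    E(rho) = E_bonded + E_intra + rho * (E_inter + E_linker) + ...

equilibrium averages at any rho can be recovered from a single simulation at
rho0 by Boltzmann reweighting of the decomposed energies (see
:mod:`domainfold.thermo`).

Electrostatics are Debye-Hueckel screened Coulomb, calibrated so that two
opposite unit charges at 0.5 nm interact with the strength of one native
contact (energy -1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .model_builder import CoarseModel, ContactSet

DH_CALIBRATION_DISTANCE = 0.5  # nm

CLASS_CODES = {"intra": 0, "inter": 1, "linker": 2, "binary": 3, "binding": 4}
COMPONENT_NAMES = (
    "bonded", "intra", "inter", "linker", "binary_basin",
    "binding", "electrostatic", "excluded",
)


def calibrate_dh(debye_length: float) -> float:
    """Prefactor A with |V_DH(0.5 nm; +1, -1)| = 1 for the given Debye length."""
    if debye_length <= 0:
        raise ValueError("Debye length must be positive")
    return DH_CALIBRATION_DISTANCE * math.exp(
        DH_CALIBRATION_DISTANCE / debye_length
    )


@dataclass(frozen=True)
class ForceField:
    """Parameters of the coarse-grained structure-based potential.

    Energies are in reduced units (the native-contact depth at rho = 1 sets
    the scale); lengths in nm; kB = 1.
    """

    eps_intra: float = 1.0
    rho: float = 1.0
    eps_binding: float = 1.0
    k_bond: float = 100.0       # eps / nm^2
    k_angle: float = 20.0       # eps / rad^2
    k_dihedral: float = 1.0     # eps
    ev_sigma: float = 0.4       # nm, excluded-volume diameter
    debye_length: float = 0.8   # nm (~150 mM monovalent salt)
    dh_prefactor: float = field(default=None)  # type: ignore[assignment]
    temperature_rescale: float = 1.0
    electrostatics: bool = True

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.temperature_rescale <= 0:
            raise ValueError("temperature_rescale must be positive")
        if self.dh_prefactor is None:
            object.__setattr__(
                self, "dh_prefactor", calibrate_dh(self.debye_length)
            )

    @property
    def eps_inter(self) -> float:
        return self.rho * self.eps_intra

    def to_config(self) -> dict:
        return {
            "eps_intra": self.eps_intra,
            "rho": self.rho,
            "eps_binding": self.eps_binding,
            "k_bond": self.k_bond,
            "k_angle": self.k_angle,
            "k_dihedral": self.k_dihedral,
            "ev_sigma": self.ev_sigma,
            "debye_length": self.debye_length,
            "dh_prefactor": self.dh_prefactor,
            "temperature_rescale": self.temperature_rescale,
            "electrostatics": self.electrostatics,
        }


def rescale_for_temperature(
    forcefield: ForceField, tf_rho0: float, tf_rho: float
) -> ForceField:
    """Shift the folding temperature at rho onto the rho0 scale.

    Multiplying the whole potential by Tf(rho0)/Tf(rho) maps the melting
    point at the modified contact weights back to the reference one, so
    kinetic runs at different rho share identical bath conditions.
    """
    if tf_rho0 <= 0 or tf_rho <= 0:
        raise ValueError("folding temperatures must be positive")
    return replace(forcefield, temperature_rescale=tf_rho0 / tf_rho)


@dataclass(frozen=True)
class EnergyReport:
    bonded: float
    intra: float
    inter: float
    linker: float
    binary_basin: float
    binding: float
    electrostatic: float
    excluded: float

    @property
    def total(self) -> float:
        return (
            self.bonded + self.intra + self.inter + self.linker
            + self.binary_basin + self.binding + self.electrostatic
            + self.excluded
        )

    @classmethod
    def from_components(cls, comps: np.ndarray) -> "EnergyReport":
        return cls(*(float(c) for c in comps))

    def as_array(self) -> np.ndarray:
        return np.array([
            self.bonded, self.intra, self.inter, self.linker,
            self.binary_basin, self.binding, self.electrostatic, self.excluded,
        ])


def contact_pair_energy(r: float, sigma: float, eps: float = 1.0) -> float:
    """12-10 native-contact pair energy; minimum -eps at r = sigma."""
    if r <= 0:
        raise ValueError("distance must be positive")
    u = sigma / r
    return eps * (5.0 * u**12 - 6.0 * u**10)


class PackedSystem:
    """Model + contacts + force field flattened to kernel-ready arrays."""

    def __init__(
        self,
        model: CoarseModel,
        contacts: ContactSet,
        forcefield: ForceField,
        include_excluded_volume: bool = True,
    ):
        self.model = model
        self.contacts = contacts
        self.forcefield = forcefield
        n = model.n_beads
        ff = forcefield

        self.frozen = model.frozen.copy()
        self.bonds = model.bonds.astype(np.int64)
        self.bond_r0 = model.bond_r0.astype(np.float64)
        self.angles = model.angles.astype(np.int64)
        self.angle_t0 = model.angle_t0.astype(np.float64)
        self.dihs = model.dihedrals.astype(np.int64)
        self.dih_p0 = model.dihedral_p0.astype(np.float64)

        ci, cj, csig, ceps, ccls = [], [], [], [], []
        eps_by_class = {
            "intra": ff.eps_intra,
            "inter": ff.eps_inter,
            "linker": ff.eps_inter,
            "binding": ff.eps_binding,
        }
        for r in contacts:
            top = r.contact_class.split(":")[0]
            if top == "unclassified":
                raise ValueError("contacts must be classified before packing")
            code = CLASS_CODES[top] if r.basin == "apo" or top == "binding" else CLASS_CODES["binary"]
            if r.basin == "binary" and top != "binding":
                eps = ff.eps_inter  # induced contacts sit at a domain interface
            else:
                eps = eps_by_class[top]
            if r.basin == "binary" and top == "binding":
                code = CLASS_CODES["binding"]
            ci.append(r.i)
            cj.append(r.j)
            csig.append(r.sigma)
            ceps.append(eps)
            ccls.append(code)
        self.ci = np.array(ci, dtype=np.int64)
        self.cj = np.array(cj, dtype=np.int64)
        self.csigma = np.array(csig, dtype=np.float64)
        self.ceps = np.array(ceps, dtype=np.float64)
        self.cclass = np.array(ccls, dtype=np.int64)

        # exclusions: bonded neighbors (1-2, 1-3, 1-4) and native contacts
        excluded_pairs = set()
        for b in self.bonds:
            excluded_pairs.add(_key(b[0], b[1]))
        for a in self.angles:
            excluded_pairs.add(_key(a[0], a[2]))
        for d in self.dihs:
            excluded_pairs.add(_key(d[0], d[3]))
        contact_pairs = {_key(i, j) for i, j in zip(self.ci, self.cj)}

        ev_i, ev_j = [], []
        if include_excluded_volume:
            for i in range(n):
                for j in range(i + 1, n):
                    if model.frozen[i] and model.frozen[j]:
                        continue
                    key = _key(i, j)
                    if key in excluded_pairs or key in contact_pairs:
                        continue
                    ev_i.append(i)
                    ev_j.append(j)
        self.ev_i = np.array(ev_i, dtype=np.int64)
        self.ev_j = np.array(ev_j, dtype=np.int64)

        el_i, el_j, el_qq = [], [], []
        if ff.electrostatics:
            charged = np.nonzero(model.charges)[0]
            for a_ in range(len(charged)):
                for b_ in range(a_ + 1, len(charged)):
                    i, j = int(charged[a_]), int(charged[b_])
                    if model.frozen[i] and model.frozen[j]:
                        continue
                    if _key(i, j) in excluded_pairs:
                        continue
                    el_i.append(i)
                    el_j.append(j)
                    el_qq.append(model.charges[i] * model.charges[j])
        self.el_i = np.array(el_i, dtype=np.int64)
        self.el_j = np.array(el_j, dtype=np.int64)
        self.el_qq = np.array(el_qq, dtype=np.float64)

        # binding contacts feed the dRMS collective variable
        bind = [
            (r.i, r.j, r.sigma) for r in contacts if r.contact_class == "binding"
        ]
        self.bind_i = np.array([b[0] for b in bind], dtype=np.int64)
        self.bind_j = np.array([b[1] for b in bind], dtype=np.int64)
        self.bind_sigma = np.array([b[2] for b in bind], dtype=np.float64)

    def kernel_args(self):
        ff = self.forcefield
        return (
            self.frozen,
            self.bonds, self.bond_r0, ff.k_bond,
            self.angles, self.angle_t0, ff.k_angle,
            self.dihs, self.dih_p0, ff.k_dihedral,
            self.ci, self.cj, self.csigma, self.ceps, self.cclass,
            self.ev_i, self.ev_j, ff.ev_sigma,
            self.el_i, self.el_j, self.el_qq, ff.dh_prefactor, ff.debye_length,
            ff.temperature_rescale,
        )


def _key(i, j):
    return (int(min(i, j)), int(max(i, j)))


def total_energy(
    model: CoarseModel,
    contacts: ContactSet,
    forcefield: ForceField,
    coords: np.ndarray,
    system: PackedSystem | None = None,
) -> EnergyReport:
    """Decomposed potential energy at the given coordinates."""
    if np.any(~np.isfinite(coords)):
        raise ValueError("coordinates contain NaN or infinity")
    if system is None:
        system = PackedSystem(model, contacts, forcefield)
    force = np.zeros_like(coords)
    comps = _kernels.forces_energy(
        np.ascontiguousarray(coords, dtype=np.float64),
        *system.kernel_args(), force,
    )
    return EnergyReport.from_components(comps)


def forces(
    model: CoarseModel,
    contacts: ContactSet,
    forcefield: ForceField,
    coords: np.ndarray,
    system: PackedSystem | None = None,
) -> np.ndarray:
    """-grad V per bead; exactly zero on frozen beads."""
    if np.any(~np.isfinite(coords)):
        raise ValueError("coordinates contain NaN or infinity")
    if system is None:
        system = PackedSystem(model, contacts, forcefield)
    force = np.zeros_like(coords, dtype=np.float64)
    _kernels.forces_energy(
        np.ascontiguousarray(coords, dtype=np.float64),
        *system.kernel_args(), force,
    )
    return force
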