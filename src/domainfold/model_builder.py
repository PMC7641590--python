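"""Build coarse-grained structure-based models from PDB structures.

Proteins are reduced to one C-alpha bead per residue; nucleotides to three
beads (phosphate, sugar, base). Native contacts are identified from the
all-heavy-atom structure with a distance cutoff and classified by the domain
architecture into intradomain, interdomain, linker, and protein-DNA binding
classes. A dual-basin contact set merges the apo-structure contacts with the
contacts unique to a ligand-bound structure, enabling open-to-closed
conformational transitions driven by binding.

Lengths are nanometers throughout; residue numbering is 1-based (PDB
convention) while bead indices are 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

POSITIVE_RESIDUES = {"ARG", "LYS", "R", "K"}
NEGATIVE_RESIDUES = {"ASP", "GLU", "D", "E"}
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: atoms assigned to the sugar bead of a nucleotide
_SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'", "O3'"}
_PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O5'"}


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


class ModelBuildError(ValueError):
    """Raised when a coarse model cannot be assembled from a structure."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # nm


@dataclass
class Residue:
    name: str
    seqid: int
    is_nucleic: bool
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms if a.element != "H"])


@dataclass
class Chain:
    name: str
    residues: list[Residue]


@dataclass
class AtomisticStructure:
    chains: list[Chain]

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


def parse_pdb(pdb_text: str) -> AtomisticStructure:
    """Parse PDB text into an atomistic structure (coordinates in nm).

    Waters and non-nucleic heteroatoms are dropped; alternate locations are
    resolved to the highest-occupancy conformer; only MODEL 1 is used.
    """
    _prescan_pdb(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise PDBParseError("PDB text contains no model")
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if res.name.strip() in WATER_NAMES:
                continue
            atoms = _resolve_altlocs(res)
            names = {a.name for a in atoms}
            is_nucleic = "C1'" in names or "C1*" in names
            is_protein = "CA" in names and len(names) > 1 or res.name in STANDARD_RESIDUES
            if not (is_nucleic or is_protein):
                continue  # ions, ligands, cofactors
            residues.append(
                Residue(
                    name=res.name.strip(),
                    seqid=res.seqid.num,
                    is_nucleic=is_nucleic,
                    atoms=atoms,
                )
            )
        if residues:
            chains.append(Chain(name=ch.name, residues=residues))
    if not chains:
        raise PDBParseError("no protein or nucleic chains found in PDB text")
    return AtomisticStructure(chains=chains)


def _prescan_pdb(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"truncated coordinate record at line {lineno}")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(
                    f"unparseable coordinates at line {lineno}"
                ) from exc


def _resolve_altlocs(res: gemmi.Residue) -> list[Atom]:
    best: dict[str, tuple[float, Atom]] = {}
    for a in res:
        atom = Atom(
            name=a.name.replace("*", "'"),
            element=a.element.name,
            pos=np.array([a.pos.x, a.pos.y, a.pos.z]) / 10.0,
        )
        occ = a.occ if a.occ > 0 else 1.0
        prev = best.get(a.name)
        if prev is None or occ > prev[0]:
            best[a.name] = (occ, atom)
    return [atom for _, atom in best.values()]


# ---------------------------------------------------------------------------
# coarse model


@dataclass
class CoarseModel:
    """Bead representation of one or two chains with bonded topology."""

    positions: np.ndarray          # (N, 3) nm
    chain_ids: list[str]
    res_ids: np.ndarray            # (N,) 1-based residue numbers
    res_names: list[str]
    kinds: list[str]               # CA | sugar | base | phosphate
    charges: np.ndarray            # (N,) elementary units
    frozen: np.ndarray             # (N,) bool
    bonds: np.ndarray              # (B, 2) int
    bond_r0: np.ndarray
    angles: np.ndarray             # (A, 3) int
    angle_t0: np.ndarray
    dihedrals: np.ndarray          # (D, 4) int
    dihedral_p0: np.ndarray
    domain_map: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    linker_name: str = "linker"

    @property
    def n_beads(self) -> int:
        return len(self.kinds)

    def domain_of_residue(self, res_id: int) -> str | None:
        for name, intervals in self.domain_map.items():
            for lo, hi in intervals:
                if lo <= res_id <= hi:
                    return name
        return None

    def domain_labels(self) -> list[str]:
        """Per-bead domain name; 'DNA' for nucleic beads."""
        labels = []
        for k in range(self.n_beads):
            if self.kinds[k] != "CA":
                labels.append("DNA")
            else:
                dom = self.domain_of_residue(int(self.res_ids[k]))
                labels.append(dom if dom is not None else "?")
        return labels

    def domain_sizes(self) -> dict[str, int]:
        sizes = {}
        for name, intervals in self.domain_map.items():
            sizes[name] = sum(hi - lo + 1 for lo, hi in intervals)
        return sizes

    def to_json(self) -> str:
        payload = {
            "n_beads": self.n_beads,
            "chain_ids": self.chain_ids,
            "res_ids": self.res_ids.tolist(),
            "res_names": self.res_names,
            "kinds": self.kinds,
            "charges": self.charges.tolist(),
            "frozen": self.frozen.astype(int).tolist(),
            "positions_nm": np.round(self.positions, 6).tolist(),
            "bonds": self.bonds.tolist(),
            "domain_map": {k: [list(iv) for iv in v] for k, v in self.domain_map.items()},
            "linker_name": self.linker_name,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def coarse_grain(
    structure: AtomisticStructure,
    domain_definitions: dict[str, list[tuple[int, int]]] | None = None,
    freeze_nucleic: bool = True,
    linker_name: str = "linker",
) -> CoarseModel:
    """Reduce an atomistic structure to beads with bonded topology.

    One CA bead per amino acid; phosphate/sugar/base beads per nucleotide.
    Angle and dihedral terms are built along protein chains only (nucleic
    chains are intended to be frozen).
    """
    positions, chain_ids, res_ids, res_names, kinds, frozen = [], [], [], [], [], []
    bonds, angles, dihedrals = [], [], []

    for chain in structure.chains:
        chain_ca: list[int] = []
        prev_sugar = None
        for res in chain.residues:
            if res.is_nucleic:
                beads = _nucleotide_beads(res)
                base_index = len(positions)
                for kname, pos in beads:
                    positions.append(pos)
                    chain_ids.append(chain.name)
                    res_ids.append(res.seqid)
                    res_names.append(res.name)
                    kinds.append(kname)
                    frozen.append(freeze_nucleic)
                # phosphate-sugar, sugar-base; sugar(prev)-phosphate backbone
                p, s, b = base_index, base_index + 1, base_index + 2
                bonds.extend([(p, s), (s, b)])
                if prev_sugar is not None:
                    bonds.append((prev_sugar, p))
                prev_sugar = s
            else:
                ca = res.atom("CA")
                if ca is None:
                    raise ModelBuildError(
                        f"residue {res.name}{res.seqid} in chain {chain.name} has no CA atom"
                    )
                chain_ca.append(len(positions))
                positions.append(ca.pos)
                chain_ids.append(chain.name)
                res_ids.append(res.seqid)
                res_names.append(res.name)
                kinds.append("CA")
                frozen.append(False)
        for a, b in zip(chain_ca, chain_ca[1:]):
            bonds.append((a, b))
        for a, b, c in zip(chain_ca, chain_ca[1:], chain_ca[2:]):
            angles.append((a, b, c))
        for a, b, c, d in zip(chain_ca, chain_ca[1:], chain_ca[2:], chain_ca[3:]):
            dihedrals.append((a, b, c, d))

    pos = np.array(positions)
    bonds_arr = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles_arr = np.array(angles, dtype=np.int64).reshape(-1, 3)
    dih_arr = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)

    model = CoarseModel(
        positions=pos,
        chain_ids=chain_ids,
        res_ids=np.array(res_ids, dtype=np.int64),
        res_names=res_names,
        kinds=kinds,
        charges=np.zeros(len(kinds)),
        frozen=np.array(frozen, dtype=bool),
        bonds=bonds_arr,
        bond_r0=_bond_lengths(pos, bonds_arr),
        angles=angles_arr,
        angle_t0=_angle_values(pos, angles_arr),
        dihedrals=dih_arr,
        dihedral_p0=_dihedral_values(pos, dih_arr),
        domain_map=dict(domain_definitions or {}),
        linker_name=linker_name,
    )
    if domain_definitions:
        _check_domain_coverage(model)
    return assign_charges(model)


def _nucleotide_beads(res: Residue) -> list[tuple[str, np.ndarray]]:
    phos, sugar, base = [], [], []
    for a in res.atoms:
        if a.element == "H":
            continue
        if a.name in _PHOSPHATE_ATOMS:
            phos.append(a.pos)
        elif a.name in _SUGAR_ATOMS:
            sugar.append(a.pos)
        else:
            base.append(a.pos)
    if not sugar or not base:
        raise ModelBuildError(
            f"nucleotide {res.name}{res.seqid} lacks sugar or base atoms"
        )
    if not phos:  # 5'-terminal nucleotide without phosphate: borrow C5' end
        phos = [sugar[0]]
    return [
        ("phosphate", np.mean(phos, axis=0)),
        ("sugar", np.mean(sugar, axis=0)),
        ("base", np.mean(base, axis=0)),
    ]


def _check_domain_coverage(model: CoarseModel) -> None:
    for k in range(model.n_beads):
        if model.kinds[k] != "CA":
            continue
        if model.domain_of_residue(int(model.res_ids[k])) is None:
            raise ModelBuildError(
                f"residue {model.res_names[k]}{model.res_ids[k]} not covered by any "
                "domain or linker interval"
            )


def _bond_lengths(pos, bonds):
    if len(bonds) == 0:
        return np.zeros(0)
    d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
    return np.linalg.norm(d, axis=1)


def _angle_values(pos, angles):
    if len(angles) == 0:
        return np.zeros(0)
    u = pos[angles[:, 0]] - pos[angles[:, 1]]
    v = pos[angles[:, 2]] - pos[angles[:, 1]]
    cosang = np.sum(u * v, axis=1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedral_values(pos, dihedrals):
    if len(dihedrals) == 0:
        return np.zeros(0)
    b0 = pos[dihedrals[:, 1]] - pos[dihedrals[:, 0]]
    b1 = pos[dihedrals[:, 2]] - pos[dihedrals[:, 1]]
    b2 = pos[dihedrals[:, 3]] - pos[dihedrals[:, 2]]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(
        np.cross(n1, n2) * b1 / np.linalg.norm(b1, axis=1)[:, None], axis=1
    )
    return np.arctan2(y, x)


def assign_charges(model: CoarseModel) -> CoarseModel:
    """Assign unit charges: Arg/Lys +1, Asp/Glu -1, DNA phosphate -1."""
    charges = np.zeros(model.n_beads)
    for k in range(model.n_beads):
        kind = model.kinds[k]
        name = model.res_names[k].upper()
        if kind == "phosphate":
            charges[k] = -1.0
        elif kind == "CA":
            if name in POSITIVE_RESIDUES:
                charges[k] = 1.0
            elif name in NEGATIVE_RESIDUES:
                charges[k] = -1.0
            elif name not in STANDARD_RESIDUES and len(name) > 1:
                logger.warning("unknown residue name %r: charge set to 0", name)
    return replace(model, charges=charges)


# ---------------------------------------------------------------------------
# contacts


@dataclass(frozen=True)
class ContactRecord:
    i: int
    j: int
    sigma: float                    # native bead-bead distance, nm
    contact_class: str              # intra:<dom> | inter:<a>|<b> | linker | binding
    basin: str = "apo"              # apo | binary

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("contact requires i < j")
        if self.sigma <= 0:
            raise ValueError("contact sigma must be positive")


@dataclass
class ContactSet:
    records: list[ContactRecord]

    def __post_init__(self):
        self.records = sorted(
            self.records, key=lambda r: (r.basin != "apo", r.i, r.j)
        )
        seen = set()
        for r in self.records:
            key = (r.i, r.j, r.basin)
            if key in seen:
                raise ValueError(f"duplicate contact {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "ContactSet":
        return ContactSet([r for r in self.records if predicate(r)])

    def by_class(self, prefix: str) -> "ContactSet":
        return self.subset(lambda r: r.contact_class.startswith(prefix))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.contact_class] = out.get(r.contact_class, 0) + 1
        return out

    def class_totals(self) -> dict[str, int]:
        """Counts aggregated over the four top-level classes."""
        out = {"intra": 0, "inter": 0, "linker": 0, "binding": 0}
        for r in self.records:
            out[r.contact_class.split(":")[0]] += 1
        return out

    def to_csv(self) -> str:
        lines = ["i,j,sigma_ij_nm,class,basin"]
        for r in self.records:
            lines.append(f"{r.i},{r.j},{r.sigma:.6f},{r.contact_class},{r.basin}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_csv(cls, text: str) -> "ContactSet":
        records = []
        for line in text.strip().splitlines()[1:]:
            i, j, sigma, cclass, basin = line.split(",")
            records.append(
                ContactRecord(int(i), int(j), float(sigma), cclass, basin)
            )
        return cls(records)


def build_contacts(
    atomistic: AtomisticStructure,
    model: CoarseModel,
    method: str = "cutoff",
    cutoff: float = 0.45,
    min_separation: int = 4,
) -> ContactSet:
    """Native contact map from all-heavy-atom distances.

    Two residues are in contact when any pair of their heavy atoms is closer
    than ``cutoff`` (nm). Same-chain protein pairs additionally require a
    sequence separation of at least ``min_separation`` residues. The contact
    joins the residues' beads (for a nucleotide, the bead nearest to the
    partner bead), with sigma the native bead-bead distance. Intra-DNA pairs
    are skipped (the DNA is rigid).
    """
    if method != "cutoff":
        raise ValueError(f"unknown contact method {method!r}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    residues = []  # (chain, res, heavy coords, bead indices)
    bead_lookup: dict[tuple[str, int], list[int]] = {}
    for k in range(model.n_beads):
        bead_lookup.setdefault((model.chain_ids[k], int(model.res_ids[k])), []).append(k)
    for chain in atomistic.chains:
        for idx, res in enumerate(chain.residues):
            beads = bead_lookup.get((chain.name, res.seqid))
            if beads is None:
                raise ModelBuildError(
                    f"residue {res.name}{res.seqid} missing from coarse model"
                )
            residues.append((chain.name, idx, res, res.heavy_coords(), beads))

    records = []
    for a in range(len(residues)):
        ch_a, ord_a, res_a, xyz_a, beads_a = residues[a]
        for b in range(a + 1, len(residues)):
            ch_b, ord_b, res_b, xyz_b, beads_b = residues[b]
            if res_a.is_nucleic and res_b.is_nucleic:
                continue
            if ch_a == ch_b and not res_a.is_nucleic and not res_b.is_nucleic:
                if abs(ord_b - ord_a) < min_separation:
                    continue
            d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=-1)
            if d.min() >= cutoff:
                continue
            bi, bj = _closest_bead_pair(model, beads_a, beads_b)
            sigma = float(np.linalg.norm(model.positions[bi] - model.positions[bj]))
            records.append(
                ContactRecord(min(bi, bj), max(bi, bj), sigma, "unclassified")
            )
    return ContactSet(records)


def _closest_bead_pair(model: CoarseModel, beads_a, beads_b) -> tuple[int, int]:
    best = None
    for i in beads_a:
        for j in beads_b:
            d = np.linalg.norm(model.positions[i] - model.positions[j])
            if best is None or d < best[0]:
                best = (d, i, j)
    return best[1], best[2]


def classify_contacts(contacts: ContactSet, model: CoarseModel) -> ContactSet:
    """Assign contact classes from the model's domain architecture.

    Both endpoints in one domain -> intra; two domains -> inter; any endpoint
    in the linker -> linker (the linker is grouped with the interdomain
    interactions downstream); protein-DNA -> binding.
    """
    labels = model.domain_labels()
    records = []
    for r in contacts:
        la, lb = labels[r.i], labels[r.j]
        if "?" in (la, lb):
            bad = r.i if la == "?" else r.j
            raise ModelBuildError(
                f"bead {bad} (residue {model.res_ids[bad]}) is outside the domain map"
            )
        if "DNA" in (la, lb):
            cclass = "binding"
        elif model.linker_name in (la, lb):
            cclass = "linker"
        elif la == lb:
            cclass = f"intra:{la}"
        else:
            cclass = "inter:" + "|".join(sorted((la, lb)))
        records.append(replace(r, contact_class=cclass))
    return ContactSet(records)


def build_dual_basin(
    apo_contacts: ContactSet,
    binary_contacts: ContactSet,
) -> ContactSet:
    """Merge apo contacts with contacts unique to the bound (binary) structure.

    Both sets must be classified over the same bead indexing (protein beads
    first, identical ordering). Intra-protein contacts present only in the
    bound structure are tagged basin='binary'; binding contacts are taken from
    the bound structure. Shared contacts keep the apo sigma.
    """
    apo_keys = {(r.i, r.j) for r in apo_contacts}
    records = list(apo_contacts.records)
    for r in binary_contacts:
        if r.contact_class == "binding":
            records.append(replace(r, basin="binary"))
        elif (r.i, r.j) not in apo_keys:
            records.append(replace(r, basin="binary"))
        else:
            apo_sigma = next(
                a.sigma for a in apo_contacts if (a.i, a.j) == (r.i, r.j)
            )
            if abs(apo_sigma - r.sigma) > 1e-6:
                logger.info(
                    "shared contact (%d,%d): sigma apo %.4f vs binary %.4f nm; "
                    "keeping apo",
                    r.i, r.j, apo_sigma, r.sigma,
                )
    return ContactSet(records)
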