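"""Deterministic toy systems exercising every pipeline stage offline.

Toy multidomain proteins are built from geometric templates (serpentine
bead grids docked edge-to-edge with an arched linker) so that the native
structure is the exact minimum of the generated Hamiltonian and contact
classes (intra / inter / linker / binding) are populated by construction.
A frozen, negatively charged three-bead-per-residue rail stands in for DNA.
Analytic references (harmonic chain, 1D quartic double well) carry closed-
form Boltzmann statistics for validating the samplers and estimators.

All generators are seed-deterministic and emit PDB text consumable by
:mod:`domainfold.model_builder` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_builder import (
    AtomisticStructure,
    CoarseModel,
    ContactSet,
    build_contacts,
    build_dual_basin,
    classify_contacts,
    coarse_grain,
    parse_pdb,
)

GRID_SPACING = 0.5        # nm between template beads
TOY_CUTOFF = 0.75         # nm, bead-bead contact cutoff for CA-only templates
TOY_MIN_SEPARATION = 3


@dataclass
class ToySpec:
    n_domains: int = 2
    beads_per_domain: int = 18
    linker_length: int = 4
    target_ratio: float = 5.0      # intra : inter (incl. linker) contacts
    seed: int = 0
    partner_length: int = 0        # nucleotides in the frozen partner rail
    charge_pattern: tuple[str, ...] = ()   # residue names cycled along chain
    dual_basin: bool = False

    def __post_init__(self):
        if self.n_domains < 1 or self.beads_per_domain < 6:
            raise ValueError("need at least one domain of 6+ beads")


@dataclass
class ToySystem:
    model: CoarseModel
    contacts: ContactSet
    pdb_text: str
    spec: ToySpec
    open_positions: np.ndarray | None = None
    elements: dict[str, list] = field(default_factory=dict)

    def element_subsets(self) -> dict[str, ContactSet]:
        """Contact subsets per structural element (domains + interfaces)."""
        out: dict[str, ContactSet] = {}
        for r in self.contacts:
            if r.basin != "apo":
                continue
            top, _, rest = r.contact_class.partition(":")
            if top == "intra":
                key = rest
            elif top == "inter":
                key = rest.replace("|", "-")
            elif top == "linker":
                key = "linker"
            else:
                continue
            out.setdefault(key, []).append(r)
        return {k: ContactSet(v) for k, v in out.items()}


def _serpentine_grid(n: int, ncols: int = 3, a: float = GRID_SPACING) -> np.ndarray:
    # alternate beads pucker out of the plane: no three consecutive beads are
    # collinear, so every native angle and dihedral is well defined
    pos = np.zeros((n, 3))
    for k in range(n):
        r, c = divmod(k, ncols)
        if r % 2 == 1:
            c = ncols - 1 - c
        pos[k] = (c * a, r * a, 0.06 * (1 if k % 2 else -1))
    return pos


def _linker_arc(start: np.ndarray, end: np.ndarray, n: int, apex: float = 0.75) -> np.ndarray:
    """n beads on an arc bulging out of the grid plane (+z)."""
    t = np.linspace(0.0, 1.0, n + 2)[1:-1]
    base = start[None, :] + t[:, None] * (end - start)[None, :]
    base[:, 2] += apex * np.sin(np.pi * t)
    return base


def _residue_names(n: int, pattern: tuple[str, ...]) -> list[str]:
    if not pattern:
        return ["GLY"] * n
    return [pattern[k % len(pattern)] for k in range(n)]


def write_pdb(
    chains: list[tuple[str, list[tuple[str, int, list[tuple[str, np.ndarray]]]]]]
) -> str:
    """Minimal PDB text: chains -> [(resname, resid, [(atom, pos nm)])]."""
    lines = []
    serial = 1
    for chain_name, residues in chains:
        for resname, resid, atoms in residues:
            for atom_name, pos in atoms:
                x, y, z = (np.asarray(pos) * 10.0).tolist()  # nm -> Angstrom
                name = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain_name}"
                    f"{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _protein_chain_entries(names, positions, start_resid=1):
    return [
        (names[k], start_resid + k, [("CA", positions[k])])
        for k in range(len(names))
    ]


def _partner_chain_entries(positions_by_nt, start_resid=1):
    entries = []
    for k, (p, s, b) in enumerate(positions_by_nt):
        entries.append(
            ("DA", start_resid + k, [("P", p), ("C1'", s), ("N1", b)])
        )
    return entries


def _assemble_protein(spec: ToySpec, open_form: bool = False):
    """Bead positions, residue names, and domain map for the toy protein."""
    rng = np.random.default_rng(spec.seed)
    segments = []
    domain_map: dict[str, list[tuple[int, int]]] = {}
    resid = 1
    prev_end = None
    gap = 0.6  # nm between docked domain faces
    for d in range(spec.n_domains):
        grid = _serpentine_grid(spec.beads_per_domain)
        y_extent = grid[:, 1].max()
        y_off = d * (y_extent + gap)
        if open_form and d > 0:
            # swing later domains out of the docking plane: interface broken
            grid = grid + np.array([0.0, 0.0, 2.0])
            y_off += 1.0
        grid = grid + np.array([0.0, y_off, 0.0])
        name = chr(ord("A") + d)
        domain_map[name] = [(resid, resid + spec.beads_per_domain - 1)]
        if prev_end is not None:
            link = _linker_arc(prev_end, grid[0], spec.linker_length)
            domain_map.setdefault("linker", []).append(
                (resid, resid + spec.linker_length - 1)
            )
            domain_map[name] = [
                (resid + spec.linker_length,
                 resid + spec.linker_length + spec.beads_per_domain - 1)
            ]
            resid += spec.linker_length
            segments.append(link)
        segments.append(grid)
        resid += spec.beads_per_domain
        prev_end = grid[-1]
    positions = np.concatenate(segments)
    positions = positions + rng.normal(0.0, 1e-4, positions.shape)
    names = _residue_names(len(positions), spec.charge_pattern)
    return positions, names, domain_map


def _partner_rail(n_nt: int, x0: float = 0.0):
    """Frozen three-bead-per-nucleotide rail below the first domain edge."""
    out = []
    for k in range(n_nt):
        x = x0 + 0.5 * k
        base = np.array([x, -0.6, 0.0])
        sugar = np.array([x, -1.1, 0.15])
        phos = np.array([x + 0.25, -1.35, 0.45])
        out.append((phos, sugar, base))
    return out


def make_toy_multidomain(spec: ToySpec | None = None) -> ToySystem:
    """Multidomain bead protein with intra, inter, and linker contacts.

    Domains are serpentine grids docked edge-to-edge; the linker arches over
    the docking gap. The emitted PDB, re-parsed through the model builder
    with the toy contact prescription (cutoff 0.75 nm, minimum sequence
    separation 3), defines the returned model and classified contacts.
    """
    spec = spec or ToySpec()
    positions, names, domain_map = _assemble_protein(spec)
    pdb_text = write_pdb([("A", _protein_chain_entries(names, positions))])
    structure = parse_pdb(pdb_text)
    model = coarse_grain(structure, domain_map)
    contacts = classify_contacts(
        build_contacts(
            structure, model, cutoff=TOY_CUTOFF,
            min_separation=TOY_MIN_SEPARATION,
        ),
        model,
    )
    totals = contacts.class_totals()
    inter_like = totals["inter"] + totals["linker"]
    if inter_like == 0 or totals["intra"] == 0:
        raise ValueError("toy construction produced an empty contact class")
    ratio = totals["intra"] / inter_like
    if spec.n_domains > 1 and abs(ratio - spec.target_ratio) > 0.2 * spec.target_ratio:
        raise ValueError(
            f"realized intra:inter ratio {ratio:.2f} deviates more than 20% "
            f"from the requested {spec.target_ratio:.2f}; adjust beads_per_domain "
            "or linker_length"
        )
    return ToySystem(model=model, contacts=contacts, pdb_text=pdb_text, spec=spec)


def make_toy_binding_system(spec: ToySpec | None = None) -> ToySystem:
    """Protein plus a frozen, charged partner rail with binding contacts.

    With ``dual_basin`` the protein's apo contact set is computed from an
    open conformation (later domains swung away from the docking interface)
    and merged with the contacts unique to the closed, partner-bound
    structure, mirroring an open-to-closed binding transition.
    """
    spec = spec or ToySpec(
        partner_length=5,
        charge_pattern=("ARG", "GLY", "GLY", "GLY", "GLY", "GLY"),
    )
    if spec.partner_length < 2:
        raise ValueError("binding system requires a partner chain (>= 2 nt)")
    positions, names, domain_map = _assemble_protein(spec)
    rail = _partner_rail(spec.partner_length)
    chains = [
        ("A", _protein_chain_entries(names, positions)),
        ("B", _partner_chain_entries(rail)),
    ]
    pdb_text = write_pdb(chains)
    structure = parse_pdb(pdb_text)
    model = coarse_grain(structure, domain_map, freeze_nucleic=True)
    bound_contacts = classify_contacts(
        build_contacts(
            structure, model, cutoff=TOY_CUTOFF,
            min_separation=TOY_MIN_SEPARATION,
        ),
        model,
    )
    open_positions = None
    if spec.dual_basin:
        open_pos, _, _ = _assemble_protein(spec, open_form=True)
        open_pdb = write_pdb([("A", _protein_chain_entries(names, open_pos))])
        open_structure = parse_pdb(open_pdb)
        open_model = coarse_grain(open_structure, domain_map)
        apo_contacts = classify_contacts(
            build_contacts(
                open_structure, open_model, cutoff=TOY_CUTOFF,
                min_separation=TOY_MIN_SEPARATION,
            ),
            open_model,
        )
        contacts = build_dual_basin(apo_contacts, bound_contacts)
        n_pro = len(open_pos)
        open_positions = np.array(model.positions)
        open_positions[:n_pro] = open_pos
    else:
        contacts = bound_contacts
    if contacts.class_totals()["binding"] == 0:
        raise ValueError("toy binding construction produced no binding contacts")
    return ToySystem(
        model=model, contacts=contacts, pdb_text=pdb_text, spec=spec,
        open_positions=open_positions,
    )


# ---------------------------------------------------------------------------
# analytic references


def make_harmonic_chain(
    n_beads: int, stiffness: float = 100.0, bond_length: float = 1.0
) -> CoarseModel:
    """Bonds-only straight chain with closed-form Boltzmann statistics.

    At temperature T each bond is one quadratic mode: mean potential energy
    T/2 and length variance T/(2 * stiffness), up to the O((dr/r0)^2)
    radial-Jacobian correction.
    """
    if n_beads < 2:
        raise ValueError("chain needs at least two beads")
    pos = np.zeros((n_beads, 3))
    pos[:, 0] = bond_length * np.arange(n_beads)
    bonds = np.array([(k, k + 1) for k in range(n_beads - 1)], dtype=np.int64)
    return CoarseModel(
        positions=pos,
        chain_ids=["A"] * n_beads,
        res_ids=np.arange(1, n_beads + 1),
        res_names=["GLY"] * n_beads,
        kinds=["CA"] * n_beads,
        charges=np.zeros(n_beads),
        frozen=np.zeros(n_beads, dtype=bool),
        bonds=bonds,
        bond_r0=np.full(n_beads - 1, float(bond_length)),
        angles=np.zeros((0, 3), dtype=np.int64),
        angle_t0=np.zeros(0),
        dihedrals=np.zeros((0, 4), dtype=np.int64),
        dihedral_p0=np.zeros(0),
        domain_map={"A": [(1, n_beads)]},
    )


@dataclass
class DoubleWell:
    """V(x) = barrier * (x^2 - 1)^2: minima at x = +-1, barrier at x = 0."""

    barrier: float

    def __post_init__(self):
        if self.barrier <= 0:
            raise ValueError("barrier must be positive")

    def potential(self, x):
        return self.barrier * (np.asarray(x) ** 2 - 1.0) ** 2

    def analytic_pmf(self, grid: np.ndarray, kT: float = 1.0) -> np.ndarray:
        """F(x) in kT with min 0 on the grid (PMF equals V/kT up to a shift)."""
        F = self.potential(grid) / kT
        return F - F.min()

    def boltzmann_density(self, grid: np.ndarray, kT: float = 1.0) -> np.ndarray:
        p = np.exp(-self.potential(grid) / kT)
        return p / np.trapezoid(p, grid)


def make_double_well(barrier_kT: float) -> DoubleWell:
    return DoubleWell(barrier=float(barrier_kT))


def brute_force_mfpt_1d(
    well: DoubleWell,
    n_runs: int = 100,
    n_steps: int = 2_000_000,
    dt: float = 0.005,
    kT: float = 1.0,
    seed: int = 0,
    target: tuple[float, float] = (0.9, 1.2),
    x0: float = -1.0,
) -> tuple[float, int]:
    """Unbiased MFPT into the target window; (mean over completed, censored)."""
    from .sampler import first_passage_1d

    fpts = []
    censored = 0
    for run in range(n_runs):
        t = first_passage_1d(
            well.barrier, target, n_steps, dt=dt, kT=kT,
            seed=seed * 1000 + run, x0=x0,
        )
        if t is None:
            censored += 1
        else:
            fpts.append(t)
    if not fpts:
        raise RuntimeError("no unbiased run reached the target window")
    return float(np.mean(fpts)), censored


def make_synthetic_melting_set(
    tms, widths, grid, noise: float = 0.0, seed: int = 0
):
    """Exact sigmoids P(T) = 1/(1+exp((T-Tm)/w)) sampled on the grid."""
    from .thermo import MeltingCurve, _sigmoid

    tms = np.atleast_1d(np.asarray(tms, float))
    widths = np.atleast_1d(np.asarray(widths, float))
    if len(tms) != len(widths):
        raise ValueError("tms and widths must have equal length")
    grid = np.asarray(grid, float)
    rng = np.random.default_rng(seed)
    curves = []
    for k, (tm, w) in enumerate(zip(tms, widths)):
        p = _sigmoid(grid, tm, w)
        if noise > 0:
            p = np.clip(p + rng.normal(0.0, noise, size=p.shape), 0.0, 1.0)
        curves.append(
            MeltingCurve(
                element=f"el{k}", temperatures=grid, p_folded=p, tm=tm, width=w,
            )
        )
    return curves
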