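# Methods

## The model

`domainfold` implements a coarse-grained structure-based model (SBM) for
multidomain proteins and their binding to a rigid nucleic-acid partner.
Each amino acid is one C-alpha bead; each nucleotide is three beads
(phosphate, sugar, base). The potential contains only interactions present
in the native structure plus generic repulsion and screened electrostatics:

    V = V_bonded + eps_intra V_intra + eps_inter (V_inter + V_linker)
        [+ V_binary + V_binding + V_elec + V_excl]

* **Bonded terms.** Harmonic bonds `K_b (r - r0)^2` with `K_b = 100
  eps/nm^2`, harmonic angles `K_a (theta - theta0)^2` with `K_a = 20
  eps/rad^2`, and dihedrals `K_d [(1 - cos dphi) + (1/2)(1 - cos 3 dphi)]`
  with `K_d = 1 eps`, all anchored at the native geometry. These are
  standard C-alpha SBM choices; nothing downstream is sensitive to them as
  long as the chain is semi-rigid.
* **Native contacts.** 12-10 pair terms
  `eps [5 (sigma/r)^12 - 6 (sigma/r)^10]` with depth `-eps` exactly at the
  native distance `sigma_ij`. Contacts are found with an all-heavy-atom
  cutoff (0.45 nm, minimum sequence separation 4 for real structures;
  0.75 nm / separation 3 for the CA-only toy templates) and classified by
  the domain map: intradomain, interdomain, linker (any endpoint in the
  linker — the linker is grouped with the interdomain class), or
  protein-DNA binding.
* **The control parameter rho.** A single dimensionless ratio
  `rho = eps_inter/eps_intra` re-weights every interdomain and linker
  contact against the intradomain ones (`rho = 1` is the homogeneous
  default). Because the potential is *linear* in rho, the energy at any
  rho follows from the stored decomposition of a single reference
  simulation: `E(rho) - E(rho0) = (rho - rho0)(V_inter + V_linker)`.
  Contacts that exist only in the partner-bound structure sit at a domain
  interface by construction and are scaled like interdomain contacts;
  protein-DNA contacts carry unit strength so that rho modulates only the
  protein's internal balance.
* **Electrostatics.** Debye-Hueckel screened Coulomb between all charged
  bead pairs (Arg/Lys +1, Asp/Glu -1, phosphate -1), Debye length 0.8 nm
  (about 150 mM monovalent salt) by default. The prefactor is calibrated
  so two opposite unit charges at 0.5 nm interact with exactly the
  strength of one native contact; only this calibration is a hard
  contract, the Debye length is configurable.
* **Excluded volume.** `(0.4 nm / r)^12` between all non-bonded,
  non-contact pairs, truncated beyond 3 diameters.
* **Temperature rescaling.** Multiplying the entire potential by
  `Tf(rho0)/Tf(rho)` maps the folding temperature at any rho back to the
  reference one, so kinetic runs at different rho share one bath
  temperature. Experimental temperatures enter through the linear map
  `T(sim) = T(exp) x Tf(sim)/Tf(exp)`.

## Sampling

Langevin dynamics uses the BAOAB splitting, unit masses, kB = 1, friction
1/tau, and a default timestep of 0.0005 tau; the toy campaigns run at
0.001-0.003 tau, which is stable for their soft Hamiltonians. Partner
(DNA) beads are frozen: they receive no integrator updates and exactly
zero force. Replica exchange swaps configurations between neighboring
temperature rungs every `exchange_interval` steps with acceptance
`min(1, exp(dbeta dE))` and velocity rescaling; the per-rung series are
continuous constant-temperature trajectories. Umbrella sampling biases
the protein-partner dRMS with harmonic windows seeded outward from the
bound pose. Well-tempered metadynamics on dRMS deposits Gaussian hills
whose deposition interval doubles each time the running acceleration
factor `<exp(V_bias/kT)>` crosses a power of ten — a deliberately simple
infrequent-deposition schedule — and accumulates the rescaled transition
time `sum(dt exp(V_bias/kT))` until first arrival in the target state.

## Analyses

* **Temperature WHAM** iterates the multiple-histogram equations on binned
  total energies (optionally jointly with a collective variable) to a
  1e-10 tolerance, yielding the density of states, heat capacity curves
  (the folding temperature is the Cv peak), and free-energy surfaces at
  any temperature. **Umbrella WHAM** unbiases the window histograms into
  a potential of mean force with per-window consistency residuals.
* **Reweighting** applies `w ∝ exp(-(E(rho)-E(rho0))/kT)` per frame using
  the stored energy decomposition, reports the effective sample size, and
  warns below 10% ESS.
* **Melting curves** are per-element folded probabilities
  `P_I(T) = P(Q_I >= 0.5)` fitted by a two-parameter sigmoid; the
  thermodynamic coupling index is `TCI = -ln <|P_I - P_J|>` over the
  ladder range, capped at `-ln(1/(10 G))` for a G-point grid so identical
  curves stay finite; MTCI applies the log to the pair-averaged mean
  difference.
* **State stabilities** are Boltzmann integrals of the free-energy surface
  over configurable CV windows, referenced to the unfolded window, and
  reported as shifts relative to rho0.
* **Binding affinity.** The bound/unbound Boltzmann integrals of the dRMS
  PMF give the bound fraction at the single-molecule box concentration
  `C_box = 1/(N_A V_box)`; `Kd = C_box I_unbound/I_bound` converts to the
  1 M standard state. Full-scale state windows are BS < 0.5 nm,
  IS 0.5-2.5 nm, EC 2.5-10 nm, US > 10 nm; the toy campaign uses scaled
  windows (0.3/1.0/3.0 nm) because the toy box is a few nanometers.
* **Kinetics.** First passage is the earliest time the total native-contact
  fraction Q reaches 0.75. Folding order ranks the commitment times of
  the configured elements (four domains and four interfaces for the
  full-scale protein; an element commits at its first threshold crossing
  after which it never falls below 0.67 x threshold before global
  folding); the order-probability matrix has stochastic columns with mean
  1/K, and its per-step standard deviation measures how deterministic the
  pathway is. Backtracking events are drops of binned Q_inter by at least
  0.05 along monotonized Q_total progress (bin width 0.02). Encounter
  statistics count evolutions versus dissociations from encounter-complex
  starts: `encounter time = k_dis/k_evo + 1`. Metadynamics transition
  times are averaged over runs with a 50-resample bootstrap error;
  censored runs are counted, never imputed.

## Synthetic systems

The toy generators define the study conditions and are fixed:

* **Multidomain toy** (default): two domains of 18 beads on puckered
  serpentine grids (0.5 nm spacing, +-0.06 nm out-of-plane so no native
  angle or dihedral is degenerate), docked edge-to-edge with a 4-bead
  linker arching over the gap. The defaults realize a 5:1
  intra-to-inter(+linker) contact ratio (40:3+5) — the "many more
  intradomain than interdomain contacts" regime — and the native
  structure is the exact minimum of every energy term except a negligible
  excluded-volume residual (|F|max < 0.01 eps/nm). Its melting transition
  sits near T = 0.9-1.0 under the default ladder (0.75-1.25).
* **Binding toy**: the same protein plus a frozen rail of 3-bead
  nucleotides carrying -1 phosphates, with Arg beads every sixth residue.
  The dual-basin option computes the apo contact set from an open
  conformation (second domain swung away) and merges in the contacts
  unique to the closed, partner-bound structure.
* **Analytic references**: a bonds-only harmonic chain (per-mode potential
  energy kT/2, bond-length variance kT/2K, up to the O((dr/r0)^2)
  radial-Jacobian correction — bonds default to 1.0 nm so that correction
  is ~0.5%) and the quartic double well `V = B (x^2 - 1)^2` with analytic
  PMF and brute-force first-passage reference.

What the toys do **not** emulate: real secondary structure and topology,
sequence-dependent energetics, realistic DNA geometry or flexibility,
solvent beyond Debye screening, and the system size of a real polymerase.
Passing tests therefore certify the correctness of the machinery (energies,
sampling, estimators) and the internal consistency of the analyses, not
quantitative predictions for any real protein.

## Problem sizes

The validation experiments are sized for a single CPU: the reweighting
check runs two 8-replica exchanges of 600k steps each on the 40-bead toy
and compares 20 Q-bins at the mid-ladder temperature (only bins with at
least 25 direct counts are compared); equipartition uses ten 80k-step
chains; the WHAM oracle 17 umbrella windows of 150k steps; the rate oracle
50 unbiased and 16 metadynamics runs. The campaign commands default to
smoke-scale settings and are meant to be scaled up through their
configuration for production use.

## Numerical choices and edge cases

WHAM iterations run in log space with `logsumexp`; empty bins carry
`-inf` free energy and are excluded from comparisons. Sigmoid fits are
bounded and flagged (not fitted) when an element never changes state
across the ladder. Folding-order ties break by element order. Degenerate
angle configurations guard `sin(theta)` at 1e-8; metadynamics hill
buffers are preallocated (20k hills). The energy guard aborts a
trajectory above 1e8 reduced units and reports divergence rather than
returning garbage. Contact maps, models, and all tables serialize to
deterministic CSV/JSON so identical inputs produce byte-identical
artifacts.

## Known limitations

Temperature WHAM bins total energy only, so reweighted heat-capacity
curves at rho != rho0 are obtained from refit melting curves rather than
from E(rho) fluctuations. The dual-basin merge assumes identical protein
bead ordering in the apo and bound structures. The encounter campaign
classifies outcomes by dRMS thresholds alone, without a contact-count
criterion for the encounter complex. Diffusion coefficients use a single
linear MSD fit window; anomalous-diffusion diagnostics are out of scope.
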