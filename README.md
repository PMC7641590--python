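# domainfold

Coarse-grained structure-based models (SBMs) for **multidomain protein
folding** and **protein–DNA binding**, with one control knob: the ratio

    rho = eps_inter / eps_intra

between the strengths of interdomain (including linker) and intradomain
native contacts. The package is aimed at researchers studying how the
balance of domain-internal versus domain-interface interactions shapes
folding mechanisms (domain-wise versus cooperative folding, backtracking,
folding order) and binding function (affinity, encounter kinetics,
open-to-closed conformational transitions) in proteins such as the
Y-family DNA polymerase DPO4 (finger, palm, thumb, and little-finger
domains joined by a flexible linker).

## What it does

* **Model building** — parse PDB structures (e.g. apo 2RDI and the
  DNA-bound binary 2RDJ), reduce proteins to C-alpha beads and nucleotides
  to phosphate/sugar/base beads, build and classify the native contact map
  (intra / inter / linker / binding), and merge apo and bound structures
  into a dual-basin model.
* **Hamiltonian** — 12-10 native contacts scaled per class by rho, standard
  bonded terms, excluded volume, and Debye–Hückel electrostatics calibrated
  so opposite unit charges at 0.5 nm match one native contact; energies are
  decomposed per class so that E(rho) is exactly linear in rho.
* **Sampling** — BAOAB Langevin dynamics in reduced units, temperature
  replica exchange, umbrella sampling on the protein–DNA distance-RMS
  (dRMS), and well-tempered metadynamics with rescaled transition times.
* **Thermodynamics** — temperature and umbrella WHAM, exact rho-reweighting
  from a single reference simulation, heat capacity and folding
  temperatures, melting curves with the thermodynamic coupling index
  TCI = −ln⟨|P_I(T) − P_J(T)|⟩ and its pair-averaged MTCI, state
  stabilities ΔΔF(rho), and dissociation constants from the dRMS PMF.
* **Kinetics** — first-passage times to Q ≥ 0.75, folding-order probability
  matrices OP_k^I with dispersion σ_OPk, backtracking detection on
  (Q_total, Q_inter), the encounter framework (encounter time =
  k_dis/k_evo + 1), and bootstrap-errored metadynamics transition times.
* **Synthetic systems** — deterministic toy multidomain proteins and a
  frozen charged partner rail, plus analytic references (harmonic chain,
  quartic double well) with closed-form statistics, so the entire pipeline
  runs and is tested without any downloads.

## Worked example

```python
from domainfold import ForceField, map_temperature, total_energy
from domainfold.synthetic_data import make_toy_multidomain

toy = make_toy_multidomain()               # two domains + linker, 40 beads
print("contact classes:", toy.contacts.class_totals())

report = total_energy(toy.model, toy.contacts, ForceField(rho=0.8),
                      toy.model.positions)
print(f"native energy at rho=0.8: intra={report.intra:.1f} "
      f"inter={report.inter:.1f} linker={report.linker:.1f} "
      f"total={report.total:.2f}")

print("room temperature in reduced units:",
      round(map_temperature(300, 369, 1.13), 2))
```

prints

```
contact classes: {'intra': 40, 'inter': 3, 'linker': 5, 'binding': 0}
native energy at rho=0.8: intra=-40.0 inter=-2.4 linker=-4.0 total=-46.40
room temperature in reduced units: 0.92
```

The toy realizes the 5:1 intradomain-to-interdomain contact ratio typical
of multidomain proteins; at the native structure every contact sits at its
minimum (−eps), so the interdomain and linker sums are exactly −rho times
the contact counts. The temperature map aligns the simulated folding
temperature (1.13 reduced units) with the experimental one (369 K), so
300 K corresponds to a reduced temperature of 0.92.

The campaign-level interface is a CLI:

```
domainfold build --toy multidomain --seed 1 --outdir runs
domainfold fold  --seed 1 --outdir runs       # REMD + reweighting + kinetics
domainfold bind  --seed 1 --outdir runs       # PMF + Kd + encounter + rates
domainfold map-temperature 353 369 1.13
```

Each campaign echoes its full configuration into the output directory and
derives every random stream from the single global seed, so reruns are
reproducible.

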