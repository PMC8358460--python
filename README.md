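# shiftbind

Quantitative mapping of disulfide-rich peptide–receptor interactions by
solution NMR and calorimetry, packaged as a tested Python library. The
worked system is chlorotoxin (ClTx) — the 36-residue, four-disulfide
scorpion toxin that targets gliomas — binding the b1 domain of the VEGF
receptor neuropilin-1 (NRP1-b1), with the small-molecule NRP1 antagonist
EG00229 as competitor. Everything is driven by seeded synthetic-data
generators with known ground truth, so the full pipeline runs and is
testable without spectrometer or calorimeter data.

## What it computes

**Binding equilibria** (`binding_equilibria`). The exact 1:1 isotherm: with
receptor total $P$, ligand total $L$ and dissociation constant $K_d$, the
complex concentration is the physical root of
$[PL]^2 - (P+L+K_d)[PL] + PL = 0$; and the one-site two-ligand competitive
equilibrium, solved by monotone bracketing of the free-receptor mass
balance. Thermodynamics via $\Delta G = RT\ln K_d$ and
$-T\Delta S = \Delta G - \Delta H$.

**HSQC titration analysis** (`titration_csp`). Combined amide perturbation
$\Delta\delta = \sqrt{\Delta\delta_H^2 + (\alpha\,\Delta\delta_N)^2}$
(α = 0.2) and intensity attenuation $I/I_0$ per residue; interface calls by
the μ + σ rule (sample sd over all scored residues); global fast-exchange
$K_d$ fits of $\Delta\delta_{obs} = \Delta\delta_{max}\,f_{bound}$; and
competitor-displacement recovery with a cross-check against the competitive
equilibrium solver.

**ITC** (`itc_model`). Forward simulation of per-injection normalized heats
under a displacement-dilution injection model, single-site and competitive
refitting with stoichiometry fixed at N = 1, Wiseman c-value bookkeeping
and the $K_d/\Delta H/\Delta G/-T\Delta S/N$ table.

**Structure ensembles** (`structure_ensemble`). Multi-model PDB I/O (gemmi),
Kabsch superposition, iterative RMSD-to-mean-coordinate statistics,
geometric disulfide detection (mutual-nearest SG–SG contacts) with
framework naming (e.g. `1-4,2-6,3-7,5-8`), single-linkage surface-patch
identification and restraint bookkeeping
(intra/sequential/medium/long-range bins).

**Docking restraints** (`docking_restraints`). The three unambiguous
ClTx:NRP1-b1 distance restraints and flexible segments 24–28/35–36 from the
NMR mapping; active/passive residue derivation from CSP flags plus a
surface-exposure proxy; CNS/HADDOCK `.tbl` writing with a byte-exact
round-trip parser; restraint-violation checking on complex models.

**Peptide chemistry** (`peptide_chem`) and **synthetic data**
(`synthetic_data`): sequence/framework handling, isotope-aware
monoisotopic/average masses, and the seeded generators for titrations,
thermograms and toy coordinate ensembles.

## Worked example

```bash
python examples/itc_thermodynamics.py
```

```
ligand        Kd (uM)     dH     dG   -TdS    N
EG00229           7.9  -10.0   -7.1    2.9  1.0
chlorotoxin     143.3   -2.4   -5.4   -3.0  1.0

competition: baseline-corrected signal ratio = 0.034 (binding is blocked when this is small)
```

Each row is a noiseless simulated thermogram (800 µM syringe into a 40 µM
cell, 12 × 3.22 µL injections at 32 °C) refit with N fixed at 1.0: the
recovered $K_d$ and $\Delta H$ reproduce the generating values, and the
decomposition shows EG00229 binding is enthalpy-driven while the toxin's is
entropy-driven. The competition line pre-loads 200 µM EG00229 into the
cell: the toxin's binding signal drops to ~3% of its free value — the
two ligands share the same site.

```bash
python examples/csp_titration.py
```

```
shift threshold mu+sigma = 0.1063 ppm
shift-perturbed residues:     [2, 20, 21, 23, 25, 26, 28, 29, 34]
intensity threshold (1-I/I0) = 0.221
intensity-perturbed residues: [2, 25, 26, 27, 28, 35, 36]

global fast-exchange fit: Kd = 147.0 uM (generator truth 143.3 uM)

competitor point (413 uM):
  mean flagged shift 0.0079 ppm vs threshold 0.1063 -> verdict: recovered
  predicted toxin occupancy 0.022 (no competitor: 0.416)
```

The flagged sets recover the generator's interface residues exactly — the
basic patch around R25/K27/R36 plus adjacent positions — and the 413 µM
competitor point restores the free-state spectrum ("recovered"), with the
equilibrium solver predicting the toxin occupancy collapsing from 42% to
2%.

The other examples (`peptide_mass.py`, `ensemble_statistics.py`,
`docking_restraint_generation.py`) cover mass conventions, ensemble
statistics and restraint generation. A thin CLI exposes the same stages:
`shiftbind mass|structure-stats|csp|itc-sim|itc-fit|restraints|simulate`.

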