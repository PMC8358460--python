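# Methods

This note records the models behind each module, the defaults that matter,
the numerical choices, and what the synthetic generators do and do not
emulate.

## Binding models

All binding stages share one equilibrium layer. The 1:1 isotherm treats the
receptor as a single site (an `n_sites` factor scales receptor total into
site total; the ITC convention N = 1 is the default everywhere) and solves
the quadratic mass balance in the cancellation-safe form
`[PL] = 2PL / (b + sqrt(b^2 - 4PL))`, `b = P + L + Kd`, which is accurate
even when the bound fraction is tiny. The two-ligand competitive case
solves the monotone free-receptor mass balance

    p + p·A/(Kd_A + p) + p·B/(Kd_B + p) = N·P_tot

by Brent bracketing on `[0, N·P_tot]`; the returned state is rejected if
its relative mass-balance residual exceeds 1e-9. The raw cubic closed form
was deliberately avoided: it loses digits catastrophically when the two Kd
values differ by many orders of magnitude, while bracketing is uniformly
robust.

Free energies use `dG = R·T·ln Kd` with R = 1.987204e-3 kcal/mol/K and an
implicit 1 M standard state; the default temperature is 305.15 K (32 °C,
the calorimetry temperature). `-T·dS = dG - dH` holds exactly by
construction wherever the three are produced together.

## ITC forward model and fitting

Injections follow a displacement-dilution treatment of a fixed-volume cell
(default V0 = 200 µL, typical of the low-volume calorimeter class used for
these experiments and configurable): each injection of volume dV displaces
an equal volume of pre-injection cell mixture, so cell species dilute by
(1 − dV/V0) and the injectant gains [syr]·dV/V0. Cumulative cell heat is
Q = V0·(dH_A·[PA] + dH_B·[PB]); the observed injection heat adds the
standard displaced-volume correction
`heat_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2`, and NDH divides by
moles injected. The 0.4 µL priming injection updates concentrations but is
excluded from the fitted points, matching experimental processing.

Fitting is least squares over (ln Kd, dH, baseline) with N fixed (default
1.0); the constant baseline absorbs heats of dilution — no separate blank
titration is modelled. Start values are deterministic (dH from the first
fitted injection minus the last, Kd from the ligand concentration at the
titration midpoint), so identical inputs give identical fits. Standard
errors come from the Jacobian with a delta-method transform for Kd.
Noiseless simulate→refit round trips recover parameters to better than
0.1% across c = N·P/Kd from 0.1 to 1000 — including the weak-binding
regime (c ≈ 0.28 for the toxin) where Kd and dH are strongly correlated
but still identified in the absence of noise.

**Competition suppression.** A pre-bound competitor contributes a
near-constant positive offset to every injection: diluting the cell shifts
the competitor equilibrium and releases heat regardless of the injectant.
That offset is heat-of-dilution, not binding signal, and is exactly what
the constant baseline (or an instrument blank subtraction) removes.
`suppression_ratio` therefore compares baseline-corrected maximum |NDH|
values by default; for the 200 µM competitor experiment the corrected
ratio is ≈ 0.03 (raw, uncorrected: ≈ 0.24, almost all of it offset).

## CSP analysis

The combined shift uses the field-standard weighting
`dd = sqrt(ddH^2 + (alpha·ddN)^2)` with alpha = 0.2 (configurable; no
glycine-specific scaling). Significance is the μ + σ rule: mean and sample
standard deviation (ddof = 1) over *all* scored residues, no iterative
trimming. Shift mode flags `dd > mu + sigma`; intensity mode scores the
fractional loss `1 − I/I0` the same way, with vanished peaks entering as
loss 1 so exchange-broadened residues remain flaggable. Scoring uses the
final receptor-only titration point against the free reference — the
saturating endpoint carries the clearest pattern — while intermediate
points feed the Kd fit only. Residues missing from a peak list are
reported absent, never as zero shift.

The fast-exchange Kd fit shares one Kd across selected residues with
per-residue saturation amplitudes; it assumes the observed shift is the
population-weighted average of free and bound states, which holds in the
fast-exchange limit the generator implements. Recovery verdicts compare
the mean perturbation of previously flagged residues at the competitor
point with the reference μ + σ threshold; the expected displacement is
cross-checked against the competitive equilibrium solver when both Kd
values are supplied.

## Structure ensembles

Backbone = {N, CA, C, O}; heavy = all non-hydrogen; both configurable
since conventions differ between packages. RMSD-to-mean iterates: fit all
models to the running mean over the selection (initial reference model 1),
recompute the mean, stop when it moves < 1e-6 Å (hard failure after 100
iterations); reported as arithmetic mean ± sample sd of per-model RMSDs.
Superposition is closed-form Kabsch with the determinant correction, so
only proper rotations are returned. Disulfides are mutual-nearest SG–SG
contacts below 2.5 Å (covalent S–S ≈ 2.05 Å plus noise margin); a cysteine
with a sub-cutoff partner that is not mutually nearest raises rather than
being silently paired. Surface patches are single-linkage clusters (union–
find) of representative side-chain points — Arg CZ/Lys NZ for the basic
class, side-chain centroids for the hydrophobic class {F, T, H} — within
10 Å, reporting clusters of two or more residues. The clustering rule and
cutoffs are this package's choices; only the resulting memberships have an
experimental reference. Residue numbering is taken verbatim from the PDB
file.

## Docking restraints

The third unambiguous restraint (K27 NZ – residue 319 CG) has no published
bounds; the default 3.0–5.0 Å is a salt-bridge-compatible range, exposed as
a parameter and echoed in output provenance. The receptor residue at 319
is referred to inconsistently as D or E in the source material; the
restraints target residue number 319 and do not validate its type. The
surface-exposure proxy counts heavy atoms within 8 Å of a residue's
side-chain centroid (cutoff 35) — a deliberately cheap stand-in for SASA
that orders buried vs exposed correctly on the fixtures used here; real
applications with full-atom models may want a proper SASA. Ambiguous
restraints default to the common 2.0 Å effective upper bound between any
atoms of the selections. Segid mapping defaults to peptide = A,
receptor = B.

## Synthetic generators

All generators are pure functions of (parameters, seed) using one
documented PRNG (`numpy.random.default_rng`); manifests record both, and
regeneration is byte-identical.

The titration generator emulates fast exchange only: peaks move by
`f_bound·dd_max` and attenuate by `1 − f_bound·(1 − beta)` with additive
Gaussian shift noise (default 0.002 ppm 1H) and multiplicative log-normal
intensity noise (default 2%); peaks below 5% of reference intensity are
dropped to emulate vanishing. Defaults encode the study conditions: 55 µM
observed peptide, receptor ladder 0/21/34/45/57/95/125 µM, ground-truth
Kd 143.3 µM, competitor point 413 µM at Kd 7.9 µM, shift interface
{2,20,21,23,25,26,28,29,34} and intensity interface {2,25,26,27,28,35,36}.
Interface saturation shifts are drawn once per seed from 0.25–0.45 ppm
(combined scale) — large enough to be unambiguous at the study occupancy
(~42% at the final point), small enough that thresholding, not the
generator, does the work. What it does *not* emulate: lineshapes,
intermediate/slow exchange, peak overlap, assignment errors — so passing
tests demonstrate the analysis logic, not robustness to those real-data
pathologies.

The toy coordinate ensemble is a geometric scaffold, not a physical
peptide: backbone atoms along a gentle helix with hand-placed anchors
realizing the native disulfide topology (SG pairs at 2.05 Å, cross-pair
distances > 6 Å), the two basic clusters and the hydrophobic cluster.
It exists to make the ensemble operators testable with known answers;
its RMSD statistics respond to the jitter scale, not to anything
biophysical.

## Problem sizes

Tests and the acceptance script run the study-sized problems directly: a
7-point titration over 34 scored residues, 12-injection thermograms, a
200-replicate noisy refit study, and ensembles of 3–10 models; the whole
suite completes in seconds.

## Known limitations

Single-site models only (no cooperativity, no ΔCp); 100% isotope
enrichment assumed for labelling mass shifts; no raw-data processing
(FIDs, power traces, vendor formats); restraint checking assumes residue
numbering is unique across the complex; the mass module handles only the
20 canonical residues plus C-terminal amidation.
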