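"""Chemical-shift-perturbation mapping of the toxin-receptor interface.

Generates the default synthetic HSQC titration (55 uM 15N-toxin; receptor at
0/21/34/45/57/95/125 uM; one competitor-displacement point at 413 uM),
then runs the full analysis: combined 1H/15N shifts, intensity losses,
mu + sigma significance flags, a global fast-exchange Kd fit, and the
competitor-recovery verdict.
"""

from shiftbind import synthetic_data as syn
from shiftbind import titration_csp as csp

series = syn.make_titration_series()  # seeded; ground-truth Kd = 143.3 uM
result = csp.analyze_series(series)

print(f"shift threshold mu+sigma = {result.shift_threshold:.4f} ppm")
print(f"shift-perturbed residues:     {sorted(result.shift_flags)}")
print(f"intensity threshold (1-I/I0) = {result.intensity_change_threshold:.3f}")
print(f"intensity-perturbed residues: {sorted(result.intensity_flags)}")

kd, ddmax, diag = csp.fit_kd_from_shifts(series, sorted(result.shift_flags))
print(f"\nglobal fast-exchange fit: Kd = {kd * 1e6:.1f} uM "
      f"(generator truth 143.3 uM)")

rec = csp.competition_recovery(series, result,
                               kd_ligand=143.3e-6, kd_competitor=7.9e-6)
pt = rec["points"][0]
print(f"\ncompetitor point ({pt['competitor_conc']*1e6:.0f} uM):")
print(f"  mean flagged shift {pt['mean_flagged_csp']:.4f} ppm "
      f"vs threshold {pt['threshold']:.4f} -> verdict: {rec['verdict']}")
print(f"  predicted toxin occupancy {pt['predicted_occupancy']:.3f} "
      f"(no competitor: {pt['occupancy_no_competitor']:.3f})")
# The flagged sets are the residues whose peaks move (fast exchange) or
# broaden (exchange) on receptor binding; recovery of the free-state
# spectrum under competitor shows both ligands share the binding site.
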