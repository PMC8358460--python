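"""Deriving docking restraints from the NMR mapping results.

Prints the three unambiguous toxin-receptor distance restraints and the
flexible segments, writes them in CNS/HADDOCK .tbl syntax, derives
active/passive residues from CSP flags on a coordinate model, and checks
restraint satisfaction on a toy complex.
"""

import tempfile
from pathlib import Path

from shiftbind import docking_restraints as dr
from shiftbind import structure_ensemble as se
from shiftbind import synthetic_data as syn
from shiftbind import titration_csp as csp

restraints, flexible = dr.cltx_nrp1_restraint_set()
print("unambiguous restraints:")
for r in restraints:
    print(f"  {r.segid_i}:{r.res_i}/{r.atom_i} - {r.segid_j}:{r.res_j}/{r.atom_j}"
          f"  {r.lower:.1f}-{r.upper:.1f} A")
print(f"flexible segments: {list(flexible.segments)}")

tbl = Path(tempfile.mkdtemp()) / "cltx_nrp1.tbl"
text = dr.write_tbl(restraints, path=tbl)
print(f"\n.tbl output ({tbl}):")
print(text)

# Active/passive selection from the CSP analysis of the default titration,
# using the toy ensemble as the coordinate model.
series = syn.make_titration_series()
result = csp.analyze_series(series)
pdb = tbl.parent / "toy.pdb"
syn.make_toy_ensemble(pdb, seed=1, n_models=1)
model = se.read_pdb_ensemble(pdb).models[0]
active, passive = dr.derive_active_passive(
    result.shift_flags | result.intensity_flags, model
)
print(f"active residues:  {active}")
print(f"passive residues: {passive}")

checks = dr.check_violations(se.read_pdb_ensemble(pdb), restraints)
for entry in checks[0]:
    tag = "ok" if entry.get("satisfied") else "violated/missing"
    print(f"  restraint check: {tag}: {entry.get('distance', entry.get('error'))}")
# Active residues are significance-flagged and surface-exposed; passive are
# their exposed sequence neighbours. On the toy model (one chain only) the
# receptor-side atoms are absent, so those checks report missing atoms.
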