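"""Coordinate-level metrics on a toy dimer with a designed interface.

The toy dimer has a known 12-residue contact patch, so the interface
detector can be checked against ground truth; superposition and B-factor
means run on the same model.
"""

import numpy as np

from padi6tools.simulate import simulate_toy_dimer
from padi6tools.structure import (
    StructureModel,
    align_and_rmsd,
    interface_stats,
    kabsch_superpose,
    region_bfactor_mean,
)

toy = simulate_toy_dimer()  # chains A (40 beads) and B (12-bead patch)

st = interface_stats(toy.model, "A", "B")
print(f"buried interface area: {st.buried_area:.1f} A^2")
print(f"interface residues:    {st.total_residues_at_interface} "
      f"(designed patch: {len(toy.contact_residues_a)} per chain)")
found_a = set(st.per_residue_buried.query("chain == 'A'")["resnum"])
print(f"chain A interface set matches design: {found_a == set(toy.contact_residues_a)}")

b = region_bfactor_mean(toy.model, "A", 1, 10, "all_atoms")
print(f"\nmean B-factor, chain A residues 1-10: {b:.1f} A^2")

# superpose a rigidly moved copy: recovered exactly by the Kabsch solution
rng = np.random.default_rng(0)
q, r = np.linalg.qr(rng.normal(size=(3, 3)))
q *= np.sign(np.diag(r))
if np.linalg.det(q) < 0:
    q[:, 0] *= -1
X = toy.model.coords()
sup = kabsch_superpose(X, X @ q.T + np.array([4.0, 1.0, -9.0]))
print(f"\nRMSD of rigidly moved copy after superposition: {sup.rmsd:.2e} A")

# outlier rejection: displace five residues and realign chain A with itself
atoms = toy.model.atoms.copy()
atoms.loc[(atoms["chain"] == "A") & atoms["resnum"].between(30, 34), "z"] += 6.0
sup2 = align_and_rmsd(toy.model, StructureModel(atoms), "A", "A")
print(f"after displacing 5 residues by 6 A: rejected {sup2.rejected_pairs} pairs, "
      f"RMSD of remainder {sup2.rmsd:.4f} A")
print("\nThe rejection loop discards genuinely moved residues so the RMSD")
print("reflects the conserved core, as molecular-graphics aligners do.")
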