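"""Analyse the deposited hPADI6 dimer and its hPADI2/4 references.

Requires the coordinate files in the local cache; populate it once with
network access enabled (files go to ~/.cache/padi6tools or
$PADI6TOOLS_CACHE):

    from padi6tools import fetch_structure
    for acc in ("9FMN", "4N20", "1WD8", "1WDA"):
        fetch_structure(acc, allow_network=True)

Offline, this script reports which accessions are missing and exits.
"""

from padi6tools.structure import (
    align_and_rmsd,
    atom_distance,
    cached_structure_path,
    interface_stats,
    read_structure,
    region_bfactor_mean,
)

ACCESSIONS = ("9FMN", "4N20", "1WD8", "1WDA")
missing = [a for a in ACCESSIONS if cached_structure_path(a) is None]
if missing:
    raise SystemExit(f"not cached: {', '.join(missing)} — see module docstring")

padi6 = read_structure(cached_structure_path("9FMN"))

print("hPADI6 structured-loop B-factors, chain B (all atoms):")
for first, last in ((321, 329), (346, 358), (379, 397), (404, 412)):
    b = region_bfactor_mean(padi6, "B", first, last)
    print(f"  residues {first}-{last}: {b:.1f} A^2")
print(f"  all residues:     {region_bfactor_mean(padi6, 'B'):.1f} A^2")

d = atom_distance(padi6, "B:675:SG", "B:666:SG")
print(f"\nC675-C666 sulphur-sulphur distance: {d:.1f} A")

st = interface_stats(padi6, "A", "B")
print(f"dimer interface: {st.buried_area:.0f} A^2 buried, "
      f"{st.total_residues_at_interface} residues "
      f"({100 * st.interface_fraction:.1f}% of modelled sequence)")

for acc in ("4N20", "1WD8", "1WDA"):
    other = read_structure(cached_structure_path(acc))
    sup = align_and_rmsd(padi6, other, "B", other.chains[0])
    print(f"Ca RMSD vs {acc}: {sup.rmsd:.3f} A over {sup.n_pairs} Ca")
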