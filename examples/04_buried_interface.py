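"""Buried-interface area of a receptor-ligand complex via Shrake-Rupley SASA.

Builds a toy binding pocket (a 3x3x2 wall of receptor pseudo-atoms) holding
a two-ring ligand, then evaluates

    interface = 0.5 * (SASA_receptor + SASA_ligand - SASA_complex)

and the per-moiety burial of each ring. With a real aptamer-ligand PDB the
same call reports how much of the fluorophore the pocket encapsulates.
"""

import numpy as np

from fqens import buried_interface, moiety_burial
from fqens.model import Atom, MolecularModel

rng = np.random.default_rng(1)
ring_a = np.column_stack([1.4 * np.cos(np.radians(60 * np.arange(6))),
                          1.4 * np.sin(np.radians(60 * np.arange(6))), np.zeros(6)])
ring_b = ring_a + [4.5, 0.0, 0.0]
xs, ys = np.meshgrid(np.arange(-3, 4, 2.0), np.arange(-3, 4, 2.0))
wall = np.column_stack([xs.ravel(), ys.ravel(), np.full(xs.size, 3.4)])
floor = wall - [0, 0, 6.8]
coords = np.vstack([ring_a, ring_b, wall, floor])

atoms = []
for i, p in enumerate(coords):
    res = "LIG" if i < 12 else "RNA"
    atoms.append(Atom(i + 1, f"C{i + 1}", "C", res, 1 if res == "RNA" else 2, "A", tuple(p)))
model = MolecularModel(0, atoms)

ligand, receptor = range(12), range(12, len(coords))
res = buried_interface(model, receptor=receptor, ligand=ligand)
print(f"SASA receptor {res.sasa_receptor:8.1f} A^2")
print(f"SASA ligand   {res.sasa_ligand:8.1f} A^2")
print(f"SASA complex  {res.sasa_complex:8.1f} A^2")
print(f"interface     {res.interface_area:8.1f} A^2 "
      f"({100 * res.relative_interface:.0f}% of ligand SASA)")

for name, idx in (("ring A (in pocket)", range(6)), ("ring B (outside)", range(6, 12))):
    mb = moiety_burial(model, receptor, ligand, idx, moiety_name=name)
    print(f"burial of {name:<20} {100 * mb.fraction:5.1f}% of its own SASA "
          f"({100 * mb.fraction_of_ligand:4.1f}% of whole-ligand SASA)")
print()
print("The sandwiched ring loses far more accessible surface than the exposed")
print("one - the same contrast used to compare semi-open vs fully encapsulated")
print("fluorophore binding pockets across aptamers.")
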