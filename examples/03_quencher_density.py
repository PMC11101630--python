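"""Map where the quencher spends its time around the fluorophore.

Superposes every conformer on the fluorophore, bins quencher heavy atoms
into a 0.5 A voxel grid, normalises to the peak, and reports the voxel
counts enclosed at isovalues of 10%, 1% and 0.01% of the maximum. The grid
is written as an OpenDX file for rendering.
"""

from fqens import accumulate_density, isosurface_report, resolve_moieties, write_grid
from fqens.synthetic import EnsembleSpec, FREE_FRACTIONS, generate_ensemble

models, _, cfg = generate_ensemble(EnsembleSpec(500, FREE_FRACTIONS, 0.05, seed=7))
mmap = resolve_moieties(models[0], cfg)

grid = accumulate_density(models, mmap, spacing=1.0)
write_grid(grid, "quencher_density.dx")

print(f"grid dims {grid.dims}, spacing {grid.spacing} A, "
      f"{grid.n_binned} atoms binned, {grid.n_out_of_bounds} out of bounds")
for rep in isosurface_report(grid, [0.10, 0.01, 0.0001]):
    box = ""
    if rep.n_voxels:
        lo = tuple(round(float(x), 1) for x in rep.bbox_min)
        hi = tuple(round(float(x), 1) for x in rep.bbox_max)
        box = f", bbox {lo} ... {hi}"
    print(f"isovalue {rep.level:>7.4f} of max: {rep.n_voxels:>5d} voxels{box}")
print()
print("Small high-isovalue pockets mark preferred quencher positions (stacking")
print("sites); the broad low-isovalue envelope shows the reach of the tether.")
print("Wrote quencher_density.dx (OpenDX).")
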