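# fqens

Conformer-ensemble analysis of fluorophore–quencher conjugates and their
RNA-aptamer complexes.

Fluorogenic probes built from a fluorophore (e.g. tetramethylrhodamine,
TMR) tethered to a quencher ring (e.g. dinitroaniline) are dark while the
quencher stacks on the chromophore and light up when an aptamer binds the
fluorophore and displaces the quencher. `fqens` is for structural biologists
and modellers who have such ensembles — multi-model PDBs from enhanced
sampling MD, NMR bundles, or synthetic test sets — and want to quantify the
quenching-relevant geometry:

* **Conformer classification.** Per conformer: contact numbers
  `Q_xq`, `Q_pq`, `Q_Tq = Q_xq + Q_pq` (heavy-atom pairs within 4.0 Å),
  ring-centroid distances `d_xq`, `d_pq`, interplanar angles and slip
  offsets. Conformers with `Q_Tq < 5` are **NonContact**; the rest are
  **StackX** (quencher π-stacked on the xanthene: centroid ≤ 4.5 Å, angle
  ≤ 30°, offset ≤ 2.0 Å), **StackP** (stacked on the phenyl) or
  **ContactUnstacked**. Ensemble fractions carry Wilson 95% intervals and
  free-vs-bound shifts get two-proportion z statistics.
* **Quencher occupancy maps.** Kabsch superposition on the fluorophore,
  voxel binning of quencher atoms, peak-normalised grids (OpenDX) with
  isovalue reports at 10% / 1% / 0.01% of the maximum.
* **Buried interfaces.** Shrake–Rupley SASA (Fibonacci lattice, probe
  1.4 Å, Bondi radii) and the buried-interface statistic
  `0.5 × (SASA_receptor + SASA_ligand − SASA_complex)` with relative
  interface and per-moiety burial — the numbers used to compare semi-open
  vs encapsulating aptamer binding pockets.
* **Synthetic ensembles with ground truth.** A geometry-only conjugate
  template (13-atom tricyclic core, hinged phenyl, tethered quencher ring)
  and a class-conditioned generator whose requested fractions are recovered
  exactly, so the whole pipeline is testable with no external data.

## Worked example

`examples/` contains one short script per capability. Classifying a
100-conformer synthetic ensemble generated at the free-probe composition
(`examples/01_classify_ensemble.py`):

```
class              count  fraction   Wilson 95% CI
StackX                28      0.28   [0.201, 0.375]
StackP                 2      0.02   [0.006, 0.070]
ContactUnstacked      58      0.58   [0.482, 0.672]
NonContact            12      0.12   [0.070, 0.198]
skipped (no quencher): 0
```

The requested fractions (0.28 / 0.02 / 0.58 / 0.12) are recovered exactly:
generation allocates class counts by largest-remainder rounding and the
classifier agrees with the generator's ground truth. Comparing against a
bound-state ensemble (`examples/02_free_vs_bound.py`):

```
class                free  bound   delta       z         p
StackX               0.28   0.01   -0.27   -5.42   5.9e-08
StackP               0.02   0.06   +0.04    1.44      0.15
ContactUnstacked     0.58   0.53   -0.05   -0.71      0.48
NonContact           0.12   0.40   +0.28    4.51   6.4e-06
```

The collapse of the xanthene-stacked class (|z| ≈ 5.4) with a matching
non-contact gain is the signature of quencher displacement on aptamer
binding. `examples/03_quencher_density.py` writes the occupancy grid and
`examples/04_buried_interface.py` prints a pocket-burial table
(e.g. a sandwiched ring 87.6% buried vs 47.2% for an exposed one).

The same analyses run from the shell via the thin `fq` CLI
(`fq synth | profile | classify | density | compare | interface`); pass
your own multi-model PDB plus a YAML moiety config mapping residue/atom
names to the xanthene, phenyl, quencher, linker, RNA and ion roles
(`fq synth --moieties-out moieties.yaml` writes the synthetic one as a
template).

See `docs/methods.md` for the model, parameter defaults and their
rationale, and what the synthetic generator does and does not emulate.

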