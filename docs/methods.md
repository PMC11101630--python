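# Methods

`fqens` analyses conformational ensembles of intramolecularly quenched
fluorophore probes — a fluorophore (e.g. tetramethylrhodamine, TMR, with its
tricyclic xanthene chromophore and pendant phenyl ring) tethered by a
flexible linker to a quencher ring (e.g. dinitroaniline, DN). Such probes
are dark while the quencher sits on the fluorophore (contact quenching) and
light up when an RNA aptamer binds the fluorophore and displaces the
quencher. The package quantifies that displacement in three ways: conformer
classification, quencher occupancy maps, and buried-interface areas of the
aptamer–ligand complex.

## Conformer descriptors

For each conformer the quencher is scored against the two fluorophore rings
separately:

* **Contact numbers.** `Q_xq` (`Q_pq`) counts quencher–xanthene
  (quencher–phenyl) heavy-atom pairs within a cutoff, and
  `Q_Tq = Q_xq + Q_pq` by construction. The cutoff defaults to **4.0 Å**,
  the conventional heavy-atom contact threshold; it is a plain parameter
  (`contact_cutoff`) so an alternative definition can be substituted. `Q` is
  a hard integer count, not a smooth switching function — the downstream
  contact/non-contact split (`Q_Tq ≥ 5`) presumes integer counts.
* **Ring geometry.** Each ring plane is a least-squares fit (centroid =
  mean position; normal = smallest principal direction of the centered
  coordinates; `planarity_rmsd` = RMS out-of-plane deviation). Derived pair
  descriptors are the centroid distances `d_xq`, `d_pq`, the interplanar
  angles `arccos|n̂_A·n̂_B| ∈ [0°, 90°]` (invariant to normal sign flips),
  and the lateral (slip) offsets — the centroid separation projected into
  the first ring's plane. All descriptors are invariant under global rigid
  transforms.

## Classification

Each complete conformer receives exactly one label:

1. `Q_Tq < 5` → **NonContact** (the `contact_cutoff_q` parameter).
2. Otherwise a π-stacking test is applied per ring: centroid distance
   ≤ 4.5 Å, interplanar angle ≤ 30°, slip offset ≤ 2.0 Å. Passing against
   xanthene → **StackX**, against phenyl → **StackP**; both → the ring with
   the smaller centroid distance (tie → StackX), with the conflict recorded
   in the label's rationale; neither → **ContactUnstacked**.

The stacking thresholds are conventional π–π geometry criteria. They are
deliberately exposed as `StackingCriteria` and echoed into every report, so
a different published stacking definition can be swapped in without code
changes. Relaxing all three thresholds can only promote conformers into the
stacked classes, never demote them (tested).

Ensemble summaries report per-class counts, fractions, and 95% Wilson score
intervals (statsmodels). Two ensembles (e.g. free vs aptamer-bound probe)
are compared class-by-class: fraction difference, a normal-approximation CI
on the difference, and a pooled two-proportion z statistic. With one class
at 28/100 vs 1/100 this yields Δ = −0.27 and |z| ≈ 5.4 — the scale of shift
expected when quencher–xanthene stacking collapses on aptamer binding.

Conformers whose quencher atoms are absent (e.g. disordered in a crystal
model) are skipped and tallied, never silently dropped: the per-run report
carries `n_skipped` and the model indices.

## Quencher spatial density

Conformers are rigidly superposed on a reference over the fluorophore heavy
atoms (Kabsch SVD superposition with a proper-rotation determinant guard;
collinear alignment sets are rejected). Quencher heavy atoms are then binned
into a cubic voxel grid — default spacing 0.5 Å, extent auto-fitted to the
quencher cloud plus a 2 Å margin — and the grid is normalised to its peak so
isosurface levels read as fractions of the maximum (defaults 0.10, 0.01 and
0.0001, i.e. 10%, 1% and 0.01% of the peak). Binning is one count per atom
per voxel (no Gaussian smearing): raw-count grids conserve
`n_models × n_quencher_atoms` up to the out-of-bounds tally, which makes the
bookkeeping exactly testable. A smearing kernel would only change rendering,
not the statistics, and is left to visualisation tools. Grids are written in
the OpenDX dialect (via GridDataFormats) for rendering in VMD/PyMOL.

## SASA and buried interface

SASA is Shrake–Rupley: each atom's sphere is expanded by the probe radius
(default **1.4 Å**), covered with a deterministic Fibonacci golden-angle
lattice of test points (no RNG), and the accessible fraction is the share of
points not inside any other expanded sphere of the scored subset. Only atoms
in the scored subset occlude, so isolated-component and in-complex SASA use
the same routine. The default of **960 points** gives < 1% single-sphere
error and ≈ 0.3% error against the two-sphere spherical-cap closed form;
point count is a parameter for convergence studies. Van der Waals radii
default to the Bondi table (shipped as `fqens/data/bondi_radii.json`,
overridable per call). Hydrogens are excluded from contact, SASA and density
sets by default — crystal structures typically lack them — and can be
included via `hydrogens_included`/`include_hydrogens`. Because the point
lattice is fixed in the lab frame, SASA is rotation-invariant only up to
quadrature error (≈ 1% at 960 points); tests budget 2% for this.

The buried interface of a complex is
`0.5 × (SASA_receptor + SASA_ligand − SASA_complex)`, with the relative
interface normalised by the ligand's isolated SASA. Ions flagged as channel
ions (e.g. K⁺ inside a G-quadruplex channel) are merged into the receptor
side; waters and other ions are excluded by default. Per-moiety burial
restricts the ligand-side SASA loss to one moiety's atoms:
`Δ = SASA(moiety | ligand alone) − SASA(moiety | complex)`, reported both as
a fraction of the moiety's own isolated SASA and of the whole ligand's —
the two denominators answer different questions ("how encapsulated is the
chromophore" vs "how much of the probe's surface does this moiety's burial
account for") and published percentages are ambiguous between them, so both
are always emitted.

## Synthetic ensembles

The generator builds a geometry-only conjugate mimic: a planar 13-atom
tricyclic patch (three fused hexagons of circumradius 1.40 Å with the meso
vertex — the phenyl attachment point in rhodamines — omitted), a phenyl
hexagon hinged below it at a settable dihedral (default 60°, matching the
inclined phenyl/xanthene orientation typical of rhodamine ligands), a
6-atom quencher hexagon and an 8-atom Bezier tether. All atoms are carbons;
the analysis consumes only coordinates and moiety identity, so no force
field or chemistry is modelled — which is exactly why passing tests
demonstrate the *analysis machinery*, not the realism of any MD ensemble.

`place_quencher` poses the quencher per class — stacked poses sample
centroid distance 3.3–4.2 Å, tilt ≤ 20°, slip ≤ 1.5 Å over the target ring;
contact-unstacked poses approach the xanthene rim edge-on at 5.2–6.8 Å;
non-contact poses sit 12–18 Å from both rings — then adds isotropic Gaussian
noise (default σ = 0.05 Å) to every atom and re-checks the class with the
actual classifier, resampling pose+noise up to 100 times. Two consequences
are intentional: requested ensembles are label-exact at any feasible noise
(classifier/ground-truth agreement is 100% by construction, so the
agreement criterion at σ = 0.15 Å holds trivially), and an infeasible
class/noise combination fails loudly rather than silently drifting. Class
counts are allocated by largest-remainder rounding of fractions × n, so
requested fractions like (0.28, 0.02, 0.58, 0.12) are recovered *exactly*
by the pipeline — fraction-recovery tests are equality tests, not
statistical ones. All randomness flows from a single seed; output is
bit-identical for identical seed + spec.

The shipped compositions `FREE_FRACTIONS` (28% StackX, 2% StackP, 58%
contact-unstacked, 12% non-contact) and `BOUND_FRACTIONS` (1%, 6%, 53%,
40%) emulate the free-probe and aptamer-bound regimes: a dominant
contact-unstacked population throughout, collapse of StackX and growth of
the non-contact class on binding. What the synthetic ensembles do **not**
emulate: Boltzmann-weighted conformational free energies, linker torsional
statistics, solvent effects, or RNA contacts — conclusions about real
probes require real ensembles (multi-model PDB in, same pipeline).

## Numerical and I/O choices

* Coordinates in Å, right-handed; models 0-indexed internally (PDB MODEL
  records are 1-based on disk).
* PDB read/write via gemmi. Alternate locations collapse to the
  highest-occupancy copy (tie → first listed). Models with differing atom
  counts are an error by default, naming the offending model indices.
* Ring-plane fits reject < 3 atoms or collinear sets (second singular value
  < 1e-8 relative). Kabsch rejects collinear alignment sets.
* Problem sizes in tests and the acceptance script: 100-conformer
  ensembles, 960-point SASA (48 000 points for the self-oracle), 30-atom
  random SASA fixtures, 50 random contact fixtures. These sizes give exact
  or sub-percent checks in seconds.

## Known limitations

* SASA orientation dependence at the quadrature level (see above); use more
  points where sub-percent orientation stability matters.
* The stacking thresholds are a convention; reported fractions depend on
  them. Every report echoes the thresholds used.
* The contact-unstacked generator poses only sample the xanthene rim, not
  the full contact manifold of a real linker.
* No SES/molecular-surface or volume computation; the interface statistic
  is SASA-based only.
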