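"""Quencher spatial-occupancy density after rigid superposition.

Each conformer is superposed onto a reference over the fluorophore heavy
atoms (Kabsch least-squares, proper rotation), quencher heavy atoms are
binned into a cubic voxel grid, and the grid is normalised to its maximum
so isovalues can be read as fractions of the peak density (e.g. 0.10, 0.01,
0.0001 of max).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import MolecularModel, MoietyMap

__all__ = [
    "DensityGrid",
    "kabsch",
    "superpose",
    "accumulate_density",
    "isosurface_report",
    "DEFAULT_GRID_SPACING",
    "DEFAULT_ISO_LEVELS",
]

DEFAULT_GRID_SPACING = 0.5  # A
DEFAULT_GRID_MARGIN = 2.0  # A padding around the quencher cloud
#: the printed figure levels 10%, 1% and 0.01% of the peak density
DEFAULT_ISO_LEVELS = (0.10, 0.01, 0.0001)


@dataclass
class DensityGrid:
    """Cubic-voxel occupancy grid.

    ``values[i, j, k]`` covers the voxel whose lower corner is
    ``origin + spacing * (i, j, k)``. ``normalization`` is ``raw_counts`` or
    ``fraction_of_max``.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    normalization: str = "raw_counts"
    n_binned: int = 0
    n_out_of_bounds: int = 0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3-D array")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("grid values must be non-negative")
        if self.normalization not in ("raw_counts", "fraction_of_max"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def normalized(self) -> "DensityGrid":
        """Copy rescaled so the maximum voxel equals 1."""
        peak = self.values.max()
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero grid")
        return DensityGrid(
            self.origin.copy(), self.spacing, self.values / peak,
            "fraction_of_max", self.n_binned, self.n_out_of_bounds,
        )


def kabsch(moving: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of point set *moving* onto *reference*.

    Returns ``(R, t, rmsd)`` with proper rotation R (det +1) such that
    ``moving @ R.T + t`` best fits *reference* in least squares.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape or moving.shape[0] < 3:
        raise ValueError("alignment sets must have equal size >= 3")
    cm, cr = moving.mean(axis=0), reference.mean(axis=0)
    a, b = moving - cm, reference - cr
    # degenerate (collinear) sets leave the rotation about the line free
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("alignment atoms are collinear; superposition is degenerate")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cr - r @ cm
    fitted = a @ r.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return r, t, rmsd


def superpose(
    model: MolecularModel,
    reference_model: MolecularModel,
    alignment_atoms: Iterable[int],
    reference_atoms: Iterable[int] | None = None,
) -> tuple[MolecularModel, float]:
    """Rigidly superpose *model* onto *reference_model* over the given atoms.

    The whole model is transformed; the returned RMSD is over the alignment
    atoms only.
    """
    idx = sorted(alignment_atoms)
    ref_idx = idx if reference_atoms is None else sorted(reference_atoms)
    r, t, rmsd = kabsch(model.coords[idx], reference_model.coords[ref_idx])
    return model.with_coords(model.coords @ r.T + t), rmsd


def accumulate_density(
    models: Sequence[MolecularModel],
    mmap: MoietyMap,
    reference: MolecularModel | None = None,
    spacing: float = DEFAULT_GRID_SPACING,
    margin: float = DEFAULT_GRID_MARGIN,
    origin: np.ndarray | None = None,
    dims: tuple[int, int, int] | None = None,
    normalize: bool = True,
) -> DensityGrid:
    """Occupancy grid of quencher heavy atoms across an aligned ensemble.

    Models are superposed on *reference* (default: the first model with a
    quencher) over the fluorophore heavy atoms; each quencher heavy atom is
    binned into the voxel containing it. With no explicit ``origin``/``dims``
    the grid extent is auto-fitted to the quencher cloud plus ``margin``.
    Atoms falling outside an explicit grid are tallied, not binned.
    """
    align = sorted(mmap.fluorophore)
    q_idx = sorted(mmap.quencher)
    if not align or not q_idx:
        raise ValueError("moiety map must resolve fluorophore and quencher atoms")
    usable = [m for m in models if len(m) > max(max(align), max(q_idx))]
    if not usable:
        raise ValueError("no models carry the quencher atoms")
    ref = reference if reference is not None else usable[0]

    clouds = []
    for m in usable:
        fitted, _ = superpose(m, ref, align)
        clouds.append(fitted.coords[q_idx])
    pts = np.concatenate(clouds, axis=0)

    if origin is None:
        lo = pts.min(axis=0) - margin
        origin = np.floor(lo / spacing) * spacing
    origin = np.asarray(origin, dtype=float)
    if dims is None:
        hi = pts.max(axis=0) + margin
        dims = tuple(int(np.ceil((h - o) / spacing)) + 1 for h, o in zip(hi, origin))

    ijk = np.floor((pts - origin) / spacing).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.array(dims)), axis=1)
    values = np.zeros(dims, dtype=float)
    np.add.at(values, tuple(ijk[inside].T), 1.0)
    grid = DensityGrid(
        origin, spacing, values, "raw_counts",
        n_binned=int(inside.sum()), n_out_of_bounds=int((~inside).sum()),
    )
    return grid.normalized() if normalize else grid


@dataclass
class IsoLevelReport:
    level: float
    n_voxels: int
    bbox_min: tuple[float, float, float] | None  # A, lower corner of box
    bbox_max: tuple[float, float, float] | None


def isosurface_report(
    grid: DensityGrid, levels: Iterable[float] = DEFAULT_ISO_LEVELS
) -> list[IsoLevelReport]:
    """Voxel counts and bounding boxes at each isovalue (fraction of max)."""
    if grid.normalization != "fraction_of_max":
        raise ValueError("isosurface_report requires a fraction_of_max grid")
    out = []
    for level in levels:
        if not (0.0 < level <= 1.0):
            raise ValueError(f"isovalue {level} outside (0, 1]")
        mask = grid.values >= level
        n = int(mask.sum())
        if n:
            ijk = np.argwhere(mask)
            lo = grid.origin + grid.spacing * ijk.min(axis=0)
            hi = grid.origin + grid.spacing * (ijk.max(axis=0) + 1)
            out.append(IsoLevelReport(level, n, tuple(lo), tuple(hi)))
        else:
            out.append(IsoLevelReport(level, 0, None, None))
    return out
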