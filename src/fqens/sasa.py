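"""Shrake-Rupley solvent-accessible surface area and buried interfaces.

SASA is evaluated by placing a deterministic Fibonacci lattice of test
points on each atom's solvent-expanded sphere (van der Waals radius plus the
probe radius, default 1.4 A) and scoring the fraction of points not occluded
by any other expanded sphere. Only atoms inside the scored subset occlude.

The buried interface between a receptor (RNA plus any channel ions) and a
ligand is

    interface = 0.5 * (SASA_receptor + SASA_ligand - SASA_complex)

with the relative interface normalised by the ligand's isolated SASA.
Per-moiety burial uses the ligand-side SASA loss of that moiety's atoms,
reported against both the moiety's own isolated SASA and the whole ligand's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .model import MolecularModel, MoietyMap

__all__ = [
    "SASAResult",
    "InterfaceResult",
    "MoietyBurial",
    "sphere_points",
    "compute_sasa",
    "buried_interface",
    "moiety_burial",
]

DEFAULT_PROBE_RADIUS = 1.4  # A, water probe
DEFAULT_N_POINTS = 960  # <1% single-sphere error; see docs/methods.md


def sphere_points(n: int) -> np.ndarray:
    """*n* quasi-uniform unit vectors from the Fibonacci (golden-angle) lattice.

    Deterministic: no random number generation is involved.
    """
    if n < 12:
        raise ValueError("need at least 12 sphere points")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class SASAResult:
    """Per-atom and total solvent-accessible area for one atom subset."""

    per_atom_area: dict[int, float]  # model atom index -> A^2
    probe_radius: float
    n_sphere_points: int
    total_area: float = field(init=False)

    def __post_init__(self):
        if any(a < 0 for a in self.per_atom_area.values()):
            raise ValueError("negative per-atom area")
        self.total_area = float(sum(self.per_atom_area.values()))


def _subset_indices(model: MolecularModel, atom_subset, include_hydrogens: bool) -> np.ndarray:
    if atom_subset is None:
        idx = np.arange(len(model))
    else:
        idx = np.asarray(sorted(atom_subset), dtype=int)
    if not include_hydrogens:
        idx = np.array([i for i in idx if not model.atoms[i].is_hydrogen], dtype=int)
    if idx.size == 0:
        raise ValueError("atom subset is empty after hydrogen filtering")
    return idx


def compute_sasa(
    model: MolecularModel,
    atom_subset: Iterable[int] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    radii: Mapping[str, float] | None = None,
    include_hydrogens: bool = False,
) -> SASAResult:
    """Shrake-Rupley SASA of ``atom_subset`` (default: all heavy atoms).

    Atoms outside the subset neither occlude nor are scored, so the same
    routine serves the isolated-component and in-complex evaluations of the
    interface formula.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    idx = _subset_indices(model, atom_subset, include_hydrogens)
    pos = model.coords[idx]
    expanded = np.array([model.atoms[i].radius(radii) for i in idx]) + probe_radius

    unit = sphere_points(n_sphere_points)
    tree = cKDTree(pos)
    r_max = expanded.max()
    per_atom: dict[int, float] = {}
    for k, (i, p, r) in enumerate(zip(idx, pos, expanded)):
        pts = p + r * unit
        neighbors = [j for j in tree.query_ball_point(p, r + r_max) if j != k]
        if neighbors:
            npos = pos[neighbors]
            nrad = expanded[neighbors]
            # keep only true overlaps
            d = np.linalg.norm(npos - p, axis=1)
            close = d < (r + nrad)
            npos, nrad = npos[close], nrad[close]
        if neighbors and len(npos):
            d2 = np.sum((pts[:, None, :] - npos[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nrad**2)[None, :], axis=1)
            n_acc = int(np.count_nonzero(~buried))
        else:
            n_acc = n_sphere_points
        per_atom[int(i)] = 4.0 * np.pi * r * r * n_acc / n_sphere_points
    return SASAResult(per_atom, probe_radius, n_sphere_points)


@dataclass
class InterfaceResult:
    """Buried-interface statistic of a receptor-ligand complex."""

    sasa_receptor: float
    sasa_ligand: float
    sasa_complex: float
    probe_radius: float
    n_sphere_points: int
    interface_area: float = field(init=False)
    relative_interface: float = field(init=False)

    def __post_init__(self):
        self.interface_area = 0.5 * (self.sasa_receptor + self.sasa_ligand - self.sasa_complex)
        self.relative_interface = (
            self.interface_area / self.sasa_ligand if self.sasa_ligand > 0 else 0.0
        )


def buried_interface(
    complex_model: MolecularModel,
    receptor: Iterable[int],
    ligand: Iterable[int],
    channel_ions: Iterable[int] = (),
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    radii: Mapping[str, float] | None = None,
    include_hydrogens: bool = False,
) -> InterfaceResult:
    """Interface = 0.5 * (SASA_receptor + SASA_ligand - SASA_complex).

    ``channel_ions`` (e.g. the K+ inside a G-quadruplex channel) are merged
    into the receptor side. The three SASA evaluations share identical probe,
    point-count and radii settings.
    """
    receptor = frozenset(receptor) | frozenset(channel_ions)
    ligand = frozenset(ligand)
    if not ligand:
        raise ValueError("ligand side is empty")
    if receptor & ligand:
        raise ValueError("receptor and ligand sides overlap")
    kw = dict(probe_radius=probe_radius, n_sphere_points=n_sphere_points,
              radii=radii, include_hydrogens=include_hydrogens)
    s_rec = compute_sasa(complex_model, receptor, **kw).total_area
    s_lig = compute_sasa(complex_model, ligand, **kw).total_area
    s_cpx = compute_sasa(complex_model, receptor | ligand, **kw).total_area
    return InterfaceResult(s_rec, s_lig, s_cpx, probe_radius, n_sphere_points)


@dataclass
class MoietyBurial:
    """Burial of one ligand moiety inside the complex.

    ``fraction`` divides the moiety's SASA loss by its own isolated-ligand
    SASA; ``fraction_of_ligand`` divides by the whole ligand's isolated SASA.
    """

    moiety: str
    sasa_isolated: float  # moiety atoms, ligand alone
    sasa_in_complex: float  # moiety atoms, full complex
    sasa_ligand_isolated: float
    buried_area: float = field(init=False)
    fraction: float = field(init=False)
    fraction_of_ligand: float = field(init=False)

    def __post_init__(self):
        self.buried_area = self.sasa_isolated - self.sasa_in_complex
        self.fraction = (
            self.buried_area / self.sasa_isolated if self.sasa_isolated > 0 else 0.0
        )
        self.fraction_of_ligand = (
            self.buried_area / self.sasa_ligand_isolated
            if self.sasa_ligand_isolated > 0
            else 0.0
        )


def moiety_burial(
    complex_model: MolecularModel,
    receptor: Iterable[int],
    ligand: Iterable[int],
    moiety_atoms: Iterable[int],
    moiety_name: str = "moiety",
    channel_ions: Iterable[int] = (),
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    radii: Mapping[str, float] | None = None,
    include_hydrogens: bool = False,
) -> MoietyBurial:
    """Burial fraction of one moiety of the ligand (e.g. the fluorophore).

    The moiety's per-atom SASA is summed in two contexts — the isolated
    ligand, and the full complex — and the loss is the buried area.
    """
    receptor = frozenset(receptor) | frozenset(channel_ions)
    ligand = frozenset(ligand)
    moiety = frozenset(moiety_atoms)
    if not moiety:
        raise ValueError(f"moiety {moiety_name!r} has no atoms")
    if not moiety <= ligand:
        raise ValueError(f"moiety {moiety_name!r} must be a subset of the ligand side")
    kw = dict(probe_radius=probe_radius, n_sphere_points=n_sphere_points,
              radii=radii, include_hydrogens=include_hydrogens)
    lig_alone = compute_sasa(complex_model, ligand, **kw)
    cpx = compute_sasa(complex_model, receptor | ligand, **kw)
    scored = set(lig_alone.per_atom_area)  # hydrogens may have been filtered
    m_scored = moiety & scored
    if not m_scored:
        raise ValueError(f"moiety {moiety_name!r} has no scored atoms")
    s_iso = sum(lig_alone.per_atom_area[i] for i in m_scored)
    s_cpx = sum(cpx.per_atom_area[i] for i in m_scored)
    return MoietyBurial(moiety_name, s_iso, s_cpx, lig_alone.total_area)


def interface_from_moiety_map(
    complex_model: MolecularModel,
    mmap: MoietyMap,
    **kwargs,
) -> InterfaceResult:
    """Convenience wrapper: receptor = RNA + ions, ligand = conjugate."""
    return buried_interface(
        complex_model,
        receptor=mmap.rna,
        ligand=mmap.ligand,
        channel_ions=mmap.ions,
        **kwargs,
    )
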