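"""Per-conformer geometric descriptors.

For each conformer of a fluorophore-quencher conjugate: least-squares ring
planes, centroid distances d_xq / d_pq between quencher and xanthene /
phenyl, interplanar angles, lateral (slip) offsets, and contact numbers
Q_xq / Q_pq with Q_Tq = Q_xq + Q_pq. A contact is a heavy-atom pair within
the cutoff (default 4.0 A). Linker atoms contribute to no contact count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .model import MolecularModel, MoietyMap

__all__ = [
    "RingPlane",
    "ContactProfile",
    "GeometryProfile",
    "ConformerProfile",
    "fit_ring_plane",
    "centroid_distance",
    "interplanar_angle",
    "lateral_offset",
    "contact_number",
    "contact_profile",
    "profile_conformer",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 4.0  # A, heavy-atom contact threshold
_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class RingPlane:
    """Least-squares plane through a ring's atoms.

    The normal's sign is arbitrary; every derived quantity is invariant
    under flipping it.
    """

    atom_indices: tuple[int, ...]
    centroid: np.ndarray
    unit_normal: np.ndarray
    planarity_rmsd: float


def fit_ring_plane(model: MolecularModel, atom_indices: Iterable[int]) -> RingPlane:
    """Fit centroid + least-squares normal to >= 3 non-collinear atoms.

    The normal is the principal direction of smallest variance of the
    centered coordinates; ``planarity_rmsd`` is the RMS out-of-plane
    deviation.
    """
    idx = tuple(sorted(atom_indices))
    if len(idx) < 3:
        raise ValueError(f"need >= 3 atoms to fit a plane, got {len(idx)}")
    coords = model.coords[list(idx)]
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # singular values sorted descending; smallest right-singular vector = normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < _COLLINEAR_TOL * max(s[0], 1.0):
        raise ValueError("atoms are collinear; ring plane is undefined")
    normal = vt[2]
    rmsd = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RingPlane(idx, centroid, normal / np.linalg.norm(normal), rmsd)


def centroid_distance(ring_a: RingPlane, ring_b: RingPlane) -> float:
    """Euclidean distance between two ring centroids (A)."""
    return float(np.linalg.norm(ring_a.centroid - ring_b.centroid))


def interplanar_angle(ring_a: RingPlane, ring_b: RingPlane) -> float:
    """Angle between ring planes, degrees in [0, 90] (normal-sign free)."""
    c = abs(float(np.dot(ring_a.unit_normal, ring_b.unit_normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def lateral_offset(ring_a: RingPlane, ring_b: RingPlane) -> float:
    """Slip of ring B's centroid: centroid separation projected into A's plane."""
    v = ring_b.centroid - ring_a.centroid
    in_plane = v - np.dot(v, ring_a.unit_normal) * ring_a.unit_normal
    return float(np.linalg.norm(in_plane))


def contact_number(
    model: MolecularModel,
    group_a: Iterable[int],
    group_b: Iterable[int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> int:
    """Number of atom pairs (a in A, b in B) with distance <= cutoff.

    Exact pairwise semantics; the groups must be disjoint and non-empty.
    """
    a = sorted(group_a)
    b = sorted(group_b)
    if not a or not b:
        raise ValueError("contact groups must be non-empty")
    if set(a) & set(b):
        raise ValueError("contact groups overlap")
    d = cdist(model.coords[a], model.coords[b])
    return int(np.count_nonzero(d <= cutoff))


@dataclass
class ContactProfile:
    """Contact counts of the quencher against the fluorophore rings."""

    q_xq: int
    q_pq: int
    per_atom_contacts: dict[int, int]
    cutoff: float
    q_tq: int = field(init=False)

    def __post_init__(self):
        self.q_tq = self.q_xq + self.q_pq


@dataclass
class GeometryProfile:
    """Centroid distances, interplanar angles and slip offsets (A / degrees)."""

    d_xq: float
    d_pq: float
    angle_xq: float
    angle_pq: float
    angle_xp: float
    offset_xq: float
    offset_pq: float


@dataclass
class ConformerProfile:
    """Joint contact + geometry descriptors of one conformer.

    ``complete`` is false when the quencher is absent (e.g. disordered in a
    crystal model); such profiles carry no contact/geometry payload and are
    skipped, not classified.
    """

    model_index: int
    complete: bool
    contacts: ContactProfile | None = None
    geometry: GeometryProfile | None = None


def contact_profile(
    model: MolecularModel,
    mmap: MoietyMap,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactProfile:
    """Q_xq, Q_pq (and the per-fluorophore-atom contact map) at *cutoff*."""
    q_atoms = sorted(mmap.quencher)
    per_atom: dict[int, int] = {}
    qc = model.coords[q_atoms]
    for part in ("xanthene", "phenyl"):
        for i in sorted(mmap[part]):
            d = np.linalg.norm(qc - model.coords[i], axis=1)
            per_atom[i] = int(np.count_nonzero(d <= cutoff))
    q_xq = sum(per_atom[i] for i in mmap.xanthene)
    q_pq = sum(per_atom[i] for i in mmap.phenyl)
    return ContactProfile(q_xq, q_pq, per_atom, cutoff)


def profile_conformer(
    model: MolecularModel,
    mmap: MoietyMap,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ConformerProfile:
    """Full descriptor set for one conformer.

    Requires resolved xanthene and phenyl sets; a missing quencher yields an
    incomplete profile rather than an error.
    """
    for role in ("xanthene", "phenyl"):
        if not mmap[role]:
            raise ValueError(f"moiety map lacks required role {role!r}")
    mmap.validate_for(model)
    if not mmap.quencher:
        return ConformerProfile(model.model_index, complete=False)

    ring_x = fit_ring_plane(model, mmap.xanthene)
    ring_p = fit_ring_plane(model, mmap.phenyl)
    ring_q = fit_ring_plane(model, mmap.quencher)
    geometry = GeometryProfile(
        d_xq=centroid_distance(ring_x, ring_q),
        d_pq=centroid_distance(ring_p, ring_q),
        angle_xq=interplanar_angle(ring_x, ring_q),
        angle_pq=interplanar_angle(ring_p, ring_q),
        angle_xp=interplanar_angle(ring_x, ring_p),
        offset_xq=lateral_offset(ring_x, ring_q),
        offset_pq=lateral_offset(ring_p, ring_q),
    )
    contacts = contact_profile(model, mmap, cutoff)
    return ConformerProfile(model.model_index, True, contacts, geometry)
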