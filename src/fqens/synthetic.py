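"""Synthetic fluorophore-quencher conjugates with known conformer classes.

The template is a geometry-only mimic of a rhodamine-quencher conjugate:
a planar tricyclic "xanthene" patch (three fused hexagons whose meso vertex
is omitted, 13 heavy atoms), a phenyl hexagon hinged below it at a settable
dihedral (default 60 degrees), a 6-atom quencher hexagon, and a smooth
8-atom linker chain. Atoms are generic carbons — the downstream analysis
consumes only coordinates and moiety identity, so no chemistry is modelled.

``place_quencher`` poses the quencher ring so a conformer belongs to a
requested class under the default classification settings, adds Gaussian
positional noise last, and rejection-resamples until the class still holds.
``generate_ensemble`` allocates class counts by largest-remainder rounding
so requested fractions are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .classify import (
    DEFAULT_CONTACT_CUTOFF_Q,
    Label,
    StackingCriteria,
    classify_conformer,
)
from .geometry import DEFAULT_CONTACT_CUTOFF, profile_conformer
from .io import resolve_moieties
from .model import Atom, MolecularModel, MoietyMap

__all__ = [
    "TemplateParams",
    "EnsembleSpec",
    "build_template",
    "default_moiety_config",
    "place_quencher",
    "generate_ensemble",
    "FREE_FRACTIONS",
    "BOUND_FRACTIONS",
]

RING_RADIUS = 1.40  # A, aromatic hexagon circumradius
_APOTHEM = RING_RADIUS * np.cos(np.pi / 6)

#: ensemble compositions used throughout the examples: a free conjugate with
#: a large xanthene-stacked population, and an RNA-bound one where the
#: xanthene-stacked class has almost vanished and non-contact dominates.
FREE_FRACTIONS = {
    Label.STACK_X: 0.28,
    Label.STACK_P: 0.02,
    Label.CONTACT_UNSTACKED: 0.58,
    Label.NON_CONTACT: 0.12,
}
BOUND_FRACTIONS = {
    Label.STACK_X: 0.01,
    Label.STACK_P: 0.06,
    Label.CONTACT_UNSTACKED: 0.53,
    Label.NON_CONTACT: 0.40,
}


@dataclass(frozen=True)
class TemplateParams:
    ring_radius: float = RING_RADIUS
    hinge_angle: float = 60.0  # degrees, phenyl vs xanthene plane
    n_linker: int = 8
    phenyl_gap: float = 1.5  # A between xanthene rim and phenyl centroid

    def __post_init__(self):
        if self.ring_radius <= 0 or self.phenyl_gap <= 0 or self.n_linker < 1:
            raise ValueError("non-physical template parameters")


def _hexagon(radius: float) -> np.ndarray:
    ang = np.radians(60.0 * np.arange(6) + 30.0)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _xanthene_core(radius: float) -> np.ndarray:
    """13 planar atoms: three linearly fused hexagons minus the meso vertex."""
    centers = np.array([[-2 * _APOTHEM / RING_RADIUS * radius, 0, 0],
                        [0, 0, 0],
                        [2 * _APOTHEM / RING_RADIUS * radius, 0, 0]])
    pts: list[np.ndarray] = []
    for c in centers:
        for v in _hexagon(radius) + c:
            if not any(np.linalg.norm(v - p) < 1e-6 for p in pts):
                pts.append(v)
    meso = np.array([0.0, -radius, 0.0])  # phenyl attachment vertex, omitted
    pts = [p for p in pts if np.linalg.norm(p - meso) > 1e-6]
    assert len(pts) == 13
    return np.array(pts)


def _linker_chain(start: np.ndarray, end: np.ndarray, n: int) -> np.ndarray:
    """Smooth quadratic-Bezier chain of *n* pseudo-atoms from start to end."""
    mid = 0.5 * (start + end)
    span = np.linalg.norm(end - start)
    # bow the chain out perpendicular to the span so it reads as a slack tether
    d = end - start
    perp = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(d, [0.0, 1.0, 0.0])
    perp = perp / max(np.linalg.norm(perp), 1e-12)
    ctrl = mid + perp * max(0.15 * span, 1.0)
    t = np.linspace(0.0, 1.0, n + 2)[1:-1, None]
    return ((1 - t) ** 2) * start + 2 * t * (1 - t) * ctrl + (t**2) * end


def _assemble(
    params: TemplateParams, quencher_centroid: np.ndarray, quencher_rot: np.ndarray
) -> MolecularModel:
    xan = _xanthene_core(params.ring_radius)
    # phenyl: hexagon tilted by the hinge angle about x, centred below the
    # omitted meso vertex
    r_hinge = _rotation_about([1.0, 0.0, 0.0], params.hinge_angle)
    phe_center = np.array([0.0, -params.ring_radius - params.phenyl_gap, 0.0])
    phe = _hexagon(params.ring_radius) @ r_hinge.T + phe_center
    qnc = _hexagon(params.ring_radius) @ quencher_rot.T + quencher_centroid
    # tether from the phenyl atom farthest from xanthene to the quencher
    phe_attach = phe[np.argmin(phe[:, 1])]
    lnk = _linker_chain(phe_attach, qnc[0], params.n_linker)

    atoms: list[Atom] = []
    serial = 1

    def add(coords: np.ndarray, resname: str, resid: int, prefix: str):
        nonlocal serial
        for k, p in enumerate(coords):
            atoms.append(Atom(serial, f"{prefix}{k + 1}", "C", resname, resid, "L", tuple(p)))
            serial += 1

    add(xan, "XAN", 1, "X")
    add(phe, "PHL", 2, "P")
    add(lnk, "LNK", 3, "L")
    add(qnc, "QNC", 4, "Q")
    return MolecularModel(0, atoms)


def default_moiety_config() -> dict:
    """Moiety config matching the synthetic template's residue naming."""
    return {
        "hydrogens_included": False,
        "roles": {
            "xanthene": [{"residue_name": "XAN"}],
            "phenyl": [{"residue_name": "PHL"}],
            "quencher": [{"residue_name": "QNC"}],
            "linker": [{"residue_name": "LNK"}],
        },
        "ligand_residues": ["XAN", "PHL", "LNK", "QNC"],
    }


def build_template(params: TemplateParams = TemplateParams()) -> tuple[MolecularModel, dict]:
    """Deterministic conjugate template plus its moiety config.

    The quencher starts in a detached pose 14 A from the xanthene centroid;
    ``place_quencher`` moves it into a class-defining pose.
    """
    model = _assemble(params, np.array([14.0, 0.0, 0.0]), np.eye(3))
    return model, default_moiety_config()


# ---------------------------------------------------------------------------
# class-conditioned placement

@dataclass(frozen=True)
class ClassGeometry:
    """Sampling ranges for the stacked poses (A / degrees)."""

    stack_distance: tuple[float, float] = (3.3, 4.2)
    stack_max_angle: float = 20.0
    stack_max_offset: float = 1.5
    unstacked_distance: tuple[float, float] = (5.2, 6.8)
    noncontact_distance: tuple[float, float] = (12.0, 18.0)


def _random_tilt(rng: np.random.Generator, max_angle: float, base_normal: np.ndarray) -> np.ndarray:
    """Rotation tilting *base_normal* by <= max_angle about a random axis."""
    ang = rng.uniform(0.0, max_angle)
    perp = np.cross(base_normal, rng.normal(size=3))
    while np.linalg.norm(perp) < 1e-8:
        perp = np.cross(base_normal, rng.normal(size=3))
    spin = _rotation_about(base_normal, rng.uniform(0.0, 360.0))
    return _rotation_about(perp, ang) @ spin


def _frame_rotation(normal: np.ndarray) -> np.ndarray:
    """Rotation taking z-hat to *normal* (for posing a flat ring)."""
    z = np.array([0.0, 0.0, 1.0])
    normal = normal / np.linalg.norm(normal)
    v = np.cross(z, normal)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if normal[2] > 0 else _rotation_about([1, 0, 0], 180.0)
    return _rotation_about(v, np.degrees(np.arctan2(s, np.dot(z, normal))))


def _propose_pose(
    label: Label,
    params: TemplateParams,
    geom: ClassGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Quencher centroid + ring orientation for one class attempt."""
    xan_centroid = _xanthene_core(params.ring_radius).mean(axis=0)
    xan_normal = np.array([0.0, 0.0, 1.0])
    r_hinge = _rotation_about([1.0, 0.0, 0.0], params.hinge_angle)
    phe_centroid = np.array([0.0, -params.ring_radius - params.phenyl_gap, 0.0])
    phe_normal = r_hinge @ np.array([0.0, 0.0, 1.0])

    if label in (Label.STACK_X, Label.STACK_P):
        base_c, base_n = (
            (xan_centroid, xan_normal) if label is Label.STACK_X else (phe_centroid, phe_normal)
        )
        side = rng.choice([-1.0, 1.0]) if label is Label.STACK_X else 1.0
        if label is Label.STACK_P:
            # stack on the phenyl face pointing away from the xanthene
            side = 1.0 if np.dot(base_n, phe_centroid - xan_centroid) > 0 else -1.0
        d = rng.uniform(*geom.stack_distance)
        # in-plane slip
        u = np.cross(base_n, rng.normal(size=3))
        u = u / np.linalg.norm(u)
        offset = rng.uniform(0.0, geom.stack_max_offset)
        centroid = base_c + side * d * base_n + offset * u
        rot = _random_tilt(rng, geom.stack_max_angle, base_n) @ _frame_rotation(side * base_n)
        return centroid, rot
    if label is Label.CONTACT_UNSTACKED:
        # approach the xanthene rim edge-on, away from the phenyl (-y) side
        phi = rng.uniform(-60.0, 240.0)
        u = np.array([np.cos(np.radians(phi)), np.sin(np.radians(phi)), 0.0])
        centroid = xan_centroid + rng.uniform(*geom.unstacked_distance) * u
        centroid[2] += rng.uniform(-1.0, 1.0)
        # ring roughly perpendicular to the xanthene plane
        normal = _rotation_about(u, rng.uniform(-20.0, 20.0)) @ np.cross(u, [0, 0, 1.0])
        rot = _rotation_about(normal, rng.uniform(0, 360.0)) @ _frame_rotation(normal)
        return centroid, rot
    if label is Label.NON_CONTACT:
        while True:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            centroid = xan_centroid + rng.uniform(*geom.noncontact_distance) * u
            if (
                np.linalg.norm(centroid - phe_centroid) >= geom.noncontact_distance[0]
                and np.linalg.norm(centroid - xan_centroid) >= geom.noncontact_distance[0]
            ):
                break
        rot = _random_tilt(rng, 90.0, np.array([0.0, 0.0, 1.0]))
        return centroid, rot
    raise ValueError(f"unknown class label {label!r}")


def place_quencher(
    label: Label | str,
    params: TemplateParams = TemplateParams(),
    geom: ClassGeometry = ClassGeometry(),
    noise_sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
    criteria: StackingCriteria = StackingCriteria(),
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    contact_cutoff_q: int = DEFAULT_CONTACT_CUTOFF_Q,
    max_tries: int = 100,
) -> MolecularModel:
    """One conformer of the requested class.

    Noise is applied to every atom after posing; pose and noise are
    resampled together until the classifier confirms the requested label
    (at most *max_tries* attempts).
    """
    label = Label(label)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    cfg = default_moiety_config()
    for _ in range(max_tries):
        centroid, rot = _propose_pose(label, params, geom, rng)
        model = _assemble(params, centroid, rot)
        if noise_sigma > 0:
            noisy = model.coords + rng.normal(scale=noise_sigma, size=(len(model), 3))
            model = model.with_coords(noisy)
        mmap = resolve_moieties(model, cfg)
        got = classify_conformer(
            profile_conformer(model, mmap, contact_cutoff), criteria, contact_cutoff_q
        )
        if got.label is label:
            return model
    raise RuntimeError(
        f"could not realise class {label.value} within {max_tries} attempts "
        f"(noise_sigma={noise_sigma})"
    )


# ---------------------------------------------------------------------------
# ensembles

@dataclass
class EnsembleSpec:
    """Recipe for a labelled synthetic ensemble."""

    n_models: int
    class_fractions: Mapping[Label, float] = field(default_factory=lambda: dict(FREE_FRACTIONS))
    noise_sigma: float = 0.05  # A
    seed: int = 0
    template: TemplateParams = TemplateParams()
    geometry: ClassGeometry = ClassGeometry()

    def __post_init__(self):
        self.class_fractions = {Label(k): float(v) for k, v in self.class_fractions.items()}
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")


def allocate_counts(fractions: Mapping[Label, float], n: int) -> dict[Label, int]:
    """Largest-remainder (Hamilton) apportionment of *n* among the classes."""
    quotas = {k: f * n for k, f in fractions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda k: (quotas[k] - counts[k]), reverse=True)
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def generate_ensemble(spec: EnsembleSpec) -> tuple[list[MolecularModel], list[Label], dict]:
    """Labelled ensemble: models, ground-truth labels, moiety config.

    Counts per class follow largest-remainder rounding of fractions x n, so
    the requested fractions are recovered exactly by downstream tallies. All
    randomness (pose order, poses, noise) derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = allocate_counts(spec.class_fractions, spec.n_models)
    labels: list[Label] = [lbl for lbl, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)  # type: ignore[arg-type]
    models = []
    for i, lbl in enumerate(labels):
        m = place_quencher(
            lbl, spec.template, spec.geometry, noise_sigma=spec.noise_sigma, rng=rng
        )
        models.append(m.with_coords(m.coords, model_index=i))
    return models, labels, default_moiety_config()
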