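"""Core in-memory containers: atoms, conformer models, and moiety maps.

Coordinates are Cartesian, in Angstrom, right-handed. Models are 0-indexed
internally even where a source format (PDB MODEL records) counts from 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Atom",
    "MolecularModel",
    "MoietyMap",
    "MOIETY_ROLES",
    "REQUIRED_ROLES",
    "bondi_radii",
    "vdw_radius",
]

#: Roles a moiety map resolves. ``xanthene`` | ``phenyl`` form the fluorophore.
MOIETY_ROLES = ("xanthene", "phenyl", "quencher", "linker", "rna", "ions")
#: Roles that must match at least one atom for a conformer to be analysable.
REQUIRED_ROLES = ("xanthene", "phenyl", "quencher")


def bondi_radii() -> dict[str, float]:
    """Return the shipped Bondi van der Waals radii table (element -> A)."""
    text = resources.files("fqens.data").joinpath("bondi_radii.json").read_text()
    return {k.upper(): float(v) for k, v in json.loads(text)["radii"].items()}


_DEFAULT_RADII = bondi_radii()


def vdw_radius(element: str, radii: Mapping[str, float] | None = None) -> float:
    """Van der Waals radius for *element*; raises ``KeyError`` if unknown."""
    table = radii if radii is not None else _DEFAULT_RADII
    key = element.strip().upper()
    if key not in table:
        raise KeyError(f"no van der Waals radius for element {element!r}")
    r = float(table[key])
    if r <= 0:
        raise ValueError(f"non-positive radius {r} for element {element!r}")
    return r


@dataclass(frozen=True)
class Atom:
    """One atom of a conformer.

    ``position`` is a length-3 tuple in Angstrom; ``vdw_radius`` is assigned
    from the radii table at construction when not given explicitly.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: tuple[float, float, float]
    vdw_radius: float | None = None

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name!r} (serial {self.serial}): bad position {self.position}")
        object.__setattr__(self, "position", tuple(float(x) for x in pos))

    @property
    def is_hydrogen(self) -> bool:
        return self.element.strip().upper() in ("H", "D")

    def radius(self, radii: Mapping[str, float] | None = None) -> float:
        if self.vdw_radius is not None:
            return self.vdw_radius
        try:
            return vdw_radius(self.element, radii)
        except KeyError as exc:
            raise KeyError(
                f"atom {self.name!r} (serial {self.serial}, residue "
                f"{self.residue_name} {self.residue_id}): {exc.args[0]}"
            ) from None


class MolecularModel:
    """One conformer: an ordered list of atoms with cached coordinate array."""

    def __init__(self, model_index: int, atoms: Iterable[Atom]):
        self.model_index = int(model_index)
        self.atoms: list[Atom] = list(atoms)
        if self.model_index < 0:
            raise ValueError("model_index must be >= 0")
        if not self.atoms:
            raise ValueError(f"model {model_index}: a model needs at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError(f"model {model_index}: duplicate atom serials")
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"MolecularModel(index={self.model_index}, n_atoms={len(self)})"

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array, Angstrom. Cached; treat as read-only."""
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
        return self._coords

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int)

    def with_coords(self, coords: np.ndarray, model_index: int | None = None) -> "MolecularModel":
        """Copy of the model with replaced coordinates (same atom metadata)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        idx = self.model_index if model_index is None else model_index
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.residue_id,
                 a.chain_id, tuple(c), a.vdw_radius)
            for a, c in zip(self.atoms, coords)
        ]
        return MolecularModel(idx, atoms)

    def radii(self, table: Mapping[str, float] | None = None) -> np.ndarray:
        return np.array([a.radius(table) for a in self.atoms], dtype=float)


@dataclass
class MoietyMap:
    """Resolved atom-index sets for the analysis roles.

    Role sets are pairwise disjoint; ``fluorophore`` is the union of the
    xanthene and phenyl sets. Hydrogens are excluded from every set unless
    ``hydrogens_included`` is true.
    """

    roles: dict[str, frozenset[int]] = field(default_factory=dict)
    hydrogens_included: bool = False

    def __post_init__(self):
        seen: dict[int, str] = {}
        for role, idx in self.roles.items():
            if role not in MOIETY_ROLES:
                raise ValueError(f"unknown moiety role {role!r}")
            for i in idx:
                if i in seen:
                    raise ValueError(
                        f"atom index {i} assigned to both {seen[i]!r} and {role!r}"
                    )
                seen[i] = role

    def __getitem__(self, role: str) -> frozenset[int]:
        return self.roles.get(role, frozenset())

    @property
    def xanthene(self) -> frozenset[int]:
        return self["xanthene"]

    @property
    def phenyl(self) -> frozenset[int]:
        return self["phenyl"]

    @property
    def quencher(self) -> frozenset[int]:
        return self["quencher"]

    @property
    def linker(self) -> frozenset[int]:
        return self["linker"]

    @property
    def rna(self) -> frozenset[int]:
        return self["rna"]

    @property
    def ions(self) -> frozenset[int]:
        return self["ions"]

    @property
    def fluorophore(self) -> frozenset[int]:
        return self.xanthene | self.phenyl

    @property
    def ligand(self) -> frozenset[int]:
        """All conjugate atoms: fluorophore + quencher + linker."""
        return self.fluorophore | self.quencher | self.linker

    def validate_for(self, model: MolecularModel) -> None:
        n = len(model)
        for role, idx in self.roles.items():
            bad = [i for i in idx if i < 0 or i >= n]
            if bad:
                raise IndexError(f"role {role!r}: atom indices {bad} outside model of {n} atoms")
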