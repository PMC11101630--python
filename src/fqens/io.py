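"""Structure and grid I/O plus moiety-definition resolution.

Reads multi-model PDB (via gemmi) and plain multi-frame XYZ; writes
multi-model PDB; reads/writes volumetric occupancy grids in the OpenDX
dialect (via GridDataFormats). A moiety config (YAML) names which atoms
belong to the xanthene, phenyl, quencher, linker, RNA and ion roles and is
resolved here into a :class:`~fqens.model.MoietyMap`.
"""

from __future__ import annotations

import os
from typing import Any, Mapping, Sequence

import gemmi
import numpy as np
import yaml
from gridData import Grid as _DXGrid

from .model import Atom, MolecularModel, MoietyMap, MOIETY_ROLES, REQUIRED_ROLES

__all__ = [
    "read_models",
    "write_models",
    "load_moiety_config",
    "resolve_moieties",
    "read_grid",
    "write_grid",
]


# ---------------------------------------------------------------------------
# structures

def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".pdb", ".ent"):
        return "pdb"
    if ext == ".xyz":
        return "xyz"
    raise ValueError(f"cannot infer structure format from {path!r}; pass format=")


def _atoms_from_gemmi_model(gm: gemmi.Model, model_index: int) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in gm:
        for res in chain:
            # altloc policy: keep the highest-occupancy alternate; on a tie
            # keep the one listed first.
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                if at.name not in best:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > best[at.name].occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_id=res.seqid.num,
                        chain_id=chain.name,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                    )
                )
    return atoms


def _read_pdb(path: str) -> list[MolecularModel]:
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: unparsable PDB record: {exc}") from exc
    atom_lists = [_atoms_from_gemmi_model(gm, i) for i, gm in enumerate(st)]
    if not any(atom_lists):
        raise ValueError(f"{path}: file contains zero models")
    n0 = len(atom_lists[0])
    bad = [i for i, atoms in enumerate(atom_lists) if len(atoms) != n0]
    if bad:
        raise ValueError(
            f"{path}: models {bad} have atom counts differing from model 0 ({n0} atoms)"
        )
    return [MolecularModel(i, atoms) for i, atoms in enumerate(atom_lists)]


def _read_xyz(path: str) -> list[MolecularModel]:
    models: list[MolecularModel] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ValueError(f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}")
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: line {i + 1}: frame truncated ({len(block)}/{n} atoms)")
        atoms = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {i + 3 + j}: bad XYZ atom record {ln!r}")
            el = parts[0]
            atoms.append(
                Atom(
                    serial=j + 1,
                    name=f"{el}{j + 1}",
                    element=el,
                    residue_name="LIG",
                    residue_id=1,
                    chain_id="A",
                    position=tuple(float(x) for x in parts[1:4]),
                )
            )
        models.append(MolecularModel(len(models), atoms))
        i += 2 + n
    if not models:
        raise ValueError(f"{path}: file contains zero frames")
    n0 = len(models[0])
    bad = [m.model_index for m in models if len(m) != n0]
    if bad:
        raise ValueError(f"{path}: frames {bad} differ in atom count from frame 0 ({n0})")
    return models


def read_models(path: str | os.PathLike, format: str | None = None) -> list[MolecularModel]:
    """Read all conformers from *path*.

    Supported formats: multi-model or single-model PDB (``"pdb"``) and
    multi-frame XYZ (``"xyz"``). One :class:`MolecularModel` is returned per
    MODEL/ENDMDL block or XYZ frame, 0-indexed in file order. Alternate
    locations are collapsed to the highest-occupancy copy.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = (format or _detect_format(path)).lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported structure format {format!r}")


def write_models(models: Sequence[MolecularModel], path: str | os.PathLike) -> None:
    """Write conformers as a (multi-model) PDB file."""
    if not models:
        raise ValueError("no models to write")
    st = gemmi.Structure()
    for k, model in enumerate(models):
        # gemmi's add_* methods copy their argument, so build bottom-up:
        # atoms into residues, residues into chains, chains into the model.
        gm = gemmi.Model(k + 1)  # PDB MODEL records count from 1
        groups: list[tuple[tuple[str, str, int], list]] = []
        for a in model.atoms:
            key = (a.chain_id, a.residue_name, a.residue_id)
            if not groups or groups[-1][0] != key:
                groups.append((key, []))
            groups[-1][1].append(a)
        chain_order: list[str] = []
        chain_groups: dict[str, list] = {}
        for key, atoms in groups:
            if key[0] not in chain_groups:
                chain_groups[key[0]] = []
                chain_order.append(key[0])
            chain_groups[key[0]].append((key, atoms))
        for cname in chain_order:
            ch = gemmi.Chain(cname)
            for (_, resname, resid), atoms in chain_groups[cname]:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resid, " ")
                res.het_flag = "H"
                for a in atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.position)
                    ga.serial = a.serial
                    ga.occ = 1.0
                    res.add_atom(ga)
                ch.add_residue(res)
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(os.fspath(path))


# ---------------------------------------------------------------------------
# moiety configuration

def load_moiety_config(path: str | os.PathLike) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "roles" not in cfg:
        raise ValueError(f"{path}: moiety config must be a mapping with a 'roles' key")
    return dict(cfg)


def _rule_matches(rule: Mapping[str, Any], atom: Atom) -> bool:
    if "residue_name" in rule and atom.residue_name != rule["residue_name"]:
        return False
    if "chain_id" in rule and atom.chain_id != rule["chain_id"]:
        return False
    if "residue_id" in rule and atom.residue_id != rule["residue_id"]:
        return False
    if "atom_names" in rule and atom.name not in rule["atom_names"]:
        return False
    return True


def resolve_moieties(
    model: MolecularModel,
    moiety_config: Mapping[str, Any],
    required: Sequence[str] = REQUIRED_ROLES,
) -> MoietyMap:
    """Resolve a moiety config into disjoint atom-index sets for *model*.

    Each role maps to a list of selection rules (``residue_name`` plus
    optional ``atom_names``/``chain_id``/``residue_id``); an atom matching any
    rule joins the role. Hydrogens are dropped unless
    ``hydrogens_included: true``. Ligand-residue atoms matched by no rule fall
    into the linker set. An atom claimed by two roles, or a *required* role
    (default xanthene/phenyl/quencher) matching nothing, is an error; pass a
    reduced ``required`` tuple to tolerate e.g. a disordered quencher.
    """
    roles_cfg = moiety_config.get("roles", {})
    unknown = set(roles_cfg) - set(MOIETY_ROLES)
    if unknown:
        raise ValueError(f"unknown moiety roles in config: {sorted(unknown)}")
    hydrogens_included = bool(moiety_config.get("hydrogens_included", False))

    assigned: dict[int, str] = {}
    sets: dict[str, set[int]] = {r: set() for r in roles_cfg}
    for i, atom in enumerate(model.atoms):
        if atom.is_hydrogen and not hydrogens_included:
            continue
        for role, rules in roles_cfg.items():
            if any(_rule_matches(rule, atom) for rule in rules or []):
                if i in assigned and assigned[i] != role:
                    raise ValueError(
                        f"atom {atom.name!r} (serial {atom.serial}, residue "
                        f"{atom.residue_name} {atom.residue_id}) matched by both "
                        f"{assigned[i]!r} and {role!r} rules"
                    )
                assigned[i] = role
                sets[role].add(i)

    # unmatched atoms of the conjugate's residues default to the linker
    ligand_residues = set(
        moiety_config.get("ligand_residues")
        or [
            rule["residue_name"]
            for role in ("xanthene", "phenyl", "quencher", "linker")
            for rule in roles_cfg.get(role) or []
            if "residue_name" in rule
        ]
    )
    sets.setdefault("linker", set())
    for i, atom in enumerate(model.atoms):
        if i in assigned:
            continue
        if atom.is_hydrogen and not hydrogens_included:
            continue
        if atom.residue_name in ligand_residues:
            sets["linker"].add(i)

    for role in required:
        if not sets.get(role):
            raise ValueError(f"required moiety {role!r} matched zero atoms")

    return MoietyMap(
        roles={r: frozenset(s) for r, s in sets.items() if s},
        hydrogens_included=hydrogens_included,
    )


# ---------------------------------------------------------------------------
# volumetric grids (OpenDX dialect)

def write_grid(grid, path: str | os.PathLike) -> None:
    """Write a :class:`~fqens.density.DensityGrid` as an OpenDX file.

    Header records origin and axis deltas; data are stored in the DX-standard
    x-fastest-varying order. Round-trips through :func:`read_grid` to 1e-6
    relative.
    """
    values = np.asarray(grid.values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot write an empty grid")
    g = _DXGrid(values, origin=np.asarray(grid.origin, dtype=float),
                delta=float(grid.spacing))
    g.export(os.fspath(path), file_format="dx")


def read_grid(path: str | os.PathLike):
    """Read an OpenDX file back into a :class:`~fqens.density.DensityGrid`."""
    from .density import DensityGrid  # local import avoids a cycle

    g = _DXGrid(os.fspath(path))
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise ValueError(f"{path}: anisotropic grid spacing {delta} not supported")
    values = np.asarray(g.grid, dtype=float)
    norm = "fraction_of_max" if values.size and np.isclose(values.max(), 1.0) else "raw_counts"
    return DensityGrid(
        origin=np.asarray(g.origin, dtype=float),
        spacing=float(delta[0]),
        values=values,
        normalization=norm,
    )
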