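import numpy as np
import pytest

from fqens.model import Atom, MolecularModel
from fqens.io import resolve_moieties
from fqens.synthetic import (
    EnsembleSpec,
    FREE_FRACTIONS,
    build_template,
    generate_ensemble,
)


def make_model(coords, element="C", resname="LIG", chain="A"):
    """Bare model from an (n, 3) coordinate array of like atoms."""
    coords = np.asarray(coords, dtype=float)
    atoms = [
        Atom(i + 1, f"{element}{i + 1}", element, resname, 1, chain, tuple(p))
        for i, p in enumerate(coords)
    ]
    return MolecularModel(0, atoms)


def hexagon(radius=1.4, z=0.0):
    ang = np.radians(60.0 * np.arange(6))
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.full(6, z)])


@pytest.fixture(scope="session")
def template():
    model, config = build_template()
    return model, config


@pytest.fixture(scope="session")
def template_map(template):
    model, config = template
    return resolve_moieties(model, config)


@pytest.fixture(scope="session")
def free_ensemble():
    """100 conformers at the free-conjugate composition, light noise."""
    spec = EnsembleSpec(100, FREE_FRACTIONS, noise_sigma=0.05, seed=7)
    return generate_ensemble(spec)


@pytest.fixture(scope="session")
def noiseless_ensemble():
    spec = EnsembleSpec(100, FREE_FRACTIONS, noise_sigma=0.0, seed=7)
    return generate_ensemble(spec)
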