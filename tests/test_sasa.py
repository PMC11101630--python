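import numpy as np
import pytest

from fqens.model import Atom, MolecularModel
from fqens.sasa import (
    MoietyBurial,
    buried_interface,
    compute_sasa,
    moiety_burial,
    sphere_points,
)

from conftest import make_model
from _oracles import random_rigid_transform, sphere_cap_sasa_two_atoms

R_C = 1.70  # Bondi carbon
PROBE = 1.4
R_EXP = R_C + PROBE  # 3.10 A expanded radius


class TestSpherePoints:
    def test_unit_and_deterministic(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, sphere_points(960))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sphere_points(4)


class TestComputeSasa:
    def test_isolated_sphere_closed_form(self):
        res = compute_sasa(make_model([[0, 0, 0]]))
        assert res.total_area == pytest.approx(4 * np.pi * R_EXP**2, rel=1e-6)

    def test_no_occlusion_at_distance(self):
        res = compute_sasa(make_model([[0, 0, 0], [20.0, 0, 0]]))
        assert res.total_area == pytest.approx(2 * 4 * np.pi * R_EXP**2, rel=1e-6)

    def test_two_sphere_overlap_matches_cap_formula(self):
        d = 3.10
        res = compute_sasa(make_model([[0, 0, 0], [d, 0, 0]]))
        exact = sphere_cap_sasa_two_atoms(R_EXP, d)
        for area in res.per_atom_area.values():
            assert area == pytest.approx(exact, rel=0.02)

    def test_convergence_with_point_count(self):
        """Single-sphere error shrinks with n and is <1% at 960 points."""
        # one occluding neighbor so the estimate is non-trivial
        model = make_model([[0, 0, 0], [3.0, 0, 0]])
        exact = sphere_cap_sasa_two_atoms(R_EXP, 3.0)
        errs = []
        for n in (96, 960):
            got = compute_sasa(model, n_sphere_points=n).per_atom_area[0]
            errs.append(abs(got - exact) / exact)
        assert errs[1] <= errs[0]
        assert errs[1] < 0.01

    def test_adding_occluder_never_increases_sasa(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-4, 4, size=(12, 3))
        base = compute_sasa(make_model(coords))
        grown = compute_sasa(make_model(np.vstack([coords, [[0.5, 0.5, 0.5]]])))
        for i in range(12):
            assert grown.per_atom_area[i] <= base.per_atom_area[i] + 1e-9

    def test_per_atom_sums_to_total(self):
        rng = np.random.default_rng(5)
        res = compute_sasa(make_model(rng.uniform(-5, 5, size=(20, 3))))
        assert res.total_area == pytest.approx(sum(res.per_atom_area.values()), rel=1e-9)

    def test_unknown_element_names_atom(self):
        model = MolecularModel(0, [Atom(1, "XX1", "Xx", "LIG", 1, "A", (0, 0, 0))])
        with pytest.raises(KeyError, match="XX1"):
            compute_sasa(model)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            compute_sasa(make_model([[0, 0, 0]]), atom_subset=[])

    def test_matches_independent_library_oracle(self):
        """Random 30-atom cluster vs biotite's Shrake-Rupley within 2%."""
        biotite_structure = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(30)
        coords = rng.uniform(-6, 6, size=(30, 3))
        ours = compute_sasa(make_model(coords), n_sphere_points=960)

        arr = biotite_structure.AtomArray(30)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 30)
        arr.res_name = np.array(["LIG"] * 30)
        arr.atom_name = np.array([f"C{i}" for i in range(30)])
        ref = biotite_structure.sasa(
            arr, probe_radius=PROBE, point_number=1000,
            vdw_radii=np.full(30, R_C),
        )
        assert ours.total_area == pytest.approx(float(ref.sum()), rel=0.02)

    def test_agreement_with_high_resolution_self_quadrature(self):
        """960-point run within 2% of the same algorithm at 50x points."""
        rng = np.random.default_rng(77)
        coords = rng.uniform(-6, 6, size=(30, 3))
        model = make_model(coords)
        lo = compute_sasa(model, n_sphere_points=960)
        hi = compute_sasa(model, n_sphere_points=48000)
        assert lo.total_area == pytest.approx(hi.total_area, rel=0.02)


class TestBuriedInterface:
    def test_separated_bodies_have_zero_interface(self):
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [30.0, 0, 0]])
        res = buried_interface(make_model(coords), receptor=[0, 1], ligand=[2])
        assert res.interface_area == pytest.approx(0.0, abs=1e-6)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        coords = np.vstack([rng.uniform(-3, 3, (6, 3)), rng.uniform(-3, 3, (4, 3)) + 4.0])
        m = make_model(coords)
        ab = buried_interface(m, receptor=range(6), ligand=range(6, 10))
        ba = buried_interface(m, receptor=range(6, 10), ligand=range(6))
        assert ab.interface_area == pytest.approx(ba.interface_area, rel=1e-9)
        assert ab.relative_interface != pytest.approx(ba.relative_interface)

    def test_two_body_contact_matches_cap_oracle(self):
        """1-atom receptor + 1-atom ligand: interface = cap overlap / 2 each side."""
        d = 3.10
        m = make_model([[0, 0, 0], [d, 0, 0]])
        res = buried_interface(m, receptor=[0], ligand=[1])
        full = 4 * np.pi * R_EXP**2
        cap_loss = full - sphere_cap_sasa_two_atoms(R_EXP, d)
        assert res.interface_area == pytest.approx(cap_loss, rel=0.02)

    def test_invariant_under_rigid_transform_to_quadrature_error(self):
        """The lab-frame point lattice makes SASA rotation-invariant only to
        the quadrature error of 960 points (<2% on the interface)."""
        rng = np.random.default_rng(9)
        coords = np.vstack([rng.uniform(-3, 3, (8, 3)), rng.uniform(-3, 3, (5, 3)) + 3.5])
        base = buried_interface(make_model(coords), receptor=range(8), ligand=range(8, 13))
        q, t = random_rigid_transform(rng)
        moved = buried_interface(
            make_model(coords @ q.T + t), receptor=range(8), ligand=range(8, 13)
        )
        assert moved.interface_area == pytest.approx(base.interface_area, rel=0.02)

    def test_channel_ions_join_receptor(self):
        coords = np.array([[0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        m = make_model(coords)
        merged = buried_interface(m, receptor=[0], ligand=[2], channel_ions=[1])
        explicit = buried_interface(m, receptor=[0, 1], ligand=[2])
        assert merged.interface_area == pytest.approx(explicit.interface_area, rel=1e-12)

    def test_empty_ligand_rejected(self):
        with pytest.raises(ValueError):
            buried_interface(make_model([[0, 0, 0]]), receptor=[0], ligand=[])


class TestMoietyBurial:
    def _wall_fixture(self):
        """Ligand dimer half-covered by a 3x3 receptor wall."""
        lig = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        xs, ys = np.meshgrid([-2.0, 0.0, 2.0], [-2.0, 0.0, 2.0])
        wall = np.column_stack([xs.ravel() + 0.75, ys.ravel(), np.full(9, 3.3)])
        return make_model(np.vstack([lig, wall]))

    def test_isolated_ligand_has_zero_burial(self):
        m = make_model([[0, 0, 0], [1.5, 0, 0], [40.0, 0, 0]])
        mb = moiety_burial(m, receptor=[2], ligand=[0, 1], moiety_atoms=[0])
        assert mb.fraction == pytest.approx(0.0, abs=1e-9)

    def test_enclosing_cage_approaches_full_burial(self):
        from fqens.sasa import sphere_points as sp

        lig = np.array([[0.0, 0.0, 0.0]])
        cage = 4.0 * sp(80)  # dense shell around the single-atom ligand
        m = make_model(np.vstack([lig, cage]))
        mb = moiety_burial(m, receptor=range(1, 81), ligand=[0], moiety_atoms=[0])
        assert mb.fraction > 0.95

    def test_half_covered_matches_high_resolution_oracle(self):
        m = self._wall_fixture()
        mb = moiety_burial(m, receptor=range(2, 11), ligand=[0, 1], moiety_atoms=[0])
        hi = moiety_burial(m, receptor=range(2, 11), ligand=[0, 1], moiety_atoms=[0],
                           n_sphere_points=10000)
        assert 0.0 < mb.fraction < 1.0
        assert mb.fraction == pytest.approx(hi.fraction, rel=0.02)
        assert isinstance(mb, MoietyBurial)
        assert mb.fraction_of_ligand < mb.fraction  # whole-ligand denominator is larger

    def test_empty_moiety_rejected(self):
        m = make_model([[0, 0, 0], [5.0, 0, 0]])
        with pytest.raises(ValueError):
            moiety_burial(m, receptor=[0], ligand=[1], moiety_atoms=[])
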