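import numpy as np
import pytest

from fqens.geometry import (
    centroid_distance,
    contact_number,
    fit_ring_plane,
    interplanar_angle,
    lateral_offset,
    profile_conformer,
)
from fqens.io import resolve_moieties

from conftest import hexagon, make_model
from _oracles import (
    brute_force_contacts,
    lateral_offset_by_projection_matrix,
    plane_rmsd_by_eigendecomposition,
    random_rigid_transform,
)


class TestRingPlane:
    def test_flat_hexagon(self):
        ring = fit_ring_plane(make_model(hexagon()), range(6))
        assert np.allclose(ring.centroid, 0.0, atol=1e-12)
        assert abs(ring.unit_normal[2]) == pytest.approx(1.0)
        assert ring.planarity_rmsd == pytest.approx(0.0, abs=1e-12)

    def test_normal_equivariance_under_rotation(self):
        rng = np.random.default_rng(4)
        q, t = random_rigid_transform(rng)
        ring = fit_ring_plane(make_model(hexagon() @ q.T + t), range(6))
        expected = q @ np.array([0.0, 0.0, 1.0])
        assert min(np.linalg.norm(ring.unit_normal - expected),
                   np.linalg.norm(ring.unit_normal + expected)) < 1e-9

    def test_noisy_rmsd_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        coords = hexagon()
        coords[:, 2] += rng.uniform(-0.1, 0.1, size=6)
        ring = fit_ring_plane(make_model(coords), range(6))
        assert ring.planarity_rmsd == pytest.approx(
            plane_rmsd_by_eigendecomposition(coords), abs=1e-12
        )

    @pytest.mark.parametrize("coords", [
        [[0, 0, 0], [1, 0, 0]],                      # too few
        [[0, 0, 0], [1, 0, 0], [2, 0, 0]],           # collinear
    ])
    def test_degenerate_sets_rejected(self, coords):
        with pytest.raises(ValueError):
            fit_ring_plane(make_model(coords), range(len(coords)))


class TestPairDescriptors:
    def test_centroid_distance_translation(self):
        a = fit_ring_plane(make_model(hexagon()), range(6))
        b = fit_ring_plane(make_model(hexagon() + [0, 0, 3.4]), range(6))
        assert centroid_distance(a, a) == pytest.approx(0.0)
        assert centroid_distance(a, b) == pytest.approx(3.4)

    @pytest.mark.parametrize("tilt,expected", [(0.0, 0.0), (90.0, 90.0), (60.0, 60.0),
                                               (120.0, 60.0)])
    def test_interplanar_angle_closed_form(self, tilt, expected):
        c, s = np.cos(np.radians(tilt)), np.sin(np.radians(tilt))
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        a = fit_ring_plane(make_model(hexagon()), range(6))
        b = fit_ring_plane(make_model(hexagon() @ rot.T + [0, 0, 5]), range(6))
        assert interplanar_angle(a, b) == pytest.approx(expected, abs=1e-9)
        assert interplanar_angle(b, a) == pytest.approx(expected, abs=1e-9)

    def test_lateral_offset_stacked_and_slipped(self):
        a = fit_ring_plane(make_model(hexagon()), range(6))
        above = fit_ring_plane(make_model(hexagon() + [0, 0, 3.4]), range(6))
        slipped = fit_ring_plane(make_model(hexagon() + [2.0, 0, 3.4]), range(6))
        assert lateral_offset(a, above) == pytest.approx(0.0, abs=1e-12)
        assert lateral_offset(a, slipped) == pytest.approx(2.0, abs=1e-12)

    def test_lateral_offset_matches_projection_oracle(self):
        rng = np.random.default_rng(21)
        q, t = random_rigid_transform(rng)
        a = fit_ring_plane(make_model(hexagon() @ q.T + t), range(6))
        b = fit_ring_plane(make_model(hexagon() + rng.uniform(-5, 5, 3)), range(6))
        expected = lateral_offset_by_projection_matrix(a.unit_normal, a.centroid, b.centroid)
        assert lateral_offset(a, b) == pytest.approx(expected, abs=1e-12)


class TestContactNumber:
    @pytest.mark.parametrize("d,expected", [(3.9, 1), (4.0, 1), (4.1, 0)])
    def test_cutoff_boundary(self, d, expected):
        m = make_model([[0, 0, 0], [d, 0, 0]])
        assert contact_number(m, [0], [1], cutoff=4.0) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-6, 6, size=(20, 3))
        m = make_model(coords)
        got = contact_number(m, range(10), range(10, 20), cutoff=4.0)
        assert got == brute_force_contacts(coords[:10], coords[10:], 4.0)

    def test_overlapping_groups_rejected(self):
        m = make_model([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError):
            contact_number(m, [0, 1], [1, 2])

    def test_empty_group_rejected(self):
        m = make_model([[0, 0, 0]])
        with pytest.raises(ValueError):
            contact_number(m, [0], [])


class TestProfileConformer:
    def test_quencher_far_away_gives_zero_contacts(self, template):
        from fqens.synthetic import place_quencher

        model = place_quencher("NonContact", rng=3)
        mmap = resolve_moieties(model, template[1])
        p = profile_conformer(model, mmap)
        assert p.complete and p.contacts.q_tq == 0

    def test_contact_sum_identity(self, free_ensemble):
        models, _, config = free_ensemble
        for m in models[:25]:
            p = profile_conformer(m, resolve_moieties(m, config))
            assert p.contacts.q_tq == p.contacts.q_xq + p.contacts.q_pq

    def test_constructed_stackx_has_contacts(self):
        """A tight stacked pose (d 3.6 A, tilt <=5 deg, slip <=0.5 A) contacts heavily."""
        from fqens.synthetic import ClassGeometry, default_moiety_config, place_quencher

        geom = ClassGeometry(stack_distance=(3.6, 3.6), stack_max_angle=5.0,
                             stack_max_offset=0.5)
        model = place_quencher("StackX", geom=geom, rng=5)
        p = profile_conformer(model, resolve_moieties(model, default_moiety_config()))
        assert p.contacts.q_xq >= 5
        assert p.geometry.d_xq <= 4.5

    def test_per_atom_contacts_sum_to_totals(self, free_ensemble):
        models, _, config = free_ensemble
        m = models[0]
        mmap = resolve_moieties(m, config)
        p = profile_conformer(m, mmap)
        assert sum(p.contacts.per_atom_contacts[i] for i in mmap.xanthene) == p.contacts.q_xq
        assert sum(p.contacts.per_atom_contacts[i] for i in mmap.phenyl) == p.contacts.q_pq

    def test_missing_quencher_flags_incomplete(self, template):
        model, config = template
        mmap = resolve_moieties(model, config, required=("xanthene", "phenyl"))
        stripped = mmap.roles.copy()
        stripped.pop("quencher")
        from fqens.model import MoietyMap

        p = profile_conformer(model, MoietyMap(stripped))
        assert not p.complete and p.contacts is None

    @pytest.mark.parametrize("seed", range(3))
    def test_descriptors_invariant_under_rigid_transform(self, free_ensemble, seed):
        models, _, config = free_ensemble
        m = models[seed]
        mmap = resolve_moieties(m, config)
        base = profile_conformer(m, mmap)
        q, t = random_rigid_transform(np.random.default_rng(100 + seed))
        moved = profile_conformer(m.with_coords(m.coords @ q.T + t), mmap)
        assert moved.contacts.q_tq == base.contacts.q_tq
        for attr in ("d_xq", "d_pq", "angle_xq", "angle_pq", "angle_xp",
                     "offset_xq", "offset_pq"):
            assert getattr(moved.geometry, attr) == pytest.approx(
                getattr(base.geometry, attr), abs=1e-6
            )
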