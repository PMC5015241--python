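"""Regular triangulation and alpha-complex classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from alphapocket import (DegeneracyError, build_alpha_complex, orthoradius2,
                         regular_triangulation, surface_atoms,
                         weighted_alpha_complex)
from alphapocket.alphashape import brute_force_regular_tetrahedra

REGULAR_TETRA = np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])


def canon(tets):
    return {tuple(sorted(t)) for t in np.asarray(tets).reshape(-1, 4)}


class TestRegularTriangulation:
    def test_minimal_simplex(self):
        tri = regular_triangulation(REGULAR_TETRA, np.ones(4))
        assert tri.n_tetrahedra == 1
        assert canon(tri.tetrahedra) == {(0, 1, 2, 3)}

    def test_centroid_splits_into_four(self):
        pts = np.vstack([REGULAR_TETRA, [0.0, 0, 0]])
        tri = regular_triangulation(pts, np.ones(5))
        assert tri.n_tetrahedra == 4
        assert canon(tri.tetrahedra) == brute_force_regular_tetrahedra(pts, np.ones(5))

    def test_cube_corners_pass_orthoball_emptiness(self):
        pts = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                        for k in (0, 1)], dtype=float)
        w = np.full(8, 0.1)
        tri = regular_triangulation(pts, w)
        # every solid output tetrahedron must have an empty orthoball
        # (zero-volume gasket tetrahedra from the cospherical corners may
        # also appear; they carry the cube's common orthoball)
        n_solid = 0
        for tet in tri.tetrahedra:
            vol = abs(np.linalg.det(pts[tet][1:] - pts[tet][0])) / 6
            if vol < 1e-12:
                continue
            n_solid += 1
            r2 = orthoradius2(pts[tet], w[tet])
            v = pts[tet][1:] - pts[tet][0]
            t = np.linalg.solve(v @ v.T, 0.5 * (np.sum(v * v, axis=1)))
            c = pts[tet][0] + t @ v
            others = np.setdiff1d(np.arange(8), tet)
            power = np.sum((pts[others] - c) ** 2, axis=1) - w[others]
            assert np.all(power >= r2 - 1e-9)
        assert n_solid >= 5
        # and the tetrahedra must tile the cube (total volume 1)
        vols = [abs(np.linalg.det(pts[t][1:] - pts[t][0])) / 6 for t in tri.tetrahedra]
        assert np.isclose(sum(vols), 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        """Oracle equivalence on small random weighted point sets."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        pts = rng.normal(0, 2.0, (n, 3))
        w = rng.uniform(0.0, 1.5, n)
        tri = regular_triangulation(pts, w)
        assert canon(tri.tetrahedra) == brute_force_regular_tetrahedra(pts, w)

    def test_redundant_point_is_hidden(self):
        """A tiny-weight atom inside a huge-weight atom vanishes."""
        pts = np.vstack([REGULAR_TETRA * 4.0, [0.0, 0, 0], [0.05, 0, 0]])
        w = np.array([1.0, 1, 1, 1, 900.0, 1e-6])
        tri = regular_triangulation(pts, w)
        assert 5 not in tri.vertex_indices
        assert 4 in tri.vertex_indices

    def test_too_few_or_coplanar_points_raise(self):
        with pytest.raises(DegeneracyError):
            regular_triangulation(np.zeros((3, 3)), np.ones(3))
        flat = np.column_stack([np.arange(6.0), np.arange(6.0) ** 2,
                                np.zeros(6)])
        with pytest.raises(DegeneracyError):
            regular_triangulation(flat, np.ones(6))
        # seeded jitter resolves it
        tri = regular_triangulation(flat, np.ones(6), jitter_seed=1)
        assert tri.n_tetrahedra >= 1

    def test_positive_orientation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 2, (15, 3))
        tri = regular_triangulation(pts, rng.uniform(0, 1, 15))
        a, b, c, d = (pts[tri.tetrahedra[:, i]] for i in range(4))
        vols = np.einsum("ij,ij->i", b - a, np.cross(c - a, d - a))
        assert np.all(vols > 0)


class TestOrthoradius:
    def test_two_equal_weight_atoms(self):
        """Edge filtration value d²/4 − w for two equal-weight atoms."""
        p = np.array([[0.0, 0, 0], [6.0, 0, 0]])
        assert np.isclose(orthoradius2(p, np.array([1.0, 1.0])), 8.0)
        p2 = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert np.isclose(orthoradius2(p2, np.array([4.0, 4.0])), 2.25 - 4.0)

    def test_matches_smallest_orthogonal_ball_search(self):
        """Brute-force grid search over centers on the segment agrees."""
        p = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        w = np.array([4.0, 2.5])
        r2 = orthoradius2(p, w)
        ts = np.linspace(-1, 2, 20001)
        centers = p[0] + ts[:, None] * (p[1] - p[0])
        pow0 = np.sum((centers - p[0]) ** 2, axis=1) - w[0]
        pow1 = np.sum((centers - p[1]) ** 2, axis=1) - w[1]
        k = np.argmin(np.abs(pow0 - pow1))
        assert np.isclose(pow0[k], r2, atol=1e-3)

    def test_single_vertex_value_is_minus_weight(self):
        assert orthoradius2(np.zeros((1, 3)), np.array([2.5])) == -2.5


class TestAlphaComplex:
    def test_alpha_infinity_keeps_all_tetrahedra(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 2, (20, 3))
        tri = regular_triangulation(pts, rng.uniform(0, 1, 20))
        ac = weighted_alpha_complex(tri, np.inf)
        assert ac.member_mask.all()

    def test_alpha_infinity_boundary_tiles_convex_hull(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 2, (25, 3))
        tri = regular_triangulation(pts, rng.uniform(0, 0.5, 25))
        ac = weighted_alpha_complex(tri, np.inf)
        hull = ConvexHull(pts)
        assert surface_atoms(ac) >= set(hull.vertices.tolist())
        # boundary triangle area equals hull area
        tris = ac.boundary_triangles
        area = 0.5 * np.linalg.norm(
            np.cross(pts[tris[:, 1]] - pts[tris[:, 0]],
                     pts[tris[:, 2]] - pts[tris[:, 0]]), axis=1).sum()
        assert np.isclose(area, hull.area, rtol=1e-9)

    @given(st.integers(0, 1000))
    def test_membership_monotone_in_alpha(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 2.0, (12, 3))
        w = rng.uniform(0, 2.0, 12)
        tri = regular_triangulation(pts, w)
        alphas = np.sort(rng.uniform(-2, 8, 3))
        masks = [weighted_alpha_complex(tri, a).member_mask for a in alphas]
        for lo, hi in zip(masks, masks[1:]):
            assert np.all(hi | ~lo)  # lo ⊆ hi

    def test_boundary_triangles_bound_exactly_one_member(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 3.0, (30, 3))
        ac = build_alpha_complex(pts, np.full(30, 9.61), alpha=0.0)
        faces = ac.member_tetrahedra[
            :, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
        faces = {tuple(sorted(f)) for f in faces.tolist()}
        for tri_face in ac.boundary_triangles:
            assert tuple(sorted(tri_face.tolist())) in faces

    def test_rigid_motion_preserves_combinatorics(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 2.0, (20, 3))
        w = rng.uniform(0.5, 2.0, 20)
        ac1 = build_alpha_complex(pts, w, alpha=0.0)
        rot = Rotation.random(random_state=42).as_matrix()
        pts2 = pts @ rot.T + np.array([5.0, -3.0, 2.0])
        ac2 = build_alpha_complex(pts2, w, alpha=0.0)
        assert canon(ac1.member_tetrahedra) == canon(ac2.member_tetrahedra)
        assert surface_atoms(ac1) == surface_atoms(ac2)


class TestSurfaceAtoms:
    def test_isolated_atom_is_singular_surface(self):
        pts = np.vstack([REGULAR_TETRA * 1.2, [30.0, 0, 0]])
        ac = build_alpha_complex(pts, np.full(5, 4.0), alpha=0.0)
        assert 4 in ac.singular_vertices
        assert 4 in surface_atoms(ac)

    def test_lattice_center_buried_faces_exposed(self):
        """5×5×5 touching lattice: the unique central atom is interior."""
        a = 3.4
        g = np.arange(5) * a
        pts = np.array([[x, y, z] for x in g for y in g for z in g])
        w = np.full(125, (1.7 + 1.4) ** 2)
        ac = build_alpha_complex(pts, w, alpha=0.0)
        center = int(np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
        surf = surface_atoms(ac)
        assert center not in surf
        face_atoms = [i for i, p in enumerate(pts)
                      if (p.min() == 0 or p.max() == 4 * a)]
        assert set(face_atoms) <= surf
        # Monte Carlo ray test: points around the center are enclosed by members
        from conftest import mc_solid_angle
        assert mc_solid_angle(ac, center, n_samples=2000, seed=0) < -0.99

    def test_hull_limit_surface_equals_hull_vertices(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 2, (30, 3))
        tri = regular_triangulation(pts, rng.uniform(0, 0.5, 30))
        ac = weighted_alpha_complex(tri, np.inf)
        assert surface_atoms(ac) == set(ConvexHull(pts).vertices.tolist())

    def test_zero_alpha_disconnected_pair_is_singular(self):
        """Two far atoms at alpha 0: both singular (d²/4 − w > 0)."""
        pts = np.vstack([REGULAR_TETRA * 6.0, [40.0, 40, 40], [46.0, 40, 40]])
        ac = build_alpha_complex(pts, np.full(6, 1.0), alpha=0.0)
        assert {4, 5} <= ac.singular_vertices
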