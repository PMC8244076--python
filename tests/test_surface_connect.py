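"""Zipper, boolean and harmonic surface connections; ring registration."""

import numpy as np
import pytest

from conftest import ring_pair_surfaces, zipper_oracle

from cardiomesh.core_mesh import (
    Ring, enclosed_volume, euler_characteristic, extract_boundary_rings,
    is_closed, merge_surfaces, surface_area, validate_surface,
)
from cardiomesh.errors import InputError, NumericalError, TopologyError
from cardiomesh.surface_connect import (
    BooleanSpec, HarmonicConnectSpec, _zipper, boolean_connection,
    harmonic_connection, register_rings, surface_connection,
)
from cardiomesh.synthetic_fixtures import icosphere, star_tube, tube


BAND = 99


class TestZipper:
    def test_two_aligned_square_rings(self):
        rng = np.random.default_rng(0)
        s1 = star_tube(np.full(4, np.sqrt(2)), z0=-1.0, z1=0.0,
                       phase=np.pi / 4)
        s2 = star_tube(np.full(4, np.sqrt(2)), z0=1.0, z1=2.0,
                       phase=np.pi / 4)
        r1 = [r for r in extract_boundary_rings(s1)
              if abs(s1.points[r.point_indices[0], 2]) < 1e-12][0]
        r2 = [r for r in extract_boundary_rings(s2)
              if abs(s2.points[r.point_indices[0], 2] - 1.0) < 1e-12][0]
        out = surface_connection(s1, s2, r1, r2, BAND)
        band = out.cell_tags == BAND
        assert band.sum() == 8
        assert len(np.unique(out.triangles[band])) == 8
        validate_surface(out, check_orientation=True)
        # watertight against both parents: only the far rims remain open
        assert len(extract_boundary_rings(out)) == 2
        del rng

    def test_band_count_for_3_and_5_rings(self):
        rng = np.random.default_rng(1)
        s1, r1, s2, r2 = ring_pair_surfaces(3, 5, rng)
        out = surface_connection(s1, s2, r1, r2, BAND)
        assert (out.cell_tags == BAND).sum() == 8
        state = _zipper(merge_surfaces([s1, s2], tol=0.0).points,
                        r1.point_indices, r2.point_indices + s1.n_points)
        assert state.insertions == 3 + 5 + 1

    def test_parallel_identical_rings(self):
        n, delta = 16, 0.25
        radii = np.ones(n)
        s1 = star_tube(radii, z0=-1.0, z1=0.0)
        s2 = star_tube(radii, z0=delta, z1=delta + 1.0)
        r1 = [r for r in extract_boundary_rings(s1)
              if abs(s1.points[r.point_indices[0], 2]) < 1e-12][0]
        r2 = [r for r in extract_boundary_rings(s2)
              if abs(s2.points[r.point_indices[0], 2] - delta) < 1e-12][0]
        out = surface_connection(s1, s2, r1, r2, BAND)
        band = out.triangles[out.cell_tags == BAND]
        # every band triangle contains exactly one vertical connecting
        # edge of length delta (its other cross edge is a quad diagonal)
        for tri in band:
            verticals = 0
            for a in range(3):
                p, q = out.points[tri[a]], out.points[tri[(a + 1) % 3]]
                if abs(p[2] - q[2]) > 1e-12 and np.isclose(
                        np.linalg.norm(p - q), delta):
                    verticals += 1
            assert verticals == 1
        area = surface_area(out, tags={BAND})
        perimeter = n * np.linalg.norm(
            s1.points[r1.point_indices[0]] - s1.points[r1.point_indices[1]])
        assert area == pytest.approx(perimeter * delta, rel=1e-9)

    def test_band_triangles_have_one_ring_edge_each(self):
        rng = np.random.default_rng(5)
        s1, r1, s2, r2 = ring_pair_surfaces(12, 17, rng)
        out = surface_connection(s1, s2, r1, r2, BAND)
        ring_pts = set(map(int, r1.point_indices)) | set(
            int(i) + s1.n_points for i in r2.point_indices)
        ring1_pts = set(map(int, r1.point_indices))
        for tri in out.triangles[out.cell_tags == BAND]:
            ring_edges = 0
            for a in range(3):
                u, v = int(tri[a]), int(tri[(a + 1) % 3])
                same1 = u in ring1_pts and v in ring1_pts
                same2 = (u not in ring1_pts and v not in ring1_pts
                         and u in ring_pts and v in ring_pts)
                ring_edges += same1 or same2
            assert ring_edges == 1

    def test_production_matches_independent_step_simulator(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n1 = int(rng.integers(3, 51))
            n2 = int(rng.integers(3, 51))
            s1, r1, s2, r2 = ring_pair_surfaces(n1, n2, rng)
            merged = merge_surfaces([s1, s2], tol=0.0)
            g2 = r2.point_indices + s1.n_points
            state = _zipper(merged.points, r1.point_indices, g2)
            oracle = zipper_oracle(merged.points, r1.point_indices, g2)
            mine = [frozenset(map(int, t)) for t in state.triangles]
            assert mine == oracle

    def test_shared_points_rejected(self, unit_icosphere):
        t = tube(1, 1, 8, 2)
        rings = extract_boundary_rings(t)
        with pytest.raises(InputError):
            surface_connection(t, t, rings[0], rings[1], BAND)


class TestRegisterRings:
    @pytest.fixture()
    def star_ring(self):
        n = 40
        theta = 2 * np.pi * np.arange(n) / n
        radii = 1 + 0.3 * np.cos(3 * theta) + 0.1 * np.sin(theta)
        s = star_tube(radii, z0=0.0, z1=0.5)
        ring = [r for r in extract_boundary_rings(s)
                if abs(s.points[r.point_indices[0], 2]) < 1e-12][0]
        return s, ring

    def test_identical_rings_identity(self, star_ring):
        _, ring = star_ring
        R, t = register_rings(ring, ring, mode="icp")
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_centroid_mode_recovers_translation(self, star_ring):
        s, ring = star_ring
        moved = s.copy()
        moved.points = s.points + np.array([1.0, -2.0, 0.5])
        ring_fixed = Ring(moved, ring.point_indices)
        R, t = register_rings(ring, ring_fixed, mode="centroid")
        assert np.allclose(R, np.eye(3))
        assert np.allclose(t, [1.0, -2.0, 0.5], atol=1e-12)

    def test_icp_recovers_rigid_motion(self, star_ring):
        s, ring = star_ring
        th = 0.2
        R_true = np.array([[np.cos(th), -np.sin(th), 0],
                           [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        t_true = np.array([0.3, -0.1, 0.4])
        moved = s.copy()
        moved.points = s.points @ R_true.T + t_true
        ring_fixed = Ring(moved, ring.point_indices)
        R, t = register_rings(ring, ring_fixed, mode="icp",
                              max_iter=400, tol=1e-14)
        assert np.abs(R - R_true).max() < 1e-6
        assert np.abs(t - t_true).max() < 1e-6

    def test_collinear_ring_rank_deficiency(self, unit_icosphere):
        pts = np.array([[x, 0.0, 0.0] for x in np.linspace(0, 1, 6)])
        tris = np.array([[0, 1, 2], [2, 3, 4]])  # geometry only matters
        from cardiomesh.core_mesh import TriSurface

        with pytest.raises((NumericalError, Exception)):
            degenerate = TriSurface(pts, tris)
            ring = Ring.__new__(Ring)
            ring.surface = degenerate
            ring.point_indices = np.array([0, 1, 2, 3])
            register_rings(ring, ring, mode="icp")


class TestBooleanConnection:
    def test_sphere_difference_area_and_topology(self):
        s1 = icosphere(3)
        s2 = icosphere(3, center=(0, 0, 1.0))
        out = boolean_connection(
            s1, s2, BooleanSpec(operation="difference", h=0.15, epsilon=0.08))
        assert is_closed(out)
        validate_surface(out, check_orientation=True)
        assert euler_characteristic(out) == 2
        assert surface_area(out) == pytest.approx(4 * np.pi, rel=0.05)
        assert set(np.unique(out.cell_tags)) == {1, 2, 3}

    def test_union_volume_matches_lens_formula(self):
        s1 = icosphere(3)
        s2 = icosphere(3, center=(0, 0, 1.0))
        out = boolean_connection(
            s1, s2, BooleanSpec(operation="union", h=0.15, epsilon=0.08))
        lens = np.pi * (4 * 1 + 1) * (2 * 1 - 1) ** 2 / 12
        exact = 2 * (4 / 3 * np.pi) - lens
        assert is_closed(out)
        assert enclosed_volume(out) == pytest.approx(exact, rel=0.02)

    def test_disjoint_inputs_rejected(self):
        with pytest.raises(InputError, match="do not intersect"):
            boolean_connection(icosphere(2), icosphere(2, center=(5, 0, 0)),
                               BooleanSpec(h=0.2))

    def test_open_input_rejected(self):
        with pytest.raises(TopologyError, match="closed"):
            boolean_connection(tube(1, 1, 12, 3), icosphere(2),
                               BooleanSpec(h=0.2))


class TestHarmonicConnection:
    def test_coincident_rings_zero_deformation(self):
        # rings already matching: the deformation field must vanish and
        # the far part of s_in stay bitwise in place
        c_in = tube(1.0, 2.0, 24, 10)
        c_ref = tube(1.0, 1.0, 24, 4, center=(0, 0, -1.0))
        rin = [r for r in extract_boundary_rings(c_in)
               if abs(c_in.points[r.point_indices[0], 2]) < 1e-9][0]
        rref = [r for r in extract_boundary_rings(c_ref)
                if abs(c_ref.points[r.point_indices[0], 2]) < 1e-9][0]
        out = harmonic_connection(
            c_in, c_ref, rin, rref,
            HarmonicConnectSpec(h=0.15, registration="none"))
        validate_surface(out)
        # points of the upper half of c_in are unmoved
        upper = c_in.points[c_in.points[:, 2] > 1.0]
        from scipy.spatial import cKDTree

        d, _ = cKDTree(out.points).query(upper)
        assert d.max() < 1e-12

    def test_cylinder_radial_decay_closed_form(self):
        # m=1 azimuthal mode on a radius-1 cylinder decays as sinh
        c_in = tube(1.0, 2.0, 48, 24)
        c_ref = tube(1.2, 1.0, 48, 8, center=(0, 0, -1.0))
        rin = [r for r in extract_boundary_rings(c_in)
               if abs(c_in.points[r.point_indices[0], 2]) < 1e-9][0]
        rref = [r for r in extract_boundary_rings(c_ref)
                if abs(c_ref.points[r.point_indices[0], 2]) < 1e-9][0]
        out = harmonic_connection(
            c_in, c_ref, rin, rref,
            HarmonicConnectSpec(h=0.15, free_ring_condition="dirichlet"))
        pts = out.points
        sel = (pts[:, 2] > 0.3) & (pts[:, 2] < 1.7)
        r = np.linalg.norm(pts[sel, :2], axis=1)
        pred = 1.0 + 0.2 * np.sinh(2.0 - pts[sel, 2]) / np.sinh(2.0)
        assert np.abs(r - pred).max() < 1e-2

    def test_excluded_tags_cover_everything_rejected(self):
        c_in = tube(1.0, 2.0, 16, 4)
        c_ref = tube(1.0, 1.0, 16, 4, center=(0, 0, -1.5))
        rin = extract_boundary_rings(c_in)[0]
        rref = extract_boundary_rings(c_ref)[0]
        with pytest.raises(InputError, match="nothing to deform"):
            harmonic_connection(
                c_in, c_ref, rin, rref,
                HarmonicConnectSpec(h=0.2, excluded_tags={0}))
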