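"""Volumetric operations: fill, connect, refine, hexify."""

import numpy as np
import pytest

from cardiomesh.core_mesh import (
    TetMesh, TriSurface, extract_surface, tet_volumes, validate_tetmesh,
)
from cardiomesh.errors import InputError, TopologyError
from cardiomesh.synthetic_fixtures import cube_tet, icosphere, slab_tet
from cardiomesh.volume_ops import (
    ConnectionSpec, RefineSpec, TetHexSpec, mesh_connection, refine_mesh,
    tet_to_hex, tetrahedralize,
)


def reference_tet():
    return TetMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
                   np.array([[0, 1, 2, 3]]))


class TestTetrahedralize:
    def test_cube_surface_cone_decomposition(self):
        surf = extract_surface(cube_tet(1))
        m = tetrahedralize(surf)
        assert m.n_cells == 12           # one tet per boundary triangle
        assert m.volume() == pytest.approx(1.0, abs=1e-14)
        validate_tetmesh(m)

    def test_icosphere_volume(self):
        m = tetrahedralize(icosphere(3))
        assert m.volume() == pytest.approx(4 / 3 * np.pi, rel=0.01)

    def test_boundary_triangulation_preserved(self):
        surf = icosphere(2)
        m = tetrahedralize(surf)
        assert np.array_equal(m.boundary_faces, surf.triangles)

    def test_torus_not_star_shaped(self):
        import trimesh

        tor = trimesh.creation.torus(major_radius=2.0, minor_radius=0.5)
        surf = TriSurface(np.array(tor.vertices), np.array(tor.faces))
        with pytest.raises(TopologyError, match="star-shaped"):
            tetrahedralize(surf)


class TestMeshConnection:
    def test_cube_gap_cube_volume_and_tags(self):
        m1 = cube_tet(2)
        m2 = slab_tet(1, 1, 1, 2, 2, 2, origin=(0, 0, 1.2))
        out = mesh_connection(m1, m2,
                              ConnectionSpec(tags_1={6}, tags_2={5}, h=0.4))
        assert out.volume() == pytest.approx(2.2, rel=0.01)
        assert set(np.unique(out.cell_tags)) == {1, 2, 3}
        wall_tags = set(np.unique(out.boundary_tags)) - {1, 2, 3, 4, 5, 6}
        assert len(wall_tags) == 1
        validate_tetmesh(out)

    def test_volume_conservation_is_exact(self):
        m1 = cube_tet(2)
        m2 = slab_tet(1, 1, 1, 2, 2, 2, origin=(0, 0, 1.2))
        out = mesh_connection(m1, m2,
                              ConnectionSpec(tags_1={6}, tags_2={5}, h=0.4))
        v3 = out.volume() - m1.volume() - m2.volume()
        assert v3 == pytest.approx(0.2, rel=0.01)
        # input tets survive untouched
        assert np.isclose(
            tet_volumes(out.points, out.tets[out.cell_tags == 1]).sum(),
            m1.volume(), rtol=1e-12)

    def test_two_patch_regions_give_two_wall_tags(self):
        # two disjoint square patches facing each other: the connection
        # surface has two closed components, one wall tag per ring pair
        m1 = cube_tet(3)
        m2 = slab_tet(1, 1, 0.4, 3, 3, 1, origin=(0, 0, 1.3))
        s1 = extract_surface(m1)
        # split the +z tag (6) of m1 into two stripes tagged 61 / 62
        def stripe_tags(mesh, ztag, zval):
            faces = mesh.boundary_faces
            centers = mesh.points[faces].mean(axis=1)
            on_top = np.isclose(centers[:, 2], zval)
            left = on_top & (centers[:, 0] < 1 / 3)
            right = on_top & (centers[:, 0] > 2 / 3)
            mesh.boundary_tags = mesh.boundary_tags.copy()
            mesh.boundary_tags[left] = 61
            mesh.boundary_tags[right] = 62
        stripe_tags(m1, 6, 1.0)
        faces2 = m2.boundary_faces
        centers2 = m2.points[faces2].mean(axis=1)
        bottom = np.isclose(centers2[:, 2], 1.3)
        m2.boundary_tags = m2.boundary_tags.copy()
        m2.boundary_tags[bottom & (centers2[:, 0] < 1 / 3)] = 51
        m2.boundary_tags[bottom & (centers2[:, 0] > 2 / 3)] = 52
        out = mesh_connection(
            m1, m2, ConnectionSpec(tags_1={61, 62}, tags_2={51, 52}, h=0.3))
        wall_tags = (set(np.unique(out.boundary_tags))
                     - set(np.unique(m1.boundary_tags))
                     - set(np.unique(m2.boundary_tags)))
        assert len(wall_tags) == 2
        validate_tetmesh(out)
        del s1

    def test_ring_count_mismatch_rejected(self):
        m1 = cube_tet(2)
        m2 = slab_tet(1, 1, 1, 2, 2, 2, origin=(0, 0, 1.2))
        # top and bottom faces of the cube: two disjoint rings vs one
        with pytest.raises(TopologyError, match="not topologically"):
            mesh_connection(m1, m2,
                            ConnectionSpec(tags_1={5, 6}, tags_2={5}, h=0.4))


class TestRefine:
    def refine_cube(self):
        c = cube_tet(2)
        c.point_fields["f"] = np.abs(c.points[:, 2] - 0.5)
        return c, refine_mesh(c, RefineSpec("f", alpha=0.2, beta=1, m=0.05))

    def test_identity_when_sizing_already_met(self):
        c = cube_tet(2)
        c.point_fields["f"] = np.full(c.n_points, 100.0)
        out = refine_mesh(c, RefineSpec("f", alpha=1.0, beta=1, m=0.05))
        assert out.n_cells == c.n_cells

    def test_every_tet_meets_the_size_criterion(self):
        c, out = self.refine_cube()
        assert out.n_cells > c.n_cells
        f = out.point_fields["f"]
        for t in out.tets:
            p = out.points[t]
            longest = max(np.linalg.norm(p[a] - p[b])
                          for a in range(4) for b in range(a + 1, 4))
            h = max(0.05, 0.2 * float(f[t].mean()))
            assert longest <= 1.5 * h + 1e-12
        assert out.volume() == pytest.approx(1.0, rel=1e-10)
        validate_tetmesh(out)

    def test_tag_projection_matches_point_in_tet_oracle(self):
        c = cube_tet(2)
        c.cell_tags = np.where(
            c.points[c.tets].mean(axis=1)[:, 2] < 0.5, 4, 9)
        c.point_fields["f"] = np.full(c.n_points, 0.3)
        out = refine_mesh(c, RefineSpec("f", alpha=1.0, beta=1, m=0.15))
        assert out.n_cells > c.n_cells
        # oracle: locate each output barycenter in the input mesh by
        # barycentric coordinates
        bary = out.points[out.tets].mean(axis=1)
        for b, tag in zip(bary, out.cell_tags):
            found = None
            for t_in, tag_in in zip(c.tets, c.cell_tags):
                p = c.points[t_in]
                M = np.column_stack([p[1] - p[0], p[2] - p[0], p[3] - p[0]])
                lam = np.linalg.solve(M, b - p[0])
                if (lam >= -1e-9).all() and lam.sum() <= 1 + 1e-9:
                    found = tag_in
                    break
            assert found == tag
        del out

    def test_zero_minimum_size_rejected(self):
        with pytest.raises(InputError, match="m"):
            RefineSpec("f", m=0.0)


class TestTetToHex:
    def test_single_tet_combinatorics_and_volume(self):
        hx = tet_to_hex(reference_tet(), TetHexSpec(0))
        assert hx.n_cells == 4
        assert hx.n_points == 15  # 4 vertices + 6 midpoints + 4 faces + 1
        assert len(hx.boundary_quads) == 12  # 3 per boundary triangle
        assert hx.volumes().sum() == pytest.approx(1 / 6, rel=1e-12)
        assert hx.corner_jacobians().min() > 0

    def test_one_rbs_iteration_multiplies_counts(self):
        hx = tet_to_hex(reference_tet(), TetHexSpec(1))
        assert hx.n_cells == 32          # 4 hexes x 8
        assert len(hx.boundary_quads) == 48  # 12 quads x 4
        assert hx.volumes().sum() == pytest.approx(1 / 6, rel=1e-12)

    def test_volume_conserved_on_a_full_mesh(self):
        m = cube_tet(2)
        for n in (0, 1):
            hx = tet_to_hex(m, TetHexSpec(n))
            assert hx.volumes().sum() == pytest.approx(1.0, rel=1e-10)
            assert hx.corner_jacobians().min() > 0

    def test_tags_inherited(self):
        m = cube_tet(2)
        m.cell_tags = np.arange(m.n_cells, dtype=np.int64)
        hx = tet_to_hex(m, TetHexSpec(0))
        assert np.array_equal(hx.cell_tags, np.repeat(m.cell_tags, 4))
        assert np.array_equal(hx.boundary_tags,
                              np.repeat(m.boundary_tags, 3))

    def test_inverted_tet_rejected(self):
        bad = reference_tet()
        bad.tets = bad.tets[:, [0, 2, 1, 3]]
        with pytest.raises(TopologyError, match="inverted"):
            tet_to_hex(bad)
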