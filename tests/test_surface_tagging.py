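"""Array-driven tagging: simple, clip, harmonic, connectivity, cells."""

import numpy as np
import pytest

from conftest import interface_points

from cardiomesh.core_mesh import surface_area, validate_surface
from cardiomesh.errors import InputError
from cardiomesh.harmonic_solver import min_triangle_angle
from cardiomesh.surface_tagging import (
    TagSpec, tag_cells, tag_clip, tag_connectivity, tag_harmonic, tag_simple,
)
from cardiomesh.synthetic_fixtures import icosphere, tube, two_cavity_shell


def sphere_with_z(level=4):
    s = icosphere(level)
    s.point_fields["z"] = s.points[:, 2].copy()
    return s


class TestSimple:
    def test_hemisphere_area(self):
        out = tag_simple(sphere_with_z(), TagSpec(field_name="z", sigma=0.0,
                                                  new_tag=7))
        assert surface_area(out, tags={7}) == pytest.approx(2 * np.pi,
                                                            rel=0.02)

    def test_sigma_below_min_tags_nothing(self):
        s = sphere_with_z(2)
        out = tag_simple(s, TagSpec(field_name="z", sigma=-2.0, new_tag=7))
        assert 7 not in out.cell_tags

    def test_invert_flips_the_partition(self):
        # sigma chosen off any barycenter value: ties belong to both
        # half-open conditions and would break the exact partition
        s = sphere_with_z(2)
        lo = tag_simple(s, TagSpec(field_name="z", sigma=0.0123, new_tag=7))
        hi = tag_simple(s, TagSpec(field_name="z", sigma=0.0123, new_tag=7,
                                   invert=True))
        assert np.array_equal(lo.cell_tags == 7, hi.cell_tags != 7)

    def test_excluded_tags_untouched(self):
        s = sphere_with_z(2)
        s.cell_tags[:50] = 5
        out = tag_simple(s, TagSpec(field_name="z", sigma=2.0, new_tag=7,
                                    excluded_tags={5}))
        assert np.array_equal(out.cell_tags[:50], s.cell_tags[:50])

    def test_idempotent(self):
        s = sphere_with_z(2)
        spec = TagSpec(field_name="z", sigma=0.0, new_tag=7)
        once = tag_simple(s, spec)
        twice = tag_simple(once, spec)
        assert np.array_equal(once.cell_tags, twice.cell_tags)


class TestClip:
    def test_interface_points_on_level_set(self):
        out = tag_clip(sphere_with_z(3), TagSpec(field_name="z", sigma=0.0,
                                                 new_tag=7))
        validate_surface(out, check_orientation=True)
        z = out.points[interface_points(out), 2]
        assert np.abs(z).max() <= 1e-9

    def test_tube_split_area_ratio_exact(self):
        t = tube(1.0, 2.0, 32, 10)
        t.point_fields["z"] = t.points[:, 2].copy()
        sigma = 0.55
        out = tag_clip(t, TagSpec(field_name="z", sigma=sigma, new_tag=7))
        a_low = surface_area(out, tags={7})
        a_tot = surface_area(out)
        assert a_low / a_tot == pytest.approx(sigma / 2.0, abs=1e-6)

    def test_tagged_area_monotone_in_sigma(self):
        s = sphere_with_z(2)
        areas = []
        for sigma in (-0.6, -0.2, 0.2, 0.6):
            out = tag_clip(s, TagSpec(field_name="z", sigma=sigma, new_tag=7))
            areas.append(surface_area(out, tags={7}))
        assert areas == sorted(areas)

    def test_sigma_outside_range_warns_and_falls_back(self):
        s = sphere_with_z(2)
        with pytest.warns(UserWarning, match="outside"):
            out = tag_clip(s, TagSpec(field_name="z", sigma=5.0, new_tag=7))
        assert out.n_cells == s.n_cells


class TestHarmonic:
    def test_ring_lands_on_level_set_with_connectivity_preserved(self):
        s = sphere_with_z(4)
        min_angle_in = min_triangle_angle(s)
        out = tag_harmonic(
            s, TagSpec(field_name="z", sigma=0.0, new_tag=7, rho=0.5),
            recompute=lambda m: m.points[:, 2],
        )
        assert out.n_cells == s.n_cells
        assert out.n_points == s.n_points
        z = out.points[interface_points(out), 2]
        assert np.abs(z).max() <= 1e-3
        validate_surface(out)  # no collapsed triangles after pruning
        assert min_triangle_angle(out) >= 0.5 * min_angle_in

    def test_zigzag_already_on_level_means_no_motion(self):
        # a tube has vertex rows exactly on z-levels: cutting between
        # rows keeps the zig-zag ring as Dirichlet data with zero
        # displacement, so the output equals the simple tagging
        t = tube(1.0, 2.0, 24, 8)
        t.point_fields["z"] = t.points[:, 2].copy()
        spec = TagSpec(field_name="z", sigma=1.0, new_tag=7, rho=0.4)
        out = tag_harmonic(t, spec, recompute=lambda m: m.points[:, 2])
        ref = tag_simple(t, spec)
        assert np.allclose(out.points, t.points, atol=1e-12)
        assert np.array_equal(out.cell_tags, ref.cell_tags)

    def test_non_distance_field_without_hook_rejected(self):
        s = sphere_with_z(3)
        with pytest.raises(InputError, match="recompute"):
            tag_harmonic(s, TagSpec(field_name="z", sigma=0.0, new_tag=7,
                                    rho=0.5))


class TestConnectivity:
    def test_biventricular_walls_get_three_tags(self):
        biv = two_cavity_shell(level=2)
        biv.cell_tags[:] = 1
        out = tag_connectivity(biv, {1})
        tags, counts = np.unique(out.cell_tags, return_counts=True)
        assert len(tags) == 3

    def test_component_count_matches_union_find_oracle(self):
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components as cc

        biv = two_cavity_shell(level=2)
        biv.cell_tags[:] = 1
        out = tag_connectivity(biv, {1})
        # oracle: union-find over shared edges via scipy
        em = {}
        for c, tri in enumerate(biv.triangles):
            for k in range(3):
                e = (min(tri[k], tri[(k + 1) % 3]),
                     max(tri[k], tri[(k + 1) % 3]))
                em.setdefault(e, []).append(c)
        rows, cols = [], []
        for faces in em.values():
            if len(faces) == 2:
                rows.append(faces[0])
                cols.append(faces[1])
        g = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(biv.n_cells, biv.n_cells))
        n_oracle, _ = cc(g, directed=False)
        assert len(np.unique(out.cell_tags)) == n_oracle

    def test_fully_connected_tag_just_renumbers(self, unit_icosphere):
        s = unit_icosphere.copy()
        out = tag_connectivity(s, {0})
        assert len(np.unique(out.cell_tags)) == 1


class TestCells:
    def test_empty_id_list_unchanged(self, unit_icosphere):
        out = tag_cells(unit_icosphere, cell_ids=[], new_tag=9)
        assert np.array_equal(out.cell_tags, unit_icosphere.cell_tags)

    def test_all_cells_uniform(self, unit_icosphere):
        out = tag_cells(unit_icosphere,
                        cell_ids=np.arange(unit_icosphere.n_cells),
                        new_tag=9)
        assert (out.cell_tags == 9).all()

    def test_seed_radius_matches_spherical_cap(self):
        s = icosphere(4)
        seed = int(np.argmax(s.points[s.triangles].mean(axis=1)[:, 2]))
        r = 0.8  # geodesic radius on the unit sphere
        out = tag_cells(s, seed=seed, radius=r, new_tag=9)
        cap_area = 2 * np.pi * (1 - np.cos(r))
        assert surface_area(out, tags={9}) == pytest.approx(cap_area,
                                                            rel=0.05)

    def test_out_of_range_id_rejected(self, unit_icosphere):
        with pytest.raises(InputError):
            tag_cells(unit_icosphere, cell_ids=[10 ** 6], new_tag=9)
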