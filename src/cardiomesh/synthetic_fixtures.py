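"""Deterministic generators of idealized cardiac-like geometries.

Closed smooth shells stand in for epicardium/endocardium segmentations,
nested two-cavity shells for biventricular walls, open tubes for atria
and vessels, thin-wall shells for the right-ventricular outflow tract,
and a truncated prolate ellipsoid for the classic idealized left
ventricle.  Every generator is purely deterministic: the same parameters
produce bit-identical output, so test fixtures never need to be stored
on disk.

All fixtures are manifold and outward-oriented; tagged fixtures use
small positive integers documented per generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .core_mesh import TriSurface, TetMesh, merge_surfaces
from .errors import InputError

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "icosphere",
    "shell",
    "two_cavity_shell",
    "tube",
    "annular_patch",
    "grid_patch",
    "cube_tet",
    "slab_tet",
    "ellipsoid_chamber",
    "truncated_ellipsoid",
    "star_tube",
]

# canonical tags used by the shell-like fixtures
OUTER_TAG = 1
INNER_TAG = 2
INNER_TAG_2 = 3
BASE_TAG = 3


# ---------------------------------------------------------------------------
# triangulated spheres
# ---------------------------------------------------------------------------

def icosphere(level: int = 3, radius: float = 1.0, center=(0.0, 0.0, 0.0),
              flip: bool = False) -> TriSurface:
    """Subdivided icosahedron: ``20 * 4**level`` triangles on a sphere.

    ``flip=True`` reverses the winding so normals point toward the
    center (used for cavity walls of shells).
    """
    if level < 0:
        raise InputError("subdivision level must be >= 0")
    t = (1.0 + np.sqrt(5.0)) / 2.0
    pts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    tris = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    for _ in range(level):
        pts, tris = _subdivide_sphere(pts, tris)
    if flip:
        tris = tris[:, [0, 2, 1]]
    return TriSurface(np.asarray(center) + radius * pts, tris)


def _subdivide_sphere(pts: np.ndarray, tris: np.ndarray):
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    mids = pts[uniq[:, 0]] + pts[uniq[:, 1]]
    mids /= np.linalg.norm(mids, axis=1)[:, None]
    mid_idx = len(pts) + np.arange(len(uniq))
    m = inv.reshape(3, -1).T + len(pts)  # m01, m12, m20 per triangle
    new_pts = np.concatenate([pts, mids])
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    m01, m12, m20 = m[:, 0], m[:, 1], m[:, 2]
    new_tris = np.concatenate([
        np.stack([a, m01, m20], axis=1),
        np.stack([b, m12, m01], axis=1),
        np.stack([c, m20, m12], axis=1),
        np.stack([m01, m12, m20], axis=1),
    ])
    return new_pts, new_tris


def shell(r_inner: float, r_outer: float, level: int = 3,
          center=(0.0, 0.0, 0.0)) -> TriSurface:
    """Concentric spherical wall: outer sphere (tag 1) + inner cavity (tag 2).

    The inner sphere is wound so its normals point into the cavity,
    i.e. outward from the wall material.
    """
    if not 0 < r_inner < r_outer:
        raise InputError("need 0 < r_inner < r_outer")
    outer = icosphere(level, r_outer, center)
    inner = icosphere(level, r_inner, center, flip=True)
    outer.cell_tags[:] = OUTER_TAG
    inner.cell_tags[:] = INNER_TAG
    out = merge_surfaces([outer, inner], tol=0.0)
    out.tag_names = {OUTER_TAG: "outer_wall", INNER_TAG: "inner_wall"}
    return out


def two_cavity_shell(outer_radius: float = 10.0, cavity_radius: float = 3.0,
                     offset: float = 4.0, level: int = 3) -> TriSurface:
    """Biventricular analog: outer sphere with two internal cavities.

    Tags: 1 outer wall, 2 cavity at (-offset, 0, 0), 3 cavity at
    (+offset, 0, 0).  Cavities must not intersect each other or the
    outer sphere.
    """
    if offset + cavity_radius >= outer_radius or 2 * cavity_radius >= 2 * offset:
        raise InputError("cavities intersect the outer wall or each other")
    outer = icosphere(level, outer_radius)
    c1 = icosphere(level, cavity_radius, (-offset, 0.0, 0.0), flip=True)
    c2 = icosphere(level, cavity_radius, (offset, 0.0, 0.0), flip=True)
    outer.cell_tags[:] = OUTER_TAG
    c1.cell_tags[:] = INNER_TAG
    c2.cell_tags[:] = INNER_TAG_2
    out = merge_surfaces([outer, c1, c2], tol=0.0)
    out.tag_names = {1: "epicardium", 2: "left_endocardium", 3: "right_endocardium"}
    return out


# ---------------------------------------------------------------------------
# tubes, patches
# ---------------------------------------------------------------------------

def tube(radius: float = 1.0, length: float = 2.0, n_circ: int = 24,
         n_axial: int = 12, center=(0.0, 0.0, 0.0)) -> TriSurface:
    """Open cylinder shell along z with two boundary rims (outward normals)."""
    if n_circ < 3 or n_axial < 1:
        raise InputError("need n_circ >= 3 and n_axial >= 1")
    phi = 2 * np.pi * np.arange(n_circ) / n_circ
    z = np.linspace(0.0, length, n_axial + 1)
    pts = np.array([
        [radius * np.cos(p), radius * np.sin(p), zz] for zz in z for p in phi
    ])
    tris = []
    for j in range(n_axial):
        for i in range(n_circ):
            a = j * n_circ + i
            b = j * n_circ + (i + 1) % n_circ
            c = a + n_circ
            d = b + n_circ
            tris.append([a, b, d])
            tris.append([a, d, c])
    return TriSurface(np.asarray(center) + pts, np.array(tris, dtype=np.int64))


def annular_patch(r_inner: float = 1.0, r_outer: float = 2.0, n_circ: int = 48,
                  n_radial: int = 8) -> TriSurface:
    """Flat annulus in the z=0 plane with inner and outer boundary rings."""
    if not 0 < r_inner < r_outer:
        raise InputError("need 0 < r_inner < r_outer")
    phi = 2 * np.pi * np.arange(n_circ) / n_circ
    r = np.linspace(r_inner, r_outer, n_radial + 1)
    pts = np.array([
        [rr * np.cos(p), rr * np.sin(p), 0.0] for rr in r for p in phi
    ])
    tris = []
    for j in range(n_radial):
        for i in range(n_circ):
            a = j * n_circ + i
            b = j * n_circ + (i + 1) % n_circ
            c = a + n_circ
            d = b + n_circ
            tris.append([a, b, d])
            tris.append([a, d, c])
    return TriSurface(pts, np.array(tris, dtype=np.int64))


def grid_patch(k: int = 8, size: float = 1.0) -> TriSurface:
    """Unit-square patch triangulated on a (k+1) x (k+1) grid in z=0."""
    if k < 1:
        raise InputError("k must be >= 1")
    xs = np.linspace(0.0, size, k + 1)
    pts = np.array([[x, y, 0.0] for y in xs for x in xs])
    tris = []
    for j in range(k):
        for i in range(k):
            a = j * (k + 1) + i
            b = a + 1
            c = a + (k + 1)
            d = c + 1
            tris.append([a, b, d])
            tris.append([a, d, c])
    return TriSurface(pts, np.array(tris, dtype=np.int64))


def star_tube(radii: np.ndarray, z0: float = 0.0, z1: float = 0.5,
              phase: float = 0.0) -> TriSurface:
    """One-strip open tube whose rim at ``z0`` is a star-shaped polygon.

    Used to manufacture parent surfaces with irregular boundary rings of
    arbitrary point count (e.g. for connection-band tests).
    """
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    if n < 3:
        raise InputError("need at least 3 radii")
    phi = phase + 2 * np.pi * np.arange(n) / n
    bottom = np.stack([radii * np.cos(phi), radii * np.sin(phi),
                       np.full(n, z0)], axis=1)
    top = bottom.copy()
    top[:, 2] = z1
    pts = np.concatenate([bottom, top])
    tris = []
    for i in range(n):
        a, b = i, (i + 1) % n
        tris.append([a, b, n + b])
        tris.append([a, n + b, n + a])
    return TriSurface(pts, np.array(tris, dtype=np.int64))


# ---------------------------------------------------------------------------
# tetrahedral fixtures
# ---------------------------------------------------------------------------

_KUHN_PATHS = [  # the 6 axis orderings of the Kuhn subdivision
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


def _box_tets(nx: int, ny: int, nz: int, lx: float, ly: float, lz: float,
              origin=(0.0, 0.0, 0.0)) -> TetMesh:
    xs = np.linspace(0, lx, nx + 1) + origin[0]
    ys = np.linspace(0, ly, ny + 1) + origin[1]
    zs = np.linspace(0, lz, nz + 1) + origin[2]

    def vid(i, j, k):
        return (k * (ny + 1) + j) * (nx + 1) + i

    pts = np.array([[x, y, z] for z in zs for y in ys for x in xs])
    tets = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                base = np.array([i, j, k])
                for path in _KUHN_PATHS:
                    corners = [base.copy()]
                    cur = base.copy()
                    for axis in path:
                        cur = cur.copy()
                        cur[axis] += 1
                        corners.append(cur)
                    tet = [vid(*c) for c in corners]
                    p = pts[tet]
                    vol = np.dot(p[1] - p[0], np.cross(p[2] - p[0], p[3] - p[0]))
                    if vol < 0:
                        tet[2], tet[3] = tet[3], tet[2]
                    tets.append(tet)
    tets = np.array(tets, dtype=np.int64)
    mesh = TetMesh(pts, tets)
    # tag boundary faces by the box side they lie on (1..6: -x,+x,-y,+y,-z,+z)
    faces = mesh.boundary_faces
    centers = pts[faces].mean(axis=1)
    tags = np.zeros(len(faces), dtype=np.int64)
    eps = 1e-9 * max(lx, ly, lz)
    lims = [(origin[0], origin[0] + lx), (origin[1], origin[1] + ly),
            (origin[2], origin[2] + lz)]
    for axis in range(3):
        lo, hi = lims[axis]
        tags[np.abs(centers[:, axis] - lo) < eps] = 2 * axis + 1
        tags[np.abs(centers[:, axis] - hi) < eps] = 2 * axis + 2
    mesh.boundary_tags = tags
    mesh.tag_names = {1: "-x", 2: "+x", 3: "-y", 4: "+y", 5: "-z", 6: "+z"}
    return mesh


def cube_tet(n: int = 2) -> TetMesh:
    """Unit cube split into ``6 n^3`` Kuhn tets; boundary faces tagged 1..6."""
    if n < 1:
        raise InputError("n must be >= 1")
    return _box_tets(n, n, n, 1.0, 1.0, 1.0)


def slab_tet(lx: float = 1.0, ly: float = 1.0, lz: float = 0.2,
             nx: int = 2, ny: int = 2, nz: int = 1,
             origin=(0.0, 0.0, 0.0)) -> TetMesh:
    """Rectangular slab of Kuhn tets (boundary tagged per side, 1..6)."""
    return _box_tets(nx, ny, nz, lx, ly, lz, origin)


# ---------------------------------------------------------------------------
# idealized left ventricle
# ---------------------------------------------------------------------------

def truncated_ellipsoid(a: float = 20.0, c: float = 40.0, cut_z: float = 15.0,
                        n_circ: int = 32, n_axial: int = 16,
                        flip: bool = False) -> TriSurface:
    """Prolate ellipsoid (semi-axes a, a, c) truncated at ``z = cut_z``.

    Open surface with apex at ``z = -c`` and a single circular base ring
    at the truncation plane.  Outward normals by default.
    """
    if not -c < cut_z < c:
        raise InputError("cut plane must intersect the ellipsoid")
    theta0 = np.arccos(cut_z / c)
    thetas = theta0 + (np.pi - theta0) * np.arange(n_axial) / n_axial
    phi = 2 * np.pi * np.arange(n_circ) / n_circ
    pts = [
        [a * np.sin(t) * np.cos(p), a * np.sin(t) * np.sin(p), c * np.cos(t)]
        for t in thetas for p in phi
    ]
    apex = len(pts)
    pts.append([0.0, 0.0, -c])
    tris = []
    for j in range(n_axial - 1):
        for i in range(n_circ):
            p0 = j * n_circ + i
            p1 = j * n_circ + (i + 1) % n_circ
            q0 = p0 + n_circ
            q1 = p1 + n_circ
            tris.append([p0, q0, q1])
            tris.append([p0, q1, p1])
    for i in range(n_circ):
        p0 = (n_axial - 1) * n_circ + i
        p1 = (n_axial - 1) * n_circ + (i + 1) % n_circ
        tris.append([p0, apex, p1])
    tris = np.array(tris, dtype=np.int64)
    if flip:
        tris = tris[:, [0, 2, 1]]
    return TriSurface(np.array(pts), tris)


def ellipsoid_chamber(a: float = 20.0, c: float = 40.0, cut_z: float = 15.0,
                      wall: float = 0.0, n_circ: int = 32,
                      n_axial: int = 16) -> TriSurface:
    """Idealized left ventricle.

    With ``wall == 0``: the blood-pool cavity — a truncated ellipsoid
    closed by a flat fan cap at the base (tags: 1 wall, 3 base cap).
    With ``wall > 0``: the myocardial shell between an outer ellipsoid
    (tag 1) and an inner one offset by ``wall`` (tag 2), closed by a
    flat base band (tag 3) connecting the two base rings.
    """
    outer = truncated_ellipsoid(a, c, cut_z, n_circ, n_axial)
    outer.cell_tags[:] = OUTER_TAG
    if wall <= 0:
        # cap: the base row is row j=0 (theta0) -> indices 0..n_circ-1
        ring = np.arange(n_circ)
        center = outer.points[ring].mean(axis=0)
        pts = np.concatenate([outer.points, center[None, :]])
        cid = len(pts) - 1
        cap = [[ring[i], ring[(i + 1) % n_circ], cid] for i in range(n_circ)]
        tris = np.concatenate([outer.triangles, np.array(cap, dtype=np.int64)])
        tags = np.concatenate([outer.cell_tags,
                               np.full(n_circ, BASE_TAG, dtype=np.int64)])
        out = TriSurface(pts, tris, tags)
        out.tag_names = {OUTER_TAG: "endocardium", BASE_TAG: "base"}
        return out
    if wall >= min(a, c - cut_z):
        raise InputError("wall too thick for the chamber dimensions")
    inner = truncated_ellipsoid(a - wall, c - wall,
                                cut_z * (c - wall) / c, n_circ, n_axial,
                                flip=True)
    inner.cell_tags[:] = INNER_TAG
    # flat base band between the two base rings (both at z ~ cut planes)
    n_out = outer.n_points
    ring_o = np.arange(n_circ)
    ring_i = np.arange(n_circ) + n_out
    pts = np.concatenate([outer.points, inner.points])
    band = []
    for i in range(n_circ):
        a0, a1 = ring_o[i], ring_o[(i + 1) % n_circ]
        b0, b1 = ring_i[i], ring_i[(i + 1) % n_circ]
        band.append([a0, a1, b1])
        band.append([a0, b1, b0])
    tris = np.concatenate([outer.triangles,
                           inner.triangles + n_out,
                           np.array(band, dtype=np.int64)])
    tags = np.concatenate([outer.cell_tags, inner.cell_tags,
                           np.full(2 * n_circ, BASE_TAG, dtype=np.int64)])
    out = TriSurface(pts, tris, tags)
    out.tag_names = {OUTER_TAG: "epicardium", INNER_TAG: "endocardium",
                     BASE_TAG: "base"}
    return out


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

_GENERATORS = {
    "icosphere": icosphere,
    "shell": shell,
    "two_cavity_shell": two_cavity_shell,
    "tube": tube,
    "annular_patch": annular_patch,
    "grid_patch": grid_patch,
    "cube_tet": cube_tet,
    "slab_tet": slab_tet,
    "ellipsoid_chamber": ellipsoid_chamber,
    "star_tube": star_tube,
    "truncated_ellipsoid": truncated_ellipsoid,
}


@dataclass
class FixtureSpec:
    """Named fixture kind plus its geometric parameters."""

    kind: str
    params: dict = dc_field(default_factory=dict)


def make_fixture(spec: FixtureSpec):
    """Build the fixture described by ``spec`` (TriSurface or TetMesh)."""
    if spec.kind not in _GENERATORS:
        raise InputError(
            f"unknown fixture kind {spec.kind!r}; "
            f"choose from {sorted(_GENERATORS)}"
        )
    return _GENERATORS[spec.kind](**spec.params)
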