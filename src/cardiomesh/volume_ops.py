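"""Volumetric mesh processing: connection, refinement, tet-to-hex.

* ``tetrahedralize`` is a backend seam: any tetrahedralizer preserving
  the boundary triangulation can be plugged in; the built-in fallback
  cones every boundary triangle to the centroid and is valid exactly
  for star-shaped regions.
* ``mesh_connection`` joins two tagged tet meshes by zipper-building
  wall surfaces between paired boundary rings, remeshing the walls,
  tetrahedralizing the enclosed gap and merging everything conformingly.
* ``refine_mesh`` is a conforming longest-edge bisection driven by a
  clamped power-law sizing function, with barycenter tag projection.
* ``tet_to_hex`` splits each tet into four hexahedra (each boundary
  triangle into three quads) and optionally refines by splitting every
  hex into eight (RBS), halving the mesh size per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_mesh import (
    TriSurface, TetMesh, HexMesh, Ring, extract_boundary_rings,
    extract_surface, extract_tags, merge_surfaces, boundary_faces_of,
    tet_volumes, is_closed, enclosed_volume,
)
from .surface_connect import connect_rings, pair_rings
from .errors import InputError, TopologyError

__all__ = [
    "ConnectionSpec",
    "RefineSpec",
    "TetHexSpec",
    "tetrahedralize",
    "mesh_connection",
    "refine_mesh",
    "tet_to_hex",
]


# ---------------------------------------------------------------------------
# tetrahedralization seam
# ---------------------------------------------------------------------------

def tetrahedralize(boundary: TriSurface, size: float | None = None,
                   backend=None) -> TetMesh:
    """Fill a closed surface with tets, preserving its triangulation.

    ``backend`` may be any callable ``(boundary, size) -> TetMesh``
    fulfilling the boundary-preservation contract.  The built-in
    fallback places one apex at the centroid and cones every boundary
    triangle to it; it requires the region to be star-shaped with
    respect to the centroid and raises otherwise.
    """
    if backend is not None:
        return backend(boundary, size)
    if not is_closed(boundary):
        raise TopologyError("tetrahedralization needs a closed surface")
    if enclosed_volume(boundary) <= 0:
        raise TopologyError("boundary must be outward-oriented")
    pts = boundary.points
    tris = boundary.triangles
    centroid = pts.mean(axis=0)
    a, b, c = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    n = np.cross(b - a, c - a)
    vis = np.einsum("ij,ij->i", n, centroid - a)
    if np.any(vis >= 0):
        raise TopologyError(
            "region not star-shaped with respect to its centroid; an "
            "external tetrahedralization backend is required"
        )
    apex = len(pts)
    new_pts = np.concatenate([pts, centroid[None, :]])
    tets = np.column_stack([
        tris[:, 1], tris[:, 0], tris[:, 2],
        np.full(len(tris), apex, dtype=np.int64),
    ])
    return TetMesh(new_pts, tets,
                   boundary_faces=tris.copy(),
                   boundary_tags=boundary.cell_tags.copy(),
                   tag_names=dict(boundary.tag_names))


# ---------------------------------------------------------------------------
# mesh connection
# ---------------------------------------------------------------------------

@dataclass
class ConnectionSpec:
    """Which boundary tags to connect and at which wall mesh size."""

    tags_1: set
    tags_2: set
    h: float = 0.5
    pairing: object = "auto"     # "auto" or explicit [(i, j), ...]
    remesh_walls: bool = True

    def __post_init__(self):
        if self.h <= 0:
            raise InputError("h must be positive")
        if not self.tags_1 or not self.tags_2:
            raise InputError("both tag sets must be non-empty")


def _orient_outward(surface: TriSurface) -> TriSurface:
    """Flip triangles until winding is consistent and globally outward."""
    out = surface.copy()
    tris = out.triangles
    em: dict = {}
    for f, t in enumerate(tris):
        for k in range(3):
            e = (min(t[k], t[(k + 1) % 3]), max(t[k], t[(k + 1) % 3]))
            em.setdefault(e, []).append(f)
    flipped = np.zeros(len(tris), dtype=bool)
    seen = np.zeros(len(tris), dtype=bool)
    for seed in range(len(tris)):
        if seen[seed]:
            continue
        stack = [seed]
        seen[seed] = True
        while stack:
            f = stack.pop()
            t = tris[f] if not flipped[f] else tris[f][::-1]
            dir_edges = {(t[k], t[(k + 1) % 3]) for k in range(3)}
            for k in range(3):
                e = (min(t[k], t[(k + 1) % 3]), max(t[k], t[(k + 1) % 3]))
                for g in em[e]:
                    if g == f or seen[g]:
                        continue
                    tg = tris[g] if not flipped[g] else tris[g][::-1]
                    g_edges = {(tg[j], tg[(j + 1) % 3]) for j in range(3)}
                    if dir_edges & g_edges:
                        flipped[g] = True
                    seen[g] = True
                    stack.append(g)
    out.triangles = np.where(flipped[:, None], tris[:, ::-1], tris)
    if is_closed(out) and enclosed_volume(out) < 0:
        out.triangles = out.triangles[:, ::-1]
    return out


def mesh_connection(m1: TetMesh, m2: TetMesh,
                    spec: ConnectionSpec) -> TetMesh:
    """Join two disjoint tet meshes with a generated connecting volume.

    The tagged boundary patches ``tags_1``/``tags_2`` are joined ring
    by ring with zipper walls (one fresh tag per wall), the walls are
    remeshed at ``h`` with the patch triangulations frozen, the closed
    wall surface is tetrahedralized, and the three meshes are merged
    into one conforming mesh with volume tags 1, 2, 3.
    """
    S1 = extract_surface(m1)
    S2 = extract_surface(m2)
    T1 = extract_tags(S1, spec.tags_1)
    T2 = extract_tags(S2, spec.tags_2)
    if T1.n_cells == 0 or T2.n_cells == 0:
        raise InputError("a connection tag set selects no boundary faces")
    rings1 = extract_boundary_rings(T1)
    rings2 = extract_boundary_rings(T2)
    if len(rings1) != len(rings2):
        raise TopologyError(
            f"regions are not topologically equivalent: "
            f"{len(rings1)} vs {len(rings2)} boundary rings"
        )
    merged = merge_surfaces([T1, T2], tol=0.0)
    off = T1.n_points
    max_tag = int(max(m1.boundary_tags.max(initial=0),
                      m2.boundary_tags.max(initial=0),
                      m1.cell_tags.max(initial=0),
                      m2.cell_tags.max(initial=0)))
    if spec.pairing == "auto":
        pairs = pair_rings(rings1, rings2)
    else:
        pairs = list(spec.pairing)
    wall_tags = []
    for j, (i1, i2) in enumerate(pairs):
        wall_tag = max_tag + 1 + j
        wall_tags.append(wall_tag)
        merged = connect_rings(
            merged,
            Ring(merged, rings1[i1].point_indices),
            Ring(merged, rings2[i2].point_indices + off),
            wall_tag,
        )
    sigma3 = _orient_outward(merged)
    if spec.remesh_walls:
        from .remeshing import RemeshSpec, isotropic_remesh

        sigma3 = isotropic_remesh(
            sigma3, RemeshSpec(size_field=spec.h, target_tags=set(wall_tags))
        )
    # the connection surface may consist of several closed components
    # (e.g. two disjoint wall prisms); fill each separately
    from .core_mesh import connected_components

    parts = [tetrahedralize(_orient_outward(comp), spec.h)
             for comp in connected_components(sigma3)]
    omega3 = _concat_tet_meshes(parts)
    return _merge_tet_meshes(m1, m2, omega3, wall_tags)


def _concat_tet_meshes(parts: list[TetMesh]) -> TetMesh:
    if len(parts) == 1:
        return parts[0]
    pts = np.concatenate([p.points for p in parts])
    offs = np.cumsum([0] + [p.n_points for p in parts])
    return TetMesh(
        pts,
        np.concatenate([p.tets + offs[i] for i, p in enumerate(parts)]),
        np.concatenate([p.cell_tags for p in parts]),
        np.concatenate([p.boundary_faces + offs[i]
                        for i, p in enumerate(parts)]),
        np.concatenate([p.boundary_tags for p in parts]),
    )


def _merge_tet_meshes(m1: TetMesh, m2: TetMesh, m3: TetMesh,
                      wall_tags) -> TetMesh:
    pts = np.concatenate([m1.points, m2.points, m3.points])
    offs = np.cumsum([0, m1.n_points, m2.n_points])
    diag = float(np.linalg.norm(pts.max(0) - pts.min(0)))
    tree = cKDTree(pts)
    pairs = tree.query_pairs(1e-9 * diag, output_type="ndarray")
    parent = np.arange(len(pts))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    root = np.array([find(i) for i in range(len(pts))])
    keep, remap = np.unique(root, return_inverse=True)
    new_pts = pts[keep]
    tets = np.concatenate([
        remap[m1.tets + offs[0]],
        remap[m2.tets + offs[1]],
        remap[m3.tets + offs[2]],
    ])
    vol_tags = np.concatenate([
        np.full(m1.n_cells, 1, dtype=np.int64),
        np.full(m2.n_cells, 2, dtype=np.int64),
        np.full(m3.n_cells, 3, dtype=np.int64),
    ])
    face_tag: dict = {}
    for mesh, off in ((m1, offs[0]), (m2, offs[1]), (m3, offs[2])):
        for face, tag in zip(mesh.boundary_faces, mesh.boundary_tags):
            key = frozenset(remap[np.asarray(face) + off].tolist())
            face_tag[key] = int(tag)
    bfaces = boundary_faces_of(tets)
    btags = np.array([face_tag.get(frozenset(f.tolist()), 0) for f in bfaces],
                     dtype=np.int64)
    names = dict(m1.tag_names)
    names.update(m2.tag_names)
    for w in wall_tags:
        names[w] = f"connection_wall_{w}"
    return TetMesh(new_pts, tets, vol_tags, bfaces, btags, tag_names=names)


# ---------------------------------------------------------------------------
# sizing-driven refinement
# ---------------------------------------------------------------------------

@dataclass
class RefineSpec:
    """Sizing function ``h(x) = max(m, alpha * f(x)**beta)`` parameters."""

    field_name: str
    alpha: float = 1.0
    beta: float = 1.0
    m: float = 0.0

    def __post_init__(self):
        if self.m <= 0:
            raise InputError("minimum mesh-size m must be positive "
                             "(m = 0 allows unbounded refinement)")


_EDGE_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_SIZE_SLACK = 1.5


def refine_mesh(mesh: TetMesh, spec: RefineSpec) -> TetMesh:
    """Conforming longest-edge bisection toward a sizing function.

    Tets whose longest edge exceeds ``1.5 * h(barycenter)`` are bisected
    through that edge; every tet sharing a split edge is bisected too,
    so the mesh stays conforming.  All tags are inherited by children,
    which coincides with barycenter projection from the input mesh.
    Point fields are interpolated at the new midpoints.
    """
    if spec.field_name not in mesh.point_fields:
        raise InputError(f"missing point field {spec.field_name!r}")
    V = [p.copy() for p in mesh.points]
    PF = {k: [np.array(x) for x in np.asarray(v)]
          for k, v in mesh.point_fields.items()}
    tets: list = [list(map(int, t)) for t in mesh.tets]
    ttags: list = list(map(int, mesh.cell_tags))
    tet_alive: list = [True] * len(tets)
    faces: list = [list(map(int, f)) for f in mesh.boundary_faces]
    ftags: list = list(map(int, mesh.boundary_tags))
    face_alive: list = [True] * len(faces)
    fname = spec.field_name

    edge2tets: dict = {}
    edge2faces: dict = {}

    def ekey(a, b):
        return (a, b) if a < b else (b, a)

    for c, t in enumerate(tets):
        for a, b in _EDGE_PAIRS:
            edge2tets.setdefault(ekey(t[a], t[b]), set()).add(c)
    for c, f in enumerate(faces):
        for k in range(3):
            edge2faces.setdefault(ekey(f[k], f[(k + 1) % 3]), set()).add(c)

    def target_h(bary_f: float) -> float:
        return max(spec.m, spec.alpha * bary_f ** spec.beta)

    def longest_edge(t):
        best = (-1.0, None)
        for a, b in _EDGE_PAIRS:
            L = float(np.linalg.norm(V[t[a]] - V[t[b]]))
            if L > best[0]:
                best = (L, ekey(t[a], t[b]))
        return best

    def split_edge(a, b):
        mid = len(V)
        V.append(0.5 * (V[a] + V[b]))
        for k in PF:
            PF[k].append(0.5 * (PF[k][a] + PF[k][b]))
        key = ekey(a, b)
        for c in list(edge2tets.get(key, ())):
            if not tet_alive[c]:
                continue
            tet_alive[c] = False
            t = tets[c]
            for x, y in _EDGE_PAIRS:
                edge2tets[ekey(t[x], t[y])].discard(c)
            for child in ([mid if i == b else i for i in t],
                          [mid if i == a else i for i in t]):
                cid = len(tets)
                tets.append(child)
                ttags.append(ttags[c])
                tet_alive.append(True)
                for x, y in _EDGE_PAIRS:
                    edge2tets.setdefault(
                        ekey(child[x], child[y]), set()).add(cid)
        for c in list(edge2faces.get(key, ())):
            if not face_alive[c]:
                continue
            face_alive[c] = False
            f = faces[c]
            for k in range(3):
                edge2faces[ekey(f[k], f[(k + 1) % 3])].discard(c)
            for child in ([mid if i == b else i for i in f],
                          [mid if i == a else i for i in f]):
                cid = len(faces)
                faces.append(child)
                ftags.append(ftags[c])
                face_alive.append(True)
                for k in range(3):
                    edge2faces.setdefault(
                        ekey(child[k], child[(k + 1) % 3]), set()).add(cid)

    while True:
        marked: dict = {}
        for c, t in enumerate(tets):
            if not tet_alive[c]:
                continue
            L, edge = longest_edge(t)
            fbar = float(np.mean([PF[fname][i] for i in t]))
            if L > _SIZE_SLACK * target_h(fbar):
                marked[edge] = max(marked.get(edge, 0.0), L)
        if not marked:
            break
        for (a, b), _ in sorted(marked.items(), key=lambda kv: -kv[1]):
            if edge2tets.get((a, b)):
                split_edge(a, b)
    live_t = [c for c in range(len(tets)) if tet_alive[c]]
    live_f = [c for c in range(len(faces)) if face_alive[c]]
    return TetMesh(
        np.array(V),
        np.array([tets[c] for c in live_t], dtype=np.int64),
        np.array([ttags[c] for c in live_t], dtype=np.int64),
        np.array([faces[c] for c in live_f], dtype=np.int64),
        np.array([ftags[c] for c in live_f], dtype=np.int64),
        {k: np.array(v) for k, v in PF.items()},
        tag_names=dict(mesh.tag_names),
    )


# ---------------------------------------------------------------------------
# tet -> hex
# ---------------------------------------------------------------------------

@dataclass
class TetHexSpec:
    """Number of refine-by-splitting iterations applied after conversion."""

    n_rbs: int = 0

    def __post_init__(self):
        if self.n_rbs < 0:
            raise InputError("n_rbs must be non-negative")


class _PointPool:
    """Shared points keyed by the set of parent corners they average."""

    def __init__(self, points: np.ndarray):
        self.coords: list = [p.copy() for p in points]
        self.key2id: dict = {frozenset([i]): i for i in range(len(points))}

    def get(self, corners) -> int:
        key = frozenset(corners)
        if key not in self.key2id:
            self.key2id[key] = len(self.coords)
            self.coords.append(
                np.mean([self.coords[i] for i in sorted(set(corners))], axis=0)
            )
        return self.key2id[key]


def tet_to_hex(mesh: TetMesh, spec: TetHexSpec | None = None) -> HexMesh:
    """Convert each tet to 4 hexes and each boundary triangle to 3 quads.

    New points appear only at edge midpoints, face barycenters and cell
    barycenters, so the total volume is conserved exactly; the node
    ordering keeps all corner Jacobians positive on valid tets.  RBS
    iterations split each hex into 8 (each quad into 4).
    """
    if spec is None:
        spec = TetHexSpec()
    vols = tet_volumes(mesh.points, mesh.tets)
    if len(vols) and vols.min() <= 0:
        raise TopologyError("input contains inverted tets")
    pool = _PointPool(mesh.points)
    hexes, htags = [], []
    for t, tag in zip(mesh.tets, mesh.cell_tags):
        t = list(map(int, t))
        c = pool.get(t)
        for idx in range(4):
            i = t[idx]
            rest = t[:idx] + t[idx + 1:]
            j, k, l = rest
            p = [np.asarray(pool.coords[v]) for v in (i, j, k, l)]
            if np.dot(p[1] - p[0], np.cross(p[2] - p[0], p[3] - p[0])) < 0:
                j, k, l = j, l, k
            hexes.append([
                i, pool.get((i, j)), pool.get((i, j, k)), pool.get((i, k)),
                pool.get((i, l)), pool.get((i, j, l)), c, pool.get((i, k, l)),
            ])
            htags.append(int(tag))
    quads, qtags = [], []
    for f, tag in zip(mesh.boundary_faces, mesh.boundary_tags):
        a, b, c3 = map(int, f)
        fb = pool.get((a, b, c3))
        for (v, n1, n2) in ((a, b, c3), (b, c3, a), (c3, a, b)):
            quads.append([v, pool.get((v, n1)), fb, pool.get((v, n2))])
            qtags.append(int(tag))
    for _ in range(spec.n_rbs):
        hexes, htags, quads, qtags = _rbs(pool, hexes, htags, quads, qtags)
    out = HexMesh(
        np.array(pool.coords), np.array(hexes, dtype=np.int64),
        np.array(htags, dtype=np.int64),
        np.array(quads, dtype=np.int64) if quads else None,
        np.array(qtags, dtype=np.int64) if quads else None,
        tag_names=dict(mesh.tag_names),
    )
    return out


# hex corner -> trilinear coordinates under the conventional ordering
_HEX_UVW = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
            (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
_UVW_HEX = {uvw: i for i, uvw in enumerate(_HEX_UVW)}


def _rbs(pool: _PointPool, hexes, htags, quads, qtags):
    """One refine-by-splitting pass: hex -> 8 hexes, quad -> 4 quads."""

    def grid_id(cell, u, v, w):
        # point at trilinear coords (u, v, w)/2 of the hex, as a corner set
        corners = []
        for du in {0, 1} if u == 1 else {u // 2}:
            for dv in {0, 1} if v == 1 else {v // 2}:
                for dw in {0, 1} if w == 1 else {w // 2}:
                    corners.append(cell[_UVW_HEX[(du, dv, dw)]])
        return pool.get(corners)

    new_hexes, new_htags = [], []
    for cell, tag in zip(hexes, htags):
        for ou in (0, 1):
            for ov in (0, 1):
                for ow in (0, 1):
                    sub = [grid_id(cell, ou + du, ov + dv, ow + dw)
                           for (du, dv, dw) in _HEX_UVW]
                    new_hexes.append(sub)
                    new_htags.append(tag)
    new_quads, new_qtags = [], []
    for q, tag in zip(quads, qtags):
        center = pool.get(tuple(q))
        mids = [pool.get((q[i], q[(i + 1) % 4])) for i in range(4)]
        for i in range(4):
            new_quads.append([q[i], mids[i], center, mids[(i - 1) % 4]])
            new_qtags.append(tag)
    return new_hexes, new_htags, new_quads, new_qtags
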