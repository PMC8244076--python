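"""Mesh data model, topology utilities and validation.

Containers for tagged triangulated surfaces, boundary rings and tagged
tetrahedral / hexahedral volume meshes, together with the topology
operations every processing algorithm relies on: boundary-ring
extraction, connected components, duplicate-point merging and warping.

Conventions
-----------
* 0-based indexing everywhere; coordinates in millimetres.
* Closed surfaces are wound counter-clockwise viewed from outside, so
  right-hand-rule triangle normals point outward.
* Boundary rings are ordered so that traversal keeps the surface on the
  left (i.e. they follow the directed boundary edges of the winding).
* Cell tags are integers stored in ``cell_tags``; ``tag_names`` maps a
  tag to a human-readable label (e.g. ``{1: "epicardium"}``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError, TopologyError

__all__ = [
    "TriSurface",
    "Ring",
    "TetMesh",
    "HexMesh",
    "extract_boundary_rings",
    "connected_components",
    "merge_surfaces",
    "warp",
    "triangle_areas",
    "triangle_normals",
    "vertex_normals",
    "surface_area",
    "enclosed_volume",
    "euler_characteristic",
    "edge_face_count",
    "is_closed",
    "validate_surface",
    "tet_volumes",
    "extract_surface",
    "extract_cells",
    "validate_tetmesh",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"points must be (n, 3), got {pts.shape}")
    return pts


def _as_cells(cells, width: int) -> np.ndarray:
    arr = np.asarray(cells, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, width)
    if arr.ndim != 2 or arr.shape[1] != width:
        raise InputError(f"cells must be (m, {width}), got {arr.shape}")
    return arr


@dataclass
class TriSurface:
    """Tagged triangulated surface (2-manifold, possibly with boundary)."""

    points: np.ndarray
    triangles: np.ndarray
    cell_tags: np.ndarray = None
    point_fields: dict = field(default_factory=dict)
    cell_fields: dict = field(default_factory=dict)
    tag_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = _as_points(self.points)
        self.triangles = _as_cells(self.triangles, 3)
        if self.cell_tags is None:
            self.cell_tags = np.zeros(len(self.triangles), dtype=np.int64)
        else:
            self.cell_tags = np.asarray(self.cell_tags, dtype=np.int64)
            if self.cell_tags.shape != (len(self.triangles),):
                raise InputError("cell_tags length must match triangle count")
        if len(self.triangles) and self.triangles.max() >= len(self.points):
            raise InputError("triangle index out of range")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.triangles)

    def copy(self) -> "TriSurface":
        return TriSurface(
            self.points.copy(),
            self.triangles.copy(),
            self.cell_tags.copy(),
            {k: np.array(v) for k, v in self.point_fields.items()},
            {k: np.array(v) for k, v in self.cell_fields.items()},
            dict(self.tag_names),
        )

    def tags(self) -> np.ndarray:
        """Sorted unique cell tags present on the surface."""
        return np.unique(self.cell_tags)

    def bbox_diagonal(self) -> float:
        if self.n_points == 0:
            return 0.0
        return float(np.linalg.norm(self.points.max(0) - self.points.min(0)))


@dataclass
class Ring:
    """Ordered closed boundary polyline of a parent surface.

    ``point_indices`` is cyclic: the last index connects back to the
    first.  Rings produced by :func:`extract_boundary_rings` keep the
    surface on the left of the traversal direction.
    """

    surface: TriSurface
    point_indices: np.ndarray

    def __post_init__(self):
        self.point_indices = np.asarray(self.point_indices, dtype=np.int64)
        if self.n < 3:
            raise InputError("a ring needs at least 3 points")
        if len(np.unique(self.point_indices)) != self.n:
            raise InputError("ring contains repeated point indices")
        if self.point_indices.max() >= self.surface.n_points:
            raise InputError("ring index out of range of parent surface")

    @property
    def n(self) -> int:
        return len(self.point_indices)

    @property
    def coords(self) -> np.ndarray:
        return self.surface.points[self.point_indices]

    def reversed(self) -> "Ring":
        return Ring(self.surface, self.point_indices[::-1].copy())

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class TetMesh:
    """Tagged tetrahedral volume mesh with tagged boundary faces.

    Tets follow the positive-volume ordering convention
    ``det[p1-p0, p2-p0, p3-p0] > 0``.  ``boundary_faces`` are the
    triangles belonging to exactly one tet, stored outward-oriented,
    with an integer tag each (``boundary_tags``).
    """

    points: np.ndarray
    tets: np.ndarray
    cell_tags: np.ndarray = None
    boundary_faces: np.ndarray = None
    boundary_tags: np.ndarray = None
    point_fields: dict = field(default_factory=dict)
    cell_fields: dict = field(default_factory=dict)
    tag_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = _as_points(self.points)
        self.tets = _as_cells(self.tets, 4)
        if self.cell_tags is None:
            self.cell_tags = np.zeros(len(self.tets), dtype=np.int64)
        else:
            self.cell_tags = np.asarray(self.cell_tags, dtype=np.int64)
        if self.boundary_faces is None:
            self.boundary_faces = boundary_faces_of(self.tets)
        else:
            self.boundary_faces = _as_cells(self.boundary_faces, 3)
        if self.boundary_tags is None:
            self.boundary_tags = np.zeros(len(self.boundary_faces), dtype=np.int64)
        else:
            self.boundary_tags = np.asarray(self.boundary_tags, dtype=np.int64)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.tets)

    def copy(self) -> "TetMesh":
        return TetMesh(
            self.points.copy(), self.tets.copy(), self.cell_tags.copy(),
            self.boundary_faces.copy(), self.boundary_tags.copy(),
            {k: np.array(v) for k, v in self.point_fields.items()},
            {k: np.array(v) for k, v in self.cell_fields.items()},
            dict(self.tag_names),
        )

    def volume(self) -> float:
        return float(tet_volumes(self.points, self.tets).sum())


@dataclass
class HexMesh:
    """Tagged hexahedral mesh (conventional node ordering).

    Hex nodes: bottom quad counter-clockwise seen from below the cell,
    then the matching top quad (VTK hexahedron convention).
    """

    points: np.ndarray
    hexes: np.ndarray
    cell_tags: np.ndarray = None
    boundary_quads: np.ndarray = None
    boundary_tags: np.ndarray = None
    point_fields: dict = field(default_factory=dict)
    cell_fields: dict = field(default_factory=dict)
    tag_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = _as_points(self.points)
        self.hexes = _as_cells(self.hexes, 8)
        if self.cell_tags is None:
            self.cell_tags = np.zeros(len(self.hexes), dtype=np.int64)
        else:
            self.cell_tags = np.asarray(self.cell_tags, dtype=np.int64)
        if self.boundary_quads is None:
            self.boundary_quads = np.zeros((0, 4), dtype=np.int64)
        else:
            self.boundary_quads = _as_cells(self.boundary_quads, 4)
        if self.boundary_tags is None:
            self.boundary_tags = np.zeros(len(self.boundary_quads), dtype=np.int64)
        else:
            self.boundary_tags = np.asarray(self.boundary_tags, dtype=np.int64)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.hexes)

    def volumes(self) -> np.ndarray:
        """Exact per-hex volume of the trilinear cell.

        The Jacobian determinant of the trilinear map has polynomial
        degree <= 2 per reference coordinate, so 2x2x2 Gauss quadrature
        integrates it exactly.
        """
        corners = self.points[self.hexes]            # (m, 8, 3)
        g = 0.5 + np.array([-0.5, 0.5]) / np.sqrt(3.0)
        uvw = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],
                       dtype=float)
        vols = np.zeros(len(self.hexes))
        for u in g:
            for v in g:
                for w in g:
                    shp = ((u * uvw[:, 0] + (1 - u) * (1 - uvw[:, 0]))
                           * (v * uvw[:, 1] + (1 - v) * (1 - uvw[:, 1]))
                           * (w * uvw[:, 2] + (1 - w) * (1 - uvw[:, 2])))
                    du = ((2 * uvw[:, 0] - 1)
                          * (v * uvw[:, 1] + (1 - v) * (1 - uvw[:, 1]))
                          * (w * uvw[:, 2] + (1 - w) * (1 - uvw[:, 2])))
                    dv = ((u * uvw[:, 0] + (1 - u) * (1 - uvw[:, 0]))
                          * (2 * uvw[:, 1] - 1)
                          * (w * uvw[:, 2] + (1 - w) * (1 - uvw[:, 2])))
                    dw = ((u * uvw[:, 0] + (1 - u) * (1 - uvw[:, 0]))
                          * (v * uvw[:, 1] + (1 - v) * (1 - uvw[:, 1]))
                          * (2 * uvw[:, 2] - 1))
                    Ju = np.einsum("c,mci->mi", du, corners)
                    Jv = np.einsum("c,mci->mi", dv, corners)
                    Jw = np.einsum("c,mci->mi", dw, corners)
                    vols += 0.125 * np.einsum(
                        "mi,mi->m", Ju, np.cross(Jv, Jw))
                    del shp
        return vols

    def corner_jacobians(self) -> np.ndarray:
        """(m, 8) Jacobian determinant of the trilinear map at each corner."""
        p = self.points
        h = self.hexes
        # edge-neighbor triples ordered so right-handed cells give det > 0
        nbrs = [(1, 3, 4), (2, 0, 5), (3, 1, 6), (0, 2, 7),
                (7, 5, 0), (4, 6, 1), (5, 7, 2), (6, 4, 3)]
        out = np.empty((len(h), 8))
        for c, (i, j, k) in enumerate(nbrs):
            e1 = p[h[:, i]] - p[h[:, c]]
            e2 = p[h[:, j]] - p[h[:, c]]
            e3 = p[h[:, k]] - p[h[:, c]]
            out[:, c] = np.einsum("mi,mi->m", e1, np.cross(e2, e3))
        return out


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def triangle_normals(surface: TriSurface, normalized: bool = True) -> np.ndarray:
    p = surface.points
    t = surface.triangles
    n = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
    if normalized:
        lens = np.linalg.norm(n, axis=1)
        lens[lens == 0] = 1.0
        n = n / lens[:, None]
    return n


def triangle_areas(surface: TriSurface) -> np.ndarray:
    return 0.5 * np.linalg.norm(triangle_normals(surface, normalized=False), axis=1)


def surface_area(surface: TriSurface, tags=None) -> float:
    areas = triangle_areas(surface)
    if tags is not None:
        areas = areas[np.isin(surface.cell_tags, list(tags))]
    return float(areas.sum())


def vertex_normals(surface: TriSurface) -> np.ndarray:
    """Angle-weighted vertex normals (unit length)."""
    p = surface.points
    t = surface.triangles
    fn = triangle_normals(surface)
    out = np.zeros_like(p)
    for k in range(3):
        a = p[t[:, (k + 1) % 3]] - p[t[:, k]]
        b = p[t[:, (k + 2) % 3]] - p[t[:, k]]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.clip(
            np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-300), -1.0, 1.0
        )
        ang = np.arccos(cosang)
        np.add.at(out, t[:, k], fn * ang[:, None])
    lens = np.linalg.norm(out, axis=1)
    lens[lens == 0] = 1.0
    return out / lens[:, None]


def enclosed_volume(surface: TriSurface) -> float:
    """Signed volume enclosed by a closed surface (positive if outward)."""
    p = surface.points
    t = surface.triangles
    return float(
        np.einsum(
            "ij,ij->i", p[t[:, 0]], np.cross(p[t[:, 1]], p[t[:, 2]])
        ).sum() / 6.0
    )


def tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = np.asarray(points)
    t = np.asarray(tets)
    return np.einsum(
        "ij,ij->i",
        p[t[:, 1]] - p[t[:, 0]],
        np.cross(p[t[:, 2]] - p[t[:, 0]], p[t[:, 3]] - p[t[:, 0]]),
    ) / 6.0


# ---------------------------------------------------------------------------
# edge topology
# ---------------------------------------------------------------------------

def _directed_edges(triangles: np.ndarray) -> np.ndarray:
    """(3m, 2) directed edges in winding order."""
    return np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )


def edge_face_count(surface: TriSurface):
    """Unique undirected edges and the number of incident triangles."""
    e = np.sort(_directed_edges(surface.triangles), axis=1)
    edges, counts = np.unique(e, axis=0, return_counts=True)
    return edges, counts


def is_closed(surface: TriSurface) -> bool:
    _, counts = edge_face_count(surface)
    return bool(len(counts) == 0 or counts.min() == 2)


def euler_characteristic(surface: TriSurface) -> int:
    used = np.unique(surface.triangles)
    edges, _ = edge_face_count(surface)
    return int(len(used) - len(edges) + len(surface.triangles))


def validate_surface(surface: TriSurface, check_orientation: bool = False) -> None:
    """Raise if the surface violates a core invariant.

    Checks index ranges, positive triangle areas and edge-manifoldness;
    with ``check_orientation`` also that no undirected edge is traversed
    twice in the same direction (consistent winding).
    """
    if len(surface.triangles) == 0:
        return
    if surface.triangles.min() < 0 or surface.triangles.max() >= surface.n_points:
        raise InputError("triangle index out of range")
    areas = triangle_areas(surface)
    if areas.min() <= 0:
        bad = int(np.argmin(areas))
        raise TopologyError(f"triangle {bad} has zero area")
    edges, counts = edge_face_count(surface)
    if counts.max() > 2:
        bad = edges[int(np.argmax(counts))]
        raise TopologyError(f"non-manifold edge ({bad[0]}, {bad[1]})")
    if check_orientation:
        de = _directed_edges(surface.triangles)
        _, dcounts = np.unique(de, axis=0, return_counts=True)
        if dcounts.max() > 1:
            raise TopologyError("inconsistent winding: repeated directed edge")


# ---------------------------------------------------------------------------
# boundary rings
# ---------------------------------------------------------------------------

def extract_boundary_rings(surface: TriSurface) -> list[Ring]:
    """All closed loops of boundary edges, ordered with the surface on the left.

    A boundary edge has exactly one incident triangle; its direction in
    that triangle's winding defines the traversal direction of the loop.
    Loops are returned sorted by their lowest contained point index, each
    starting at that index (deterministic output).
    """
    validate_surface(surface)
    de = _directed_edges(surface.triangles)
    und = np.sort(de, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    bde = de[boundary]
    if len(bde) == 0:
        return []
    succ = {int(a): int(b) for a, b in bde}
    if len(succ) != len(bde):
        raise TopologyError("boundary edges do not form simple loops")
    rings = []
    remaining = set(succ)
    while remaining:
        start = min(remaining)
        loop = [start]
        nxt = succ[start]
        while nxt != start:
            loop.append(nxt)
            remaining.discard(nxt)
            nxt = succ[nxt]
        remaining.discard(start)
        rings.append(Ring(surface, np.array(loop, dtype=np.int64)))
    rings.sort(key=lambda r: int(r.point_indices[0]))
    return rings


# ---------------------------------------------------------------------------
# connectivity / merging / warping
# ---------------------------------------------------------------------------

def _component_labels(triangles: np.ndarray) -> np.ndarray:
    """Edge-connectivity component label per triangle (union-find)."""
    m = len(triangles)
    parent = np.arange(m)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    e = np.sort(_directed_edges(triangles), axis=1)
    face = np.tile(np.arange(m), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    e = e[order]
    face = face[order]
    same = np.all(e[1:] == e[:-1], axis=1)
    for k in np.nonzero(same)[0]:
        a, b = find(face[k]), find(face[k + 1])
        if a != b:
            parent[b] = a
    labels = np.array([find(i) for i in range(m)])
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def extract_cells(surface: TriSurface, cell_mask) -> TriSurface:
    """Sub-surface made of the masked triangles (points reindexed)."""
    cell_mask = np.asarray(cell_mask)
    if cell_mask.dtype != bool:
        mask = np.zeros(surface.n_cells, dtype=bool)
        mask[cell_mask] = True
        cell_mask = mask
    tris = surface.triangles[cell_mask]
    used = np.unique(tris)
    remap = np.full(surface.n_points, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriSurface(
        surface.points[used],
        remap[tris],
        surface.cell_tags[cell_mask].copy(),
        {k: np.array(v)[used] for k, v in surface.point_fields.items()},
        {k: np.array(v)[cell_mask] for k, v in surface.cell_fields.items()},
        dict(surface.tag_names),
    )
    return out


def extract_tags(surface: TriSurface, tags) -> TriSurface:
    """Sub-surface made of the cells whose tag is in ``tags``."""
    return extract_cells(surface, np.isin(surface.cell_tags, list(tags)))


def connected_components(surface: TriSurface) -> list[TriSurface]:
    """Partition by edge connectivity, ordered by lowest contained cell index."""
    if surface.n_cells == 0:
        return []
    labels = _component_labels(surface.triangles)
    comps = []
    for lab in range(labels.max() + 1):
        comps.append(extract_cells(surface, labels == lab))
    return comps


def merge_surfaces(parts, tol: float | None = None) -> TriSurface:
    """Concatenate surfaces, unifying duplicate points within ``tol``.

    ``tol`` defaults to 1e-9 times the bounding-box diagonal of the
    union.  Tags and fields are preserved; point fields present on every
    part are carried over (first occurrence wins at shared points).
    Raises :class:`TopologyError` if unification creates a non-manifold
    edge.
    """
    parts = list(parts)
    if not parts:
        raise InputError("no surfaces to merge")
    pts = np.concatenate([s.points for s in parts])
    offs = np.cumsum([0] + [s.n_points for s in parts])
    tris = np.concatenate(
        [s.triangles + offs[i] for i, s in enumerate(parts)]
    )
    tags = np.concatenate([s.cell_tags for s in parts])
    diag = float(np.linalg.norm(pts.max(0) - pts.min(0))) if len(pts) else 0.0
    if tol is None:
        tol = 1e-9 * diag
    common_pf = set.intersection(*[set(s.point_fields) for s in parts])
    pfields = {
        k: np.concatenate([np.asarray(s.point_fields[k]) for s in parts])
        for k in common_pf
    }
    common_cf = set.intersection(*[set(s.cell_fields) for s in parts])
    cfields = {
        k: np.concatenate([np.asarray(s.cell_fields[k]) for s in parts])
        for k in common_cf
    }
    if tol > 0 and len(pts):
        tree = cKDTree(pts)
        groups = tree.query_pairs(tol, output_type="ndarray")
        # union-find on duplicate pairs
        parent = np.arange(len(pts))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in groups:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        root = np.array([find(i) for i in range(len(pts))])
    else:
        root = np.arange(len(pts))
    keep, remap = np.unique(root, return_inverse=True)
    new_pts = pts[keep]
    new_tris = remap[tris]
    degenerate = (
        (new_tris[:, 0] == new_tris[:, 1])
        | (new_tris[:, 1] == new_tris[:, 2])
        | (new_tris[:, 2] == new_tris[:, 0])
    )
    new_tris = new_tris[~degenerate]
    tags = tags[~degenerate]
    cfields = {k: v[~degenerate] for k, v in cfields.items()}
    pfields = {k: np.asarray(v)[keep] for k, v in pfields.items()}
    tag_names = {}
    for s in parts:
        tag_names.update(s.tag_names)
    out = TriSurface(new_pts, new_tris, tags, pfields, cfields, tag_names)
    validate_surface(out)
    return out


def warp(surface: TriSurface, displacement: np.ndarray) -> TriSurface:
    """Translate every point by a per-point 3D displacement field."""
    disp = np.asarray(displacement, dtype=float)
    if disp.shape != (surface.n_points, 3):
        raise InputError(
            f"displacement must be ({surface.n_points}, 3), got {disp.shape}"
        )
    out = surface.copy()
    out.points = out.points + disp
    return out


def boundary_faces_of(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented faces belonging to exactly one tet."""
    tets = np.asarray(tets, dtype=np.int64)
    if len(tets) == 0:
        return np.zeros((0, 3), dtype=np.int64)
    # outward faces under the positive-volume node ordering
    faces = np.concatenate([
        tets[:, [0, 2, 1]],
        tets[:, [0, 1, 3]],
        tets[:, [1, 2, 3]],
        tets[:, [0, 3, 2]],
    ])
    key = np.sort(faces, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def extract_surface(mesh: TetMesh) -> TriSurface:
    """Boundary of a tet mesh as a tagged TriSurface (points reindexed)."""
    faces = mesh.boundary_faces
    used = np.unique(faces)
    remap = np.full(mesh.n_points, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriSurface(
        mesh.points[used],
        remap[faces],
        mesh.boundary_tags.copy(),
        {k: np.asarray(v)[used] for k, v in mesh.point_fields.items()},
        tag_names=dict(mesh.tag_names),
    )


def validate_tetmesh(mesh: TetMesh) -> None:
    """Raise if tet volumes are non-positive or boundary faces inconsistent."""
    if mesh.n_cells == 0:
        return
    vols = tet_volumes(mesh.points, mesh.tets)
    if vols.min() <= 0:
        raise TopologyError(
            f"tet {int(np.argmin(vols))} has non-positive volume {vols.min():g}"
        )
    expected = boundary_faces_of(mesh.tets)
    a = set(map(frozenset, expected.tolist()))
    b = set(map(frozenset, mesh.boundary_faces.tolist()))
    if a != b:
        raise TopologyError("boundary_faces do not match the one-tet faces")
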