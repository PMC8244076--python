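"""Array-driven surface tagging.

Five ways to create a new cell tag on a surface:

* ``simple``: threshold a per-point field at the cell barycenters;
  fast, leaves the triangulation untouched, produces a zig-zag
  inter-tag ring.
* ``clip``: split the triangles exactly at the level set of the field;
  precise tag boundary, but distorted triangles.
* ``harmonic``: move the zig-zag ring points onto the level set and
  blend the movement harmonically inside a buffer zone; precise tag
  boundary with the original connectivity preserved.
* ``connectivity``: give each edge-connected component of a tag its own
  fresh tag.
* ``cells``: tag an explicit list of cells, or all cells within a
  geodesic radius of a seed cell.

The driving field is either a named per-point scalar array or computed
on the fly as a (signed or unsigned) distance from a reference surface
or ring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .core_mesh import TriSurface, Ring, warp, triangle_normals
from ._levelset import split_by_field, level_segments
from .distance_fields import surface_distance, ring_distance
from .harmonic_solver import HarmonicProblem, solve_harmonic
from .errors import InputError, QualityError

__all__ = [
    "TagSpec",
    "tag_simple",
    "tag_clip",
    "tag_harmonic",
    "tag_connectivity",
    "tag_cells",
]


@dataclass
class TagSpec:
    """Parameters of an array-based tagging operation.

    ``sigma`` is the cut-off value; cells where the field at the
    barycenter is <= sigma receive ``new_tag`` (>= sigma with
    ``invert``).  ``rho`` is the buffer radius of the harmonic
    algorithm.  ``reference`` may name a surface or ring from which the
    field is computed as a distance (``signed`` selects the signed
    variant); otherwise ``field_name`` must identify an existing
    per-point scalar array.  Cells whose tag is in ``excluded_tags``
    are never modified.
    """

    field_name: str = "f"
    sigma: float = 0.0
    new_tag: int = 1
    rho: float | None = None
    invert: bool = False
    excluded_tags: set = dc_field(default_factory=set)
    reference: object = None
    signed: bool = False
    distance_like: bool | None = None


def _field_values(surface: TriSurface, spec: TagSpec) -> np.ndarray:
    if spec.reference is not None:
        if isinstance(spec.reference, Ring):
            return ring_distance(surface.points, spec.reference).values
        if isinstance(spec.reference, TriSurface):
            return surface_distance(surface.points, spec.reference,
                                    signed=spec.signed).values
        raise InputError("reference must be a TriSurface or a Ring")
    if spec.field_name not in surface.point_fields:
        raise InputError(f"missing point field {spec.field_name!r}")
    f = np.asarray(surface.point_fields[spec.field_name], dtype=float)
    if f.shape != (surface.n_points,):
        raise InputError("tagging field must be scalar per point")
    return f


def _eligible(surface: TriSurface, spec: TagSpec) -> np.ndarray:
    if not spec.excluded_tags:
        return np.ones(surface.n_cells, dtype=bool)
    return ~np.isin(surface.cell_tags, list(spec.excluded_tags))


def tag_simple(surface: TriSurface, spec: TagSpec) -> TriSurface:
    """Threshold the field at cell barycenters; geometry untouched."""
    f = _field_values(surface, spec)
    out = surface.copy()
    fc = f[surface.triangles].mean(axis=1)
    hit = (fc >= spec.sigma) if spec.invert else (fc <= spec.sigma)
    out.cell_tags = np.where(hit & _eligible(surface, spec), spec.new_tag,
                             surface.cell_tags)
    return out


def tag_clip(surface: TriSurface, spec: TagSpec) -> TriSurface:
    """Split the surface exactly along ``{f = sigma}`` and tag one side."""
    f = _field_values(surface, spec)
    if spec.sigma < f.min() or spec.sigma > f.max():
        warnings.warn("cut-off outside the field range: clip reduces to the "
                      "simple algorithm", stacklevel=2)
        return tag_simple(surface, spec)
    split, below = split_by_field(surface, f, spec.sigma,
                                  cell_mask=_eligible(surface, spec))
    fnew = split.point_fields.pop("_levelset_field")
    if spec.reference is None:
        split.point_fields[spec.field_name] = fnew
    hit = ~below if spec.invert else below
    eligible = np.ones(split.n_cells, dtype=bool)
    if spec.excluded_tags:
        eligible = ~np.isin(split.cell_tags, list(spec.excluded_tags))
    split.cell_tags = np.where(hit & eligible, spec.new_tag, split.cell_tags)
    return split


def _zigzag_rings(surface: TriSurface, hit: np.ndarray) -> list[list[int]]:
    """Ordered loops of points on edges between hit and non-hit cells."""
    em: dict = {}
    for c, tri in enumerate(surface.triangles):
        for k in range(3):
            e = (min(tri[k], tri[(k + 1) % 3]), max(tri[k], tri[(k + 1) % 3]))
            em.setdefault(e, []).append(c)
    interface = [e for e, cells in em.items()
                 if len(cells) == 2 and hit[cells[0]] != hit[cells[1]]]
    succ: dict = {}
    for a, b in interface:
        succ.setdefault(a, []).append(b)
        succ.setdefault(b, []).append(a)
    loops = []
    visited: set = set()
    for start in sorted(succ):
        if start in visited or len(succ[start]) != 2:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = start, succ[start][0]
        while cur != start:
            if cur in visited or len(succ.get(cur, [])) != 2:
                loop = None
                break
            loop.append(cur)
            visited.add(cur)
            nxt = succ[cur][0] if succ[cur][0] != prev else succ[cur][1]
            prev, cur = cur, nxt
        if loop and len(loop) >= 3:
            loops.append(loop)
    return loops


def _prune_ring(loop: list[int], surface: TriSurface) -> list[int]:
    """Drop ring points so no triangle keeps three consecutive ring points.

    Scanning the loop in order, whenever three consecutive points share
    a triangle one of the two middle candidates is deleted; the first
    one only if its predecessor is still present, otherwise the second.
    This prevents triangles from collapsing to lines when the ring is
    later flattened onto the level set.
    """
    point_tris: dict = {}
    for c, tri in enumerate(surface.triangles):
        for v in tri:
            point_tris.setdefault(int(v), set()).add(c)
    keep = {p: True for p in loop}
    n = len(loop)
    for i in range(n):
        xi, xi1, xi2 = loop[i], loop[(i + 1) % n], loop[(i + 2) % n]
        if not (keep[xi] and keep[xi1] and keep[xi2]):
            continue
        shared = (point_tris.get(xi, set()) & point_tris.get(xi1, set())
                  & point_tris.get(xi2, set()))
        if not shared:
            continue
        prev = loop[(i - 1) % n]
        if keep.get(prev, False):
            keep[xi] = False
        else:
            keep[xi1] = False
    return [p for p in loop if keep[p]]


def tag_harmonic(surface: TriSurface, spec: TagSpec,
                 recompute=None) -> TriSurface:
    """Precise tag with original connectivity: warp the zig-zag ring
    onto the level set, blending harmonically inside a ``rho`` buffer.

    ``recompute`` is an optional hook ``f(surface) -> values`` used to
    refresh a non-distance field after the warp; unsigned-distance
    fields are updated in place as ``f + |phi|``.  The triangle and
    point counts of the output equal those of the input.
    """
    f = _field_values(surface, spec)
    rho = spec.rho
    if rho is None:
        e = surface.points[surface.triangles]
        lens = np.linalg.norm(e - np.roll(e, 1, axis=1), axis=2)
        rho = 5.0 * float(lens.mean())
    if rho <= 0:
        raise InputError("rho must be positive")
    fc = f[surface.triangles].mean(axis=1)
    hit = ((fc >= spec.sigma) if spec.invert else (fc <= spec.sigma)) \
        & _eligible(surface, spec)
    segs = level_segments(surface, f, spec.sigma)
    if len(segs) == 0:
        return tag_simple(surface, spec)
    loops = _zigzag_rings(surface, hit)
    ring_pts: list[int] = []
    for loop in loops:
        ring_pts.extend(_prune_ring(loop, surface))
    if not ring_pts:
        return tag_simple(surface, spec)
    # displacement of the pruned ring onto the clip polyline
    from .remeshing import _project_to_segments

    targets = _project_to_segments(surface.points[ring_pts], segs)
    d_delta = targets - surface.points[ring_pts]
    # buffer zone: points within rho of the pruned ring
    ring_coords = surface.points[ring_pts]
    diff = surface.points[:, None, :] - ring_coords[None, :, :]
    d0 = np.sqrt(np.einsum("kpi,kpi->kp", diff, diff)).min(axis=1)
    dirichlet = {int(p): d_delta[k] for k, p in enumerate(ring_pts)}
    for p in np.nonzero(d0 > rho)[0]:
        dirichlet.setdefault(int(p), np.zeros(3))
    phi = solve_harmonic(HarmonicProblem(surface, dirichlet)).values
    normals_before = triangle_normals(surface)
    out = warp(surface, phi)
    normals_after = triangle_normals(out)
    flipped = np.einsum("ij,ij->i", normals_before, normals_after) <= 0
    if flipped.any():
        raise QualityError(
            f"{int(flipped.sum())} triangles inverted by the harmonic warp; "
            f"increase the buffer radius rho (current {rho:g})"
        )
    mag = np.linalg.norm(phi, axis=1)
    if spec.reference is not None or spec.distance_like:
        fnew = f + mag
    elif recompute is not None:
        fnew = np.asarray(recompute(out), dtype=float)
    elif np.allclose(mag, 0.0):
        fnew = f
    else:
        raise InputError(
            "field is not distance-like and no recompute hook was given; "
            "refusing to tag with a stale field"
        )
    if spec.reference is None:
        out.point_fields[spec.field_name] = fnew
    fc = fnew[out.triangles].mean(axis=1)
    hit = ((fc >= spec.sigma) if spec.invert else (fc <= spec.sigma)) \
        & _eligible(out, spec)
    out.cell_tags = np.where(hit, spec.new_tag, out.cell_tags)
    return out


def tag_connectivity(surface: TriSurface, base_tags=None) -> TriSurface:
    """Fresh tag per edge-connected component within each base tag.

    Components are numbered deterministically by their lowest contained
    cell index, starting after the current maximum tag.
    """
    out = surface.copy()
    if base_tags is None:
        base_tags = set(np.unique(surface.cell_tags).tolist())
    next_tag = int(surface.cell_tags.max()) + 1
    em: dict = {}
    for c, tri in enumerate(surface.triangles):
        for k in range(3):
            e = (min(tri[k], tri[(k + 1) % 3]), max(tri[k], tri[(k + 1) % 3]))
            em.setdefault(e, []).append(c)
    for tag in sorted(base_tags):
        cells = np.nonzero(surface.cell_tags == tag)[0]
        if len(cells) == 0:
            continue
        in_tag = set(cells.tolist())
        adj: dict = {c: [] for c in in_tag}
        for faces in em.values():
            if len(faces) == 2 and faces[0] in in_tag and faces[1] in in_tag:
                adj[faces[0]].append(faces[1])
                adj[faces[1]].append(faces[0])
        seen: set = set()
        for seed in sorted(in_tag):
            if seed in seen:
                continue
            stack = [seed]
            comp = []
            seen.add(seed)
            while stack:
                c = stack.pop()
                comp.append(c)
                for nb in adj[c]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            out.cell_tags[comp] = next_tag
            next_tag += 1
    return out


def tag_cells(surface: TriSurface, cell_ids=None, seed: int | None = None,
              radius: float | None = None, new_tag: int = 1) -> TriSurface:
    """Tag an explicit cell list, or cells within a geodesic radius of a seed.

    The geodesic variant measures distance along the cell-adjacency
    graph weighted by barycenter-to-barycenter length (a non-interactive
    replacement for hand drawing).
    """
    out = surface.copy()
    if cell_ids is not None:
        ids = np.asarray(cell_ids, dtype=np.int64)
        if len(ids) and (ids.min() < 0 or ids.max() >= surface.n_cells):
            raise InputError("cell id out of range")
        out.cell_tags[ids] = new_tag
        return out
    if seed is None or radius is None:
        raise InputError("need either cell_ids or seed and radius")
    if not 0 <= seed < surface.n_cells:
        raise InputError("seed cell id out of range")
    # geodesic distances on the vertex graph, augmented with the
    # diagonals of each edge's adjacent-triangle rhombus to reduce the
    # metric inflation of pure edge paths
    pts = surface.points
    em: dict = {}
    for c, tri in enumerate(surface.triangles):
        for k in range(3):
            e = (min(tri[k], tri[(k + 1) % 3]), max(tri[k], tri[(k + 1) % 3]))
            em.setdefault(e, []).append((c, int(tri[(k + 2) % 3])))
    links = set()
    for (a, b), inc in em.items():
        links.add((a, b))
        if len(inc) == 2:
            u, v = inc[0][1], inc[1][1]
            links.add((min(u, v), max(u, v)))
    rows, cols, vals = [], [], []
    for a, b in links:
        w = float(np.linalg.norm(pts[a] - pts[b]))
        rows += [a, b]
        cols += [b, a]
        vals += [w, w]
    graph = sp.csr_matrix((vals, (rows, cols)),
                          shape=(surface.n_points, surface.n_points))
    seed_tri = surface.triangles[seed]
    seed_bary = pts[seed_tri].mean(axis=0)
    dist = dijkstra(graph, indices=seed_tri, min_only=True)
    dist = dist + 0.0
    # account for the hop from the seed barycenter to its vertices
    offset = np.linalg.norm(pts[seed_tri] - seed_bary, axis=1).min()
    cell_dist = dist[surface.triangles].mean(axis=1) + offset
    out.cell_tags[cell_dist <= radius] = new_tag
    return out
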