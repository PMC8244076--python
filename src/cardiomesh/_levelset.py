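"""Split/clip a surface along a level set of a per-point scalar field.

Triangles crossing the level are cut by linear interpolation along
their edges; the cut polygons are fan-triangulated from their first
vertex.  Intersection points are shared per undirected edge, so the two
sides of a split stay conforming and the cut polyline is watertight.
"""

from __future__ import annotations

import numpy as np

from .core_mesh import TriSurface, extract_cells
from .errors import InputError

__all__ = ["split_by_field", "clip_by_field", "level_segments"]


def split_by_field(surface: TriSurface, values, level: float,
                   cell_mask=None):
    """Split every eligible triangle along ``{f = level}``.

    Returns ``(surface, below)`` where ``below`` marks the cells of the
    output lying on the ``f <= level`` side.  Cells excluded by
    ``cell_mask`` are copied unchanged and classified by their mean
    value.  Point fields are interpolated at the new cut points.
    """
    f = np.asarray(values, dtype=float)
    if f.shape != (surface.n_points,):
        raise InputError("field must be scalar per point")
    if cell_mask is None:
        cell_mask = np.ones(surface.n_cells, dtype=bool)
    s = f - level
    pts = [surface.points]
    pfields = {k: [np.asarray(v)] for k, v in surface.point_fields.items()}
    fvals = [f]
    next_id = surface.n_points
    cut_point: dict = {}

    def cut(a: int, b: int) -> int:
        nonlocal next_id
        key = (min(a, b), max(a, b))
        if key in cut_point:
            return cut_point[key]
        i, j = key
        t = s[i] / (s[i] - s[j])
        pts.append((surface.points[i] + t * (surface.points[j] - surface.points[i]))[None, :])
        for k, chunks in pfields.items():
            vi = np.asarray(surface.point_fields[k])[i]
            vj = np.asarray(surface.point_fields[k])[j]
            chunks.append(np.asarray(vi + t * (vj - vi))[None, ...])
        fvals.append(np.array([level], dtype=float))
        cut_point[key] = next_id
        next_id += 1
        return cut_point[key]

    new_tris: list = []
    new_tags: list = []
    new_below: list = []
    new_cf = {k: [] for k in surface.cell_fields}

    def emit(tri, tag, below, src):
        new_tris.append(tri)
        new_tags.append(tag)
        new_below.append(below)
        for k in new_cf:
            new_cf[k].append(np.asarray(surface.cell_fields[k])[src])

    for c, tri in enumerate(surface.triangles):
        tag = surface.cell_tags[c]
        sv = s[tri]
        if not cell_mask[c] or np.all(sv <= 0) or np.all(sv >= 0):
            emit(list(tri), tag, bool(sv.mean() <= 0), c)
            continue
        below_poly: list = []
        above_poly: list = []
        for k in range(3):
            a, b = tri[k], tri[(k + 1) % 3]
            if s[a] <= 0:
                below_poly.append(a)
            if s[a] >= 0:
                above_poly.append(a)
            if s[a] * s[b] < 0:
                m = cut(a, b)
                below_poly.append(m)
                above_poly.append(m)
        for poly, below in ((below_poly, True), (above_poly, False)):
            for k in range(1, len(poly) - 1):
                emit([poly[0], poly[k], poly[k + 1]], tag, below, c)

    out = TriSurface(
        np.concatenate(pts),
        np.array(new_tris, dtype=np.int64),
        np.array(new_tags, dtype=np.int64),
        {k: np.concatenate(v) for k, v in pfields.items()},
        {k: np.array(v) for k, v in new_cf.items()},
        dict(surface.tag_names),
    )
    out.point_fields["_levelset_field"] = np.concatenate(fvals)
    return out, np.array(new_below, dtype=bool)


def clip_by_field(surface: TriSurface, values, level: float,
                  keep: str = "below") -> TriSurface:
    """Keep only the ``f <= level`` (or ``>= level``) side of the surface."""
    if keep not in {"below", "above"}:
        raise InputError("keep must be 'below' or 'above'")
    split, below = split_by_field(surface, values, level)
    split.point_fields.pop("_levelset_field")
    return extract_cells(split, below if keep == "below" else ~below)


def level_segments(surface: TriSurface, values, level: float) -> np.ndarray:
    """Segments of the level-set polyline ``{f = level}``, shape (k, 2, 3).

    One segment per triangle crossed transversally; triangle edges lying
    exactly on the level contribute themselves.
    """
    f = np.asarray(values, dtype=float)
    s = f - level
    pts = surface.points
    segs = []
    for tri in surface.triangles:
        sv = s[tri]
        crossings = []
        for k in range(3):
            a, b = tri[k], tri[(k + 1) % 3]
            if s[a] == 0:
                crossings.append(pts[a])
            if s[a] * s[b] < 0:
                t = s[a] / (s[a] - s[b])
                crossings.append(pts[a] + t * (pts[b] - pts[a]))
        if len(crossings) >= 2:
            uniq = []
            for p in crossings:
                if not any(np.allclose(p, q) for q in uniq):
                    uniq.append(p)
            if len(uniq) >= 2:
                segs.append([uniq[0], uniq[1]])
    if not segs:
        return np.zeros((0, 2, 3))
    return np.array(segs)
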