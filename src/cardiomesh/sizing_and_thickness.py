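"""Wall thickness, thickening, mesh-size fields, smoothing, curvature.

The thickness of a tagged wall (e.g. a ventricular myocardium between
endocardium and epicardium tags) is assembled from unsigned distances
between the tagged sub-surfaces; a two-cavity variant handles the
septum of biventricular walls.  The thickening operation pushes both
walls apart along the outward normals until a minimum thickness is
reached.  Mesh-size fields map geometric quantities (curvature,
thickness, distances, ...) through a clamped power law and combine
several of them by a pointwise minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .core_mesh import TriSurface, extract_tags, vertex_normals, warp
from .distance_fields import closest_point_on_surface, surface_distance
from .harmonic_solver import cotangent_laplacian, mixed_voronoi_areas
from .errors import InputError

__all__ = [
    "SizingSpec",
    "ThickenSpec",
    "surface_thickness",
    "surface_thicken",
    "mesh_size",
    "smooth_field",
    "mean_curvature",
]


@dataclass
class SizingSpec:
    """One clamped power-law term of a mesh-size function.

    Maps a per-point field f to ``clamp(alpha * f**beta + gamma)``
    constrained to the interval [m, M] (all lengths in mm).
    """

    field_name: str
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.0
    m: float = 0.0
    M: float = np.inf

    def __post_init__(self):
        if self.m > self.M:
            raise InputError("lower clamp m must not exceed upper clamp M")

    def evaluate(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if self.beta != int(self.beta) and np.any(f <= 0):
            raise InputError(
                f"field {self.field_name!r} has non-positive values; "
                f"power {self.beta} is undefined"
            )
        return np.maximum(self.m,
                          np.minimum(self.alpha * f ** self.beta + self.gamma,
                                     self.M))


@dataclass
class ThickenSpec:
    """Thickening parameters: target thickness sigma, scale alpha.

    Points with thickness below sigma (above, with ``invert``) and not
    in ``excluded_tags`` move by ``0.5 * alpha * (sigma - tau)`` along
    the outward normal; the 1/2 accounts for the deformation acting on
    both the inner and the outer wall.
    """

    sigma: float
    alpha: float = 1.0
    excluded_tags: set = dc_field(default_factory=set)
    invert: bool = False

    def __post_init__(self):
        if self.sigma <= 0:
            raise InputError("sigma must be positive")


def surface_thickness(surface: TriSurface, internal_tags_1, external_tags,
                      internal_tags_2=None,
                      field_name: str = "thickness") -> TriSurface:
    """Wall thickness from unsigned distances between tagged walls.

    Single-cavity walls use ``max(D_ext, D_int1)`` (distance to the
    other wall on each wall).  With a second internal cavity the septum
    is handled by ``max(min(max(D_int1, D_int2), D_ext), D_int)`` where
    ``D_int`` is the distance to the union of the cavities.  On cells
    outside the named tags the thickness is projected from the nearest
    tagged point.
    """
    int1 = set(internal_tags_1)
    ext = set(external_tags)
    int2 = set(internal_tags_2) if internal_tags_2 else set()
    if not int1 or not ext:
        raise InputError("internal_tags_1 and external_tags must be non-empty")
    if (int1 & ext) or (int1 & int2) or (ext & int2):
        raise InputError("tag sets must be disjoint")
    all_tags = int1 | ext | int2
    s_ext = extract_tags(surface, ext)
    s_int1 = extract_tags(surface, int1)
    if s_ext.n_cells == 0 or s_int1.n_cells == 0:
        raise InputError("a named tag set selects no cells")
    t_mask = np.isin(surface.cell_tags, list(all_tags))
    t_pts = np.unique(surface.triangles[t_mask])
    q = surface.points[t_pts]
    d_ext = surface_distance(q, s_ext).values
    d_int1 = surface_distance(q, s_int1).values
    if int2:
        s_int2 = extract_tags(surface, int2)
        s_int = extract_tags(surface, int1 | int2)
        d_int2 = surface_distance(q, s_int2).values
        d_int = surface_distance(q, s_int).values
        tau_t = np.maximum(np.minimum(np.maximum(d_int1, d_int2), d_ext),
                           d_int)
    else:
        tau_t = np.maximum(d_ext, d_int1)
    tau = np.zeros(surface.n_points)
    tau[t_pts] = tau_t
    rest = np.setdiff1d(np.arange(surface.n_points), t_pts)
    if len(rest):
        # nearest-neighbor projection from the tagged region
        from scipy.spatial import cKDTree

        _, nearest = cKDTree(surface.points[t_pts]).query(
            surface.points[rest], k=1)
        tau[rest] = tau_t[nearest]
    out = surface.copy()
    out.point_fields[field_name] = tau
    return out


def surface_thicken(surface: TriSurface, spec: ThickenSpec,
                    field_name: str = "thickness") -> TriSurface:
    """Push walls apart (or together) toward a minimum thickness.

    Requires the thickness field on the surface; normals are recomputed
    immediately before warping (angle-weighted at vertices).
    """
    if field_name not in surface.point_fields:
        raise InputError(f"missing thickness field {field_name!r}")
    tau = np.asarray(surface.point_fields[field_name], dtype=float)
    n = vertex_normals(surface)
    if spec.invert:
        move = tau > spec.sigma
    else:
        move = tau < spec.sigma
    if spec.excluded_tags:
        excluded = np.isin(surface.cell_tags, list(spec.excluded_tags))
        exc_pts = np.unique(surface.triangles[excluded])
        move = move.copy()
        move[exc_pts] = False
    w = np.where(move[:, None],
                 0.5 * spec.alpha * (spec.sigma - tau)[:, None] * n,
                 0.0)
    return warp(surface, w)


def mesh_size(surface: TriSurface, specs, target_tags=None,
              smooth_iterations: int = 10,
              field_name: str = "h") -> TriSurface:
    """Combine sizing terms into a mesh-size field (pointwise minimum).

    ``specs`` is a constant (the constant algorithm), a single
    :class:`SizingSpec`, or a list of them (the combination algorithm).
    With ``target_tags`` an existing field ``h`` is only modified on the
    points of those tags.  The smoothed companion field ``h_smooth`` is
    written alongside.
    """
    out = surface.copy()
    if np.isscalar(specs):
        h_new = np.full(surface.n_points, float(specs))
        if float(specs) <= 0:
            raise InputError("constant mesh-size must be positive")
    else:
        if isinstance(specs, SizingSpec):
            specs = [specs]
        if not specs:
            raise InputError("no sizing specs given")
        terms = []
        for s in specs:
            if s.field_name not in surface.point_fields:
                raise InputError(f"missing point field {s.field_name!r}")
            terms.append(s.evaluate(surface.point_fields[s.field_name]))
        h_new = np.min(terms, axis=0)
    if target_tags is not None and field_name in surface.point_fields:
        h = np.asarray(surface.point_fields[field_name], dtype=float).copy()
        mask = np.isin(surface.cell_tags, list(target_tags))
        pts = np.unique(surface.triangles[mask])
        h[pts] = h_new[pts]
    else:
        h = h_new
    out.point_fields[field_name] = h
    out = smooth_field(out, field_name, iterations=smooth_iterations,
                       output_name=field_name + "_smooth")
    return out


def smooth_field(surface: TriSurface, field_name: str, iterations: int = 10,
                 relaxation: float = 1.0,
                 output_name: str | None = None) -> TriSurface:
    """Iterative 1-ring averaging: ``v <- (1-lambda) v + lambda mean(nbrs)``.

    A convex combination, so the global min/max bounds of the field are
    preserved.
    """
    if field_name not in surface.point_fields:
        raise InputError(f"missing point field {field_name!r}")
    if not 0.0 <= relaxation <= 1.0:
        raise InputError("relaxation must be in [0, 1]")
    v = np.asarray(surface.point_fields[field_name], dtype=float).copy()
    edges = np.concatenate([surface.triangles[:, [0, 1]],
                            surface.triangles[:, [1, 2]],
                            surface.triangles[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    deg = np.zeros(surface.n_points)
    np.add.at(deg, edges[:, 0], 1.0)
    np.add.at(deg, edges[:, 1], 1.0)
    deg[deg == 0] = 1.0
    for _ in range(iterations):
        acc = np.zeros_like(v)
        np.add.at(acc, edges[:, 0], v[edges[:, 1]])
        np.add.at(acc, edges[:, 1], v[edges[:, 0]])
        v = (1.0 - relaxation) * v + relaxation * acc / deg
    out = surface.copy()
    out.point_fields[output_name or field_name] = v
    return out


def mean_curvature(surface: TriSurface,
                   field_name: str = "curvature") -> TriSurface:
    """Magnitude of the discrete mean curvature, |Laplace(x)| / 2.

    Cotangent Laplace-Beltrami applied to the coordinate functions,
    normalized by the mixed Voronoi vertex areas; the sign is discarded.
    """
    K = cotangent_laplacian(surface)
    areas = mixed_voronoi_areas(surface)
    if areas.min() <= 0:
        raise InputError("degenerate triangles: vertex area vanishes")
    hn = (K @ surface.points) / areas[:, None]
    out = surface.copy()
    out.point_fields[field_name] = 0.5 * np.linalg.norm(hn, axis=1)
    return out


def project_field(surface: TriSurface, reference: TriSurface,
                  field_name: str) -> np.ndarray:
    """Sample a reference point field at the closest reference points."""
    if field_name not in reference.point_fields:
        raise InputError(f"missing point field {field_name!r} on reference")
    cps, _, tids = closest_point_on_surface(surface.points, reference)
    vals = np.asarray(reference.point_fields[field_name], dtype=float)
    tris = reference.triangles[tids]
    # inverse-distance blend of the triangle's corner values
    corners = reference.points[tris]
    d = np.linalg.norm(corners - cps[:, None, :], axis=2)
    w = 1.0 / np.maximum(d, 1e-12)
    w /= w.sum(axis=1, keepdims=True)
    return np.einsum("kc,kc->k", w, vals[tris])
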