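"""Connecting two surfaces: zipper, boolean and harmonic connections.

The zipper (``surface_connection``) greedily triangulates the band
between two boundary rings, always adding the triangle with the
shortest connecting edge; it is the primitive the boolean and harmonic
connections (and the volumetric mesh connection) build on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .core_mesh import (
    TriSurface, Ring, extract_boundary_rings, merge_surfaces, warp,
    is_closed, validate_surface,
)
from ._levelset import clip_by_field
from .distance_fields import (
    surface_distance, ring_distance, closest_point_on_ring,
)
from .harmonic_solver import HarmonicProblem, solve_harmonic
from .errors import InputError, NumericalError, TopologyError

__all__ = [
    "ZipperState",
    "BooleanSpec",
    "HarmonicConnectSpec",
    "surface_connection",
    "connect_rings",
    "boolean_connection",
    "harmonic_connection",
    "register_rings",
    "pair_rings",
]


# ---------------------------------------------------------------------------
# zipper
# ---------------------------------------------------------------------------

@dataclass
class ZipperState:
    """Final bookkeeping of one zipper run (mainly for tests/inspection)."""

    triangles: np.ndarray        # (n1+n2, 3) global point indices
    insertions: int              # points inserted incl. the doubled start
    start1: int
    start2: int
    direction2: int              # +1 / -1 along ring2's stored order


def _zipper(points: np.ndarray, ring1: np.ndarray, ring2: np.ndarray,
            rng: np.random.Generator | None = None) -> ZipperState:
    """Greedy band triangulation between two rings of one point set.

    Starts from a point on ring1 (lowest index by default, random with
    ``rng``) and its closest point on ring2, then repeatedly adds the
    triangle with the shorter of the two candidate connecting edges,
    advancing on ring1 at ties.  Triangle winding follows ring1's stored
    order, which yields a consistently oriented band when the parents
    face each other with coherent outward windings.
    """
    n1, n2 = len(ring1), len(ring2)
    p = points
    s1 = 0 if rng is None else int(rng.integers(n1))
    start1 = ring1[s1]
    d2 = np.linalg.norm(p[ring2] - p[start1], axis=1)
    s2 = int(np.argmin(d2))
    start2 = ring2[s2]
    # direction on ring1: stored successor order; on ring2: the neighbor
    # of the start closest to ring1's first candidate
    cand1 = ring1[(s1 + 1) % n1]
    nb_fwd = ring2[(s2 + 1) % n2]
    nb_bwd = ring2[(s2 - 1) % n2]
    dir2 = 1 if (np.linalg.norm(p[nb_fwd] - p[cand1])
                 <= np.linalg.norm(p[nb_bwd] - p[cand1])) else -1
    tris = []
    cur1, cur2 = start1, start2
    k1 = k2 = 1
    inserted = 2
    while inserted < n1 + n2 + 1:
        c1 = ring1[(s1 + k1) % n1] if k1 <= n1 else None
        c2 = ring2[(s2 + dir2 * k2) % n2] if k2 <= n2 else None
        d1 = np.linalg.norm(p[c1] - p[cur2]) if c1 is not None else np.inf
        d2 = np.linalg.norm(p[c2] - p[cur1]) if c2 is not None else np.inf
        if d1 <= d2:
            tris.append([c1, cur1, cur2])
            cur1 = c1
            k1 += 1
        else:
            tris.append([cur1, cur2, c2])
            cur2 = c2
            k2 += 1
        inserted += 1
    # exactly one ring has wrapped (re-inserted its start)
    missing = start2 if k1 > n1 else start1
    tris.append([cur1, cur2, missing])
    return ZipperState(np.array(tris, dtype=np.int64), inserted,
                       start1, start2, dir2)


def _directed_conflicts(triangles: np.ndarray) -> int:
    de = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]],
                         triangles[:, [2, 0]]])
    _, counts = np.unique(de, axis=0, return_counts=True)
    return int((counts > 1).sum())


def connect_rings(surface: TriSurface, ring1: Ring, ring2: Ring,
                  band_tag: int, rng=None) -> TriSurface:
    """Add a zipper band between two boundary rings of one surface.

    No new points are created: the band reuses the ring points, so
    indices of the input surface stay valid on the output.
    """
    for ring in (ring1, ring2):
        if ring.surface is not surface:
            raise InputError("rings must belong to the given surface")
    state = _zipper(surface.points, ring1.point_indices, ring2.point_indices,
                    rng)
    out = surface.copy()
    band = state.triangles
    all_tris = np.concatenate([out.triangles, band])
    if _directed_conflicts(all_tris) > 0:
        flipped = np.concatenate([out.triangles, band[:, ::-1]])
        if _directed_conflicts(flipped) == 0:
            all_tris = flipped
        else:
            warnings.warn("zipper band could not be oriented consistently "
                          "with both parents", stacklevel=2)
    out.triangles = all_tris
    out.cell_tags = np.concatenate([
        out.cell_tags, np.full(len(band), band_tag, dtype=np.int64)
    ])
    for k, v in list(out.cell_fields.items()):
        v = np.asarray(v)
        pad = np.zeros((len(band),) + v.shape[1:], dtype=v.dtype)
        out.cell_fields[k] = np.concatenate([v, pad])
    return out


def surface_connection(s1: TriSurface, s2: TriSurface, ring1: Ring,
                       ring2: Ring, band_tag: int = 10,
                       rng=None) -> TriSurface:
    """Join two disjoint open surfaces with a greedy zipper band.

    ``ring1``/``ring2`` must be boundary rings of ``s1``/``s2``.  The
    output is a single surface carrying both parents unchanged plus the
    band tagged ``band_tag``.
    """
    if ring1.surface is not s1 or ring2.surface is not s2:
        raise InputError("ring1 must belong to s1 and ring2 to s2")
    _check_boundary_ring(s1, ring1)
    _check_boundary_ring(s2, ring2)
    if _surfaces_share_points(s1, s2):
        raise InputError("input surfaces share points; they must be disjoint")
    merged = merge_surfaces([s1, s2], tol=0.0)
    off = s1.n_points
    r1 = Ring(merged, ring1.point_indices)
    r2 = Ring(merged, ring2.point_indices + off)
    return connect_rings(merged, r1, r2, band_tag, rng)


def _check_boundary_ring(surface: TriSurface, ring: Ring) -> None:
    boundary = {frozenset(map(int, e)) for r in extract_boundary_rings(surface)
                for e in zip(r.point_indices, np.roll(r.point_indices, -1))}
    idx = ring.point_indices
    for a, b in zip(idx, np.roll(idx, -1)):
        if frozenset((int(a), int(b))) not in boundary:
            raise InputError(
                f"ring edge ({a}, {b}) is not a boundary edge of its surface"
            )


def _surfaces_share_points(s1: TriSurface, s2: TriSurface) -> bool:
    from scipy.spatial import cKDTree

    if s1.n_points == 0 or s2.n_points == 0:
        return False
    d, _ = cKDTree(s1.points).query(s2.points, k=1)
    return bool(d.min() == 0.0)


# ---------------------------------------------------------------------------
# ring registration
# ---------------------------------------------------------------------------

def register_rings(ring_moving: Ring, ring_fixed: Ring, mode: str = "icp",
                   max_iter: int = 50, tol: float = 1e-6):
    """Rigid transform (R, t) aligning ``ring_moving`` onto ``ring_fixed``.

    ``centroid`` mode returns the pure translation between geometric
    centers; ``icp`` alternates closest-point-on-polyline assignment
    with a least-squares (Kabsch) rigid fit until the relative change of
    the mean residual drops below ``tol``.
    """
    a = ring_moving.coords
    if mode == "centroid":
        t = ring_fixed.centroid() - ring_moving.centroid()
        return np.eye(3), t
    if mode != "icp":
        raise InputError(f"unknown registration mode {mode!r}")
    R = np.eye(3)
    t = np.zeros(3)
    prev = None
    for _ in range(max_iter):
        cur = a @ R.T + t
        targets, dists = closest_point_on_ring(cur, ring_fixed)
        R, t = _kabsch(a, targets)
        resid = float(np.mean(dists))
        if prev is not None and abs(prev - resid) <= tol * max(prev, 1e-30):
            break
        prev = resid
    return R, t


def _kabsch(a: np.ndarray, b: np.ndarray):
    ca, cb = a.mean(0), b.mean(0)
    H = (a - ca).T @ (b - cb)
    U, S, Vt = np.linalg.svd(H)
    if S[-1] <= 1e-12 * max(S[0], 1e-30) and S[-2] <= 1e-12 * max(S[0], 1e-30):
        raise NumericalError("degenerate (collinear) ring: rigid fit is rank-deficient")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    return R, t


# ---------------------------------------------------------------------------
# boolean connection
# ---------------------------------------------------------------------------

@dataclass
class BooleanSpec:
    """Parameters of the boolean connection.

    ``epsilon`` is the clip offset pulling both kept parts back from the
    intersection curve; ``h`` the mesh size of the connection band.
    When unset, ``epsilon`` defaults to ``2 h``.
    """

    operation: str = "difference"
    h: float = 0.5
    epsilon: float | None = None
    clip_both: bool = True
    buffer_only: bool = True
    remesh: bool = True

    def __post_init__(self):
        if self.operation not in {"difference", "union", "intersection"}:
            raise InputError("operation must be difference, union or intersection")
        if self.h <= 0:
            raise InputError("h must be positive")
        if self.epsilon is None:
            self.epsilon = 2.0 * self.h
        if self.epsilon <= 0:
            raise InputError("epsilon must be positive")


def pair_rings(rings_a: list[Ring], rings_b: list[Ring]):
    """Pair rings across two sets by minimum average distance, nearest first."""
    if len(rings_a) != len(rings_b):
        raise TopologyError(
            f"ring count mismatch: {len(rings_a)} vs {len(rings_b)}"
        )
    cost = np.zeros((len(rings_a), len(rings_b)))
    for i, ra in enumerate(rings_a):
        for j, rb in enumerate(rings_b):
            _, d = closest_point_on_ring(ra.coords, rb)
            cost[i, j] = d.mean()
    pairs = []
    used_a: set = set()
    used_b: set = set()
    for _ in range(len(rings_a)):
        best = None
        for i in range(len(rings_a)):
            if i in used_a:
                continue
            for j in range(len(rings_b)):
                if j in used_b:
                    continue
                if best is None or cost[i, j] < cost[best[0], best[1]]:
                    best = (i, j)
        used_a.add(best[0])
        used_b.add(best[1])
        pairs.append(best)
    return pairs


PART1_TAG = 1
PART2_TAG = 2
BAND_TAG = 3


def boolean_connection(s1: TriSurface, s2: TriSurface,
                       spec: BooleanSpec) -> TriSurface:
    """Difference/union/intersection of two closed intersecting surfaces.

    Both inputs are clipped at their intersection, pulled back by
    ``epsilon`` along the surface distance from the intersection curve,
    optionally remeshed at size ``h`` (whole surface or a 3h-wide buffer
    around the cut), and reconnected with zipper bands.  Output tags:
    1 = kept part of s1, 2 = kept part of s2, 3 = connection band.
    """
    for name, s in (("s1", s1), ("s2", s2)):
        if not is_closed(s):
            raise TopologyError(f"{name} must be a closed surface")
    d1 = surface_distance(s1.points, s2, signed=True).values
    d2 = surface_distance(s2.points, s1, signed=True).values
    if d1.min() >= 0 or d1.max() <= 0 or d2.min() >= 0 or d2.max() <= 0:
        raise InputError("surfaces do not intersect")
    keep1, keep2 = {
        "difference": ("above", "below"),
        "union": ("above", "above"),
        "intersection": ("below", "below"),
    }[spec.operation]
    p1 = clip_by_field(s1, d1, 0.0, keep=keep1)
    p2 = clip_by_field(s2, d2, 0.0, keep=keep2)
    if spec.operation == "difference":
        # the kept part of s2 bounds the difference with reversed orientation
        p2.triangles = p2.triangles[:, ::-1].copy()
    parts = []
    for part, do_clip in ((p1, True), (p2, spec.clip_both)):
        if do_clip:
            part = _offset_clip(part, spec.epsilon)
        if spec.remesh:
            part = _remesh_near_boundary(part, spec.h, spec.buffer_only)
        parts.append(part)
    p1, p2 = parts
    p1.cell_tags[:] = PART1_TAG
    p2.cell_tags[:] = PART2_TAG
    merged = merge_surfaces([p1, p2], tol=0.0)
    rings1 = [r for r in extract_boundary_rings(merged)
              if r.point_indices[0] < p1.n_points]
    rings2 = [r for r in extract_boundary_rings(merged)
              if r.point_indices[0] >= p1.n_points]
    for i, j in pair_rings(rings1, rings2):
        merged = connect_rings(
            merged,
            Ring(merged, rings1[i].point_indices),
            Ring(merged, rings2[j].point_indices),
            BAND_TAG,
        )
    if spec.remesh:
        from .remeshing import RemeshSpec, isotropic_remesh

        merged = isotropic_remesh(
            merged, RemeshSpec(size_field=spec.h, target_tags={BAND_TAG})
        )
    merged.tag_names = {PART1_TAG: "surface_1", PART2_TAG: "surface_2",
                        BAND_TAG: "connection"}
    validate_surface(merged)
    return merged


def _offset_clip(part: TriSurface, epsilon: float) -> TriSurface:
    """Pull a clipped part back by ``epsilon`` from its boundary rings."""
    rings = extract_boundary_rings(part)
    if not rings:
        return part
    D = np.full(part.n_points, np.inf)
    for ring in rings:
        D = np.minimum(D, ring_distance(part.points, ring).values)
    return clip_by_field(part, D, epsilon, keep="above")


def _remesh_near_boundary(part: TriSurface, h: float,
                          buffer_only: bool) -> TriSurface:
    from .remeshing import RemeshSpec, isotropic_remesh

    part = part.copy()
    if buffer_only:
        rings = extract_boundary_rings(part)
        if not rings:
            return part
        D = np.full(part.n_points, np.inf)
        for ring in rings:
            D = np.minimum(D, ring_distance(part.points, ring).values)
        near = D[part.triangles].min(axis=1) <= 3.0 * h
        saved = part.cell_tags.copy()
        part.cell_tags = np.where(near, part.cell_tags + 1000, part.cell_tags)
        target = set(np.unique(part.cell_tags[near]).tolist())
        out = isotropic_remesh(part, RemeshSpec(size_field=h, target_tags=target))
        out.cell_tags = np.where(out.cell_tags >= 1000, out.cell_tags - 1000,
                                 out.cell_tags)
        del saved
        return out
    return isotropic_remesh(part, RemeshSpec(size_field=h, target_tags=None))


# ---------------------------------------------------------------------------
# harmonic connection
# ---------------------------------------------------------------------------

@dataclass
class HarmonicConnectSpec:
    """Parameters of the harmonic connection."""

    h: float = 0.5
    registration: str = "none"          # none | centroid | icp
    excluded_tags: set = dc_field(default_factory=set)
    free_ring_condition: str = "neumann"  # neumann | dirichlet
    remesh_deformed: bool = False
    band_tag: int | None = None

    def __post_init__(self):
        if self.h <= 0:
            raise InputError("h must be positive")
        if self.registration not in {"none", "centroid", "icp"}:
            raise InputError("registration must be none, centroid or icp")
        if self.free_ring_condition not in {"neumann", "dirichlet"}:
            raise InputError("free_ring_condition must be neumann or dirichlet")


def harmonic_connection(s_in: TriSurface, s_ref: TriSurface, ring_in: Ring,
                        ring_ref: Ring, spec: HarmonicConnectSpec) -> TriSurface:
    """Deform ``s_in`` so ``ring_in`` lands on ``ring_ref`` and connect.

    The displacement of the ring is extended over the deformable part of
    ``s_in`` as a (componentwise) harmonic field with zero deformation
    on the excluded tags and on Dirichlet free rings; the deformed
    surface is clipped ``h`` away from ``ring_ref`` and zipper-connected
    to ``s_ref``.
    """
    if ring_in.surface is not s_in or ring_ref.surface is not s_ref:
        raise InputError("ring_in must belong to s_in and ring_ref to s_ref")
    excluded_pts = set()
    if spec.excluded_tags:
        mask = np.isin(s_in.cell_tags, list(spec.excluded_tags))
        if mask.all():
            raise InputError("excluded tags cover the whole surface: "
                             "nothing to deform")
        excluded_pts = set(np.unique(s_in.triangles[mask]).tolist())
    moved = s_in
    if spec.registration != "none":
        R, t = register_rings(ring_in, ring_ref, mode=spec.registration)
        moved = s_in.copy()
        moved.points = s_in.points @ R.T + t
        ring_in = Ring(moved, ring_in.point_indices)
    dref = ring_distance(moved.points[ring_in.point_indices], ring_ref,
                         vector=True).vectors
    dirichlet = {int(i): dref[k] for k, i in enumerate(ring_in.point_indices)}
    for i in excluded_pts:
        dirichlet.setdefault(int(i), np.zeros(3))
    if spec.free_ring_condition == "dirichlet":
        ring_set = set(map(int, ring_in.point_indices))
        for ring in extract_boundary_rings(moved):
            pts = set(map(int, ring.point_indices))
            if pts != ring_set:
                for i in pts:
                    dirichlet.setdefault(i, np.zeros(3))
    phi = solve_harmonic(HarmonicProblem(moved, dirichlet)).values
    deformed = warp(moved, phi)
    dist = ring_distance(deformed.points, ring_ref).values
    clipped = clip_by_field(deformed, dist, spec.h, keep="above")
    band_tag = spec.band_tag
    if band_tag is None:
        band_tag = int(max(clipped.cell_tags.max(), s_ref.cell_tags.max())) + 1
    # connect along the ring of the clipped surface nearest to ring_ref
    rings = extract_boundary_rings(clipped)
    if not rings:
        raise TopologyError("clip removed the whole deformed surface")
    means = [closest_point_on_ring(r.coords, ring_ref)[1].mean() for r in rings]
    gap_ring = rings[int(np.argmin(means))]
    out = surface_connection(clipped, s_ref, gap_ring,
                             Ring(s_ref, ring_ref.point_indices), band_tag)
    if spec.remesh_deformed:
        from .remeshing import RemeshSpec, isotropic_remesh

        targets = set(np.unique(clipped.cell_tags).tolist()) | {band_tag}
        out = isotropic_remesh(out, RemeshSpec(size_field=spec.h,
                                               target_tags=targets))
    else:
        from .remeshing import RemeshSpec, isotropic_remesh

        out = isotropic_remesh(out, RemeshSpec(size_field=spec.h,
                                               target_tags={band_tag}))
    return out
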