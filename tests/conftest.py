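"""Shared fixtures and helpers for the cardiomesh test suite."""

import numpy as np
import pytest

from cardiomesh.core_mesh import TriSurface, extract_boundary_rings
from cardiomesh.synthetic_fixtures import star_tube


def smooth_ring_radii(n: int, rng: np.random.Generator,
                      base: float = 1.0) -> np.ndarray:
    """Smooth star-shaped ring radii: low-order Fourier perturbation.

    Emulates anatomical annuli (smooth closed curves), as opposed to
    white-noise stars whose radius jumps can degenerate the greedy band.
    """
    theta = 2 * np.pi * np.arange(n) / n
    r = np.full(n, base)
    for k in (1, 2, 3):
        r += rng.uniform(0.0, 0.15) * base * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return r


def ring_pair_surfaces(n1: int, n2: int, rng: np.random.Generator,
                       gap: float = 0.5):
    """Two open tube surfaces facing each other across ``gap``.

    Returns (s1, ring1, s2, ring2) where ring1 is the top rim of s1 at
    z=0 and ring2 the bottom rim of s2 at z=gap.
    """
    s1 = star_tube(smooth_ring_radii(n1, rng), z0=-0.5, z1=0.0)
    s2 = star_tube(smooth_ring_radii(n2, rng), z0=gap, z1=gap + 0.5,
                   phase=rng.uniform(0, 2 * np.pi))
    ring1 = [r for r in extract_boundary_rings(s1)
             if abs(s1.points[r.point_indices[0], 2]) < 1e-12][0]
    ring2 = [r for r in extract_boundary_rings(s2)
             if abs(s2.points[r.point_indices[0], 2] - gap) < 1e-12][0]
    return s1, ring1, s2, ring2


def interface_points(surface: TriSurface):
    """Point indices on edges shared by two cells of different tags."""
    em = {}
    for c, tri in enumerate(surface.triangles):
        for k in range(3):
            e = (min(tri[k], tri[(k + 1) % 3]), max(tri[k], tri[(k + 1) % 3]))
            em.setdefault(e, []).append(c)
    pts = set()
    for e, cells in em.items():
        if len(cells) == 2 and surface.cell_tags[cells[0]] != surface.cell_tags[cells[1]]:
            pts.update(int(v) for v in e)
    return sorted(pts)


def zipper_oracle(points: np.ndarray, ring1: np.ndarray,
                  ring2: np.ndarray) -> list:
    """Independent step-by-step transcription of the greedy band build.

    Maintains the explicit point set P and neighbor bookkeeping on the
    two cyclic rings, advancing by the shorter connecting edge and
    closing with the doubly-inserted start point; returns the triangles
    as unordered vertex triples in creation order.
    """
    ring1 = [int(i) for i in ring1]
    ring2 = [int(i) for i in ring2]
    n1, n2 = len(ring1), len(ring2)
    pos1 = {p: k for k, p in enumerate(ring1)}
    pos2 = {p: k for k, p in enumerate(ring2)}

    p10 = ring1[0]
    d = [np.linalg.norm(points[q] - points[p10]) for q in ring2]
    p20 = ring2[int(np.argmin(d))]
    P = [p10, p20]
    inserted = {p10: 1, p20: 1}
    T = []
    # first direction: successor on ring1; on ring2 the neighbor of p20
    # closest to that candidate
    p1s = ring1[(pos1[p10] + 1) % n1]
    nb = [ring2[(pos2[p20] + 1) % n2], ring2[(pos2[p20] - 1) % n2]]
    p2s = min(nb, key=lambda q: np.linalg.norm(points[q] - points[p1s]))
    dir1 = +1
    dir2 = +1 if p2s == ring2[(pos2[p20] + 1) % n2] else -1
    p1, p2 = p10, p20
    i = 2
    while i <= n1 + n2:
        d1 = (np.linalg.norm(points[p1s] - points[p2])
              if p1s is not None else np.inf)
        d2 = (np.linalg.norm(points[p2s] - points[p1])
              if p2s is not None else np.inf)
        if d1 <= d2:
            star = p1s
        else:
            star = p2s
        P.append(star)
        inserted[star] = inserted.get(star, 0) + 1
        i += 1
        T.append(frozenset((p1, p2, star)) if len({p1, p2, star}) == 3
                 else (p1, p2, star))
        if d1 <= d2:
            p1 = star
            nxt = ring1[(pos1[p1] + dir1) % n1]
            p1s = nxt if inserted.get(nxt, 0) == 0 or nxt == p10 else None
            if p1 == p10 and inserted[p10] == 2:
                p1s = None
        else:
            p2 = star
            nxt = ring2[(pos2[p2] + dir2) % n2]
            p2s = nxt if inserted.get(nxt, 0) == 0 or nxt == p20 else None
            if p2 == p20 and inserted[p20] == 2:
                p2s = None
    assert len(P) == n1 + n2 + 1
    if p1 == p10 and inserted[p10] == 2:
        T.append(frozenset((p1, p2, p20)))
    else:
        T.append(frozenset((p1, p2, p10)))
    return T


@pytest.fixture(scope="session")
def unit_icosphere():
    from cardiomesh.synthetic_fixtures import icosphere

    return icosphere(3)
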