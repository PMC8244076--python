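"""Piecewise-linear finite-element Laplace-Beltrami solver on surfaces.

The discrete operator is the classical cotangent-weight stiffness matrix
of P1 finite elements on a triangulated 2-manifold.  Dirichlet data is
imposed by symmetric elimination; every unconstrained boundary point
carries the natural (homogeneous Neumann) condition.  Vector-valued
problems are solved componentwise, sharing one factorization.

Obtuse triangles are permitted: the cotangent weights are used as-is,
without clamping, so the discrete maximum principle is only guaranteed
on non-obtuse meshes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core_mesh import TriSurface, triangle_areas
from .errors import InputError, NumericalError

__all__ = [
    "HarmonicProblem",
    "HarmonicSolution",
    "solve_harmonic",
    "cotangent_laplacian",
    "mixed_voronoi_areas",
    "min_triangle_angle",
]


@dataclass
class HarmonicProblem:
    """Laplace-Beltrami boundary-value problem on a surface domain.

    ``dirichlet`` maps point index -> prescribed value (scalar or 3-vector).
    All remaining boundary points get the natural homogeneous Neumann
    condition.
    """

    domain: TriSurface
    dirichlet: dict

    def __post_init__(self):
        if not self.dirichlet:
            raise InputError("Dirichlet set is empty: the system is singular")
        n = self.domain.n_points
        for idx in self.dirichlet:
            if not 0 <= int(idx) < n:
                raise InputError(f"Dirichlet index {idx} out of range")


@dataclass
class HarmonicSolution:
    """Solution values per domain point (scalar (n,) or vector (n, 3))."""

    values: np.ndarray


def min_triangle_angle(surface: TriSurface) -> float:
    """Smallest interior angle over all triangles (radians)."""
    p = surface.points
    t = surface.triangles
    angles = []
    for k in range(3):
        a = p[t[:, (k + 1) % 3]] - p[t[:, k]]
        b = p[t[:, (k + 2) % 3]] - p[t[:, k]]
        cosang = np.einsum("ij,ij->i", a, b) / np.maximum(
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1), 1e-300
        )
        angles.append(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(np.min(angles))


def cotangent_laplacian(surface: TriSurface) -> sp.csr_matrix:
    """Cotangent-weight stiffness matrix (positive semi-definite)."""
    p = surface.points
    t = surface.triangles
    n = surface.n_points
    rows, cols, vals = [], [], []
    for k in range(3):
        i = t[:, (k + 1) % 3]
        j = t[:, (k + 2) % 3]
        o = t[:, k]
        u = p[i] - p[o]
        v = p[j] - p[o]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-300)
        w = 0.5 * cot
        rows.extend([i, j, i, j])
        cols.extend([j, i, i, j])
        vals.extend([-w, -w, w, w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def mixed_voronoi_areas(surface: TriSurface) -> np.ndarray:
    """Per-vertex mixed Voronoi areas (Meyer et al. discrete operators).

    Non-obtuse triangles contribute the true Voronoi area; obtuse
    triangles contribute half their area at the obtuse vertex and a
    quarter at the other two.
    """
    p = surface.points
    t = surface.triangles
    areas = triangle_areas(surface)
    out = np.zeros(surface.n_points)
    cots = np.empty((len(t), 3))
    for k in range(3):
        u = p[t[:, (k + 1) % 3]] - p[t[:, k]]
        v = p[t[:, (k + 2) % 3]] - p[t[:, k]]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cots[:, k] = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-300)
    obtuse = cots.min(axis=1) < 0
    # non-obtuse: Voronoi formula 1/8 sum of opposite-edge contributions
    for k in range(3):
        i = t[:, k]
        lj = np.einsum("ij,ij->i", p[t[:, (k + 2) % 3]] - p[i],
                       p[t[:, (k + 2) % 3]] - p[i])
        lk = np.einsum("ij,ij->i", p[t[:, (k + 1) % 3]] - p[i],
                       p[t[:, (k + 1) % 3]] - p[i])
        contrib = (lj * cots[:, (k + 1) % 3] + lk * cots[:, (k + 2) % 3]) / 8.0
        contrib = np.where(obtuse,
                           np.where(cots[:, k] < 0, areas / 2.0, areas / 4.0),
                           contrib)
        np.add.at(out, i, contrib)
    return out


def solve_harmonic(problem: HarmonicProblem) -> HarmonicSolution:
    """Solve the discrete Laplace-Beltrami equation with the given data."""
    surf = problem.domain
    min_angle = min_triangle_angle(surf)
    if min_angle <= 1e-6:
        raise NumericalError(
            f"domain has degenerate triangles (min angle {min_angle:.2e} rad)"
        )
    K = cotangent_laplacian(surf)
    n = surf.n_points
    fixed_idx = np.array(sorted(int(i) for i in problem.dirichlet), dtype=np.int64)
    sample = np.asarray(problem.dirichlet[int(fixed_idx[0])], dtype=float)
    vector = sample.ndim == 1 and sample.shape == (3,)
    width = 3 if vector else 1
    g = np.zeros((len(fixed_idx), width))
    for r, i in enumerate(fixed_idx):
        g[r] = np.asarray(problem.dirichlet[int(i)], dtype=float)
    free = np.setdiff1d(np.arange(n), fixed_idx)
    values = np.zeros((n, width))
    values[fixed_idx] = g
    if len(free):
        Kff = K[free][:, free].tocsc()
        Kfd = K[free][:, fixed_idx]
        rhs = -Kfd @ g
        try:
            lu = spla.splu(Kff)
            sol = np.column_stack([lu.solve(rhs[:, c]) for c in range(width)])
        except RuntimeError as exc:
            raise NumericalError(
                f"sparse solve failed ({exc}); min triangle angle "
                f"{min_angle:.3e} rad"
            ) from exc
        if not np.all(np.isfinite(sol)):
            raise NumericalError(
                f"singular or ill-conditioned system; min triangle angle "
                f"{min_angle:.3e} rad"
            )
        values[free] = sol
    return HarmonicSolution(values if vector else values[:, 0])
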