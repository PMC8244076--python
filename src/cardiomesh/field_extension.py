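"""Harmonic extension of fields defined on a tagged subregion.

A scalar or vector field known only on a set of source tags is extended
to the rest of the surface as the solution of a Laplace-Beltrami
problem: the shared boundary with the source region carries the known
values as Dirichlet data, optional zero tags are clamped to zero, and
the remaining free boundary rings are either left natural (homogeneous
Neumann) or clamped to user constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .core_mesh import TriSurface, extract_boundary_rings, extract_cells
from .harmonic_solver import HarmonicProblem, solve_harmonic
from .errors import InputError

__all__ = ["ExtensionSpec", "harmonic_extension"]


@dataclass
class ExtensionSpec:
    """Where the field lives and how the free boundaries are treated.

    ``ring_values`` maps the index of a free boundary ring (position in
    the deterministic ring ordering of the extension domain) to a
    constant Dirichlet value; rings not listed follow
    ``free_ring_default`` (``"neumann"`` or ``"dirichlet-zero"``).
    """

    source_tags: set
    zero_tags: set = dc_field(default_factory=set)
    ring_values: dict = dc_field(default_factory=dict)
    free_ring_default: str = "neumann"
    normalize: bool = False

    def __post_init__(self):
        if not self.source_tags:
            raise InputError("source_tags must be non-empty")
        if self.free_ring_default not in {"neumann", "dirichlet-zero"}:
            raise InputError(
                "free_ring_default must be 'neumann' or 'dirichlet-zero'"
            )


def harmonic_extension(surface: TriSurface, field_name: str,
                       spec: ExtensionSpec) -> TriSurface:
    """Extend a point field from the source tags over the whole surface.

    The output surface carries the field with its original values on the
    source tags, zero on the zero tags, and the harmonic extension in
    between.  Vector fields are extended componentwise; with
    ``spec.normalize`` the extended vectors are rescaled to unit length
    afterwards (useful for fiber-like direction fields).
    """
    if field_name not in surface.point_fields:
        raise InputError(f"missing point field {field_name!r}")
    values = np.asarray(surface.point_fields[field_name], dtype=float)
    vector = values.ndim == 2
    src_mask = np.isin(surface.cell_tags, list(spec.source_tags))
    zero_mask = np.isin(surface.cell_tags, list(spec.zero_tags)) \
        if spec.zero_tags else np.zeros(surface.n_cells, dtype=bool)
    star_mask = ~(src_mask | zero_mask)
    if not star_mask.any():
        raise InputError("extension domain is empty: nothing to extend")
    src_pts = set(np.unique(surface.triangles[src_mask]).tolist())
    zero_pts = set(np.unique(surface.triangles[zero_mask]).tolist())
    domain = extract_cells(surface, star_mask)
    dom_pts = np.unique(surface.triangles[star_mask])
    local = {int(g): i for i, g in enumerate(dom_pts)}

    dirichlet: dict = {}
    for g in dom_pts:
        g = int(g)
        if g in src_pts:
            dirichlet[local[g]] = values[g]
        elif g in zero_pts:
            dirichlet[local[g]] = (np.zeros(3) if vector else 0.0)
    # free rings: boundary rings of the domain not constrained above
    free_rings = []
    for ring in extract_boundary_rings(domain):
        if all(i not in dirichlet for i in map(int, ring.point_indices)):
            free_rings.append(ring)
    for k, ring in enumerate(free_rings):
        if k in spec.ring_values:
            g = spec.ring_values[k]
            for i in map(int, ring.point_indices):
                dirichlet[i] = (np.full(3, g) if vector and np.isscalar(g)
                                else np.asarray(g, dtype=float) if vector
                                else float(g))
        elif spec.free_ring_default == "dirichlet-zero":
            for i in map(int, ring.point_indices):
                dirichlet[i] = (np.zeros(3) if vector else 0.0)
    sol = solve_harmonic(HarmonicProblem(domain, dirichlet)).values

    out = surface.copy()
    ext = np.zeros_like(values)
    used = np.unique(surface.triangles[src_mask])
    ext[used] = values[used]
    ext[dom_pts] = sol
    # source values win at shared points (identity on the source region)
    ext[list(src_pts)] = values[list(src_pts)]
    if spec.zero_tags:
        only_zero = sorted(zero_pts - src_pts - set(map(int, dom_pts)))
        if only_zero:
            ext[only_zero] = 0.0
    if spec.normalize and vector:
        lens = np.linalg.norm(ext, axis=1)
        lens[lens == 0] = 1.0
        ext = ext / lens[:, None]
    out.point_fields[field_name] = ext
    return out
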