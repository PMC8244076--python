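"""Tag-preserving isotropic surface remeshing driven by a sizing field.

Incremental remeshing in the Botsch-Kobbelt style: edges longer than
4/3 of the local target size are split, edges shorter than 4/5 are
collapsed, interior edges are flipped toward the regular valence, and
vertices are tangentially relaxed and projected back onto the input
surface.  The action is restricted to a set of target tags: cells of
other tags are left untouched, vertices they use are frozen, and edges
on tag-tag interfaces or on the surface boundary are treated as
constraint polylines whose vertices only slide along the original
polyline geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_mesh import TriSurface, validate_surface
from .distance_fields import closest_point_on_surface
from .errors import InputError

__all__ = ["RemeshSpec", "isotropic_remesh"]

FREE, CONSTRAINED, FIXED = 0, 1, 2


@dataclass
class RemeshSpec:
    """Remeshing parameters.

    ``size_field`` is either a constant target edge length (mm) or the
    name of a per-point scalar field; ``target_tags`` restricts the
    operation (None = every tag); tag boundaries are always preserved.
    """

    size_field: object = 1.0
    target_tags: set | None = None
    iterations: int = 10


def _project_to_segments(q: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Closest point on a segment soup per query point."""
    a, b = segs[:, 0], segs[:, 1]
    ab = b - a
    ab2 = np.maximum(np.einsum("si,si->s", ab, ab), 1e-300)
    qa = q[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("ksi,si->ks", qa, ab) / ab2[None, :], 0.0, 1.0)
    cp = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d2 = np.einsum("ksi,ksi->ks", cp - q[:, None, :], cp - q[:, None, :])
    best = np.argmin(d2, axis=1)
    return cp[np.arange(len(q)), best]


class _Remesher:
    def __init__(self, surface: TriSurface, spec: RemeshSpec):
        self.spec = spec
        self.orig = surface
        n = surface.n_points
        if spec.target_tags is None:
            self.target = np.ones(surface.n_cells, dtype=bool)
        else:
            self.target = np.isin(surface.cell_tags, list(spec.target_tags))
        if isinstance(spec.size_field, str):
            if spec.size_field not in surface.point_fields:
                raise InputError(f"missing size field {spec.size_field!r}")
            hvals = np.asarray(surface.point_fields[spec.size_field], dtype=float)
        else:
            hvals = np.full(n, float(spec.size_field))
        if np.any(hvals[np.unique(surface.triangles[self.target])] <= 0):
            raise InputError("size field must be positive on the target region")
        self.V = [p.copy() for p in surface.points]
        self.H = list(map(float, hvals))
        self.PF = {k: [np.array(v) for v in np.asarray(vals)]
                   for k, vals in surface.point_fields.items()}
        self.F: list = [list(map(int, t)) for t in surface.triangles]
        self.FT: list = list(map(int, surface.cell_tags))
        self.Ftarget: list = list(map(bool, self.target))
        self.alive: list = [True] * len(self.F)
        self.v2f: list = [set() for _ in range(n)]
        for f, tri in enumerate(self.F):
            for v in tri:
                self.v2f[v].add(f)
        self.vclass = [FREE] * n
        for f, tri in enumerate(self.F):
            if not self.Ftarget[f]:
                for v in tri:
                    self.vclass[v] = FIXED
        constraint_segs = []
        cons_edges: dict = {}
        for (u, v), faces in self._edge_map().items():
            if self._is_constraint(u, v, faces):
                constraint_segs.append([surface.points[u], surface.points[v]])
                cons_edges.setdefault(u, []).append(v)
                cons_edges.setdefault(v, []).append(u)
                for w in (u, v):
                    if self.vclass[w] == FREE:
                        self.vclass[w] = CONSTRAINED
        # pin polyline corners: junctions and vertices where the
        # constraint polyline bends by more than 30 degrees
        for v, nbrs in cons_edges.items():
            if self.vclass[v] != CONSTRAINED:
                continue
            if len(nbrs) != 2:
                self.vclass[v] = FIXED
                continue
            d1 = surface.points[nbrs[0]] - surface.points[v]
            d2 = surface.points[v] - surface.points[nbrs[1]]
            cosang = np.dot(d1, d2) / max(
                np.linalg.norm(d1) * np.linalg.norm(d2), 1e-300)
            if cosang < np.cos(np.radians(30.0)):
                self.vclass[v] = FIXED
        self.constraints = (np.array(constraint_segs)
                            if constraint_segs else np.zeros((0, 2, 3)))

    # -- topology helpers ---------------------------------------------------

    def _edge_map(self) -> dict:
        em: dict = {}
        for f, tri in enumerate(self.F):
            if not self.alive[f]:
                continue
            for k in range(3):
                e = (min(tri[k], tri[(k + 1) % 3]),
                     max(tri[k], tri[(k + 1) % 3]))
                em.setdefault(e, []).append(f)
        return em

    def _edge_faces(self, u: int, v: int) -> list:
        return [f for f in self.v2f[u] & self.v2f[v] if self.alive[f]]

    def _is_constraint(self, u: int, v: int, faces) -> bool:
        live = [f for f in faces if self.alive[f]]
        if len(live) == 1:
            return True
        return len({self.FT[f] for f in live}) > 1

    def _he(self, u: int, v: int) -> float:
        return 0.5 * (self.H[u] + self.H[v])

    def _len(self, u: int, v: int) -> float:
        return float(np.linalg.norm(self.V[u] - self.V[v]))

    def _add_vertex(self, pos, h, cls, interp=None):
        self.V.append(np.asarray(pos, dtype=float))
        self.H.append(float(h))
        self.vclass.append(cls)
        self.v2f.append(set())
        for k, vals in self.PF.items():
            if interp is None:
                vals.append(np.zeros_like(vals[0]))
            else:
                a, b = interp
                vals.append(0.5 * (vals[a] + vals[b]))
        return len(self.V) - 1

    def _add_face(self, tri, tag):
        self.F.append(list(tri))
        self.FT.append(tag)
        self.Ftarget.append(True)
        self.alive.append(True)
        fid = len(self.F) - 1
        for v in tri:
            self.v2f[v].add(fid)
        return fid

    def _kill_face(self, f):
        self.alive[f] = False
        for v in self.F[f]:
            self.v2f[v].discard(f)

    def _neighbors(self, v: int) -> set:
        out = set()
        for f in self.v2f[v]:
            if self.alive[f]:
                out.update(self.F[f])
        out.discard(v)
        return out

    # -- passes -------------------------------------------------------------

    def split_pass(self):
        for (u, v), _ in list(self._edge_map().items()):
            faces = self._edge_faces(u, v)
            if not faces or not all(self.Ftarget[f] for f in faces):
                continue
            if self._len(u, v) <= (4.0 / 3.0) * self._he(u, v):
                continue
            constrained = self._is_constraint(u, v, faces)
            cls = CONSTRAINED if constrained else FREE
            mid = self._add_vertex(0.5 * (self.V[u] + self.V[v]),
                                   self._he(u, v), cls, interp=(u, v))
            for f in faces:
                a, b, c = self.F[f]
                tag = self.FT[f]
                self._kill_face(f)
                tri = [a, b, c]
                iu, iv = tri.index(u), tri.index(v)
                t1 = tri.copy()
                t1[iv] = mid
                t2 = tri.copy()
                t2[iu] = mid
                self._add_face(t1, tag)
                self._add_face(t2, tag)

    def collapse_pass(self):
        for (u, v), _ in list(self._edge_map().items()):
            faces = self._edge_faces(u, v)
            if not faces or not all(self.Ftarget[f] for f in faces):
                continue
            if self._len(u, v) >= 0.8 * self._he(u, v):
                continue
            cu, cv = self.vclass[u], self.vclass[v]
            constrained = self._is_constraint(u, v, faces)
            if cu == FIXED and cv == FIXED:
                continue
            if cu > cv:
                keep, rem = u, v
            elif cv > cu:
                keep, rem = v, u
            else:
                keep, rem = u, v
            if self.vclass[rem] == CONSTRAINED and not constrained:
                continue
            if any(not self.Ftarget[f] for f in self.v2f[rem] if self.alive[f]):
                continue
            # link condition: shared neighbors must be the shared-face apexes
            apexes = {w for f in faces for w in self.F[f]} - {u, v}
            if self._neighbors(u) & self._neighbors(v) != apexes:
                continue
            if self.vclass[keep] == self.vclass[rem]:
                new_pos = 0.5 * (self.V[u] + self.V[v])
            else:
                new_pos = self.V[keep].copy()
            if not self._collapse_valid(keep, rem, faces, new_pos):
                continue
            self.V[keep] = new_pos
            self.H[keep] = self._he(u, v)
            for k, vals in self.PF.items():
                vals[keep] = 0.5 * (vals[u] + vals[v])
            for f in faces:
                self._kill_face(f)
            for f in list(self.v2f[rem]):
                if not self.alive[f]:
                    continue
                tri = self.F[f]
                tri[tri.index(rem)] = keep
                self.v2f[rem].discard(f)
                self.v2f[keep].add(f)

    def _collapse_valid(self, keep, rem, dead_faces, new_pos) -> bool:
        for v0 in (keep, rem):
            for f in self.v2f[v0]:
                if not self.alive[f] or f in dead_faces:
                    continue
                tri = [new_pos if w in (keep, rem) else self.V[w]
                       for w in self.F[f]]
                old = [self.V[w] for w in self.F[f]]
                n_new = np.cross(tri[1] - tri[0], tri[2] - tri[0])
                n_old = np.cross(old[1] - old[0], old[2] - old[0])
                if np.linalg.norm(n_new) < 1e-14:
                    return False
                if np.dot(n_new, n_old) <= 0:
                    return False
                for k in range(3):
                    a = tri[k]
                    b = tri[(k + 1) % 3]
                    wa = self.F[f][k]
                    wb = self.F[f][(k + 1) % 3]
                    hmean = self._he(wa if wa not in (keep, rem) else keep,
                                     wb if wb not in (keep, rem) else keep)
                    if np.linalg.norm(a - b) > (4.0 / 3.0) * hmean:
                        return False
        return True

    def flip_pass(self):
        for (u, v), _ in list(self._edge_map().items()):
            faces = self._edge_faces(u, v)
            if len(faces) != 2 or not all(self.Ftarget[f] for f in faces):
                continue
            if self.FT[faces[0]] != self.FT[faces[1]]:
                continue
            a = [w for w in self.F[faces[0]] if w not in (u, v)][0]
            b = [w for w in self.F[faces[1]] if w not in (u, v)][0]
            if a == b or b in self._neighbors(a):
                continue

            def val(w):
                return len(self._neighbors(w))

            def opt(w):
                return 4 if self.vclass[w] != FREE else 6

            before = sum((val(w) - opt(w)) ** 2 for w in (u, v, a, b))
            after = ((val(u) - 1 - opt(u)) ** 2 + (val(v) - 1 - opt(v)) ** 2
                     + (val(a) + 1 - opt(a)) ** 2 + (val(b) + 1 - opt(b)) ** 2)
            if after >= before:
                continue
            if not self._flip_valid(u, v, a, b, faces):
                continue
            tag = self.FT[faces[0]]
            # keep orientation: new triangles share directed edge a->b / b->a
            f0 = self.F[faces[0]]
            iu = f0.index(u)
            if f0[(iu + 1) % 3] == v:
                t1, t2 = [u, b, a], [v, a, b]
            else:
                t1, t2 = [u, a, b], [v, b, a]
            for f in faces:
                self._kill_face(f)
            self._add_face(t1, tag)
            self._add_face(t2, tag)

    def _flip_valid(self, u, v, a, b, faces) -> bool:
        n_old = np.zeros(3)
        for f in faces:
            tri = [self.V[w] for w in self.F[f]]
            n_old += np.cross(tri[1] - tri[0], tri[2] - tri[0])
        for tri in ([self.V[u], self.V[b], self.V[a]],
                    [self.V[v], self.V[a], self.V[b]]):
            n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            if np.linalg.norm(n) < 1e-14 or np.dot(n, n_old) <= 0:
                return False
        return True

    def relax_pass(self):
        free_ids = [v for v in range(len(self.V))
                    if self.vclass[v] == FREE and any(
                        self.alive[f] for f in self.v2f[v])]
        new_pos = {}
        for v in free_ids:
            acc = np.zeros(3)
            wsum = 0.0
            for f in self.v2f[v]:
                if not self.alive[f]:
                    continue
                tri = [self.V[w] for w in self.F[f]]
                area = 0.5 * np.linalg.norm(
                    np.cross(tri[1] - tri[0], tri[2] - tri[0]))
                acc += area * (tri[0] + tri[1] + tri[2]) / 3.0
                wsum += area
            if wsum > 0:
                new_pos[v] = acc / wsum
        if new_pos:
            q = np.array([new_pos[v] for v in free_ids if v in new_pos])
            proj, _, _ = closest_point_on_surface(q, self.orig)
            for i, v in enumerate([v for v in free_ids if v in new_pos]):
                self.V[v] = proj[i]
        # constrained vertices slide along the original constraint polylines
        if len(self.constraints) == 0:
            return
        cons_ids = []
        targets = []
        for v in range(len(self.V)):
            if self.vclass[v] != CONSTRAINED:
                continue
            nbrs = [w for w in self._neighbors(v)
                    if self.vclass[w] != FREE
                    and self._is_constraint(*sorted((v, w)),
                                            self._edge_faces(v, w))]
            if len(nbrs) == 2:
                cons_ids.append(v)
                targets.append(0.5 * (self.V[nbrs[0]] + self.V[nbrs[1]]))
        if cons_ids:
            proj = _project_to_segments(np.array(targets), self.constraints)
            for i, v in enumerate(cons_ids):
                self.V[v] = proj[i]

    # -- driver -------------------------------------------------------------

    def run(self) -> TriSurface:
        for _ in range(self.spec.iterations):
            self.split_pass()
            self.collapse_pass()
            self.flip_pass()
            self.relax_pass()
        live = [f for f in range(len(self.F)) if self.alive[f]]
        used = sorted({v for f in live for v in self.F[f]})
        remap = {v: i for i, v in enumerate(used)}
        out = TriSurface(
            np.array([self.V[v] for v in used]),
            np.array([[remap[v] for v in self.F[f]] for f in live],
                     dtype=np.int64),
            np.array([self.FT[f] for f in live], dtype=np.int64),
            {k: np.array([vals[v] for v in used])
             for k, vals in self.PF.items()},
            tag_names=dict(self.orig.tag_names),
        )
        if isinstance(self.spec.size_field, str):
            out.point_fields[self.spec.size_field] = np.array(
                [self.H[v] for v in used])
        validate_surface(out)
        return out


def isotropic_remesh(surface: TriSurface, spec: RemeshSpec) -> TriSurface:
    """Remesh the target tags of a surface toward the local size field."""
    if spec.target_tags is not None and len(spec.target_tags) == 0:
        return surface.copy()
    remesher = _Remesher(surface, spec)
    if not remesher.target.any():
        return surface.copy()
    return remesher.run()
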