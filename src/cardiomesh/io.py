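"""Mesh file I/O.

VTK legacy ASCII is the canonical format because it carries point/cell
data: surfaces as POLYDATA, tet/hex meshes as UNSTRUCTURED_GRID with an
integer CELL_DATA SCALARS array named "tag".  Volume meshes store their
tagged boundary faces as extra triangle/quad cells in the same grid.
STL, OBJ and PLY are untagged import/export conveniences handled through
trimesh; reading an STL deduplicates the triangle soup exactly.
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .core_mesh import TriSurface, TetMesh, HexMesh
from .errors import InputError, ParseError

__all__ = ["read_mesh", "write_mesh"]

_SURFACE_FORMATS = {"stl", "obj", "ply", "vtk"}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _SURFACE_FORMATS:
        raise InputError(f"unsupported format {fmt!r} (use STL, OBJ, PLY or VTK)")
    return fmt


def read_mesh(path: str, fmt: str | None = None):
    """Read a surface or volume mesh; returns TriSurface, TetMesh or HexMesh."""
    fmt = _infer_format(path, fmt)
    if fmt == "vtk":
        return _read_vtk(path)
    import trimesh

    mesh = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    pts = np.asarray(mesh.vertices, dtype=float)
    tris = np.asarray(mesh.faces, dtype=np.int64)
    if fmt == "stl":
        # STL is a triangle soup: unify exactly coincident vertices
        uniq, remap = np.unique(pts, axis=0, return_inverse=True)
        pts, tris = uniq, remap[tris]
    return TriSurface(pts, tris)


def write_mesh(mesh, path: str, fmt: str | None = None) -> None:
    """Write a mesh; tags/fields survive only in VTK legacy (and PLY geometry)."""
    fmt = _infer_format(path, fmt)
    if fmt == "vtk":
        _write_vtk(mesh, path)
        return
    if not isinstance(mesh, TriSurface):
        raise InputError(f"volume meshes can only be written as VTK, not {fmt}")
    if np.any(mesh.cell_tags != 0) or mesh.point_fields or mesh.cell_fields:
        warnings.warn(
            f"writing tagged surface to {fmt.upper()}: tags and fields dropped",
            stacklevel=2,
        )
    import trimesh

    tm = trimesh.Trimesh(mesh.points, mesh.triangles, process=False)
    tm.export(path, file_type=fmt)


# ---------------------------------------------------------------------------
# VTK legacy ASCII
# ---------------------------------------------------------------------------

class _Lines:
    """Line cursor that remembers position for parse errors."""

    def __init__(self, text: str):
        self.lines = text.splitlines()
        self.i = 0

    def next_tokens(self):
        while self.i < len(self.lines):
            self.i += 1
            toks = self.lines[self.i - 1].split()
            if toks:
                return toks
        return None

    def read_numbers(self, count: int, dtype=float) -> np.ndarray:
        out: list = []
        while len(out) < count:
            toks = self.next_tokens()
            if toks is None:
                raise ParseError(
                    f"unexpected end of file: expected {count} values, got {len(out)}",
                    self.i,
                )
            try:
                out.extend(dtype(t) for t in toks)
            except ValueError as exc:
                raise ParseError(str(exc), self.i) from exc
        if len(out) != count:
            raise ParseError(f"ragged data block ({len(out)} != {count})", self.i)
        return np.array(out)


def _read_vtk(path: str):
    with open(path) as fh:
        cur = _Lines(fh.read())
    header = cur.next_tokens()
    if header is None or not header[0].startswith("#"):
        raise ParseError("missing VTK header", 1)
    cur.next_tokens()  # title
    enc = cur.next_tokens()
    if enc is None or enc[0].upper() != "ASCII":
        raise ParseError("only ASCII VTK legacy files are supported", cur.i)
    ds = cur.next_tokens()
    if ds is None or ds[0].upper() != "DATASET":
        raise ParseError("expected DATASET line", cur.i)
    kind = ds[1].upper()
    if kind not in {"POLYDATA", "UNSTRUCTURED_GRID"}:
        raise ParseError(f"unsupported dataset {kind}", cur.i)

    points = None
    polys = None
    cells = None
    cell_types = None
    point_data: dict = {}
    cell_data: dict = {}
    toks = cur.next_tokens()
    n_cells_total = 0
    while toks is not None:
        kw = toks[0].upper()
        if kw == "POINTS":
            n = int(toks[1])
            points = cur.read_numbers(3 * n).reshape(n, 3)
        elif kw == "POLYGONS":
            m, total = int(toks[1]), int(toks[2])
            data = cur.read_numbers(total, int).astype(np.int64)
            polys, k = [], 0
            for _ in range(m):
                cnt = int(data[k])
                if cnt != 3:
                    raise ParseError("only triangle polygons supported", cur.i)
                polys.append(data[k + 1:k + 4])
                k += cnt + 1
            polys = np.array(polys, dtype=np.int64)
            n_cells_total = m
        elif kw == "CELLS":
            m, total = int(toks[1]), int(toks[2])
            data = cur.read_numbers(total, int).astype(np.int64)
            cells, k = [], 0
            for _ in range(m):
                cnt = int(data[k])
                cells.append(data[k + 1:k + 1 + cnt])
                k += cnt + 1
            n_cells_total = m
        elif kw == "CELL_TYPES":
            m = int(toks[1])
            cell_types = cur.read_numbers(m, int).astype(int)
        elif kw in {"POINT_DATA", "CELL_DATA"}:
            n = int(toks[1])
            target = point_data if kw == "POINT_DATA" else cell_data
            toks = _read_data_arrays(cur, n, target)
            continue
        else:
            raise ParseError(f"unexpected keyword {toks[0]!r}", cur.i)
        toks = cur.next_tokens()

    if points is None:
        raise ParseError("file has no POINTS block", cur.i)
    tags = cell_data.pop("tag", np.zeros(n_cells_total, dtype=np.int64)).astype(np.int64)
    if kind == "POLYDATA":
        if polys is None:
            raise ParseError("POLYDATA has no POLYGONS block", cur.i)
        return TriSurface(points, polys, tags, point_data, cell_data)
    return _assemble_grid(points, cells, cell_types, tags, point_data, cell_data, cur)


def _assemble_grid(points, cells, cell_types, tags, point_data, cell_data, cur):
    if cells is None or cell_types is None:
        raise ParseError("UNSTRUCTURED_GRID needs CELLS and CELL_TYPES", cur.i)
    cell_types = np.asarray(cell_types)
    tet_m = cell_types == 10
    tri_m = cell_types == 5
    hex_m = cell_types == 12
    quad_m = cell_types == 9
    if not np.all(tet_m | tri_m | hex_m | quad_m):
        raise ParseError("only tet/hex volume cells and tri/quad faces supported", cur.i)

    def gather(mask, width):
        sel = [cells[i] for i in np.nonzero(mask)[0]]
        if not sel:
            return np.zeros((0, width), dtype=np.int64)
        return np.array(sel, dtype=np.int64)

    def split_cd(mask):
        return {k: np.asarray(v)[mask] for k, v in cell_data.items()}

    if hex_m.any():
        return HexMesh(points, gather(hex_m, 8), tags[hex_m],
                       gather(quad_m, 4), tags[quad_m],
                       point_data, split_cd(hex_m))
    return TetMesh(points, gather(tet_m, 4), tags[tet_m],
                   gather(tri_m, 3) if tri_m.any() else None,
                   tags[tri_m] if tri_m.any() else None,
                   point_data, split_cd(tet_m))


def _read_data_arrays(cur: _Lines, n: int, target: dict):
    """Read SCALARS/VECTORS blocks until the next section keyword."""
    toks = cur.next_tokens()
    while toks is not None:
        kw = toks[0].upper()
        if kw == "SCALARS":
            name, dtype = toks[1], toks[2].lower()
            lut = cur.next_tokens()
            if lut is None or lut[0].upper() != "LOOKUP_TABLE":
                raise ParseError("SCALARS must be followed by LOOKUP_TABLE", cur.i)
            caster = int if dtype in {"int", "long", "short"} else float
            target[name] = cur.read_numbers(n, caster)
            if caster is int:
                target[name] = target[name].astype(np.int64)
        elif kw == "VECTORS":
            name = toks[1]
            target[name] = cur.read_numbers(3 * n).reshape(n, 3)
        else:
            return toks
        toks = cur.next_tokens()
    return None


def _fmt_floats(arr: np.ndarray) -> str:
    return "\n".join(" ".join(f"{v:.10g}" for v in row) for row in arr)


def _write_data_arrays(fh, fields: dict, n: int, kind: str) -> None:
    if not fields:
        return
    fh.write(f"{kind} {n}\n")
    for name, values in fields.items():
        values = np.asarray(values)
        if values.ndim == 2 and values.shape[1] == 3:
            fh.write(f"VECTORS {name} float\n")
            fh.write(_fmt_floats(values) + "\n")
        else:
            if np.issubdtype(values.dtype, np.integer):
                fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(str(int(v)) for v in values) + "\n")
            else:
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{float(v):.10g}" for v in values) + "\n")


def _write_vtk(mesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\ncardiomesh output\nASCII\n")
        if isinstance(mesh, TriSurface):
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {mesh.n_points} float\n")
            fh.write(_fmt_floats(mesh.points) + "\n")
            m = mesh.n_cells
            fh.write(f"POLYGONS {m} {4 * m}\n")
            fh.write("\n".join(
                "3 " + " ".join(map(str, t)) for t in mesh.triangles
            ) + "\n")
            cd = {"tag": mesh.cell_tags, **mesh.cell_fields}
            _write_data_arrays(fh, cd, m, "CELL_DATA")
            _write_data_arrays(fh, mesh.point_fields, mesh.n_points, "POINT_DATA")
        elif isinstance(mesh, (TetMesh, HexMesh)):
            volume = mesh.tets if isinstance(mesh, TetMesh) else mesh.hexes
            faces = (mesh.boundary_faces if isinstance(mesh, TetMesh)
                     else mesh.boundary_quads)
            vtype = 10 if isinstance(mesh, TetMesh) else 12
            ftype = 5 if isinstance(mesh, TetMesh) else 9
            fh.write("DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {mesh.n_points} float\n")
            fh.write(_fmt_floats(mesh.points) + "\n")
            m = len(volume) + len(faces)
            total = len(volume) * (volume.shape[1] + 1) + len(faces) * (faces.shape[1] + 1)
            fh.write(f"CELLS {m} {total}\n")
            for cell in volume:
                fh.write(f"{len(cell)} " + " ".join(map(str, cell)) + "\n")
            for face in faces:
                fh.write(f"{len(face)} " + " ".join(map(str, face)) + "\n")
            fh.write(f"CELL_TYPES {m}\n")
            fh.write("\n".join([str(vtype)] * len(volume) + [str(ftype)] * len(faces)) + "\n")
            tags = np.concatenate([mesh.cell_tags, mesh.boundary_tags])
            cd = {"tag": tags}
            for k, v in mesh.cell_fields.items():
                v = np.asarray(v)
                pad_shape = (len(faces),) + v.shape[1:]
                cd[k] = np.concatenate([v, np.zeros(pad_shape, dtype=v.dtype)])
            _write_data_arrays(fh, cd, m, "CELL_DATA")
            _write_data_arrays(fh, mesh.point_fields, mesh.n_points, "POINT_DATA")
        else:
            raise InputError(f"cannot write object of type {type(mesh).__name__}")
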