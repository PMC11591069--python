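"""Point-cloud file I/O.

PLY is the canonical interchange format (both ASCII and binary little
endian dialects are read; writing defaults to binary for losslessness).
PCD v0.7 is accepted read-only. Only vertex x/y/z (plus optional
nx/ny/nz) are interpreted; other properties are skipped with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .geometry import PointCloud

__all__ = ["read_ply", "write_ply", "read_pcd"]

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


class PlyParseError(ValueError):
    """Malformed PLY content; message names the offending header line."""


def _parse_ply_header(fh):
    """Returns (fmt, elements, header_len). elements = [(name, count, [(prop, dtype)...])]."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise PlyParseError(f"not a PLY file (first line: {magic!r})")
    fmt = None
    elements = []
    while True:
        raw = fh.readline()
        if not raw:
            raise PlyParseError("unexpected end of header (no end_header line)")
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        tokens = line.split()
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] not in (
                "ascii",
                "binary_little_endian",
            ):
                raise PlyParseError(f"unsupported format line: {line!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            if len(tokens) != 3:
                raise PlyParseError(f"malformed element line: {line!r}")
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise PlyParseError(f"property before any element: {line!r}")
            if tokens[1] == "list":
                if len(tokens) != 5:
                    raise PlyParseError(f"malformed list property line: {line!r}")
                elements[-1][2].append((tokens[4], ("list", tokens[2], tokens[3])))
            else:
                if len(tokens) != 3 or tokens[1] not in _PLY_DTYPES:
                    raise PlyParseError(f"malformed property line: {line!r}")
                elements[-1][2].append((tokens[2], _PLY_DTYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
        else:
            raise PlyParseError(f"unrecognized header line: {line!r}")
    if fmt is None:
        raise PlyParseError("header has no format line")
    return fmt, elements


def read_ply(path) -> PointCloud:
    """Read a PLY point cloud (vertex x/y/z, optional nx/ny/nz).

    Extra vertex properties (color etc.) are ignored with a warning;
    non-vertex elements (faces) are skipped.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, elements = _parse_ply_header(fh)
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise PlyParseError("no vertex element in PLY header")
        _, count, props = vertex
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise PlyParseError(f"vertex element lacks required property '{axis}'")
        if any(isinstance(p[1], tuple) for p in props):
            raise PlyParseError("list-typed vertex properties are not supported")
        extras = [n for n in names if n not in ("x", "y", "z", "nx", "ny", "nz")]
        if extras:
            warnings.warn(f"ignoring extra PLY vertex properties: {extras}", stacklevel=2)

        if fmt == "ascii":
            rows = []
            for i in range(count):
                line = fh.readline()
                if not line:
                    raise PlyParseError(f"vertex data truncated at row {i}")
                values = line.split()
                if len(values) < len(props):
                    raise PlyParseError(f"vertex row {i} has {len(values)} values, expected {len(props)}")
                rows.append([float(v) for v in values[: len(props)]])
            data = {n: np.array([r[j] for r in rows]) for j, n in enumerate(names)}
        else:
            dtype = np.dtype([(n, "<" + t) for n, t in props])
            buf = fh.read(dtype.itemsize * count)
            if len(buf) < dtype.itemsize * count:
                raise PlyParseError("vertex data truncated")
            rec = np.frombuffer(buf, dtype=dtype, count=count)
            data = {n: rec[n].astype(float) for n in names}

    pts = np.column_stack([data["x"], data["y"], data["z"]]) if count else np.empty((0, 3))
    normals = None
    if all(n in names for n in ("nx", "ny", "nz")) and count:
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]])
        norms = np.linalg.norm(normals, axis=1)
        if np.any(norms <= 0):
            normals = None
        else:
            normals = normals / norms[:, None]
    return PointCloud(pts, normals)


def write_ply(cloud: PointCloud, path, binary: bool = True) -> None:
    """Write a cloud as PLY; binary little endian keeps double precision."""
    path = Path(path)
    has_normals = cloud.normals is not None
    n = len(cloud)
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {n}")
    header += [f"property double {c}" for c in ("x", "y", "z")]
    if has_normals:
        header += [f"property double {c}" for c in ("nx", "ny", "nz")]
    header.append("end_header")
    cols = cloud.points if not has_normals else np.hstack([cloud.points, cloud.normals])
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(cols, dtype="<f8").tobytes())
        else:
            for row in cols:
                fh.write((" ".join(repr(float(v)) for v in row) + "\n").encode("ascii"))


def read_pcd(path) -> PointCloud:
    """Read an (ASCII) PCD v0.7 file; x/y/z fields only."""
    path = Path(path)
    with open(path, "rb") as fh:
        fields = None
        count = None
        data_mode = None
        while True:
            raw = fh.readline()
            if not raw:
                raise ValueError("unexpected end of PCD header")
            line = raw.decode("ascii", errors="replace").strip()
            if line.startswith("#") or not line:
                continue
            key, _, rest = line.partition(" ")
            if key == "FIELDS":
                fields = rest.split()
            elif key == "POINTS":
                count = int(rest)
            elif key == "DATA":
                data_mode = rest.strip()
                break
        if fields is None or count is None:
            raise ValueError("PCD header lacks FIELDS or POINTS")
        for axis in ("x", "y", "z"):
            if axis not in fields:
                raise ValueError(f"PCD lacks required field '{axis}'")
        if data_mode != "ascii":
            raise ValueError(f"only ascii PCD DATA supported, got {data_mode!r}")
        ix, iy, iz = (fields.index(a) for a in ("x", "y", "z"))
        rows = []
        for i in range(count):
            line = fh.readline()
            if not line:
                raise ValueError(f"PCD data truncated at row {i}")
            vals = line.split()
            rows.append((float(vals[ix]), float(vals[iy]), float(vals[iz])))
    return PointCloud(np.array(rows).reshape(-1, 3))
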