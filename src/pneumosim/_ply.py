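"""Binary little-endian PLY I/O with float64 vertices.

Exists so mesh round-trips are bit-exact (the standard exporters quantize
vertices to float32) and so per-vertex scalar fields plus RGB colors can be
stored together for error colormaps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DTYPES = {
    "char": "i1", "uchar": "u1", "short": "i2", "ushort": "u2",
    "int": "i4", "uint": "u4", "float": "f4", "double": "f8",
    "float32": "f4", "float64": "f8", "int8": "i1", "uint8": "u1",
    "int16": "i2", "uint16": "u2", "int32": "i4", "uint32": "u4",
}


def write_ply(path, vertices, faces, *, colors=None, scalar=None,
              scalar_name: str = "quality") -> None:
    """Write a binary PLY.  ``colors`` is (V,3) uint8, ``scalar`` (V,) float."""
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int32)
    nv, nf = len(vertices), len(faces)
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {nv}",
              "property double x", "property double y", "property double z"]
    fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    if colors is not None:
        colors = np.asarray(colors, dtype=np.uint8)
        header += ["property uchar red", "property uchar green",
                   "property uchar blue"]
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
    if scalar is not None:
        scalar = np.asarray(scalar, dtype=np.float64)
        header.append(f"property double {scalar_name}")
        fields.append((scalar_name, "<f8"))
    header += [f"element face {nf}",
               "property list uchar int vertex_indices", "end_header", ""]

    vdata = np.empty(nv, dtype=np.dtype(fields))
    vdata["x"], vdata["y"], vdata["z"] = vertices.T
    if colors is not None:
        vdata["red"], vdata["green"], vdata["blue"] = colors.T
    if scalar is not None:
        vdata[scalar_name] = scalar
    fdata = np.empty(nf, dtype=np.dtype([("n", "u1"), ("idx", "<i4", (3,))]))
    fdata["n"] = 3
    fdata["idx"] = faces
    with open(Path(path), "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(vdata.tobytes())
        fh.write(fdata.tobytes())


def read_ply(path) -> dict:
    """Read a binary little-endian PLY written by :func:`write_ply` (or any
    triangle PLY with scalar vertex properties).  Returns a dict with
    ``vertices``, ``faces`` and one array per extra vertex property."""
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise ValueError(f"{path}: not a PLY file")
    body = raw[raw.find(b"\n", end) + 1:]
    props: list[tuple[str, str]] = []
    nv = nf = 0
    current = None
    fmt = None
    for line in raw[:end].decode("ascii", "replace").splitlines():
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            current = tok[1]
            if current == "vertex":
                nv = int(tok[2])
            elif current == "face":
                nf = int(tok[2])
        elif tok[0] == "property" and current == "vertex":
            if tok[1] == "list":
                raise ValueError("list properties on vertices unsupported")
            props.append((tok[-1], "<" + _DTYPES[tok[1]]))
    if fmt != "binary_little_endian":
        raise ValueError(f"{path}: only binary little-endian PLY supported")
    vdt = np.dtype(props)
    vdata = np.frombuffer(body, dtype=vdt, count=nv)
    fdt = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
    fdata = np.frombuffer(body[nv * vdt.itemsize:], dtype=fdt, count=nf)
    if nf and not (fdata["n"] == 3).all():
        raise ValueError(f"{path}: non-triangular faces present")
    out = {
        "vertices": np.column_stack([vdata["x"], vdata["y"], vdata["z"]]),
        "faces": fdata["idx"].copy(),
    }
    for name, _ in props:
        if name not in ("x", "y", "z"):
            out[name] = vdata[name].copy()
    return out
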