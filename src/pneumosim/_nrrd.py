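"""Minimal NRRD read/write support for label volumes.

Covers the subset of NRRD used for segmentation volumes: 3-D arrays,
``raw`` or ``gzip`` encoding, little-endian, axis-aligned ``space
directions`` (voxel spacing) and ``space origin``.  Data are stored
fastest-axis-first as NRRD prescribes; arrays round-trip in index order
``[x, y, z]``.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_MAGIC = "NRRD0004"

_TYPE_MAP = {
    "signed char": np.int8,
    "int8": np.int8,
    "uchar": np.uint8,
    "unsigned char": np.uint8,
    "uint8": np.uint8,
    "short": np.int16,
    "int16": np.int16,
    "unsigned short": np.uint16,
    "uint16": np.uint16,
    "int": np.int32,
    "int32": np.int32,
    "unsigned int": np.uint32,
    "uint32": np.uint32,
    "float": np.float32,
    "double": np.float64,
}
_INV_TYPE = {np.dtype(np.uint8): "uint8", np.dtype(np.int16): "int16",
             np.dtype(np.int32): "int32", np.dtype(np.float32): "float",
             np.dtype(np.float64): "double"}


def read_nrrd(path) -> tuple[np.ndarray, dict]:
    """Read an NRRD file -> (array indexed [x, y, z], header dict).

    The header dict carries ``spacing`` (mm triple) and ``origin`` (mm triple)
    when the file declares them.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not an NRRD file (magic {magic!r})")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, val = text.split(":", 1)
            fields[key.strip().lower()] = val.lstrip("=").strip()
        blob = fh.read()

    if "data file" in fields or "datafile" in fields:
        raise ValueError(f"{path}: detached NRRD data files are not supported")
    dtype = _TYPE_MAP.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    encoding = fields.get("encoding", "raw").lower()
    if encoding in ("gzip", "gz"):
        blob = gzip.decompress(blob)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    endian = fields.get("endian", "little")
    dt = np.dtype(dtype).newbyteorder("<" if endian == "little" else ">")
    n = int(np.prod(sizes))
    arr = np.frombuffer(blob, dtype=dt, count=n)
    # NRRD sizes are fastest-first: reshape in Fortran order to get [x, y, z]
    arr = arr.reshape(sizes, order="F").astype(dtype)

    header: dict = {"sizes": sizes}
    if "space directions" in fields:
        dirs = _parse_vectors(fields["space directions"])
        header["spacing"] = tuple(float(np.linalg.norm(d)) for d in dirs)
    elif "spacings" in fields:
        header["spacing"] = tuple(float(s) for s in fields["spacings"].split())
    if "space origin" in fields:
        header["origin"] = tuple(_parse_vectors(fields["space origin"])[0])
    return arr, header


def write_nrrd(path, array: np.ndarray, spacing, origin=(0.0, 0.0, 0.0),
               encoding: str = "gzip") -> None:
    """Write a 3-D array indexed [x, y, z] with axis-aligned spacing (mm)."""
    path = Path(path)
    arr = np.ascontiguousarray(np.asarray(array))
    if arr.ndim != 3:
        raise ValueError("write_nrrd expects a 3-D array")
    if arr.dtype not in _INV_TYPE:
        arr = arr.astype(np.int16)
    sx, sy, sz = (float(s) for s in np.broadcast_to(spacing, (3,)))
    ox, oy, oz = (float(o) for o in origin)
    header = [
        _MAGIC,
        f"type: {_INV_TYPE[arr.dtype]}",
        "dimension: 3",
        "space: left-posterior-superior",
        f"sizes: {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}",
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})",
        "kinds: domain domain domain",
        "endian: little",
        f"encoding: {encoding}",
        f"space origin: ({ox},{oy},{oz})",
        "",
        "",
    ]
    blob = arr.astype(arr.dtype.newbyteorder("<")).tobytes(order="F")
    if encoding == "gzip":
        blob = gzip.compress(blob, mtime=0)
    elif encoding != "raw":
        raise ValueError(f"unsupported encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(blob)


def _parse_vectors(text: str):
    out = []
    for chunk in text.replace(") ", ")|").split("|"):
        chunk = chunk.strip().strip("()")
        if chunk.lower() == "none" or not chunk:
            continue
        out.append([float(t) for t in chunk.replace(",", " ").split()])
    return out
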