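"""Minimal single-file NRRD read/write for 3D raster volumes.

Supports the small subset of NRRD needed here: 3D arrays, raw little-endian
encoding, axis-aligned ``space directions`` (diagonal) and ``space origin``.
Kept in-repo so the package has no dependency on pynrrd.
"""

from __future__ import annotations

import os
from typing import Tuple

import numpy as np

from .grid import GridSpec

_TYPE_TO_DTYPE = {
    "uint8": np.uint8,
    "uchar": np.uint8,
    "unsigned char": np.uint8,
    "float": np.float32,
    "double": np.float64,
    "short": np.int16,
    "int": np.int32,
}
_DTYPE_TO_TYPE = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
    np.dtype(np.int16): "short",
    np.dtype(np.int32): "int",
}


def write_nrrd(path: str, array: np.ndarray, grid: GridSpec) -> None:
    """Write a 3D array as a raw little-endian NRRD with lattice metadata."""
    array = np.ascontiguousarray(array)
    if array.ndim != 3:
        raise ValueError("only 3D volumes are supported")
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} != grid shape {grid.shape}")
    dtype = np.dtype(array.dtype)
    if dtype == np.dtype(bool):
        array = array.astype(np.uint8)
        dtype = array.dtype
    if dtype not in _DTYPE_TO_TYPE:
        raise ValueError(f"unsupported dtype {dtype}")
    sx, sy, sz = grid.spacing
    ox, oy, oz = grid.origin
    header = [
        "NRRD0004",
        "# generated by adaptrt",
        f"type: {_DTYPE_TO_TYPE[dtype]}",
        "dimension: 3",
        "space: left-posterior-superior",
        "sizes: {} {} {}".format(*array.shape),
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
        f"space origin: ({ox},{oy},{oz})",
        "",
        "",
    ]
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        # NRRD stores the fastest-varying axis first; write Fortran order so
        # sizes line up with axis 0 fastest.
        fh.write(array.astype(dtype.newbyteorder("<")).tobytes(order="F"))


def _parse_vector(text: str) -> Tuple[float, ...]:
    return tuple(float(t) for t in text.strip().lstrip("(").rstrip(")").split(","))


def read_nrrd(path: str) -> Tuple[np.ndarray, GridSpec]:
    """Read a raw-encoded NRRD written by :func:`write_nrrd` (or compatible)."""
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii").strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields = {}
        while True:
            line = fh.readline().decode("ascii")
            if line in ("\n", "\r\n", ""):
                break
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            fields[key.strip().lower()] = value.strip()
        if fields.get("encoding", "raw") != "raw":
            raise ValueError(f"{path}: only raw encoding is supported")
        dtype = np.dtype(_TYPE_TO_DTYPE[fields["type"]])
        if fields.get("endian", "little") != "little" and dtype.itemsize > 1:
            raise ValueError(f"{path}: only little-endian data is supported")
        sizes = tuple(int(s) for s in fields["sizes"].split())
        if len(sizes) != 3:
            raise ValueError(f"{path}: only 3D volumes are supported")
        directions = [
            _parse_vector(v) for v in fields["space directions"].split(") (")
        ]
        spacing = tuple(directions[i][i] for i in range(3))
        for i, d in enumerate(directions):
            off_diag = [abs(d[j]) for j in range(3) if j != i]
            if any(v > 1e-9 for v in off_diag):
                raise ValueError(f"{path}: non-axis-aligned volumes not supported")
        origin = _parse_vector(fields.get("space origin", "(0,0,0)"))
        raw = fh.read(int(np.prod(sizes)) * dtype.itemsize)
        array = np.frombuffer(raw, dtype=dtype.newbyteorder("<")).reshape(
            sizes, order="F"
        )
    grid = GridSpec(shape=sizes, spacing=spacing, origin=origin)
    return np.array(array), grid
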