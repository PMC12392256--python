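"""Minimal MRC2014 reader/writer for 2-D images and image stacks.

Covers what the pipeline needs: modes 0 (int8), 1 (int16), 2 (float32)
and 6 (uint16), single sections and stacks, little-endian, no extended
header on write (skipped on read).  Written files carry the standard
'MAP ' tag and machine stamp and record the pixel size in the cell
dimensions (Angstrom per voxel times grid size).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_MODE_DTYPES = {
    0: np.int8,
    1: np.int16,
    2: np.float32,
    6: np.uint16,
}
_HEADER_SIZE = 1024


def write_mrc(path: str | Path, data: np.ndarray, pixel_size_nm: float = 0.0) -> None:
    """Write a 2-D image or a (nz, ny, nx) stack as MRC mode 2 (float32)."""
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D image or 3-D stack, got ndim={arr.ndim}")
    arr = np.ascontiguousarray(arr, dtype="<f4")
    nz, ny, nx = arr.shape
    apix = pixel_size_nm * 10.0  # nm -> Angstrom

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)  # NX NY NZ
    struct.pack_into("<i", header, 12, 2)  # MODE
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    struct.pack_into("<3f", header, 40, apix * nx, apix * ny, apix * nz)  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean())
    )  # DMIN DMAX DMEAN
    struct.pack_into("<2i", header, 88, 0, 0)  # ISPG (0: image stack), NSYMBT
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(arr.std()))  # RMS
    struct.pack_into("<i", header, 220, 0)  # NLABL

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(arr.tobytes())


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC file; returns (array, pixel_size_nm).

    The array is 2-D for a single section, (nz, ny, nx) otherwise.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode = struct.unpack_from("<i", header, 12)[0]
        mx = struct.unpack_from("<i", header, 28)[0]
        cella_x = struct.unpack_from("<f", header, 40)[0]
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        if nsymbt:
            fh.seek(nsymbt, 1)  # skip extended header
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=count)
        if data.size != count:
            raise ValueError(f"{path}: truncated MRC data block")
    arr = data.reshape(nz, ny, nx).astype(np.float64)
    apix = cella_x / mx if mx else 0.0
    pixel_size_nm = apix / 10.0
    return (arr[0] if nz == 1 else arr), pixel_size_nm
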