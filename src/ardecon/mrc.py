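"""Minimal MRC2014 volume I/O.

Implements the subset of the MRC2014 format needed here: mode 2 (float32)
cubic volumes with the voxel size carried in the cell dimensions. The full
1024-byte header is written; unused fields are zeroed. Axis order is kept
as C-order (z, y, x) with MAPC/MAPR/MAPS = 1/2/3.
"""

from __future__ import annotations

import os
import struct

import numpy as np

HEADER_SIZE = 1024
_MAP_ID = b"MAP "
# machine stamp for little-endian IEEE data
_MACHST_LE = b"\x44\x44\x00\x00"

MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    6: np.dtype(np.uint16),
    12: np.dtype(np.float16),
}


class MRCError(IOError):
    """Raised for malformed or unsupported MRC files."""


def read_mrc(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read an MRC volume, returning ``(data, voxel_size)``.

    ``data`` has shape (nz, ny, nx) in C order; ``voxel_size`` is the
    x cell spacing in Angstrom (0 if the header does not define one).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        header = fh.read(HEADER_SIZE)
        if len(header) < HEADER_SIZE:
            raise MRCError(f"{path}: truncated header ({len(header)} bytes)")
        if header[208:212] != _MAP_ID:
            raise MRCError(f"{path}: missing 'MAP ' identifier; not an MRC2014 file")
        # words 1-3: nx, ny, nz (fastest to slowest)
        nx, ny, nz, mode = struct.unpack("<4i", header[0:16])
        if mode not in MODE_DTYPES:
            raise MRCError(f"{path}: unsupported mode {mode}")
        mx, my, mz = struct.unpack("<3i", header[28:40])
        xlen, ylen, zlen = struct.unpack("<3f", header[40:52])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        if nsymbt:
            fh.seek(nsymbt, os.SEEK_CUR)
        dtype = MODE_DTYPES[mode]
        count = nx * ny * nz
        raw = fh.read(count * dtype.itemsize)
        if len(raw) != count * dtype.itemsize:
            raise MRCError(f"{path}: truncated data section")
    data = np.frombuffer(raw, dtype=dtype.newbyteorder("<")).reshape(nz, ny, nx)
    voxel = xlen / mx if mx > 0 and xlen > 0 else 0.0
    return np.ascontiguousarray(data), float(voxel)


def write_mrc(path: str | os.PathLike, data: np.ndarray, voxel_size: float) -> None:
    """Write ``data`` as an MRC2014 mode-2 (float32) volume."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise MRCError(f"expected a 3D array, got shape {data.shape}")
    vol = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = vol.shape
    header = bytearray(HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    # nxstart/nystart/nzstart left 0; mx/my/mz = sampling = grid size
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    struct.pack_into(
        "<3f", header, 40, nx * voxel_size, ny * voxel_size, nz * voxel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    dmin, dmax, dmean = float(vol.min()), float(vol.max()), float(vol.mean())
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    header[208:212] = _MAP_ID
    header[212:216] = _MACHST_LE
    struct.pack_into("<f", header, 216, float(vol.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(vol.tobytes())
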