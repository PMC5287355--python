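"""Minimal MRC image I/O (modes 0, 1, 2).

EM images travel as MRC: a fixed 1024-byte little-endian header followed by
the raw pixel array.  Only what the correlative workflow needs is
implemented — 2D (or single-volume 3D) images in signed 8-bit (mode 0),
signed 16-bit (mode 1) or 32-bit float (mode 2), plus the pixel size stored
in the cell dimensions.  Extended headers are skipped on read and never
written.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}
_HEADER_SIZE = 1024


def read_mrc(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read an MRC file; returns ``(data, pixel_size)``.

    ``data`` has shape (ny, nx) for single sections or (nz, ny, nx)
    otherwise; ``pixel_size`` is in the file's cell units per pixel (None
    when the cell dimensions are unset).
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise ValueError(f"{path}: file shorter than MRC header")
    nx, ny, nz, mode = struct.unpack("<4i", raw[0:16])
    if mode not in _MODE_DTYPES:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    cella_x = struct.unpack("<f", raw[40:44])[0]
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    offset = _HEADER_SIZE + nsymbt
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    data = data.reshape(nz, ny, nx)
    if nz == 1:
        data = data[0]
    pixel_size = cella_x / nx if cella_x > 0 else None
    return np.array(data), pixel_size


def write_mrc(path: str | Path, data: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write a 2D image or 3D volume as little-endian MRC.

    Float input is written as mode 2, int8 as mode 0, int16 as mode 1.
    ``pixel_size`` goes into the cell dimensions (same unit convention the
    reader returns).
    """
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    if data.dtype == np.int8:
        mode = 0
    elif data.dtype == np.int16:
        mode = 1
    else:
        mode = 2
        data = data.astype(np.float32)
    nz, ny, nx = data.shape

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    data_le = data.astype(np.dtype(data.dtype).newbyteorder("<"), copy=False)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data_le.tobytes())
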