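"""MRC2014 image/volume files and STAR metadata tables.

Conventions used by this package (STAR dialects in the cryo-EM
ecosystem differ; these are the ones we read and write):

* **Coordinates in STAR files are 0-based pixel positions of the particle
  centre** (``_rlnCoordinateX``/``Y``).
* MRC files are written in mode 2 (32-bit float) only; modes 0, 1, 2 and 6
  are readable.  Pixel size is stored as cell dimension / sampling
  (``cella / mx``).
* STAR numeric cells are emitted with 6 significant digits; text cells are
  never quoted.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MapHeader",
    "StarTable",
    "read_mrc",
    "write_mrc",
    "read_star",
    "write_star",
]


class FormatError(ValueError):
    """A file violates the MRC2014 or STAR format."""


_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_SIZE = 1024


@dataclass
class MapHeader:
    """The fields of an MRC2014 header this package interprets."""

    dims: tuple  # (nx, ny, nz), in pixels
    pixel_size: float  # Å/px
    origin: tuple = (0.0, 0.0, 0.0)  # Å
    mode: int = 2

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if self.mode not in _MRC_MODES:
            raise ValueError(f"unsupported MRC mode {self.mode}")

    @property
    def cell(self) -> tuple:
        """Unit cell dimensions in Å (dims × pixel size)."""
        return tuple(d * self.pixel_size for d in self.dims)


def read_mrc(path):
    """Read an MRC2014 file.

    Returns ``(grid, header)`` where ``grid`` is an
    :class:`~aberro.grids.ImageGrid` for single 2D images (nz == 1) and a
    :class:`~aberro.grids.VolumeGrid` for volumes and image stacks.

    Raises :class:`FormatError` naming the offending header field on
    malformed input.
    """
    from .grids import ImageGrid, VolumeGrid

    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise FormatError(
            f"{path}: file of {len(raw)} bytes is shorter than the 1024-byte MRC header"
        )
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if min(nx, ny, nz) < 1:
        raise FormatError(f"{path}: non-positive dimensions nx/ny/nz = {(nx, ny, nz)}")
    if mode not in _MRC_MODES:
        raise FormatError(f"{path}: unsupported mode field {mode}")
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    if mx < 1:
        raise FormatError(f"{path}: non-positive sampling field mx = {mx}")
    pixel_size = cella[0] / mx
    if not pixel_size > 0:
        raise FormatError(f"{path}: non-positive cella/mx pixel size {pixel_size}")
    maptag = raw[208:212]
    if maptag not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: missing 'MAP ' tag in the map field ({maptag!r})")
    origin = struct.unpack_from("<3f", raw, 196)
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    nvox = nx * ny * nz
    need = _HEADER_SIZE + nvox * dtype.itemsize
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    data_start = _HEADER_SIZE + max(nsymbt, 0)
    if len(raw) < data_start + nvox * dtype.itemsize:
        raise FormatError(
            f"{path}: data section truncated (nx*ny*nz field implies "
            f"{need} bytes, file has {len(raw)})"
        )
    data = np.frombuffer(raw, dtype=dtype, count=nvox, offset=data_start)
    data = data.reshape(nz, ny, nx).astype(np.float32)
    header = MapHeader(dims=(nx, ny, nz), pixel_size=pixel_size, origin=origin, mode=mode)
    if nz == 1:
        return ImageGrid(data[0].copy(), pixel_size), header
    return VolumeGrid(data.copy(), pixel_size), header


def write_mrc(grid, path, header: MapHeader | None = None) -> None:
    """Write an image/volume grid as a mode-2 (float32) MRC2014 file.

    ``header`` defaults to one derived from the grid; if given, its dims
    must match the grid (validation error otherwise).  Round trip through
    :func:`read_mrc` is bit-exact for float32 data.
    """
    data = np.asarray(grid.data, dtype=np.float32)
    if data.ndim == 2:
        data3 = data[None]
    elif data.ndim == 3:
        data3 = data
    else:
        raise ValueError(f"grid must be 2D or 3D, got {data.ndim}D")
    nz, ny, nx = data3.shape
    if header is None:
        header = MapHeader(dims=(nx, ny, nz), pixel_size=grid.pixel_size)
    if tuple(header.dims) != (nx, ny, nz):
        raise ValueError(
            f"header dims {tuple(header.dims)} do not match grid dims {(nx, ny, nz)}"
        )
    if not header.pixel_size > 0:
        raise ValueError(f"pixel_size must be > 0, got {header.pixel_size}")

    buf = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", buf, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", buf, 16, 0, 0, 0)  # nxstart
    struct.pack_into("<3i", buf, 28, nx, ny, nz)  # sampling
    struct.pack_into("<3f", buf, 40, *(d * header.pixel_size for d in (nx, ny, nz)))
    struct.pack_into("<3f", buf, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", buf, 64, 1, 2, 3)  # axis order x fastest
    struct.pack_into("<3f", buf, 76, float(data3.min()), float(data3.max()), float(data3.mean()))
    # ispg: 1 for volumes, 0 for single images / stacks
    struct.pack_into("<i", buf, 88, 1 if (data.ndim == 3) else 0)
    struct.pack_into("<i", buf, 92, 0)  # nsymbt
    buf[104:108] = b"MRCO"  # exttyp
    struct.pack_into("<i", buf, 108, 20140)  # nversion
    struct.pack_into("<3f", buf, 196, *header.origin)
    buf[208:212] = b"MAP "
    buf[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machine stamp
    struct.pack_into("<f", buf, 216, float(data3.std()))
    struct.pack_into("<i", buf, 220, 0)
    with open(path, "wb") as fh:
        fh.write(bytes(buf))
        fh.write(data3.astype("<f4").tobytes())


# ---------------------------------------------------------------------------
# STAR
# ---------------------------------------------------------------------------


@dataclass
class StarTable:
    """One ``data_`` block of a STAR file: a name and a typed table.

    ``df`` columns keep their full ``_rlnSomething`` labels verbatim; cells
    that parse as numbers are stored as numbers, everything else as text.
    """

    name: str
    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        cols = list(self.df.columns)
        if len(set(cols)) != len(cols):
            raise FormatError(f"block '{self.name}': duplicate column labels in {cols}")

    @property
    def columns(self) -> list:
        return list(self.df.columns)

    def __len__(self) -> int:
        return len(self.df)


def _coerce_column(cells: list):
    """Parse a column of text cells as int, float, or leave as text."""
    try:
        return [int(c) for c in cells]
    except ValueError:
        pass
    try:
        return [float(c) for c in cells]
    except ValueError:
        return cells


def read_star(path) -> list:
    """Parse a STAR file into a list of :class:`StarTable`.

    Supports loop and non-loop blocks; ``#`` comments are stripped.
    Duplicate column labels within a block raise :class:`FormatError`.
    """
    lines = Path(path).read_text().splitlines()
    tables: list[StarTable] = []
    i = 0
    n = len(lines)

    def strip(line: str) -> str:
        # strip comments, but keep '#' inside a label's "#N" ordinal
        return line.split("//")[0].strip()

    while i < n:
        line = strip(lines[i])
        if not line.startswith("data_"):
            i += 1
            continue
        name = line[len("data_"):]
        i += 1
        # skip blanks
        while i < n and not strip(lines[i]):
            i += 1
        if i < n and strip(lines[i]) == "loop_":
            i += 1
            columns: list[str] = []
            while i < n and strip(lines[i]).startswith("_"):
                label = strip(lines[i]).split()[0]
                if label in columns:
                    raise FormatError(f"block '{name}': duplicate column label {label}")
                columns.append(label)
                i += 1
            rows = []
            while i < n:
                row_line = strip(lines[i])
                if not row_line or row_line.startswith("data_"):
                    break
                cells = row_line.split()
                if len(cells) != len(columns):
                    raise FormatError(
                        f"block '{name}': row has {len(cells)} cells, "
                        f"expected {len(columns)}"
                    )
                rows.append(cells)
                i += 1
            if rows:
                cols = {
                    c: _coerce_column([r[j] for r in rows]) for j, c in enumerate(columns)
                }
                df = pd.DataFrame(cols)
            else:
                df = pd.DataFrame({c: [] for c in columns})
            tables.append(StarTable(name, df))
        else:
            # non-loop block: "_label value" pairs become a one-row table
            labels, values = [], []
            while i < n:
                kv = strip(lines[i])
                if kv.startswith("data_"):
                    break
                if kv.startswith("_"):
                    parts = kv.split(None, 1)
                    if len(parts) != 2:
                        raise FormatError(f"block '{name}': malformed pair '{kv}'")
                    if parts[0] in labels:
                        raise FormatError(
                            f"block '{name}': duplicate column label {parts[0]}"
                        )
                    labels.append(parts[0])
                    values.append(parts[1].strip())
                i += 1
            df = pd.DataFrame({l: _coerce_column([v]) for l, v in zip(labels, values)})
            tables.append(StarTable(name, df))
    return tables


def _format_cell(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}"
    return str(value)


def write_star(tables, path) -> None:
    """Write a list of :class:`StarTable` as a STAR file (loop blocks)."""
    out = []
    for table in tables:
        for col in table.columns:
            if not str(col).startswith("_"):
                raise ValueError(
                    f"block '{table.name}': STAR column labels must start "
                    f"with '_', got {col!r}"
                )
        out.append(f"data_{table.name}")
        out.append("")
        out.append("loop_")
        for j, col in enumerate(table.columns, start=1):
            out.append(f"{col} #{j}")
        for _, row in table.df.iterrows():
            out.append(" ".join(_format_cell(v) for v in row))
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")
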