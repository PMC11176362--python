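"""Minimal nmrPipe-format reader/writer.

Implements the subset of the nmrPipe binary format the pipeline needs:
single-file 2D spectra and single-file 3D streams, time- or frequency-
domain.  A file is a 512-float32 header followed by float32 data.  Complex
vectors along the directly detected dimension are stored as all real points
followed by all imaginary points; indirect hypercomplex (States) components
are interleaved row pairs, matching the package's in-memory convention.

Only the canonical header fields required to round-trip the package's own
:class:`~methyldec.grid.SpectrumGrid` objects (sizes, sweep widths,
observe/carrier frequencies, quadrature/FT/transpose flags, axis labels)
are written; everything else is left zero.  This is a documented subset
writer, not a full re-implementation of the format.
"""

from __future__ import annotations

import numpy as np

from .axes import AxisSpec
from .grid import SpectrumGrid

HEADER_SIZE = 512

# canonical FDATA word offsets
FDMAGIC = 0
FDFLTFORMAT = 1
FDFLTORDER = 2
FDDIMCOUNT = 9
FDDIMORDER = (24, 25, 26, 27)
FDPIPEFLAG = 57
FDSIZE = 99
FDREALSIZE = 97
FDSPECNUM = 219
FDQUADFLAG = 106
FDTRANSPOSED = 221
FD2DPHASE = 256
FDFILECOUNT = 442

# per-dimension offsets: F2 is the directly detected dimension
_DIM = {
    "F2": {"SW": 100, "OBS": 119, "ORIG": 101, "FT": 220, "QUAD": 56,
           "CAR": 66, "CENTER": 79, "LABEL": 16},
    "F1": {"SW": 229, "OBS": 218, "ORIG": 249, "FT": 222, "QUAD": 55,
           "CAR": 67, "CENTER": 80, "LABEL": 18},
    "F3": {"SW": 11, "OBS": 10, "ORIG": 12, "FT": 13, "QUAD": 51,
           "CAR": 68, "CENTER": 81, "SIZE": 15, "LABEL": 20},
}

_FLT_FORMAT = np.float32(4008636160.0)
_FLT_ORDER = np.float32(2.345)


def _set_label(header: np.ndarray, word: int, label: str) -> None:
    raw = label.encode()[:8].ljust(8, b"\x00")
    header[word : word + 2] = np.frombuffer(raw, dtype=np.float32)


def _get_label(header: np.ndarray, word: int) -> str:
    raw = header[word : word + 2].tobytes()
    return raw.split(b"\x00", 1)[0].decode(errors="replace")


def _axis_header(header: np.ndarray, dim: str, axis: AxisSpec, domain: str,
                 quad_complex: bool) -> None:
    d = _DIM[dim]
    header[d["SW"]] = axis.sweep_width
    header[d["OBS"]] = axis.larmor_frequency
    header[d["CAR"]] = axis.carrier
    header[d["ORIG"]] = (
        axis.carrier * axis.larmor_frequency - axis.sweep_width / 2.0
    )
    header[d["FT"]] = 1.0 if domain == "freq" else 0.0
    header[d["QUAD"]] = 0.0 if quad_complex else 1.0
    _set_label(header, d["LABEL"], axis.nucleus)


def _axis_from_header(header: np.ndarray, dim: str, n_complex: int) -> tuple:
    d = _DIM[dim]
    nucleus = _get_label(header, d["LABEL"]) or "1H"
    axis = AxisSpec(
        n_complex_points=max(int(n_complex), 8),
        sweep_width=float(header[d["SW"]]),
        larmor_frequency=float(header[d["OBS"]]),
        carrier=float(header[d["CAR"]]),
        nucleus=nucleus if nucleus in ("1H", "13C") else "1H",
    )
    domain = "freq" if header[d["FT"]] else "time"
    return axis, domain


def write_pipe_2d(path, grid: SpectrumGrid) -> None:
    """Write a 2D grid (indirect axis first, direct axis last)."""
    if grid.data.ndim != 2:
        raise ValueError("write_pipe_2d expects a 2D grid")
    header = np.zeros(HEADER_SIZE, dtype=np.float32)
    header[FDFLTFORMAT] = _FLT_FORMAT
    header[FDFLTORDER] = _FLT_ORDER
    header[FDDIMCOUNT] = 2
    header[FDFILECOUNT] = 1
    for word, value in zip(FDDIMORDER, (2, 1, 3, 4)):
        header[word] = value
    direct_complex = np.iscomplexobj(grid.data)
    n_rows, n_direct = grid.data.shape
    header[FDSIZE] = n_direct
    header[FDREALSIZE] = n_direct
    header[FDSPECNUM] = n_rows
    header[FDQUADFLAG] = 0.0 if (direct_complex or grid.interleaved[0]) else 1.0
    header[FD2DPHASE] = 2.0  # States
    _axis_header(header, "F2", grid.axes[1], grid.domains[1], direct_complex)
    _axis_header(header, "F1", grid.axes[0], grid.domains[0], grid.interleaved[0])
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        if direct_complex:
            row = np.empty((n_rows, 2 * n_direct), dtype=np.float32)
            row[:, :n_direct] = grid.data.real
            row[:, n_direct:] = grid.data.imag
            fh.write(row.tobytes())
        else:
            fh.write(grid.data.astype(np.float32).tobytes())


def read_pipe_2d(path) -> SpectrumGrid:
    with open(path, "rb") as fh:
        header = np.frombuffer(fh.read(HEADER_SIZE * 4), dtype=np.float32)
        if header[FDFLTORDER] != _FLT_ORDER:
            raise ValueError("unsupported byte order or not an nmrPipe file")
        if int(header[FDDIMCOUNT]) != 2:
            raise ValueError("not a 2D file")
        n_direct = int(header[FDSIZE])
        n_rows = int(header[FDSPECNUM])
        direct_complex = header[_DIM["F2"]["QUAD"]] == 0.0
        raw = np.frombuffer(fh.read(), dtype=np.float32)
    if direct_complex:
        raw = raw.reshape(n_rows, 2 * n_direct)
        data = raw[:, :n_direct] + 1j * raw[:, n_direct:]
    else:
        data = raw.reshape(n_rows, n_direct).astype(np.float64)
    indirect_interleaved = header[_DIM["F1"]["QUAD"]] == 0.0
    axis_f2, dom_f2 = _axis_from_header(header, "F2", n_direct)
    n1 = n_rows // 2 if indirect_interleaved else n_rows
    axis_f1, dom_f1 = _axis_from_header(header, "F1", n1)
    grid = SpectrumGrid(
        data,
        [axis_f1, axis_f2],
        [dom_f1, dom_f2],
        [bool(indirect_interleaved), False],
    )
    grid.log(f"read_pipe_2d({path})")
    return grid


def write_pipe_3d(path, grid: SpectrumGrid) -> None:
    """Write a 3D grid as a single-file stream (axis order: F3, F1, F2)."""
    if grid.data.ndim != 3:
        raise ValueError("write_pipe_3d expects a 3D grid")
    header = np.zeros(HEADER_SIZE, dtype=np.float32)
    header[FDFLTFORMAT] = _FLT_FORMAT
    header[FDFLTORDER] = _FLT_ORDER
    header[FDDIMCOUNT] = 3
    header[FDPIPEFLAG] = 1
    header[FDFILECOUNT] = 1
    for word, value in zip(FDDIMORDER, (2, 1, 3, 4)):
        header[word] = value
    direct_complex = np.iscomplexobj(grid.data)
    n3, n1, n_direct = grid.data.shape
    header[FDSIZE] = n_direct
    header[FDSPECNUM] = n1
    header[_DIM["F3"]["SIZE"]] = n3
    header[FDQUADFLAG] = 0.0 if direct_complex else 1.0
    header[FD2DPHASE] = 2.0
    _axis_header(header, "F2", grid.axes[2], grid.domains[2], direct_complex)
    _axis_header(header, "F1", grid.axes[1], grid.domains[1], grid.interleaved[1])
    _axis_header(header, "F3", grid.axes[0], grid.domains[0], grid.interleaved[0])
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        flat = grid.data.reshape(n3 * n1, n_direct)
        if direct_complex:
            row = np.empty((flat.shape[0], 2 * n_direct), dtype=np.float32)
            row[:, :n_direct] = flat.real
            row[:, n_direct:] = flat.imag
            fh.write(row.tobytes())
        else:
            fh.write(flat.astype(np.float32).tobytes())


def read_pipe_3d(path) -> SpectrumGrid:
    with open(path, "rb") as fh:
        header = np.frombuffer(fh.read(HEADER_SIZE * 4), dtype=np.float32)
        if header[FDFLTORDER] != _FLT_ORDER:
            raise ValueError("unsupported byte order or not an nmrPipe file")
        if int(header[FDDIMCOUNT]) != 3:
            raise ValueError("not a 3D stream")
        n_direct = int(header[FDSIZE])
        n1 = int(header[FDSPECNUM])
        n3 = int(header[_DIM["F3"]["SIZE"]])
        direct_complex = header[_DIM["F2"]["QUAD"]] == 0.0
        raw = np.frombuffer(fh.read(), dtype=np.float32)
    if direct_complex:
        raw = raw.reshape(n3 * n1, 2 * n_direct)
        data = (raw[:, :n_direct] + 1j * raw[:, n_direct:]).reshape(n3, n1, n_direct)
    else:
        data = raw.reshape(n3, n1, n_direct).astype(np.float64)
    inter1 = header[_DIM["F1"]["QUAD"]] == 0.0
    inter3 = header[_DIM["F3"]["QUAD"]] == 0.0
    axis_f2, dom_f2 = _axis_from_header(header, "F2", n_direct)
    axis_f1, dom_f1 = _axis_from_header(header, "F1", n1 // 2 if inter1 else n1)
    axis_f3, dom_f3 = _axis_from_header(header, "F3", n3 // 2 if inter3 else n3)
    grid = SpectrumGrid(
        data,
        [axis_f3, axis_f1, axis_f2],
        [dom_f3, dom_f1, dom_f2],
        [bool(inter3), bool(inter1), False],
    )
    grid.log(f"read_pipe_3d({path})")
    return grid
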