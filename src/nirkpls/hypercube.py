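"""Hyperspectral cubes: I/O, rectangular ROI extraction and spectral averaging.

A cube has two spatial dimensions and one spectral dimension.  The pipeline
pools the pixel spectra of one or more rectangular regions of interest
(ROIs) — the reference protocol uses two 5 x 5 ROIs, i.e. 50 pixels per
sample — and averages them into a single spectrum per sample.

Two on-disk dialects are supported:

* ``envi`` — a plain-text ``.hdr`` header next to a raw binary payload
  (BIL/BIP/BSQ interleaves read, BIL written), the lingua franca of
  hyperspectral instruments;
* ``npz`` — a NumPy archive, convenient for fixtures.

Cubes are assumed already reflectance-calibrated; white/dark reference
correction happens upstream of this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tables import SpectraTable


class CubeFormatError(ValueError):
    """Header or payload cannot be parsed in the requested dialect."""


class CubeConsistencyError(ValueError):
    """Header metadata and payload disagree (e.g. band-count mismatch)."""


@dataclass
class HyperCube:
    """rows x cols x bands reflectance cube with a wavelength axis in nm."""

    data: np.ndarray
    wavelengths: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise CubeConsistencyError(
                f"cube has {self.data.shape[2]} bands but "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class RoiSpec:
    """Rectangular ROI: 0-based top-left corner (inclusive) plus extents."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI corner must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


# ---------------------------------------------------------------------------
# ENVI dialect

_ENVI_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2"}


def _envi_header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


def write_envi(cube: HyperCube, path) -> None:
    """Write ``path`` (raw BIL float64 little-endian) and ``path.hdr``."""
    path = Path(path)
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{{cube.sample_id}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 5\n"
        "interleave = bil\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    _envi_header_path(path).write_text(header)
    # BIL: line-major, then band, then sample => (rows, bands, cols)
    payload = np.ascontiguousarray(cube.data.transpose(0, 2, 1), dtype="<f8")
    payload.tofile(path)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise CubeFormatError("not an ENVI header (missing magic line)")
    # collapse {...} blocks onto single lines, then split on key = value
    fields: dict[str, str] = {}
    for m in re.finditer(r"^([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text, re.M | re.S):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def read_envi(path, wavelengths=None) -> HyperCube:
    """Read an ENVI header + raw binary cube.

    ``wavelengths`` overrides the header's wavelength list (some headers
    omit it).
    """
    path = Path(path)
    hdr_path = _envi_header_path(path)
    if not hdr_path.exists():
        raise CubeFormatError(f"missing ENVI header: {hdr_path}")
    if not path.exists():
        raise CubeFormatError(f"missing ENVI payload: {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "5"))
        interleave = fields.get("interleave", "bil").lower()
    except (KeyError, ValueError) as exc:
        raise CubeFormatError(f"malformed ENVI header {hdr_path}: {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise CubeFormatError(f"unsupported ENVI data type {dtype_code}")
    byte_order = int(fields.get("byte order", "0"))
    dtype = np.dtype(("<" if byte_order == 0 else ">") + _ENVI_DTYPES[dtype_code])
    offset = int(fields.get("header offset", "0"))

    raw = np.fromfile(path, dtype=dtype, offset=offset)
    expected = rows * cols * bands
    if raw.size != expected:
        raise CubeConsistencyError(
            f"header declares {rows}x{cols}x{bands}={expected} values but the "
            f"payload holds {raw.size}"
        )
    if interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise CubeFormatError(f"unsupported interleave '{interleave}'")

    if wavelengths is None:
        m = re.search(r"\{([^}]*)\}", fields.get("wavelength", ""))
        if m is None:
            raise CubeFormatError(
                "header has no wavelength list and none was supplied"
            )
        wavelengths = np.array([float(v) for v in m.group(1).replace("\n", " ").split(",")])
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != bands:
        raise CubeConsistencyError(
            f"{wavelengths.size} wavelengths for {bands} bands"
        )
    desc = re.search(r"\{([^}]*)\}", fields.get("description", "{}"))
    sample_id = desc.group(1).strip() if desc else ""
    return HyperCube(data, wavelengths, sample_id)


# ---------------------------------------------------------------------------
# npz dialect

def write_npz(cube: HyperCube, path) -> None:
    np.savez(path, data=cube.data, wavelengths=cube.wavelengths,
             sample_id=np.array(cube.sample_id))


def read_npz(path) -> HyperCube:
    path = Path(path)
    if not path.exists():
        raise CubeFormatError(f"missing cube file: {path}")
    try:
        with np.load(path, allow_pickle=False) as npz:
            return HyperCube(npz["data"], npz["wavelengths"], str(npz["sample_id"]))
    except (KeyError, ValueError, OSError) as exc:
        if isinstance(exc, CubeConsistencyError):
            raise
        raise CubeFormatError(f"cannot read npz cube {path}: {exc}") from exc


def read_cube(path, dialect: str = "auto", wavelengths=None) -> HyperCube:
    """Read a cube in the ``envi`` or ``npz`` dialect (``auto`` by suffix)."""
    path = Path(path)
    if dialect == "auto":
        dialect = "npz" if path.suffix == ".npz" else "envi"
    if dialect == "npz":
        return read_npz(path)
    if dialect == "envi":
        return read_envi(path, wavelengths=wavelengths)
    raise ValueError(f"unknown cube dialect '{dialect}'")


def write_cube(cube: HyperCube, path, dialect: str = "auto") -> None:
    path = Path(path)
    if dialect == "auto":
        dialect = "npz" if path.suffix == ".npz" else "envi"
    if dialect == "npz":
        write_npz(cube, path)
    elif dialect == "envi":
        write_envi(cube, path)
    else:
        raise ValueError(f"unknown cube dialect '{dialect}'")


# ---------------------------------------------------------------------------
# ROI extraction and averaging

def extract_roi_spectra(cube: HyperCube, rois) -> SpectraTable:
    """Pull the pixel spectra of each ROI, one row per pixel.

    Rows are ordered row-major within each ROI; ROIs are concatenated in
    input order.  Raises :class:`IndexError` for an out-of-bounds ROI.
    """
    rows, cols, _ = cube.shape
    blocks = []
    ids = []
    for k, roi in enumerate(rois):
        if roi.row0 + roi.height > rows or roi.col0 + roi.width > cols:
            raise IndexError(
                f"ROI {k} ({roi}) exceeds the cube's spatial extent {rows}x{cols}"
            )
        block = cube.data[roi.row0:roi.row0 + roi.height,
                          roi.col0:roi.col0 + roi.width, :]
        blocks.append(block.reshape(roi.n_pixels, -1))
        for r in range(roi.row0, roi.row0 + roi.height):
            for c in range(roi.col0, roi.col0 + roi.width):
                ids.append(f"{cube.sample_id or 'px'}:roi{k}:r{r}c{c}")
    if not blocks:
        raise ValueError("at least one ROI is required")
    return SpectraTable(np.vstack(blocks), cube.wavelengths, ids)


def average_spectrum(pixels: SpectraTable) -> np.ndarray:
    """Arithmetic mean spectrum over all pixel rows."""
    if pixels.n_samples < 1:
        raise ValueError("cannot average an empty spectra table")
    return pixels.X.mean(axis=0)


def roi_mean_spectrum(cube: HyperCube, rois) -> np.ndarray:
    """Extract + average in one step (50 pixels -> 1 spectrum by default)."""
    return average_spectrum(extract_roi_spectra(cube, rois))
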