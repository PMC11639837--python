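"""Hyperspectral cube handling.

ENVI-style I/O (text header + raw binary, BSQ/BIL/BIP), black/white
reflectance calibration, pseudo-color synthesis from three bands, region
spectrum extraction, and bounding-box annotation I/O (JSON, plus a minimal
Pascal-VOC XML importer).

Conventions
-----------
* Cube values are indexed ``(row, col, band)``.
* Reflectance is stored as a fraction in [0, 1]; percentage formatting is a
  display concern only.
* Box coordinates are 0-based, half-open: a box covers pixels
  ``[x0, x1) x [y0, y1)``.
"""
from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class EnviFormatError(ValueError):
    """Malformed or incomplete ENVI header."""


class DimensionError(ValueError):
    """Array/grid shape mismatch."""


class CalibrationError(ValueError):
    """Invalid black/white reference data."""


class WavelengthRangeError(ValueError):
    """Requested wavelength outside the grid span."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-center wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("wavelength grid must be a non-empty 1-D sequence")
        if w.size > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", w)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """360 bands starting at 382.3 nm with 1.8 nm spacing."""
        return cls(382.3 + 1.8 * np.arange(360))

    @classmethod
    def desk(cls, n_bands: int = 60) -> "WavelengthGrid":
        """Coarse grid over the same span as :meth:`default`, for fast runs."""
        full = cls.default().wavelengths_nm
        return cls(np.linspace(full[0], full[-1], n_bands))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based half-open ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        for name in ("x0", "y0", "x1", "y1"):
            object.__setattr__(self, name, int(getattr(self, name)))
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate box {self.as_tuple()}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains(self, other: "BoundingBox") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )


@dataclass
class Hypercube:
    """Reflectance (or raw intensity) cube with its wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid
    calibrated: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise DimensionError(f"cube must be 3-D (rows, cols, bands); got {v.ndim}-D")
        if v.shape[2] != len(self.grid):
            raise DimensionError(
                f"band dimension {v.shape[2]} != grid length {len(self.grid)}"
            )
        if self.calibrated and (not np.all(np.isfinite(v)) or v.min() < 0 or v.max() > 1):
            raise ValueError("calibrated cube must have finite values in [0, 1]")
        self.values = v

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class CalibrationPair:
    """Dark (B) and white (W) reference arrays, broadcastable to the cube."""

    black: np.ndarray
    white: np.ndarray

    def __post_init__(self):
        self.black = np.asarray(self.black, dtype=float)
        self.white = np.asarray(self.white, dtype=float)


# ---------------------------------------------------------------------------
# ENVI I/O

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


def _parse_envi_header(text: str) -> dict:
    lines = text.splitlines()
    if not lines or lines[0].strip().upper() != "ENVI":
        raise EnviFormatError("missing ENVI magic line")
    fields: dict[str, str] = {}
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value and i < len(lines):
                value += " " + lines[i].strip()
                i += 1
            if "}" not in value:
                raise EnviFormatError(f"unterminated brace block for field '{key}'")
            value = value.strip("{} ").strip()
        fields[key] = value
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI header + raw binary cube pair into a :class:`Hypercube`.

    The data file is located next to the header: the header path with its
    ``.hdr`` suffix removed, or with ``.img``/``.dat`` appended to the stem.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_envi_header(header_path.read_text())

    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise EnviFormatError(f"header missing required field '{required}'")
    if "wavelength" not in fields:
        raise EnviFormatError("header missing required field 'wavelength'")

    n_cols = int(fields["samples"])
    n_rows = int(fields["lines"])
    n_bands = int(fields["bands"])
    dtype_code = int(fields["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported data type code {dtype_code}")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave '{interleave}'")
    offset = int(fields.get("header offset", "0"))

    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace(",", " ").split()]
    )
    if wavelengths.size != n_bands:
        raise DimensionError(
            f"wavelength count {wavelengths.size} != band count {n_bands}"
        )

    stem = header_path.with_suffix("") if header_path.suffix == ".hdr" else header_path
    candidates = [stem, stem.with_suffix(stem.suffix + ".img"), stem.with_suffix(stem.suffix + ".dat")]
    data_path = next((c for c in candidates if c.exists() and c != header_path), None)
    if data_path is None:
        raise FileNotFoundError(f"no data file found for header {header_path}")

    raw = np.fromfile(data_path, dtype=_ENVI_DTYPES[dtype_code], offset=offset)
    expected = n_rows * n_cols * n_bands
    if raw.size != expected:
        raise EnviFormatError(
            f"data file has {raw.size} elements, header declares {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(n_bands, n_rows, n_cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(n_rows, n_bands, n_cols).transpose(0, 2, 1)
    else:  # bip
        cube = raw.reshape(n_rows, n_cols, n_bands)
    calibrated = fields.get("calibrated", "0").strip() == "1"
    return Hypercube(cube.astype(float), WavelengthGrid(wavelengths), calibrated=calibrated)


def write_envi(
    cube: Hypercube,
    header_path: str | Path,
    interleave: str = "bsq",
    dtype=np.float64,
) -> None:
    """Write ``cube`` as an ENVI header (``.hdr``) plus raw binary (``.img``)."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave '{interleave}'")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(header_path.suffix + ".hdr")
    data_path = header_path.with_suffix("").with_suffix(
        header_path.with_suffix("").suffix + ".img"
    )

    v = cube.values
    if interleave == "bsq":
        flat = v.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = v.transpose(0, 2, 1)
    else:
        flat = v
    wl = ", ".join(f"{w:.6g}" for w in cube.grid.wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {cube.n_cols}\n"
        f"lines = {cube.n_rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"calibrated = {1 if cube.calibrated else 0}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(flat).astype(dtype).tofile(data_path)


# ---------------------------------------------------------------------------
# Calibration and spectral helpers


def correct_reflectance(raw: Hypercube, cal: CalibrationPair) -> Hypercube:
    """Black/white reflectance correction ``R = (I - B) / (W - B)``.

    The result is stored as a fraction clipped to [0, 1] and flagged as
    calibrated.  References may be full cubes or per-band arrays broadcastable
    to the cube shape.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    denom = cal.white - cal.black
    denom_b = np.broadcast_to(denom, raw.values.shape)
    bad = int(np.count_nonzero(denom_b <= 0))
    if bad:
        raise CalibrationError(
            f"white - black is non-positive at {bad} element(s)"
        )
    r = (raw.values - cal.black) / denom
    return Hypercube(np.clip(r, 0.0, 1.0), raw.grid, calibrated=True)


def nearest_band_index(grid: WavelengthGrid, target_nm: float) -> int:
    """Index of the band center closest to ``target_nm``.

    Ties at exactly half the band spacing break toward the higher index.
    Targets outside the grid span (plus half a spacing on each side) raise
    :class:`WavelengthRangeError`.
    """
    w = grid.wavelengths_nm
    half = float(np.diff(w).max()) / 2.0 if w.size > 1 else 0.0
    if target_nm < w[0] - half or target_nm > w[-1] + half:
        raise WavelengthRangeError(
            f"{target_nm} nm outside grid span [{w[0]}, {w[-1]}] +/- {half}"
        )
    d = np.abs(w - target_nm)
    # distances within 1e-9 nm count as tied (half-spacing targets would
    # otherwise be decided by float rounding); ties break to the higher index
    return int(np.flatnonzero(d <= d.min() + 1e-9)[-1])


def synthesize_pseudocolor(cube: Hypercube, bands) -> np.ndarray:
    """Compose three bands into an 8-bit RGB image.

    Channel order is (R, G, B) = (longest, middle, shortest wavelength).
    Each channel is min-max scaled to [0, 255] independently over the image;
    a zero-range channel maps to 0.
    """
    bands = [int(b) for b in bands]
    if len(bands) != 3 or len(set(bands)) != 3:
        raise ValueError("exactly three distinct band indices required")
    if not cube.calibrated:
        raise ValueError("pseudo-color synthesis requires a calibrated cube")
    for b in bands:
        if not 0 <= b < cube.n_bands:
            raise ValueError(f"band index {b} out of range")
    ordered = sorted(bands, key=lambda b: cube.grid.wavelengths_nm[b], reverse=True)
    out = np.zeros((cube.n_rows, cube.n_cols, 3), dtype=np.uint8)
    for ch, b in enumerate(ordered):
        plane = cube.values[:, :, b]
        lo, hi = float(plane.min()), float(plane.max())
        if hi > lo:
            out[:, :, ch] = np.rint((plane - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return out


def save_pseudocolor_png(image: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), image)


def extract_roi_spectrum(cube: Hypercube, box: BoundingBox) -> np.ndarray:
    """Per-band mean reflectance over the half-open box; length = grid length."""
    if not cube.calibrated:
        raise ValueError("spectrum extraction requires a calibrated cube")
    if box.x0 < 0 or box.y0 < 0 or box.x1 > cube.n_cols or box.y1 > cube.n_rows:
        raise ValueError(f"box {box.as_tuple()} outside image bounds")
    region = cube.values[box.y0 : box.y1, box.x0 : box.x1, :]
    if region.size == 0:
        raise ValueError("empty box")
    return region.mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# Annotation I/O


def save_annotations(truths: list[tuple[str, BoundingBox]], path: str | Path) -> None:
    """Write ``[(label, box), ...]`` to a JSON annotation file."""
    records = [
        {"label": label, "x0": b.x0, "y0": b.y0, "x1": b.x1, "y1": b.y1}
        for label, b in truths
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def load_annotations(path: str | Path) -> list[tuple[str, BoundingBox]]:
    records = json.loads(Path(path).read_text())
    return [
        (r["label"], BoundingBox(r["x0"], r["y0"], r["x1"], r["y1"])) for r in records
    ]


def load_voc_annotations(path: str | Path) -> list[tuple[str, BoundingBox]]:
    """Import Pascal-VOC XML boxes, converting 1-based inclusive coordinates
    to the 0-based half-open convention."""
    root = ET.parse(Path(path)).getroot()
    truths = []
    for obj in root.iter("object"):
        label = obj.findtext("name")
        bb = obj.find("bndbox")
        if label is None or bb is None:
            raise ValueError("VOC object missing name or bndbox")
        xmin = int(float(bb.findtext("xmin")))
        ymin = int(float(bb.findtext("ymin")))
        xmax = int(float(bb.findtext("xmax")))
        ymax = int(float(bb.findtext("ymax")))
        truths.append((label, BoundingBox(xmin - 1, ymin - 1, xmax, ymax)))
    return truths
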