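"""Hyperspectral cube I/O and region-of-interest handling.

Cubes live in ENVI raster format: an ASCII ``.hdr`` describing shape,
interleave, data type and band wavelengths, next to a raw binary file.
All three classic interleaves (BSQ, BIL, BIP) and both byte orders are
supported.  In memory a cube is always a ``(rows, cols, bands)`` array
with row 0 at the top and 0-based indices; every module in the package
shares this convention.

Pixels excluded by an ROI are tracked in a boolean validity mask carried
alongside the data array, never as a magic value inside it, so spectral
statistics downstream are unaffected by masked-out pixels.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HyperCube",
    "RoiMask",
    "read_envi",
    "write_envi",
    "crop_roi",
    "read_roi_mask",
    "polygon_mask",
]

#: ENVI numeric data-type codes <-> numpy dtype characters.
_ENVI_DTYPES = {
    1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8",
    12: "u2", 13: "u4", 14: "i8", 15: "u8",
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_KNOWN_KEYS = {
    "description", "samples", "lines", "bands", "header offset",
    "file type", "data type", "interleave", "byte order", "wavelength",
    "wavelength units", "reflectance scale factor", "data units",
    "sensor type", "band names",
}


@dataclass
class HyperCube:
    """A hyperspectral image cube.

    Parameters
    ----------
    data : ndarray, shape (n_rows, n_cols, n_bands)
        Per-pixel spectra, either raw digital numbers or reflectance.
    wavelengths : ndarray, shape (n_bands,)
        Band-center wavelengths in nm, strictly increasing.
    units : {"digital_number", "reflectance"}
    valid : ndarray of bool, shape (n_rows, n_cols), optional
        Pixel validity mask; ``None`` means every pixel is valid.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    units: str = "digital_number"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.data.size == 0:
            raise ValueError("cube has zero pixels")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.shape != (self.data.shape[2],):
            raise ValueError(
                f"{len(self.wavelengths)} wavelengths for {self.data.shape[2]} bands"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.units not in ("digital_number", "reflectance"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == "reflectance" and not np.all(
            np.isfinite(self.data[self.valid_mask])
        ):
            raise ValueError("reflectance cube contains non-finite valid pixels")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape[:2]:
                raise ValueError("validity mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.data.shape[:2], dtype=bool)
        return self.valid


@dataclass
class RoiMask:
    """Boolean region-of-interest mask with its offset in the parent image."""

    mask: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask selects no pixels")
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise ValueError("ROI origin must be non-negative")


# ---------------------------------------------------------------------------
# ENVI raster format
# ---------------------------------------------------------------------------

def _binary_path(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for candidate in (stem, stem.with_suffix(".img"), stem.with_suffix(".dat"),
                      stem.with_suffix(".raw"), stem.with_suffix(".bsq")):
        if candidate.exists() and candidate != header_path:
            return candidate
    raise FileNotFoundError(f"no binary file found next to {header_path}")


def _parse_header(text: str) -> dict[str, str]:
    lines = iter(text.splitlines())
    fields: dict[str, str] = {}
    for line in lines:
        line = line.strip()
        if not line or line.upper() == "ENVI" or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and not value.endswith("}"):
            parts = [value]
            for cont in lines:
                parts.append(cont.strip())
                if cont.strip().endswith("}"):
                    break
            value = " ".join(parts)
        if value.startswith("{"):
            value = value.strip("{}").strip()
        fields[key] = value
        if key not in _KNOWN_KEYS:
            logger.warning("ignoring unknown ENVI header key %r", key)
    return fields


def read_envi(header_path: str | os.PathLike) -> HyperCube:
    """Read an ENVI raster (``.hdr`` + raw binary) into a :class:`HyperCube`.

    Wavelengths come from the header's ``wavelength`` field when present,
    else uniformly spaced placeholders ``0..bands-1``.  Units default to
    digital numbers unless the header carries ``data units = reflectance``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_header(header_path.read_text())

    try:
        samples = int(fields["samples"])
        lines_n = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required key {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")

    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(("<" if byte_order == 0 else ">") + _ENVI_DTYPES[dtype_code])
    offset = int(fields.get("header offset", 0))

    binary = _binary_path(header_path)
    expected = offset + samples * lines_n * bands * dtype.itemsize
    actual = binary.stat().st_size
    if actual < expected:
        raise ValueError(
            f"{binary} holds {actual} bytes but header implies {expected}"
        )

    flat = np.fromfile(binary, dtype=dtype, count=samples * lines_n * bands,
                       offset=offset)
    if interleave == "bsq":
        data = flat.reshape(bands, lines_n, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines_n, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines_n, samples, bands)
    data = np.ascontiguousarray(data.astype(dtype.newbyteorder("=")))

    if "wavelength" in fields:
        wavelengths = np.array(
            [float(w) for w in fields["wavelength"].replace(",", " ").split()]
        )
        if len(wavelengths) != bands:
            raise ValueError("wavelength list length disagrees with band count")
    else:
        wavelengths = np.arange(bands, dtype=float)

    units = "digital_number"
    if fields.get("data units", "").lower() == "reflectance":
        units = "reflectance"
        scale = float(fields.get("reflectance scale factor", 1.0))
        if scale != 1.0:
            data = data.astype(float) / scale
    return HyperCube(data=data, wavelengths=wavelengths, units=units)


def write_envi(cube: HyperCube, header_path: str | os.PathLike,
               interleave: str = "bsq") -> None:
    """Write a cube as an ENVI raster; round-trips exactly through
    :func:`read_envi` for integer dtypes and to float round-off otherwise."""
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    data = np.asarray(cube.data)
    dtype = data.dtype
    if dtype not in _DTYPE_CODES:
        data = data.astype(np.float64)
        dtype = data.dtype
    rows, cols, bands = data.shape

    if interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    else:
        ordered = data
    binary = header_path.with_suffix(".img")
    np.ascontiguousarray(ordered).astype(dtype.newbyteorder("<")).tofile(binary)

    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = nm",
        "wavelength = {" + ", ".join(f"{w:.6g}" for w in cube.wavelengths) + "}",
    ]
    if cube.units == "reflectance":
        lines.append("data units = reflectance")
        lines.append("reflectance scale factor = 1")
    header_path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ROI handling
# ---------------------------------------------------------------------------

def crop_roi(cube: HyperCube, roi: RoiMask) -> HyperCube:
    """Restrict a cube to the bounding box of an ROI mask.

    Pixels inside the box but outside the mask are flagged invalid and
    excluded from every downstream statistic.
    """
    r0, c0 = roi.origin
    rows = np.flatnonzero(roi.mask.any(axis=1))
    cols = np.flatnonzero(roi.mask.any(axis=0))
    top, bottom = r0 + rows[0], r0 + rows[-1] + 1
    left, right = c0 + cols[0], c0 + cols[-1] + 1
    if bottom > cube.shape[0] or right > cube.shape[1]:
        raise ValueError("ROI extends beyond the cube")

    sub = cube.data[top:bottom, left:right]
    inside = roi.mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    valid = inside & cube.valid_mask[top:bottom, left:right]
    return HyperCube(data=sub.copy(), wavelengths=cube.wavelengths,
                     units=cube.units, valid=valid)


def read_roi_mask(path: str | os.PathLike,
                  shape: tuple[int, int] | None = None) -> RoiMask:
    """Load an ROI from a PNG mask (nonzero = inside) or a JSON polygon file.

    JSON polygons are ``{"vertices": [[row, col], ...]}`` filled with the
    even-odd rule; ``shape`` is required for polygons.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        if shape is None:
            raise ValueError("image shape required to rasterize a polygon ROI")
        spec = json.loads(path.read_text())
        return RoiMask(polygon_mask(spec["vertices"], shape))
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].max(axis=2)
    return RoiMask(img != 0)


def polygon_mask(vertices: list[tuple[float, float]],
                 shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a (row, col) polygon with the even-odd fill rule."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    mask = np.zeros(shape, dtype=bool)
    r1 = np.roll(verts[:, 0], -1)
    c1 = np.roll(verts[:, 1], -1)
    r0, c0 = verts[:, 0], verts[:, 1]
    for row in range(shape[0]):
        y = row
        crosses = (r0 <= y) != (r1 <= y)
        if not crosses.any():
            continue
        x = c0[crosses] + (y - r0[crosses]) * (c1[crosses] - c0[crosses]) / (
            r1[crosses] - r0[crosses]
        )
        x = np.sort(x)
        for left, right in zip(x[::2], x[1::2]):
            lo = int(np.ceil(left))
            hi = int(np.floor(right))
            if hi >= lo:
                mask[row, max(lo, 0):min(hi + 1, shape[1])] = True
    return mask
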