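"""Reflectance calibration of raw digital-number cubes.

Raw sensor counts are converted to relative reflectance with the classic
two-reference flat-field relation

    R = rho_white * (I - D) / (W - D)

where ``D`` is a dark-current frame (lens capped, illumination off) and
``W`` the image of a white standard.  In this instrument class the white
standard is a PTFE tile of ~98% reflectance placed inside the scene, so
``W`` is usually a per-band spectrum collapsed from the tile pixels and
broadcast spatially rather than a full flat-field frame; ``rho_white``
(default 0.98) rescales "fraction of the tile's signal" to absolute
reflectance.

Reflectance is clipped to [0, 1.5]: values slightly above 1 arise from
specular glints and must survive, because the Spectral Angle Mapper
downstream is intensity-tolerant and hard clipping at 1 would distort
spectral shape.  Bands where the white-minus-dark denominator collapses
are floored and the affected pixels flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cube_io import HyperCube, RoiMask

__all__ = ["ReferencePair", "ReflectanceCalibrator", "calibrate", "collapse_white"]

CLIP_MAX = 1.5


@dataclass
class ReferencePair:
    """Dark and white reference cubes (or per-band spectra) in digital numbers."""

    dark: HyperCube | np.ndarray
    white: HyperCube | np.ndarray

    def dark_array(self) -> np.ndarray:
        return _as_array(self.dark)

    def white_array(self) -> np.ndarray:
        return _as_array(self.white)


def _as_array(ref: HyperCube | np.ndarray) -> np.ndarray:
    """A reference as a broadcastable float array: full frame or (bands,)."""
    if isinstance(ref, HyperCube):
        return np.asarray(ref.data, dtype=float)
    arr = np.asarray(ref, dtype=float)
    if arr.ndim not in (1, 3):
        raise ValueError("reference must be a cube or a per-band spectrum")
    return arr


class ReflectanceCalibrator(BaseEstimator, TransformerMixin):
    """Dark/white reference calibration as a transformer.

    Parameters
    ----------
    white_reflectance : float, default 0.98
        Reflectance of the white standard (PTFE tile spec: ~98% in VIS-NIR).
    clip_max : float, default 1.5
        Upper clip for calibrated reflectance; lower clip is 0.
    denominator_floor_frac : float, default 1e-6
        Denominator floor as a fraction of the white dynamic range; pixels
        whose white-minus-dark hits the floor are flagged invalid.

    Attributes
    ----------
    dark_ : ndarray
        Dark reference, frame or per-band spectrum.
    white_ : ndarray
        White reference, frame or per-band spectrum.
    floor_ : float
        Absolute denominator floor derived from the white dynamic range.
    """

    def __init__(self, white_reflectance: float = 0.98, clip_max: float = CLIP_MAX,
                 denominator_floor_frac: float = 1e-6):
        self.white_reflectance = white_reflectance
        self.clip_max = clip_max
        self.denominator_floor_frac = denominator_floor_frac

    def fit(self, refs: ReferencePair, y=None) -> "ReflectanceCalibrator":
        self.dark_ = refs.dark_array()
        self.white_ = refs.white_array()
        span = float(np.max(self.white_) - np.min(self.dark_))
        if span <= 0:
            raise ValueError("white reference does not exceed dark reference")
        self.floor_ = self.denominator_floor_frac * span
        denom = self.white_ - self.dark_
        if np.all(denom <= self.floor_):
            raise ValueError("white minus dark is non-positive everywhere")
        return self

    def transform(self, raw: HyperCube) -> HyperCube:
        if raw.units != "digital_number":
            raise ValueError("calibration expects a digital-number cube")
        dark, white = self.dark_, self.white_
        for ref in (dark, white):
            if ref.ndim == 3 and ref.shape != raw.shape:
                raise ValueError("reference frame shape differs from raw cube")
            if ref.ndim == 1 and ref.shape[0] != raw.n_bands:
                raise ValueError("reference spectrum band count differs from cube")

        denom = white - dark
        floored = denom < self.floor_
        denom = np.maximum(denom, self.floor_)
        refl = self.white_reflectance * (raw.data.astype(float) - dark) / denom
        refl = np.clip(refl, 0.0, self.clip_max)

        valid = raw.valid_mask.copy()
        if np.any(floored):
            bad = np.broadcast_to(floored, raw.shape).any(axis=2)
            valid &= ~bad
        return HyperCube(data=refl, wavelengths=raw.wavelengths,
                         units="reflectance", valid=valid)


def calibrate(raw: HyperCube, refs: ReferencePair,
              white_reflectance: float = 0.98) -> HyperCube:
    """Convert a raw cube to reflectance using a dark/white reference pair."""
    return ReflectanceCalibrator(white_reflectance=white_reflectance).fit(
        refs
    ).transform(raw)


def collapse_white(white_cube: HyperCube, tile_mask: RoiMask) -> np.ndarray:
    """Per-band mean spectrum over the white-tile pixels, for spatial broadcast.

    The tile occupies only part of the scene, so its pixels are averaged
    into one spectrum used as the white reference everywhere.
    """
    r0, c0 = tile_mask.origin
    rows, cols = np.nonzero(tile_mask.mask)
    rows, cols = rows + r0, cols + c0
    if rows.max() >= white_cube.shape[0] or cols.max() >= white_cube.shape[1]:
        raise ValueError("tile mask extends beyond the white cube")
    return white_cube.data[rows, cols].astype(float).mean(axis=0)
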