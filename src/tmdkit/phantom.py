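"""Synthetic hyperspectral skin phantoms with ground truth.

The generator emulates the acquisition geometry of a VIS-NIR pushbroom
skin imager (205 bands over 400-800 nm at 348 x 260 pixels at full
scale; a 64 x 64 x 40 downscale is the default for desk-scale work) and
the reflectance contrast between normal skin and non-melanoma carcinoma:
a tumor area darker than surrounding skin by a configurable Delta-R at
700 nm, on the order of 0.2-0.3.

Spectra are purely synthetic: normal skin follows a smooth monotone
curve anchored at (400 nm, 0.15), (600 nm, 0.45), (800 nm, 0.85); the
tumor curve subtracts ``delta_r_700`` times a ramp that vanishes below
500 nm and equals 1 at 700 nm, so the 700 nm contrast is exact and the
spectral *shape* changes (a pure intensity scaling would be invisible to
the scale-invariant SAM classifier).  An optional third tissue zone
carries a spectrum rotated away from both class spectra by a chosen
angle, to exercise the unclassified pathway.

The phantom also synthesizes the raw acquisition: dark frame, in-scene
white-tile spectrum, and a raw digital-number cube built so that
dark/white calibration recovers the constructed reflectance scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .calibration import ReferencePair
from .cube_io import HyperCube, RoiMask

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "make_spectra",
    "zone_spectrum",
    "generate",
    "third_tissue_zone",
    "FULL_SCALE_SHAPE",
]

#: native acquisition geometry (rows, cols, bands)
FULL_SCALE_SHAPE = (260, 348, 205)

_NORMAL_ANCHORS = ((400.0, 0.15), (600.0, 0.45), (800.0, 0.85))
REFLECTANCE_MAX = 1.2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom scene.

    ``delta_r_700`` is the normal-minus-tumor reflectance contrast at the
    band nearest 700 nm; ``noise_sigma`` is i.i.d. per-band additive
    Gaussian noise; ``texture_sigma`` scales a smooth per-pixel
    multiplicative field emulating within-class skin texture (scalar per
    pixel, hence invisible to SAM).  ``zone_angle_offset`` (radians), when
    set, inserts a third tissue zone inside the tumor whose spectrum sits
    at least that angle from both class spectra.
    """

    shape: tuple[int, int, int] = (64, 64, 40)
    tumor_shape: str = "disc"            # disc | ellipse | blob
    tumor_radius_frac: float = 0.25
    delta_r_700: float = 0.2
    noise_sigma: float = 0.02
    texture_sigma: float = 0.04
    illumination_gradient: float = 0.0
    zone_angle_offset: float | None = None
    zone_area_frac: float = 0.016
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.delta_r_700 <= 0.5:
            raise ValueError("delta_r_700 must lie in [0, 0.5]")
        rows, cols, _ = self.shape
        if self.tumor_radius_frac * min(rows, cols) > min(rows, cols) / 2:
            raise ValueError("tumor shape exceeds the image")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(400.0, 800.0, self.shape[2])


@dataclass
class PhantomResult:
    """Everything a pipeline stage might need, with ground truth attached."""

    raw: HyperCube                       # digital-number cube
    refs: ReferencePair                  # dark frame + white-tile spectrum
    roi: RoiMask
    truth: np.ndarray                    # 0 normal, 1 tumor, 2 third zone
    reflectance: HyperCube               # the scene actually embedded in raw
    class_spectra: dict[str, np.ndarray]
    spec: PhantomSpec

    TRUTH_NAMES = ("normal", "tumor", "other")


def make_spectra(class_name: str, delta_r_700: float,
                 wavelengths: np.ndarray) -> np.ndarray:
    """Reflectance curve for a tissue class on the given wavelength grid."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    anchors = np.array(_NORMAL_ANCHORS)
    normal = PchipInterpolator(anchors[:, 0], anchors[:, 1])(wavelengths)
    if class_name == "normal":
        return normal
    if class_name == "tumor":
        ramp = np.clip((wavelengths - 500.0) / 200.0, 0.0, None)
        return np.clip(normal - delta_r_700 * ramp, 0.02, None)
    raise ValueError(f"unknown class {class_name!r}")


def zone_spectrum(normal: np.ndarray, tumor: np.ndarray,
                  angle_offset: float) -> np.ndarray:
    """A spectrum rotated ``angle_offset`` radians away from the tumor
    spectrum, in a direction orthogonal to both class spectra, so its SAM
    angle to the tumor is the offset and to normal skin strictly larger."""
    if angle_offset == 0:
        return tumor.copy()
    t_hat = tumor / np.linalg.norm(tumor)
    # high-frequency carrier, Gram-Schmidt against both class spectra
    x = np.linspace(0.0, 1.0, len(tumor))
    w = np.sin(4 * np.pi * x + 0.7)
    for basis in (normal / np.linalg.norm(normal), t_hat):
        w = w - (w @ basis) * basis
    w /= np.linalg.norm(w)
    z = np.linalg.norm(tumor) * (np.cos(angle_offset) * t_hat
                                 + np.sin(angle_offset) * w)
    return np.clip(z, 0.0, REFLECTANCE_MAX)


def _tumor_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols, _ = spec.shape
    r0, c0 = rows / 2, cols / 2
    radius = spec.tumor_radius_frac * min(rows, cols)
    rr, cc = np.mgrid[0:rows, 0:cols]
    if spec.tumor_shape == "disc":
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    if spec.tumor_shape == "ellipse":
        return ((rr - r0) / radius) ** 2 + ((cc - c0) / (0.6 * radius)) ** 2 <= 1
    if spec.tumor_shape == "blob":
        # disc with a random-walk perturbation of the boundary radius
        theta = np.arctan2(rr - r0, cc - c0)
        steps = rng.standard_normal(64)
        walk = np.cumsum(steps)
        walk -= np.linspace(walk[0], walk[-1], 64)  # close the loop
        walk = gaussian_filter(walk, 2, mode="wrap")
        walk /= max(np.abs(walk).max(), 1e-12)
        bins = ((theta + np.pi) / (2 * np.pi) * 63).astype(int)
        r_theta = radius * (1 + 0.3 * walk[bins])
        return np.hypot(rr - r0, cc - c0) <= r_theta
    raise ValueError(f"unknown tumor shape {spec.tumor_shape!r}")


def generate(spec: PhantomSpec) -> PhantomResult:
    """Build the phantom scene and its simulated raw acquisition.

    Deterministic under ``spec.seed``.  The raw cube satisfies
    ``raw = dark + R * (white - dark) / 0.98`` so that standard
    calibration with ``white_reflectance=0.98`` recovers the scene.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols, bands = spec.shape
    wl = spec.wavelengths

    normal = make_spectra("normal", spec.delta_r_700, wl)
    tumor = make_spectra("tumor", spec.delta_r_700, wl)
    spectra = {"normal": normal, "tumor": tumor}

    truth = np.zeros((rows, cols), dtype=np.int32)
    tumor_mask = _tumor_mask(spec, rng)
    truth[tumor_mask] = 1
    if spec.zone_angle_offset is not None:
        spectra["other"] = zone_spectrum(normal, tumor, spec.zone_angle_offset)
        zone_radius = np.sqrt(spec.zone_area_frac * rows * cols / np.pi)
        rr, cc = np.mgrid[0:rows, 0:cols]
        zone = (rr - rows / 2) ** 2 + (cc - cols / 2) ** 2 <= zone_radius**2
        truth[zone & tumor_mask] = 2

    scene = np.empty((rows, cols, bands))
    lookup = np.stack([normal, tumor, spectra.get("other", tumor)])
    scene[:] = lookup[truth]

    if spec.texture_sigma > 0:
        # normal skin: smooth texture; tumor tissue: finer and stronger
        # heterogeneity, reflecting the spectral heterogeneity of carcinomas
        g = gaussian_filter(rng.standard_normal((rows, cols)), sigma=rows / 12)
        g /= max(g.std(), 1e-12)
        g_tumor = gaussian_filter(rng.standard_normal((rows, cols)),
                                  sigma=rows / 24)
        g_tumor /= max(g_tumor.std(), 1e-12)
        field = np.where(tumor_mask, 1.5 * g_tumor, g)
        scene *= (1.0 + spec.texture_sigma * field)[..., None]
    if spec.illumination_gradient != 0:
        ramp = np.linspace(-0.5, 0.5, cols)
        scene *= (1.0 + spec.illumination_gradient * ramp)[None, :, None]
    if spec.noise_sigma > 0:
        scene = scene + spec.noise_sigma * rng.standard_normal(scene.shape)
    scene = np.clip(scene, 0.0, REFLECTANCE_MAX)

    reflectance = HyperCube(data=scene, wavelengths=wl, units="reflectance")

    dark_level = 100.0
    lamp = 0.6 + 0.4 * np.sin(np.pi * (wl - 400.0) / 400.0)  # halogen-ish
    white = dark_level + 3000.0 * lamp
    dark = HyperCube(data=np.full((rows, cols, bands), dark_level),
                     wavelengths=wl, units="digital_number")
    raw_data = dark_level + scene * (white - dark_level) / 0.98
    raw = HyperCube(data=raw_data, wavelengths=wl, units="digital_number")

    return PhantomResult(
        raw=raw,
        refs=ReferencePair(dark=dark, white=white),
        roi=RoiMask(np.ones((rows, cols), dtype=bool)),
        truth=truth,
        reflectance=reflectance,
        class_spectra=spectra,
        spec=spec,
    )


def third_tissue_zone(spec: PhantomSpec, angle_offset: float) -> PhantomSpec:
    """A copy of ``spec`` with a third tissue zone inside the tumor whose
    spectrum sits ``angle_offset`` radians from the class references."""
    if angle_offset < 0:
        raise ValueError("angle_offset must be non-negative")
    return replace(spec, zone_angle_offset=angle_offset)
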