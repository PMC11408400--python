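"""Margin-map quality metrics: ROC/AUC, maximum horizontal distance,
and Bland-Altman agreement.

ROC curves score each unit (segment by default, pixel optionally) by its
SAM rule angle to a class reference — lower angle means more class-like —
or, in a compatibility mode, by mean reflectance swept over a fixed
threshold range.  The AUC equals the Mann-Whitney two-sample statistic
normalised by n1*n0, which the test suite checks against an exhaustive
pairwise oracle.

The maximum horizontal distance D_max is read from a classification map
as the distance from the tumor center to the farthest tumor-class pixel
on the center row, converted to mm by the pixel pitch; this mirrors how
the same distance is measured on a dermoscopic photograph, enabling a
Bland-Altman comparison of the two measurement methods (mean difference
and mean +/- 1.96 SD limits of agreement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .sam_classification import ClassificationMap
from .segmentation import SegmentMap

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "MarginDistance",
    "BlandAltmanResult",
    "roc_curve",
    "dmax_from_map",
    "bland_altman",
    "summarize_auc",
]


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    class_name: str = ""


@dataclass
class MarginDistance:
    center: tuple[int, int]
    margin_point: tuple[int, int]
    d_max: float                      # physical length, mm


@dataclass
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    limits: tuple[float, float]
    pairs: np.ndarray


def roc_curve(
    scores: np.ndarray,
    truth: np.ndarray,
    polarity: str = "lower_is_positive",
    class_name: str = "",
    thresholds: np.ndarray | None = None,
) -> RocResult:
    """ROC curve and AUC for per-unit scores against binary truth.

    ``polarity`` says whether smaller scores indicate the positive class
    (the SAM-angle convention) or larger ones (reflectance convention).
    By default every distinct score is swept; an explicit threshold grid
    (e.g. the 0.10-0.78 reflectance range) can be supplied instead.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    if polarity not in ("lower_is_positive", "higher_is_positive"):
        raise ValueError(f"unknown polarity {polarity!r}")
    decision = -scores if polarity == "lower_is_positive" else scores

    if thresholds is None:
        fpr, tpr, thr = _skm.roc_curve(truth, decision, drop_intermediate=False)
        out_thr = -thr if polarity == "lower_is_positive" else thr
    else:
        grid = np.sort(np.asarray(thresholds, dtype=float))
        cuts = -grid[::-1] if polarity == "lower_is_positive" else grid
        cuts = np.concatenate(([np.inf], cuts[::-1], [-np.inf]))
        pos, neg = truth.sum(), (~truth).sum()
        tpr = np.array([(decision >= c)[truth].sum() / pos for c in cuts])
        fpr = np.array([(decision >= c)[~truth].sum() / neg for c in cuts])
        out_thr = -cuts if polarity == "lower_is_positive" else cuts
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=np.asarray(out_thr), fpr=fpr, tpr=tpr,
                     auc=auc, class_name=class_name)


def dmax_from_map(
    cmap: ClassificationMap | np.ndarray,
    center: tuple[int, int],
    pixel_pitch: float,
    seg: SegmentMap | None = None,
    tumor_class: str = "tumor",
    any_direction: bool = False,
) -> MarginDistance:
    """Maximum horizontal distance from the tumor center to its margin.

    Scans the image row through ``center`` for the farthest tumor-class
    pixel; ``any_direction=True`` instead takes the farthest tumor pixel
    anywhere (also the fallback when the center row holds none).
    """
    if isinstance(cmap, ClassificationMap):
        if seg is None:
            raise ValueError("segment map required to rasterize the class map")
        tumor = cmap.class_mask(seg, tumor_class)
    else:
        tumor = np.asarray(cmap).astype(bool)
    if not tumor.any():
        raise ValueError("classification map contains no tumor pixels")
    r, c = center
    if not (0 <= r < tumor.shape[0] and 0 <= c < tumor.shape[1]):
        raise ValueError("center lies outside the image")

    if not any_direction:
        cols = np.flatnonzero(tumor[r])
        if len(cols) == 0:
            logger.warning("no tumor pixels on the center row; "
                           "falling back to the any-direction distance")
        else:
            far = cols[np.argmax(np.abs(cols - c))]
            return MarginDistance(center=center, margin_point=(r, int(far)),
                                  d_max=float(abs(far - c)) * pixel_pitch)
    rows, cols = np.nonzero(tumor)
    dist = np.hypot(rows - r, cols - c)
    k = int(np.argmax(dist))
    return MarginDistance(center=center, margin_point=(int(rows[k]), int(cols[k])),
                          d_max=float(dist[k]) * pixel_pitch)


def bland_altman(pairs: np.ndarray, limit_multiplier: float = 1.96
                 ) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired distance series.

    Differences are d1 - d2; limits of agreement are the mean difference
    +/- ``limit_multiplier`` sample standard deviations (n-1 denominator).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
        raise ValueError("need at least two (d1, d2) pairs")
    diff = pairs[:, 0] - pairs[:, 1]
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean,
        sd_difference=sd,
        limits=(mean - limit_multiplier * sd, mean + limit_multiplier * sd),
        pairs=pairs,
    )


def summarize_auc(auc_values, group: str = "") -> dict:
    """Median/min/max/quartile summary of per-image AUC values.

    Quartiles use linear interpolation between order statistics; the
    convention is recorded in the output for reproducibility.
    """
    values = np.asarray(list(auc_values), dtype=float)
    if len(values) == 0:
        raise ValueError(f"no AUC values for group {group!r}")
    return {
        "group": group,
        "n": int(len(values)),
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "q1": float(np.quantile(values, 0.25)),
        "q3": float(np.quantile(values, 0.75)),
        "quantile_convention": "linear",
    }
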