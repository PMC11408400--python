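"""Spectral Angle Mapper (SAM) classification of segments.

SAM measures similarity between a test spectrum t and a reference
spectrum r as the angle between them viewed as vectors in band-space:

    alpha = arccos( t.r / (||t|| ||r||) )

The angle ignores overall magnitude, which makes the classifier robust to
illumination intensity differences — only spectral *shape* matters.

Classification here is region-based: angles are computed on segment mean
spectra, one decision per segment, rather than per pixel (a per-pixel
mode exists for comparison).  A segment is assigned the class of its
nearest reference if that angle is within ``max_angle`` (default 0.1 rad),
otherwise it is left unclassified.  Reference spectra are built per class
as the pixel-area-weighted mean over physician-style training segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .cube_io import HyperCube
from .segmentation import SegmentMap, SegmentStats

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralReference",
    "TrainingSet",
    "ClassificationMap",
    "SAMClassifier",
    "spectral_angle",
    "build_references",
    "select_training",
    "sam_classify",
    "classify_pixels",
    "class_fractions",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "unclassified"

#: canonical class order; ties at exactly equal angle go to the earlier entry
DEFAULT_CLASS_ORDER = ("tumor", "normal")


@dataclass
class SpectralReference:
    """A named class with its mean reflectance spectrum."""

    class_name: str
    spectrum: np.ndarray

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if np.linalg.norm(self.spectrum) == 0:
            raise ValueError(f"reference {self.class_name!r} has zero norm")


@dataclass
class TrainingSet:
    """Segment ids with their class labels, used to build references."""

    members: list[tuple[int, str]]
    fraction: float | None = None

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate segment ids in training set")
        if len({c for _, c in self.members}) < 2:
            raise ValueError("training set must represent both classes")

    def ids_for(self, class_name: str) -> list[int]:
        return [i for i, c in self.members if c == class_name]

    @property
    def segment_ids(self) -> list[int]:
        return [i for i, _ in self.members]


@dataclass
class ClassificationMap:
    """Per-segment class decisions plus the SAM rule angles."""

    segment_classes: np.ndarray          # (n_segments,) of str, may be UNCLASSIFIED
    angles: np.ndarray                   # (n_segments, n_classes) radians
    class_names: list[str]
    areas: np.ndarray                    # (n_segments,) pixel counts

    def pixel_classes(self, seg: SegmentMap) -> np.ndarray:
        """Integer class image: index into class_names, -1 unclassified,
        -2 invalid."""
        codes = np.array(
            [self.class_names.index(c) if c != UNCLASSIFIED else -1
             for c in self.segment_classes],
            dtype=np.int32,
        )
        out = np.full(seg.labels.shape, -2, dtype=np.int32)
        out[seg.valid] = codes[seg.labels[seg.valid]]
        return out

    def class_mask(self, seg: SegmentMap, class_name: str) -> np.ndarray:
        codes = self.pixel_classes(seg)
        return codes == self.class_names.index(class_name)


def spectral_angle(t: np.ndarray, r: np.ndarray) -> float:
    """Spectral angle between two spectra, in radians within [0, pi]."""
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if t.shape != r.shape:
        raise ValueError("spectra lengths differ")
    nt, nr = np.linalg.norm(t), np.linalg.norm(r)
    if nt == 0 or nr == 0:
        raise ValueError("spectral angle undefined for a zero-norm spectrum")
    return float(np.arccos(np.clip(t @ r / (nt * nr), -1.0, 1.0)))


class SAMClassifier(BaseEstimator, ClassifierMixin):
    """Spectral Angle Mapper as a scikit-learn style classifier.

    Parameters
    ----------
    max_angle : float, default 0.1
        Maximum angle (radians) for assignment to a named class; samples
        farther than this from every reference come back unclassified.
    class_order : tuple of str
        Preferred ordering of classes; exact angle ties resolve to the
        earlier class.

    Attributes
    ----------
    classes_ : ndarray of str
        Fitted class names in decision order.
    references_ : ndarray, shape (n_classes, n_bands)
        Per-class (weight-averaged) reference spectra.
    """

    def __init__(self, max_angle: float = 0.1,
                 class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER):
        self.max_angle = max_angle
        self.class_order = class_order

    def fit(self, X: np.ndarray, y, sample_weight: np.ndarray | None = None
            ) -> "SAMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_samples, n_bands) aligned with y")
        if sample_weight is None:
            sample_weight = np.ones(len(y))
        sample_weight = np.asarray(sample_weight, dtype=float)

        seen = list(dict.fromkeys(y))
        ordered = [c for c in self.class_order if c in seen]
        ordered += [c for c in seen if c not in ordered]
        refs = []
        for name in ordered:
            pick = y == name
            w = sample_weight[pick]
            if w.sum() <= 0:
                raise ValueError(f"class {name!r} has no training weight")
            refs.append((w[:, None] * X[pick]).sum(axis=0) / w.sum())
        self.classes_ = np.asarray(ordered, dtype=object)
        self.references_ = np.vstack(refs)
        if np.any(np.linalg.norm(self.references_, axis=1) == 0):
            raise ValueError("a fitted reference spectrum has zero norm")
        return self

    def angles(self, X: np.ndarray) -> np.ndarray:
        """SAM angle of each sample to each class reference (the rule image)."""
        X = np.asarray(X, dtype=float)
        norms = np.linalg.norm(X, axis=1)
        rnorms = np.linalg.norm(self.references_, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosine = (X @ self.references_.T) / np.outer(norms, rnorms)
        out = np.arccos(np.clip(cosine, -1.0, 1.0))
        out[norms == 0] = np.pi  # zero-norm spectra match nothing
        return out

    transform = angles

    def predict(self, X: np.ndarray) -> np.ndarray:
        ang = self.angles(X)
        best = np.argmin(ang, axis=1)  # argmin takes the first (earlier class) on ties
        labels = self.classes_[best].copy()
        labels[ang[np.arange(len(ang)), best] > self.max_angle] = UNCLASSIFIED
        zero = np.linalg.norm(np.asarray(X, dtype=float), axis=1) == 0
        if zero.any():
            logger.warning("%d zero-norm spectra left unclassified", zero.sum())
            labels[zero] = UNCLASSIFIED
        return labels


def build_references(training: TrainingSet,
                     stats: SegmentStats) -> list[SpectralReference]:
    """Per-class reference spectra: area-weighted mean over training segments
    (equal to the pixel mean over all training pixels of the class)."""
    refs = []
    classes = list(dict.fromkeys(c for _, c in training.members))
    ordered = [c for c in DEFAULT_CLASS_ORDER if c in classes]
    ordered += [c for c in classes if c not in ordered]
    for name in ordered:
        ids = training.ids_for(name)
        if not ids:
            raise ValueError(f"no training segments for class {name!r}")
        w = stats.areas[ids].astype(float)
        spectrum = (w[:, None] * stats.mean_spectra[ids]).sum(axis=0) / w.sum()
        refs.append(SpectralReference(class_name=name, spectrum=spectrum))
    return refs


def select_training(
    n_segments: int,
    labels: np.ndarray,
    fraction: float = 0.37,
    seed: int = 0,
    explicit: list[tuple[int, str]] | None = None,
) -> TrainingSet:
    """Stratified random selection of training segments.

    Picks ``round(fraction * n_segments)`` segments, allocated across
    classes proportionally (largest-remainder) with every class getting at
    least one.  An explicit (segment id, class) list bypasses sampling,
    mirroring physician-chosen training segments.
    """
    if explicit is not None:
        return TrainingSet(members=list(explicit), fraction=None)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != n_segments:
        raise ValueError("one label per segment required")
    classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need segments of at least two classes")

    total = int(round(fraction * n_segments))
    total = max(total, len(classes))
    counts = {c: int((labels == c).sum()) for c in classes}
    if any(v == 0 for v in counts.values()):
        raise ValueError("a class has no segments")
    # largest-remainder allocation with a floor of 1 per class
    quota = {c: fraction * counts[c] for c in classes}
    alloc = {c: max(1, int(quota[c])) for c in classes}
    while sum(alloc.values()) < total:
        c = max(classes, key=lambda c: (quota[c] - alloc[c], -classes.index(c)))
        if alloc[c] >= counts[c]:
            quota[c] = -np.inf
            continue
        alloc[c] += 1
    while sum(alloc.values()) > total:
        c = min(classes, key=lambda c: (quota[c] - alloc[c], classes.index(c)))
        if alloc[c] <= 1:
            quota[c] = np.inf
            continue
        alloc[c] -= 1

    rng = np.random.default_rng(seed)
    members: list[tuple[int, str]] = []
    for c in classes:
        ids = np.flatnonzero(labels == c)
        take = min(alloc[c], len(ids))
        chosen = rng.choice(ids, size=take, replace=False)
        members.extend((int(i), str(c)) for i in sorted(chosen))
    return TrainingSet(members=members, fraction=fraction)


def sam_classify(stats: SegmentStats, refs: list[SpectralReference],
                 max_angle: float = 0.1) -> ClassificationMap:
    """Classify every segment by its mean spectrum against the references."""
    if len(refs) < 2:
        raise ValueError("references must cover both classes")
    clf = SAMClassifier(max_angle=max_angle,
                        class_order=tuple(r.class_name for r in refs))
    clf.classes_ = np.asarray([r.class_name for r in refs], dtype=object)
    clf.references_ = np.vstack([r.spectrum for r in refs])
    labels = clf.predict(stats.mean_spectra)
    return ClassificationMap(
        segment_classes=labels,
        angles=clf.angles(stats.mean_spectra),
        class_names=[r.class_name for r in refs],
        areas=stats.areas.copy(),
    )


def classify_pixels(cube: HyperCube, refs: list[SpectralReference],
                    max_angle: float = 0.1) -> np.ndarray:
    """Per-pixel SAM classification (comparison mode): integer class image,
    -1 unclassified, -2 invalid."""
    clf = SAMClassifier(max_angle=max_angle)
    clf.classes_ = np.asarray([r.class_name for r in refs], dtype=object)
    clf.references_ = np.vstack([r.spectrum for r in refs])
    valid = cube.valid_mask
    spectra = np.asarray(cube.data, dtype=float)[valid]
    labels = clf.predict(spectra)
    names = [r.class_name for r in refs]
    codes = np.array([names.index(c) if c != UNCLASSIFIED else -1
                      for c in labels], dtype=np.int32)
    out = np.full(cube.shape[:2], -2, dtype=np.int32)
    out[valid] = codes
    return out


def class_fractions(cmap: ClassificationMap) -> dict[str, float]:
    """Share of valid pixel area per class (plus unclassified); sums to 1."""
    total = float(cmap.areas.sum())
    out = {name: 0.0 for name in cmap.class_names}
    out[UNCLASSIFIED] = 0.0
    for cls, area in zip(cmap.segment_classes, cmap.areas):
        out[str(cls)] += float(area) / total
    return out
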