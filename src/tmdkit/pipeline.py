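"""End-to-end tumor-margin-delineation runs.

The pipeline chains the stages: reflectance calibration -> ROI crop ->
edge-based segmentation + lambda-schedule merging -> training-segment
selection -> SAM classification -> ROC/AUC evaluation.  Every stage is a
pure function of (inputs, config, seed); a JSON manifest captures the
configuration so a run can be replayed bit-exactly.

Defaults mirror the settings of the margin-delineation study this
pipeline implements: scale level 30, merge level 75, SAM threshold
0.1 rad, 37% training segments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .calibration import ReferencePair, calibrate, collapse_white
from .cube_io import HyperCube, RoiMask, crop_roi, read_envi, read_roi_mask, write_envi
from .evaluation import RocResult, dmax_from_map, roc_curve
from .phantom import PhantomResult
from .sam_classification import (
    UNCLASSIFIED,
    ClassificationMap,
    TrainingSet,
    build_references,
    class_fractions,
    sam_classify,
    select_training,
)
from .segmentation import SegmentMap, TMDSegmenter, segment_stats

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "TMDResult",
    "majority_labels",
    "run_arrays",
    "run_tmd",
    "write_labels_png",
    "read_labels_png",
    "write_class_png",
]

#: classification-map palette, index = class code (tumor red, normal green,
#: unclassified black)
_PALETTE = {"tumor": (220, 30, 30), "normal": (30, 180, 30)}


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    raw: Path
    dark: Path
    white: Path
    roi: Path | None = None
    truth: Path | None = None
    train_file: Path | None = None
    white_tile_mask: Path | None = None
    scale_level: float = 30.0
    merge_level: float = 75.0
    sam_threshold: float = 0.1
    train_fraction: float = 0.37
    white_reflectance: float = 0.98
    pixel_pitch: float = 0.1          # mm per pixel
    seed: int = 0
    out_dir: Path = Path("tmd_out")


@dataclass
class TMDResult:
    """In-memory bundle of every stage output."""

    calibrated: HyperCube
    segments: SegmentMap
    initial_n_segments: int
    schedule: object
    training: TrainingSet | None
    classification: ClassificationMap | None
    fractions: dict[str, float] | None
    roc: dict[str, RocResult] = field(default_factory=dict)
    segment_truth: np.ndarray | None = None
    test_ids: np.ndarray | None = None


def majority_labels(seg: SegmentMap, truth: np.ndarray,
                    names: tuple[str, ...] = PhantomResult.TRUTH_NAMES
                    ) -> np.ndarray:
    """Per-segment majority vote over a pixel-level integer truth image."""
    truth = np.asarray(truth)
    if truth.shape != seg.labels.shape:
        raise ValueError("truth image and segment map shapes differ")
    n = seg.n_segments
    k = int(truth.max()) + 1
    counts = np.zeros((n, k), dtype=np.int64)
    valid = seg.valid
    np.add.at(counts, (seg.labels[valid], truth[valid]), 1)
    return np.asarray([names[c] for c in counts.argmax(axis=1)], dtype=object)


def run_arrays(
    raw: HyperCube,
    refs: ReferencePair,
    roi: RoiMask | None = None,
    truth: np.ndarray | None = None,
    training: TrainingSet | None = None,
    scale_level: float = 30.0,
    merge_level: float = 75.0,
    sam_threshold: float = 0.1,
    train_fraction: float = 0.37,
    white_reflectance: float = 0.98,
    seed: int = 0,
) -> TMDResult:
    """Run the full pipeline on in-memory cubes.

    ``truth`` (pixel label image: 0 normal, 1 tumor, 2 other) drives
    stratified training selection and segment-level ROC on the held-out
    test segments; alternatively an explicit ``training`` set may be
    given, mirroring physician-chosen segments.
    """
    t0 = time.perf_counter()
    cal = calibrate(raw, refs, white_reflectance=white_reflectance)
    if roi is not None:
        cal = crop_roi(cal, roi)
        if truth is not None:
            truth = crop_roi(
                HyperCube(truth[..., None].astype(float),
                          np.array([0.0]), units="digital_number"),
                roi,
            ).data[..., 0].astype(int)
    logger.info("stage=calibrate wall=%.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    segmenter = TMDSegmenter(scale_level=scale_level, merge_level=merge_level)
    segmenter.fit(cal)
    seg = segmenter.segment_map_
    stats = segment_stats(seg, cal)
    logger.info(
        "stage=segment wall=%.2fs n_initial=%d n_final=%d",
        time.perf_counter() - t0,
        segmenter.initial_segments_.n_segments, seg.n_segments,
    )

    seg_truth = None
    if truth is not None:
        seg_truth = majority_labels(seg, truth)
        truth_for_training = np.where(seg_truth == "other", "tumor", seg_truth)
        if training is None:
            training = select_training(seg.n_segments, truth_for_training,
                                       fraction=train_fraction, seed=seed)
    if training is None:
        return TMDResult(
            calibrated=cal, segments=seg,
            initial_n_segments=segmenter.initial_segments_.n_segments,
            schedule=segmenter.schedule_, training=None,
            classification=None, fractions=None, segment_truth=seg_truth,
        )

    refs_spectra = build_references(training, stats)
    cmap = sam_classify(stats, refs_spectra, max_angle=sam_threshold)
    fractions = class_fractions(cmap)
    logger.info("stage=classify fractions=%s",
                {k: round(v, 4) for k, v in fractions.items()})

    result = TMDResult(
        calibrated=cal, segments=seg,
        initial_n_segments=segmenter.initial_segments_.n_segments,
        schedule=segmenter.schedule_, training=training,
        classification=cmap, fractions=fractions, segment_truth=seg_truth,
    )
    if seg_truth is not None:
        train_ids = set(training.segment_ids)
        test_ids = np.array(
            [i for i in range(seg.n_segments) if i not in train_ids],
            dtype=int,
        )
        result.test_ids = test_ids
        for ci, name in enumerate(cmap.class_names):
            truth_bin = (seg_truth[test_ids] == name)
            if truth_bin.all() or not truth_bin.any():
                logger.warning("class %s absent from test segments; ROC skipped",
                               name)
                continue
            result.roc[name] = roc_curve(
                cmap.angles[test_ids, ci], truth_bin,
                polarity="lower_is_positive", class_name=name,
            )
    return result


# ---------------------------------------------------------------------------
# file-level artifacts
# ---------------------------------------------------------------------------

def write_labels_png(labels: np.ndarray, path: Path) -> None:
    """Segment labels as 16-bit PNG, stored as label+1 (0 = invalid)."""
    shifted = (np.asarray(labels) + 1).astype(np.uint16)
    iio.imwrite(path, shifted)


def read_labels_png(path: Path) -> SegmentMap:
    labels = np.asarray(iio.imread(path)).astype(np.int64) - 1
    return SegmentMap(labels=labels, n_segments=int(labels.max()) + 1)


def write_class_png(cmap: ClassificationMap, seg: SegmentMap, path: Path) -> None:
    """Classification map as RGB PNG: tumor red, normal green, black
    unclassified/invalid."""
    codes = cmap.pixel_classes(seg)
    rgb = np.zeros(codes.shape + (3,), dtype=np.uint8)
    for idx, name in enumerate(cmap.class_names):
        rgb[codes == idx] = _PALETTE.get(name, (128, 128, 128))
    iio.imwrite(path, rgb)


def run_tmd(config: RunConfig) -> TMDResult:
    """Execute the pipeline from files on disk and write the artifact bundle.

    Writes the calibrated cube, segment map, merge schedule,
    classification map, rule angles, ROC report and a run manifest into
    ``config.out_dir``.  On stage failure, partial outputs stay behind
    with a FAILED marker naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        raw = read_envi(config.raw)
        dark = read_envi(config.dark)
        white_cube = read_envi(config.white)
        if config.white_tile_mask is not None:
            tile = read_roi_mask(config.white_tile_mask,
                                 shape=white_cube.shape[:2])
            white = collapse_white(white_cube, tile)
        else:
            white = white_cube
        refs = ReferencePair(dark=dark, white=white)
        roi = (read_roi_mask(config.roi, shape=raw.shape[:2])
               if config.roi else None)
        truth = None
        if config.truth is not None:
            truth = np.asarray(iio.imread(config.truth)).astype(int)
        training = None
        if config.train_file is not None:
            table = pd.read_csv(config.train_file)
            training = TrainingSet(
                members=[(int(r.segment_id), str(r.class_name))
                         for r in table.itertuples()]
            )

        stage = "pipeline"
        result = run_arrays(
            raw, refs, roi=roi, truth=truth, training=training,
            scale_level=config.scale_level, merge_level=config.merge_level,
            sam_threshold=config.sam_threshold,
            train_fraction=config.train_fraction,
            white_reflectance=config.white_reflectance, seed=config.seed,
        )

        stage = "write_outputs"
        write_envi(result.calibrated, out / "calibrated.hdr")
        write_labels_png(result.segments.labels, out / "segments.png")
        pd.DataFrame(
            [(a, b, c, i) for i, (a, b, c) in
             enumerate(result.schedule.events)],
            columns=["a", "b", "cost", "step"],
        ).to_csv(out / "merge_schedule.csv", index=False)
        if result.classification is not None:
            cmap = result.classification
            write_class_png(cmap, result.segments, out / "classification.png")
            pd.DataFrame(
                cmap.angles, columns=[f"angle_{c}" for c in cmap.class_names]
            ).assign(segment=np.arange(len(cmap.angles)),
                     predicted=cmap.segment_classes).to_csv(
                out / "rule_angles.csv", index=False)
        report = {}
        for name, roc in result.roc.items():
            report[name] = {"auc": roc.auc}
            pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr,
                          "tpr": roc.tpr}).to_csv(
                out / f"roc_{name}.csv", index=False)
        (out / "roc_auc.json").write_text(json.dumps(report, indent=2))

        manifest = {
            "tool": "tmdkit", "version": __version__,
            "config": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in dataclasses.asdict(config).items()},
            "n_segments_initial": result.initial_n_segments,
            "n_segments_final": result.segments.n_segments,
            "class_fractions": result.fractions,
            "auc": {k: v.auc for k, v in result.roc.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return result
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
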