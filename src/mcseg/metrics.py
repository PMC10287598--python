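"""Segmentation and detection metrics: IoU variants, FROC, bootstrap pAUC.

Detection is scored free-response style: a predicted object is a true
positive when its centroid lies within 5 px (0.35 mm at 0.070 mm/px) of a
ground-truth object's centroid, or when the two overlap with IoU >= 0.3.
Matching is one-to-one, greedy in ascending centroid distance. The FROC
curve plots the pooled true-positive rate against false positives per cm^2
of imaged area while the proximity threshold p_thr is swept; the partial
area under it over 0-1 FP/cm^2, normalized by the range width, summarizes
it, with confidence intervals from bootstrap resampling of images.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fusion import combine
from .hessianblob import SegmentedObjectSet
from .proximity import ProximityMap, threshold_map

__all__ = [
    "DetectionObject",
    "MatchResult",
    "FROCCurve",
    "iou",
    "mean_iou_per_image",
    "iou_per_object",
    "match_detections",
    "froc_curve",
    "partial_auc",
    "bootstrap_pauc",
    "operating_point",
    "objects_from_mask",
    "truth_objects_from_annotations",
]

MATCH_DISTANCE_PX = 5.0
MATCH_IOU = 0.3


@dataclass(frozen=True)
class DetectionObject:
    """A detection or ground-truth object: centroid plus (optional) pixels.

    Point-annotated ground truth carries an empty pixel set; its centroid is
    the annotated point itself.
    """

    centroid: tuple[float, float]
    rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    cols: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def area(self) -> int:
        return len(self.rows)

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]  # (prediction index, truth index)


@dataclass
class FROCCurve:
    """Monotone FROC sample: one (FP/cm^2, TPR) point per threshold."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fp_per_cm2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("thresholds", "tpr", "fp_per_cm2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))


# ---------------------------------------------------------------------------
# pixel-mask IoU metrics
# ---------------------------------------------------------------------------

def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 1 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum()) / float(union)


def mean_iou_per_image(pred: np.ndarray, truth: np.ndarray) -> float:
    """Average of the foreground-class IoU and the background-class IoU."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    return 0.5 * (iou(pred, truth) + iou(~pred, ~truth))


def _pixel_iou(obj_a: DetectionObject, obj_b: DetectionObject) -> float:
    sa, sb = obj_a.pixel_set(), obj_b.pixel_set()
    if not sa and not sb:
        return 1.0
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


def iou_per_object(
    pred_objects: Sequence[DetectionObject],
    truth_objects: Sequence[DetectionObject],
) -> float:
    """Mean, over truth objects, of IoU with the best-overlapping prediction.

    For each reference object the prediction object sharing the most pixels
    is selected; truth objects intersecting nothing contribute 0.
    """
    if len(truth_objects) == 0:
        warnings.warn("iou_per_object undefined for an empty truth set")
        return float("nan")
    pred_sets = [p.pixel_set() for p in pred_objects]
    scores = []
    for t in truth_objects:
        ts = t.pixel_set()
        best_inter, best_idx = 0, -1
        for j, ps in enumerate(pred_sets):
            inter = len(ts & ps)
            if inter > best_inter:
                best_inter, best_idx = inter, j
        if best_idx < 0:
            scores.append(0.0)
        else:
            scores.append(_pixel_iou(t, pred_objects[best_idx]))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# detection matching and FROC
# ---------------------------------------------------------------------------

def match_detections(
    pred_objects: Sequence[DetectionObject],
    truth_objects: Sequence[DetectionObject],
    max_distance_px: float = MATCH_DISTANCE_PX,
    min_iou: float = MATCH_IOU,
) -> MatchResult:
    """Greedy one-to-one matching by ascending centroid distance.

    A (prediction, truth) pair is a candidate when the centroid distance is
    at most ``max_distance_px`` (boundary inclusive) or the pixelwise IoU is
    at least ``min_iou``. Unmatched predictions count as false positives,
    unmatched truths as false negatives.
    """
    candidates = []
    for i, p in enumerate(pred_objects):
        for j, t in enumerate(truth_objects):
            d = math.hypot(p.centroid[0] - t.centroid[0], p.centroid[1] - t.centroid[1])
            # the IoU rule needs pixel sets on both sides; point-annotated
            # objects can only match through the distance rule
            overlap_ok = p.area > 0 and t.area > 0 and _pixel_iou(p, t) >= min_iou
            if d <= max_distance_px or overlap_ok:
                candidates.append((d, i, j))
    candidates.sort(key=lambda x: (x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(pred_objects) - tp, fn=len(truth_objects) - tp, pairs=pairs)


def objects_from_mask(mask: np.ndarray) -> list[DetectionObject]:
    """8-connected components of a binary mask as detection objects."""
    from scipy import ndimage as ndi

    labels, n = ndi.label(np.asarray(mask, bool), structure=np.ones((3, 3), bool))
    out = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        out.append(
            DetectionObject(
                centroid=(float(rows.mean()), float(cols.mean())), rows=rows, cols=cols
            )
        )
    return out


def truth_objects_from_annotations(ann, truth_mask: np.ndarray | None = None) -> list[DetectionObject]:
    """Ground-truth objects from a mixed annotation set.

    Point annotations become centroid-only objects; contour annotations are
    rasterized individually into pixel sets. When a ``truth_mask`` is given,
    point objects additionally claim the 8-connected truth component they
    sit on, so IoU-based matching can fire for them too.
    """
    from scipy import ndimage as ndi

    from .image import AnnotationSet, rasterize_annotations

    objs: list[DetectionObject] = []
    labels = None
    if truth_mask is not None:
        labels, _ = ndi.label(np.asarray(truth_mask, bool), structure=np.ones((3, 3), bool))
    for r, c in ann.points:
        if labels is not None and labels[r, c] > 0:
            rows, cols = np.nonzero(labels == labels[r, c])
            objs.append(DetectionObject(centroid=(float(r), float(c)), rows=rows, cols=cols))
        else:
            objs.append(DetectionObject(centroid=(float(r), float(c))))
    for poly in ann.contours:
        single = AnnotationSet(points=(), contours=(poly,), image_shape=ann.image_shape)
        m = rasterize_annotations(single)
        rows, cols = np.nonzero(m)
        objs.append(
            DetectionObject(centroid=(float(rows.mean()), float(cols.mean())), rows=rows, cols=cols)
        )
    return objs


@dataclass(frozen=True)
class FROCImage:
    """Per-image inputs to the FROC sweep."""

    proximity: ProximityMap
    blob_objects: SegmentedObjectSet
    truth_objects: Sequence[DetectionObject]
    area_cm2: float


def _froc_counts(
    images: Sequence[FROCImage], grid: np.ndarray, o_thr: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-image, per-threshold TP/FP counts plus truth counts and areas."""
    n_img, n_thr = len(images), len(grid)
    tp = np.zeros((n_img, n_thr))
    fp = np.zeros((n_img, n_thr))
    truths = np.array([len(im.truth_objects) for im in images], dtype=float)
    areas = np.array([im.area_cm2 for im in images], dtype=float)
    for i, im in enumerate(images):
        for j, thr in enumerate(grid):
            region = threshold_map(im.proximity, float(thr))
            fused = combine(im.blob_objects, region, o_thr=o_thr)
            preds = [
                DetectionObject(centroid=o.centroid, rows=o.rows, cols=o.cols)
                for o in fused.objects
            ]
            res = match_detections(preds, im.truth_objects)
            tp[i, j] = res.tp
            fp[i, j] = res.fp
    return tp, fp, truths, areas


def _curve_from_counts(tp, fp, truths, areas, grid) -> FROCCurve:
    n_truth = truths.sum()
    tpr = tp.sum(axis=0) / n_truth if n_truth else np.zeros(len(grid))
    return FROCCurve(
        thresholds=grid, tpr=tpr, fp_per_cm2=fp.sum(axis=0) / areas.sum()
    )


def froc_curve(
    images: Sequence[FROCImage],
    p_thr_grid: np.ndarray | None = None,
    o_thr: float = 0.3,
) -> FROCCurve:
    """Sweep p_thr: fuse, match per image, pool TP/FN and normalize FPs.

    TPR is pooled over all images (sum TP / sum truth); false positives are
    normalized by the total imaged area in cm^2.
    """
    if len(images) == 0:
        raise ValueError("froc_curve needs at least one image")
    grid = np.linspace(0.0, 1.0, 51) if p_thr_grid is None else np.asarray(p_thr_grid, float)
    tp, fp, truths, areas = _froc_counts(images, grid, o_thr)
    return _curve_from_counts(tp, fp, truths, areas, grid)


def partial_auc(curve: FROCCurve, fp_range: tuple[float, float] = (0.0, 1.0)) -> float:
    """Normalized trapezoidal area of TPR over FP/cm^2 in ``fp_range``.

    The curve is linearly interpolated between samples and held constant
    beyond its ends; the integral is divided by the range width, so an
    always-perfect detector scores 1.
    """
    lo, hi = fp_range
    if hi <= lo:
        raise ValueError("fp_range must be increasing")
    fp = np.asarray(curve.fp_per_cm2, float)
    tpr = np.asarray(curve.tpr, float)
    order = np.argsort(fp, kind="stable")
    fp, tpr = fp[order], tpr[order]
    # collapse duplicate FP values to their maximal TPR (threshold sweep may
    # produce several operating points at the same FP rate)
    uniq_fp, inverse = np.unique(fp, return_inverse=True)
    uniq_tpr = np.zeros_like(uniq_fp)
    for i, t in zip(inverse, tpr):
        uniq_tpr[i] = max(uniq_tpr[i], t)
    xs = np.unique(np.concatenate([uniq_fp, [lo, hi]]))
    xs = xs[(xs >= lo) & (xs <= hi)]
    ys = np.interp(xs, uniq_fp, uniq_tpr)  # np.interp constant-extrapolates
    return float(np.trapezoid(ys, xs) / (hi - lo))


def bootstrap_pauc(
    images: Sequence[FROCImage],
    n_bootstrap: int = 100,
    seed: int = 0,
    p_thr_grid: np.ndarray | None = None,
    o_thr: float = 0.3,
    fp_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[float, float, float]:
    """Mean pAUC and percentile 95% CI over image-level bootstrap resamples.

    Per-image, per-threshold detection counts are computed once; each
    bootstrap replicate re-pools the counts of a with-replacement sample of
    images, which is exactly the pooled FROC of that resampled image set.
    """
    if len(images) < 2:
        raise ValueError("bootstrap requires at least 2 images")
    grid = np.linspace(0.0, 1.0, 51) if p_thr_grid is None else np.asarray(p_thr_grid, float)
    tp, fp, truths, areas = _froc_counts(images, grid, o_thr)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(images), size=len(images))
        curve = _curve_from_counts(tp[idx], fp[idx], truths[idx], areas[idx], grid)
        vals.append(partial_auc(curve, fp_range))
    vals = np.asarray(vals)
    return float(vals.mean()), float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def froc_curve_to_csv(curve: FROCCurve, path) -> None:
    """Write a FROC curve as CSV with columns p_thr, tpr, fp_per_cm2."""
    import csv
    from pathlib import Path

    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["p_thr", "tpr", "fp_per_cm2"])
        for t, tpr, fp in zip(curve.thresholds, curve.tpr, curve.fp_per_cm2):
            writer.writerow([repr(float(t)), repr(float(tpr)), repr(float(fp))])


def operating_point(curve: FROCCurve) -> float:
    """Threshold whose (FP/cm^2, TPR) point is closest to the ideal (0, 1).

    Ties are broken toward the larger threshold.
    """
    if len(curve.thresholds) == 0:
        raise ValueError("empty curve")
    d2 = curve.fp_per_cm2**2 + (1.0 - curve.tpr) ** 2
    best = np.flatnonzero(d2 == d2.min())
    thr = curve.thresholds[best]
    return float(thr.max())
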