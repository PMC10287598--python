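"""Hessian analysis of the DoG planes and blob shape extraction.

The DoG blob detector yields blob locations and scales but no shapes. Shapes
are recovered from the local convexity structure of the DoG plane at each
blob's own scale: at a bright blob both Hessian eigenvalues are large and
negative, at a bright tubular structure one eigenvalue is large and negative
and the other small of arbitrary sign. Both cases — and nothing else — pass
the per-pixel constraint

    tr(H) < 0  and  ( det(H) < 0  or  det(H) / tr(H)^2 <= h_thr ),

where H is the 2x2 Hessian of the DoG plane. The connected component of the
constraint mask spanning each blob's location is that blob's object; all
objects are merged into a single binary segmentation mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .image import MammogramImage, PipelineConfig
from .scalespace import (
    Blob,
    DoGStack,
    build_scale_sequence,
    detect_blobs,
    gaussian_scale_space,
    normalized_dog_stack,
    prune_overlapping_blobs,
)

__all__ = [
    "SegmentedObject",
    "SegmentedObjectSet",
    "hessian_derivatives",
    "hessian_constraint_mask",
    "extract_blob_objects",
    "hessian_dog_segment",
]

logger = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentedObject:
    """One extracted object: its pixels and the blob that seeded it."""

    rows: np.ndarray
    cols: np.ndarray
    blob: Blob

    @property
    def area(self) -> int:
        return len(self.rows)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    def as_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass
class SegmentedObjectSet:
    """Labeled objects plus their union as one binary mask."""

    objects: list[SegmentedObject]
    shape: tuple[int, int]

    @property
    def merged_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for obj in self.objects:
            mask[obj.rows, obj.cols] = True
        return mask

    def __len__(self) -> int:
        return len(self.objects)


def save_objects(objects: SegmentedObjectSet, label_png, csv_path) -> None:
    """Write objects as a labeled 16-bit PNG plus a per-object CSV.

    CSV columns: label, blob_row, blob_col, sigma, response, area.
    """
    import csv

    import imageio.v3 as iio

    labels = np.zeros(objects.shape, dtype=np.uint16)
    for i, obj in enumerate(objects.objects, start=1):
        labels[obj.rows, obj.cols] = i
    iio.imwrite(label_png, labels)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "blob_row", "blob_col", "sigma", "response", "area"])
        for i, obj in enumerate(objects.objects, start=1):
            b = obj.blob
            writer.writerow([i, b.row, b.col, repr(b.sigma), repr(b.response), obj.area])


def hessian_derivatives(plane: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Second derivatives (d_rr, d_rc, d_cc) by central differences.

    Borders are handled by reflective padding, consistent with the border
    policy of the Gaussian convolutions.
    """
    p = np.pad(np.asarray(plane, dtype=np.float64), 1, mode="reflect")
    center = p[1:-1, 1:-1]
    d_rr = p[2:, 1:-1] - 2.0 * center + p[:-2, 1:-1]
    d_cc = p[1:-1, 2:] - 2.0 * center + p[1:-1, :-2]
    d_rc = (p[2:, 2:] - p[2:, :-2] - p[:-2, 2:] + p[:-2, :-2]) / 4.0
    return d_rr, d_rc, d_cc


def hessian_constraint_mask(dog_plane: np.ndarray, h_thr: float) -> np.ndarray:
    """Pixels whose DoG Hessian is consistent with a bright blob or tube.

    Foreground iff tr(H) < 0 and (det(H) < 0 or det(H)/tr(H)^2 <= h_thr);
    the ratio clause is evaluated as det <= h_thr * tr^2, which is exact for
    tr < 0 and never divides by zero (tr = 0 already fails the first clause).
    """
    d_rr, d_rc, d_cc = hessian_derivatives(dog_plane)
    trace = d_rr + d_cc
    det = d_rr * d_cc - d_rc**2
    return (trace < 0) & ((det < 0) | (det <= h_thr * trace**2))


def extract_blob_objects(
    blobs: list[Blob],
    constraint_masks: dict[float, np.ndarray],
    shape: tuple[int, int],
) -> SegmentedObjectSet:
    """Pick, for each blob, the 8-connected constraint-mask component at its
    own scale that spans the blob's location.

    Blobs whose seed pixel falls on constraint background are discarded (and
    logged). Two blobs at the same scale seeded in the same component would
    produce byte-identical objects; such duplicates are collapsed, keeping
    the higher-response blob link.
    """
    labeled: dict[float, np.ndarray] = {}
    for sigma, mask in constraint_masks.items():
        labeled[sigma], _ = ndi.label(mask, structure=_EIGHT_CONN)

    objects: list[SegmentedObject] = []
    claimed: dict[tuple[float, int], int] = {}  # (sigma, label) -> index in objects
    for blob in sorted(blobs, key=lambda b: -b.response):
        if blob.sigma not in labeled:
            raise RuntimeError(f"no constraint mask computed for scale {blob.sigma}")
        lab_img = labeled[blob.sigma]
        lab = int(lab_img[blob.row, blob.col])
        if lab == 0:
            logger.debug(
                "blob at (%d, %d, sigma=%.3f) seeded on constraint background; dropped",
                blob.row, blob.col, blob.sigma,
            )
            continue
        key = (blob.sigma, lab)
        if key in claimed:
            continue
        rows, cols = np.nonzero(lab_img == lab)
        claimed[key] = len(objects)
        objects.append(SegmentedObject(rows=rows, cols=cols, blob=blob))
    return SegmentedObjectSet(objects=objects, shape=shape)


def hessian_dog_segment(
    img: MammogramImage | np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[SegmentedObjectSet, list[Blob]]:
    """Full blob branch: scale space -> DoG -> blobs -> Hessian shapes.

    ``img`` must be intensity-normalized to [0, 1] (the DoG threshold
    T_DoG = 0.006 is calibrated on that scale).
    """
    config = config or PipelineConfig()
    if isinstance(img, MammogramImage):
        if not img.normalized:
            raise ValueError("hessian_dog_segment expects a normalized image")
        pixels = img.pixels
    else:
        pixels = np.asarray(img, dtype=np.float64)
    scales = build_scale_sequence(config.sigma_min, config.sigma_max, config.k)
    l_stack = gaussian_scale_space(pixels, scales)
    dog = normalized_dog_stack(l_stack, scales)
    blobs = detect_blobs(dog, config.t_dog)
    blobs = prune_overlapping_blobs(blobs, config.o_dog)
    masks = {
        scales.sigmas[n]: hessian_constraint_mask(dog.values[n], config.h_thr)
        for n in range(dog.values.shape[0])
    }
    objects = extract_blob_objects(blobs, masks, pixels.shape)
    return objects, blobs
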