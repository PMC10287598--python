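"""Fusion of the blob branch with the regression region mask.

The blob branch segments every bright salient structure; the regression
branch marks regions where microcalcifications are likely. The final
segmentation keeps exactly those blob-branch objects that overlap the
region mask by at least the fraction ``o_thr`` (intersection over the
object's own area). Retained objects contribute their full pixel sets — the
point of the method is shape-accurate MC masks, so objects are not clipped
to the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hessianblob import SegmentedObject, SegmentedObjectSet

__all__ = ["FinalSegmentation", "combine"]


@dataclass
class FinalSegmentation:
    """Retained objects, their overlap fractions, and the union mask."""

    objects: list[SegmentedObject]
    overlap_fractions: list[float]
    shape: tuple[int, int]

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for obj in self.objects:
            m[obj.rows, obj.cols] = True
        return m

    def __len__(self) -> int:
        return len(self.objects)


def combine(
    objects: SegmentedObjectSet,
    region_mask: np.ndarray,
    o_thr: float = 0.3,
    strict: bool = False,
) -> FinalSegmentation:
    """Retain blob objects overlapping the region mask by at least o_thr.

    The overlap fraction of an object is |object ∩ region| / |object|. The
    boundary is inclusive (``>=``) by default; ``strict=True`` switches to a
    strict ``>`` comparison.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != objects.shape:
        raise ValueError(
            f"shape mismatch: objects on {objects.shape}, region {region_mask.shape}"
        )
    if not 0.0 <= o_thr <= 1.0:
        raise ValueError("o_thr must lie in [0, 1]")
    kept: list[SegmentedObject] = []
    fractions: list[float] = []
    for obj in objects.objects:
        inside = int(region_mask[obj.rows, obj.cols].sum())
        frac = inside / obj.area if obj.area else 0.0
        retained = frac > o_thr if strict else frac >= o_thr
        if retained:
            kept.append(obj)
            fractions.append(frac)
    return FinalSegmentation(objects=kept, overlap_fractions=fractions, shape=objects.shape)
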