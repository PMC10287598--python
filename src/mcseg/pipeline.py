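"""End-to-end convenience wrappers around the two-branch pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import FinalSegmentation, combine
from .hessianblob import SegmentedObjectSet, hessian_dog_segment
from .image import MammogramImage, PipelineConfig
from .proximity import ProximityMap, threshold_map
from .regressor import FPNRegressor, predict_proximity
from .scalespace import Blob

__all__ = ["SegmentationResult", "segment_image"]


@dataclass
class SegmentationResult:
    """Everything the pipeline produced for one image."""

    final: FinalSegmentation
    blob_objects: SegmentedObjectSet
    blobs: list[Blob]
    proximity: ProximityMap
    region_mask: np.ndarray


def segment_image(
    img: MammogramImage,
    model: FPNRegressor | None = None,
    config: PipelineConfig | None = None,
    region_mask: np.ndarray | None = None,
    tile: int = 512,
) -> SegmentationResult:
    """Run both branches and fuse them.

    The region mask is taken from (in order of precedence) an explicit
    ``region_mask`` argument, a trained regressor's thresholded proximity
    prediction, or — with neither — all-ones, which reduces the pipeline to
    the blob branch alone.
    """
    config = config or PipelineConfig()
    objects, blobs = hessian_dog_segment(img, config)
    if region_mask is not None:
        proximity = ProximityMap(values=region_mask.astype(float), xi=config.xi, alpha=config.alpha)
        region = np.asarray(region_mask, dtype=bool)
    elif model is not None:
        proximity = predict_proximity(model, img.pixels, tile=tile,
                                      xi=config.xi, alpha=config.alpha)
        region = threshold_map(proximity, config.p_thr)
    else:
        proximity = ProximityMap(values=np.ones(img.shape), xi=config.xi, alpha=config.alpha)
        region = np.ones(img.shape, dtype=bool)
    final = combine(objects, region, o_thr=config.o_thr)
    return SegmentationResult(
        final=final, blob_objects=objects, blobs=blobs, proximity=proximity, region_mask=region
    )
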