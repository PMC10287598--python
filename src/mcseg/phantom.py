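"""Synthetic mammogram phantoms with known microcalcification ground truth.

The generator emulates the statistical appearance of a mammographic patch at
the scale that matters for MC work: a smooth, textured low-frequency
parenchyma-like background, small bright Gaussian spots (punctate MCs), short
bright anisotropic ridges (tubular/rod-like calcifications or vessel wall
segments), and a few larger contour-annotated objects (coarse calcifications).
Every planted object comes with an analytically defined truth mask — the
half-maximum level set of its added signal — and a mixed point/contour
annotation mirroring how real datasets are labelled: small objects by a
single pixel at the center, large objects by a polygonal outline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .image import AnnotationSet, MammogramImage, save_image, save_mask_png

__all__ = [
    "PhantomSpec",
    "PlantedObject",
    "generate_background",
    "plant_objects",
    "generate_phantom",
    "generate_dataset",
    "write_dataset",
]

#: Objects with equivalent diameter below this (px) get a point annotation,
#: larger ones a contour — mirroring the small-vs-large labelling split in
#: clinical annotation practice (the exact cutoff is unreported there).
POINT_ANNOTATION_DIAMETER_PX = 10.0


@dataclass(frozen=True)
class PlantedObject:
    """Ground-truth record of one planted structure."""

    kind: Literal["spot", "tube", "large"]
    center: tuple[float, float]      # (row, col)
    amplitude: float
    sigma: float                     # isotropic width, or minor width for tubes
    annotation: Literal["point", "contour"]
    clipped: bool = False


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one phantom image.

    Defaults correspond to the standard study conditions used throughout the
    test-bench: 256x256 px at 0.070 mm/px, ten punctate spots of amplitude
    ~0.4 and width 1.5-2.5 px over a smooth background with mild pixel noise.
    """

    shape: tuple[int, int] = (256, 256)
    n_spots: int = 10
    n_tubes: int = 0
    n_large: int = 0
    amplitude_range: tuple[float, float] = (0.4, 0.4)
    sigma_range: tuple[float, float] = (1.5, 2.5)
    tube_length_range: tuple[float, float] = (8.0, 16.0)
    large_radius_range: tuple[float, float] = (6.0, 10.0)
    background_correlation_px: float = 20.0
    noise_sd: float = 0.01
    spacing_mm: float = 0.070
    min_separation_factor: float = 4.0
    allow_overlap: bool = False
    seed: int = 0


def generate_background(
    shape: tuple[int, int],
    correlation_px: float,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> MammogramImage:
    """Smooth low-frequency field plus independent pixel noise.

    Gaussian-filtered white noise is rescaled into a mid-gray band
    [0.2, 0.6], then independent N(0, noise_sd) pixel noise is added and the
    result clipped to [0, 1]. Deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field_ = rng.standard_normal(shape)
    if correlation_px > 0:
        field_ = ndi.gaussian_filter(field_, correlation_px, mode="reflect")
    lo, hi = float(field_.min()), float(field_.max())
    if hi > lo:
        field_ = 0.2 + 0.4 * (field_ - lo) / (hi - lo)
    else:
        field_ = np.full(shape, 0.4)
    if noise_sd > 0:
        field_ = field_ + rng.normal(0.0, noise_sd, shape)
    return MammogramImage(
        pixels=np.clip(field_, 0.0, 1.0), spacing_mm=0.070, bit_depth=14, normalized=True
    )


def _spot_signal(shape, center, amplitude, sigma):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma**2))


def _tube_signal(shape, center, amplitude, sigma, length, theta):
    """Anisotropic Gaussian ridge: wide along the axis, sigma across it."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    along = dr * math.cos(theta) + dc * math.sin(theta)
    across = -dr * math.sin(theta) + dc * math.cos(theta)
    sig_along = length / 2.0
    return amplitude * np.exp(-(along**2) / (2 * sig_along**2) - across**2 / (2 * sigma**2))


def _superellipse_signal(shape, center, amplitude, radius, aspect, power, theta):
    """Filled super-ellipse with a soft shoulder so half-max is well defined."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    rho = (np.abs(u / radius) ** power + np.abs(v / (radius * aspect)) ** power) ** (1.0 / power)
    # smooth radial falloff: ~1 inside rho<1, half-max exactly at rho=1
    return amplitude * np.exp(-rho**4 * math.log(2.0))


def _superellipse_contour(center, radius, aspect, power, theta, n=48):
    ts = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    # param form of |u/a|^p + |v/b|^p = 1
    cu = np.sign(np.cos(ts)) * np.abs(np.cos(ts)) ** (2.0 / power) * radius
    cv = np.sign(np.sin(ts)) * np.abs(np.sin(ts)) ** (2.0 / power) * radius * aspect
    r = center[0] + cu * math.cos(theta) - cv * math.sin(theta)
    c = center[1] + cu * math.sin(theta) + cv * math.cos(theta)
    return tuple(zip(r.tolist(), c.tolist()))


def _place_centers(rng, shape, n, margin, min_sep, allow_overlap):
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n and attempts < 2000 * max(n, 1):
        attempts += 1
        r = rng.uniform(margin, shape[0] - 1 - margin)
        c = rng.uniform(margin, shape[1] - 1 - margin)
        if allow_overlap or all(math.hypot(r - pr, c - pc) >= min_sep for pr, pc in centers):
            centers.append((r, c))
    if len(centers) < n:
        raise RuntimeError(f"could not place {n} objects with separation {min_sep}")
    return centers


def plant_objects(
    background: MammogramImage, spec: PhantomSpec
) -> tuple[MammogramImage, AnnotationSet, np.ndarray, list[PlantedObject]]:
    """Add spots, tubes, and large objects to a background.

    Returns the image, the mixed annotation set, the truth mask (union of
    per-object half-maximum level sets of the added signal), and per-object
    ground-truth records.
    """
    rng = np.random.default_rng(spec.seed)
    shape = background.shape
    max_sigma = spec.sigma_range[1] if not spec.n_large else max(
        spec.sigma_range[1], spec.large_radius_range[1]
    )
    min_sep = spec.min_separation_factor * max_sigma
    margin = 3.0 * max_sigma
    n_total = spec.n_spots + spec.n_tubes + spec.n_large
    centers = _place_centers(rng, shape, n_total, margin, min_sep, spec.allow_overlap)

    pixels = background.pixels.copy()
    truth = np.zeros(shape, dtype=bool)
    points: list[tuple[int, int]] = []
    contours: list[tuple[tuple[float, float], ...]] = []
    objects: list[PlantedObject] = []
    idx = 0

    for _ in range(spec.n_spots):
        center = centers[idx]; idx += 1
        a = rng.uniform(*spec.amplitude_range)
        s = rng.uniform(*spec.sigma_range)
        signal = _spot_signal(shape, center, a, s)
        pixels += signal
        obj_mask = signal > a / 2.0
        truth |= obj_mask
        eq_diam = 2.0 * math.sqrt(obj_mask.sum() / math.pi)
        if eq_diam < POINT_ANNOTATION_DIAMETER_PX:
            points.append((int(round(center[0])), int(round(center[1]))))
            ann = "point"
        else:
            from skimage import measure
            cs = measure.find_contours(signal, a / 2.0)
            contours.append(tuple((float(r), float(c)) for r, c in cs[0][::2]))
            ann = "contour"
        objects.append(PlantedObject("spot", center, a, s, ann))

    for _ in range(spec.n_tubes):
        center = centers[idx]; idx += 1
        a = rng.uniform(*spec.amplitude_range)
        s = rng.uniform(*spec.sigma_range)
        length = rng.uniform(*spec.tube_length_range)
        theta = rng.uniform(0.0, math.pi)
        signal = _tube_signal(shape, center, a, s, length, theta)
        pixels += signal
        truth |= signal > a / 2.0
        points.append((int(round(center[0])), int(round(center[1]))))
        objects.append(PlantedObject("tube", center, a, s, "point"))

    for _ in range(spec.n_large):
        center = centers[idx]; idx += 1
        a = rng.uniform(*spec.amplitude_range)
        radius = rng.uniform(*spec.large_radius_range)
        aspect = rng.uniform(0.7, 1.0)
        power = rng.uniform(2.0, 4.0)
        theta = rng.uniform(0.0, math.pi)
        signal = _superellipse_signal(shape, center, a, radius, aspect, power, theta)
        pixels += signal
        truth |= signal > a / 2.0
        poly = _superellipse_contour(center, radius, aspect, power, theta)
        poly = tuple(
            (min(max(r, 0.0), shape[0] - 1), min(max(c, 0.0), shape[1] - 1)) for r, c in poly
        )
        contours.append(poly)
        objects.append(PlantedObject("large", center, a, radius, "contour"))

    image = replace(background, pixels=np.clip(pixels, 0.0, 1.0))
    ann_set = AnnotationSet(points=tuple(points), contours=contours, image_shape=shape)
    return image, ann_set, truth, objects


def generate_phantom(spec: PhantomSpec):
    """Background + objects in one call; seed drives both stages."""
    rng = np.random.default_rng(spec.seed)
    bg_seed, obj_seed = rng.integers(0, 2**31 - 1, size=2)
    background = generate_background(
        spec.shape, spec.background_correlation_px, spec.noise_sd, int(bg_seed)
    )
    background = replace(background, spacing_mm=spec.spacing_mm)
    return plant_objects(background, replace(spec, seed=int(obj_seed)))


@dataclass(frozen=True)
class PhantomSample:
    image: MammogramImage
    annotations: AnnotationSet
    truth_mask: np.ndarray
    objects: list[PlantedObject]
    split: Literal["train", "val", "test"]
    seed: int


def generate_dataset(
    n_images: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> list[PhantomSample]:
    """Generate a case-disjoint train/val/test phantom dataset.

    Each image is one independent case with its own child seed derived from
    the master seed, so two runs with the same arguments are bit-identical
    and no two images coincide.
    """
    if n_images < 3:
        raise ValueError("need at least 3 images for a 3-way split")
    spec = spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_images)]
    n_train = int(round(split_fractions[0] * n_images))
    n_val = int(round(split_fractions[1] * n_images))
    samples = []
    for i, child in enumerate(child_seeds):
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        img, ann, truth, objs = generate_phantom(replace(spec, seed=child))
        samples.append(PhantomSample(img, ann, truth, objs, split, child))
    return samples


def write_dataset(samples: list[PhantomSample], out_dir: Path | str) -> None:
    """Write images (16-bit PNG), annotations (CSV/JSON) and truth masks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        stem = f"phantom_{i:03d}_{s.split}"
        save_image(s.image, out / f"{stem}.png")
        s.annotations.save(out / f"{stem}_points.csv", out / f"{stem}_contours.json")
        save_mask_png(s.truth_mask, out / f"{stem}_truth.png")
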