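"""Gaussian/DoG scale space and blob detection as 3-D local maxima.

The scale-space representation of an image I is L(x, y; sigma) =
G(., sigma) * I. Adjacent smoothed planes are combined into the
scale-normalized difference of Gaussians

    DoG(x, y, n) = sigma_n / (sigma_{n+1} - sigma_n) * (L_n - L_{n+1}),

which approximates the negated scale-normalized Laplacian -sigma^2 * lap(L):
positive and peaked at the centers of bright blob-like structures, with the
response magnitude comparable across scales. Blobs are local maxima of the
resulting (scale, row, col) volume above a response threshold T_DoG; the
sign convention (smaller scale minus larger) is what makes a lower-bound
threshold and maxima detection select bright structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "ScaleSequence",
    "DoGStack",
    "Blob",
    "build_scale_sequence",
    "gaussian_scale_space",
    "normalized_dog_stack",
    "detect_blobs",
    "prune_overlapping_blobs",
    "disc_overlap_fraction",
]


@dataclass(frozen=True)
class ScaleSequence:
    """Geometric scale ladder sigma_n = k^n * sigma_min, n = 0..n_max."""

    sigmas: tuple[float, ...]
    k: float

    def __post_init__(self) -> None:
        s = self.sigmas
        if len(s) < 2 or any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scale sequence must be strictly increasing, length >= 2")

    def __len__(self) -> int:
        return len(self.sigmas)

    def __iter__(self):
        return iter(self.sigmas)


@dataclass(frozen=True)
class DoGStack:
    """Scale-normalized DoG volume, axis order (scale index, row, col)."""

    values: np.ndarray
    scales: ScaleSequence

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("DoG stack must be 3-D (scale, row, col)")
        if self.values.shape[0] != len(self.scales) - 1:
            raise ValueError("scale axis must be one shorter than the Gaussian ladder")


@dataclass(frozen=True)
class Blob:
    """One detected blob: location, scale, and DoG response at the maximum."""

    row: int
    col: int
    sigma: float
    response: float

    @property
    def radius(self) -> float:
        """Radius of the binary disc whose DoG response peaks at this scale."""
        return math.sqrt(2.0) * self.sigma


def build_scale_sequence(sigma_min: float, sigma_max: float, k: float = 2 ** (1 / 3)) -> ScaleSequence:
    """Smallest geometric ladder from sigma_min that reaches sigma_max.

    n_max is the smallest integer with k**n_max * sigma_min >= sigma_max; the
    returned sequence includes both endpoints of the ladder (its last element
    may overshoot sigma_max).
    """
    if sigma_min <= 0 or sigma_max <= sigma_min:
        raise ValueError("need 0 < sigma_min < sigma_max")
    if k <= 1:
        raise ValueError("k must be > 1")
    n_max = max(1, math.ceil(math.log(sigma_max / sigma_min) / math.log(k) - 1e-12))
    sigmas = tuple(sigma_min * k**n for n in range(n_max + 1))
    return ScaleSequence(sigmas=sigmas, k=k)


def gaussian_scale_space(image: np.ndarray, scales: ScaleSequence) -> np.ndarray:
    """Stack of Gaussian-smoothed planes L(x, y; sigma), reflective borders."""
    image = np.asarray(image, dtype=np.float64)
    return np.stack([ndi.gaussian_filter(image, s, mode="reflect") for s in scales])


def normalized_dog_stack(l_stack: np.ndarray, scales: ScaleSequence) -> DoGStack:
    """Scale-normalized DoG planes from adjacent Gaussian levels."""
    sig = np.asarray(scales.sigmas)
    if l_stack.shape[0] != len(sig):
        raise ValueError("one Gaussian plane per scale required")
    norm = sig[:-1] / (sig[1:] - sig[:-1])
    values = norm[:, None, None] * (l_stack[:-1] - l_stack[1:])
    return DoGStack(values=values, scales=scales)


def detect_blobs(dog: DoGStack, t_dog: float) -> list[Blob]:
    """Local maxima of the DoG volume above the response threshold T_DoG.

    A voxel qualifies when it is >= all of its (up to) 26 neighbors in
    (scale, row, col) and strictly greater than at least one of them; within
    a connected equal-valued plateau of qualifying voxels only the
    lexicographically smallest (n, row, col) is kept. Maxima on the first and
    last scale planes are allowed (compared against existing neighbors only).
    Responses must exceed T_DoG strictly.
    """
    v = dog.values
    # neighborhood max/min via a 3x3x3 window that excludes the center
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndi.maximum_filter(v, footprint=footprint, mode="nearest")
    # 'nearest' replication makes out-of-volume neighbors copies of edge
    # voxels, which never beat the center: equivalent to comparing only
    # against existing neighbors.
    qualifies = (v > t_dog) & (v >= neigh_max)
    # drop plateau interiors where every existing neighbor is equal-valued
    neigh_min = ndi.minimum_filter(v, footprint=footprint, mode="constant", cval=np.inf)
    qualifies &= v > neigh_min  # strictly greater than at least one neighbor
    if not qualifies.any():
        return []
    # one representative per connected equal-valued plateau
    labels, n_lab = ndi.label(qualifies, structure=np.ones((3, 3, 3), dtype=bool))
    blobs: list[Blob] = []
    sig = dog.scales.sigmas
    idx = np.argwhere(qualifies)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    seen: set[int] = set()
    for n, r, c in idx[order]:
        lab = labels[n, r, c]
        if lab in seen:
            continue
        seen.add(lab)
        blobs.append(Blob(row=int(r), col=int(c), sigma=sig[n], response=float(v[n, r, c])))
    return blobs


def save_blobs_csv(blobs: list[Blob], path) -> None:
    """Write a blob set as CSV with columns row, col, sigma, response."""
    import csv
    from pathlib import Path

    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "sigma", "response"])
        for b in blobs:
            writer.writerow([b.row, b.col, repr(b.sigma), repr(b.response)])


def load_blobs_csv(path) -> list[Blob]:
    import csv
    from pathlib import Path

    with open(Path(path), newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            Blob(row=int(r["row"]), col=int(r["col"]),
                 sigma=float(r["sigma"]), response=float(r["response"]))
            for r in reader
        ]


def disc_overlap_fraction(a: Blob, b: Blob) -> float:
    """Intersection area of the two blob discs over the smaller disc's area."""
    ra, rb = a.radius, b.radius
    d = math.hypot(a.row - b.row, a.col - b.col)
    r_small = min(ra, rb)
    if d >= ra + rb:
        return 0.0
    if d <= abs(ra - rb):
        return 1.0
    # circle-circle intersection (lens) area
    def seg(r, other, dd):
        cos_arg = (dd**2 + r**2 - other**2) / (2 * dd * r)
        cos_arg = min(1.0, max(-1.0, cos_arg))
        return r**2 * math.acos(cos_arg)
    area = (
        seg(ra, rb, d)
        + seg(rb, ra, d)
        - 0.5 * math.sqrt(
            max(0.0, (-d + ra + rb) * (d + ra - rb) * (d - ra + rb) * (d + ra + rb))
        )
    )
    return area / (math.pi * r_small**2)


def prune_overlapping_blobs(blobs: list[Blob], o_dog: float) -> list[Blob]:
    """Eliminate the smaller of two overlapping blobs.

    Blobs are modelled as discs of radius sqrt(2)*sigma. Candidates are
    processed in descending response order; a blob is dropped iff its disc
    overlaps an already-kept blob of larger-or-equal sigma by a fraction
    (intersection over the smaller disc) strictly greater than O_DoG. With
    O_DoG = 1 the strict inequality never fires and pruning is disabled.
    """
    if not 0.0 <= o_dog <= 1.0:
        raise ValueError("O_DoG must lie in [0, 1]")
    ordered = sorted(blobs, key=lambda b: (-b.response, b.row, b.col, b.sigma))
    kept: list[Blob] = []
    for cand in ordered:
        drop = False
        for k in kept:
            if k.sigma >= cand.sigma and disc_overlap_fraction(cand, k) > o_dog:
                drop = True
                break
        if not drop:
            kept.append(cand)
    return kept
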