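"""Image and annotation containers, I/O, and intensity normalization.

Coordinate convention used throughout the package: ``(row, col)``, 0-based,
with pixel centers at integer coordinates. All scales (sigma) and distances
are expressed in pixels unless a name is suffixed ``_mm``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pydicom
import tifffile
from skimage.draw import polygon as _draw_polygon
from skimage.draw import polygon_perimeter as _draw_polygon_perimeter

__all__ = [
    "MammogramImage",
    "AnnotationSet",
    "PipelineConfig",
    "MissingSpacingError",
    "load_image",
    "save_image",
    "normalize_intensity",
    "rasterize_annotations",
    "save_mask_png",
    "load_mask_png",
]

#: Pixel pitch of both source mammography systems (Siemens MammoNovation,
#: Hologic Selenia), in mm per pixel.
DEFAULT_SPACING_MM = 0.070


class MissingSpacingError(ValueError):
    """Raised when an image carries no pixel spacing and none was supplied."""


@dataclass(frozen=True)
class MammogramImage:
    """A 2D grayscale mammogram with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensity grid, shape ``(rows, cols)``. Raw detector
        counts before :func:`normalize_intensity`, values in ``[0, 1]`` after.
    spacing_mm : float
        Physical size of one pixel in millimetres (isotropic).
    bit_depth : int
        Dynamic range of the detector (12- and 14-bit are typical).
    normalized : bool
        Whether ``pixels`` has been rescaled to ``[0, 1]``.
    """

    pixels: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM
    bit_depth: int = 14
    normalized: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {px.shape}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_cm2(self) -> float:
        """Imaged area in cm^2 (rows * cols * spacing^2 / 100)."""
        r, c = self.shape
        return r * c * self.spacing_mm**2 / 100.0


@dataclass(frozen=True)
class AnnotationSet:
    """Mixed microcalcification annotations for one image.

    Small MCs are marked by a single pixel; larger ones by closed pixel-wise
    contours (polygons). Both rasterize to the binary reference mask M(x, y).
    """

    points: tuple[tuple[int, int], ...]
    contours: tuple[tuple[tuple[float, float], ...], ...]
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        pts = tuple((int(r), int(c)) for r, c in self.points)
        ctrs = tuple(tuple((float(r), float(c)) for r, c in poly) for poly in self.contours)
        rows, cols = self.image_shape
        for r, c in pts:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"point ({r}, {c}) outside image {self.image_shape}")
        for poly in ctrs:
            if len(poly) < 3:
                raise ValueError("a contour needs at least 3 vertices")
            for r, c in poly:
                if not (0 <= r < rows and 0 <= c < cols):
                    raise ValueError(f"vertex ({r}, {c}) outside image {self.image_shape}")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "contours", ctrs)

    @property
    def n_objects(self) -> int:
        return len(self.points) + len(self.contours)

    # -- file dialects: points as 2-column CSV (row,col), contours as JSON ----

    def save(self, points_csv: Path | str, contours_json: Path | str) -> None:
        pts = np.asarray(self.points, dtype=int).reshape(-1, 2)
        np.savetxt(points_csv, pts, fmt="%d", delimiter=",", header="row,col", comments="")
        payload = {
            "image_shape": list(self.image_shape),
            "contours": [[[r, c] for r, c in poly] for poly in self.contours],
        }
        Path(contours_json).write_text(json.dumps(payload))

    @classmethod
    def load(
        cls,
        points_csv: Path | str,
        contours_json: Path | str,
        image_shape: tuple[int, int] | None = None,
    ) -> "AnnotationSet":
        pts = np.loadtxt(points_csv, dtype=int, delimiter=",", skiprows=1, ndmin=2)
        payload = json.loads(Path(contours_json).read_text())
        shape = tuple(payload["image_shape"]) if image_shape is None else image_shape
        contours = tuple(tuple((r, c) for r, c in poly) for poly in payload["contours"])
        return cls(points=tuple(map(tuple, pts)), contours=contours, image_shape=shape)  # type: ignore[arg-type]


@dataclass
class PipelineConfig:
    """Tunable parameters of the full segmentation pipeline.

    Defaults are the operating point selected on mammography validation data:
    scale range sigma in [1.18, 3.1] px with three scales per octave,
    ``T_DoG = 0.006`` on [0, 1]-normalized intensities, Hessian threshold
    ``h_thr = 1.4``, blob-overlap pruning disabled (``O_DoG = 1``), proximity
    parameters ``xi = 10`` px and ``alpha = 1``, and fusion overlap
    ``o_thr = 0.3``.
    """

    sigma_min: float = 1.18
    sigma_max: float = 3.1
    k: float = 2 ** (1 / 3)
    t_dog: float = 0.006
    o_dog: float = 1.0
    h_thr: float = 1.4
    xi: float = 10.0
    alpha: float = 1.0
    p_thr: float = 0.5
    o_thr: float = 0.3
    patch_size: int = 512
    stride: int = 480
    spacing_mm: float = DEFAULT_SPACING_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma_min < self.sigma_max:
            raise ValueError("sigma_min must be < sigma_max")
        if self.k <= 1:
            raise ValueError("scale ratio k must be > 1")
        for name in ("o_dog", "p_thr", "o_thr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.xi <= 0:
            raise ValueError("xi must be positive")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path: Path | str, **overrides) -> "PipelineConfig":
        """Read a ``key=value`` config file; later keyword overrides win."""
        values: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in cls.__dataclass_fields__:
                raise KeyError(f"unknown config key {key!r}")
            typ = type(getattr(cls(), key))
            values[key] = typ(raw) if typ is not bool else raw.lower() in ("1", "true")
        values.update(overrides)
        return cls(**values)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_bit_depth(pixels: np.ndarray) -> int:
    """Smallest depth in {8, 10, 12, 14, 16} that covers the pixel maximum."""
    peak = float(pixels.max(initial=0))
    for b in (8, 10, 12, 14, 16):
        if peak <= 2**b - 1:
            return b
    return int(math.ceil(math.log2(peak + 1)))


def load_image(
    path: Path | str,
    spacing_override: float | None = None,
    bit_depth: int | None = None,
) -> MammogramImage:
    """Read a DICOM, PNG, or TIFF mammogram.

    Pixel spacing is taken from DICOM metadata when present, else from
    ``spacing_override``. PNG/TIFF carry no trusted spacing metadata, so the
    override is mandatory for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array.astype(np.float64)
        spacing = spacing_override
        if spacing is None and "PixelSpacing" in ds:
            sp = [float(v) for v in ds.PixelSpacing]
            spacing = sp[0]
        depth = bit_depth or int(getattr(ds, "BitsStored", 0)) or _infer_bit_depth(pixels)
    elif suffix in (".png", ".tif", ".tiff"):
        if suffix == ".png":
            pixels = iio.imread(path).astype(np.float64)
        else:
            pixels = tifffile.imread(path).astype(np.float64)
        if pixels.ndim == 3:  # drop a redundant channel axis from grayscale RGB
            pixels = pixels[..., 0]
        spacing = spacing_override
        depth = bit_depth or _infer_bit_depth(pixels)
    else:
        raise IOError(f"unsupported image format: {path.name}")
    if spacing is None:
        raise MissingSpacingError(
            f"{path.name} carries no pixel spacing; pass spacing_override "
            f"(source datasets use {DEFAULT_SPACING_MM} mm/px)"
        )
    return MammogramImage(pixels=pixels, spacing_mm=spacing, bit_depth=depth)


def save_image(img: MammogramImage, path: Path | str) -> None:
    """Write a mammogram as 16-bit PNG/TIFF (raw counts, bit-exact)."""
    path = Path(path)
    if img.normalized:
        counts = np.rint(img.pixels * (2**img.bit_depth - 1)).astype(np.uint16)
    else:
        counts = np.rint(img.pixels).astype(np.uint16)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, counts)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, counts)
    else:
        raise IOError(f"unsupported output format: {path.name}")


def normalize_intensity(img: MammogramImage) -> MammogramImage:
    """Rescale raw counts to [0, 1] by dividing by ``2**bit_depth - 1``.

    Refuses double application: normalizing an already-normalized image is
    an error, since the divisor would no longer be meaningful.
    """
    if img.normalized:
        raise ValueError("image is already normalized")
    scale = float(2**img.bit_depth - 1)
    return replace(img, pixels=img.pixels / scale, normalized=True)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_annotations(ann: AnnotationSet) -> np.ndarray:
    """Rasterize mixed point/contour annotations to a binary mask M(x, y).

    Point annotations set single pixels; contour interiors are filled
    boundary-inclusively (a pixel on the polygon outline is foreground).
    The result is the union over all objects, dtype bool.
    """
    mask = np.zeros(ann.image_shape, dtype=bool)
    for r, c in ann.points:
        mask[r, c] = True
    for poly in ann.contours:
        rr = np.array([p[0] for p in poly])
        cc = np.array([p[1] for p in poly])
        fr, fc = _draw_polygon(rr, cc, shape=ann.image_shape)
        mask[fr, fc] = True
        pr, pc = _draw_polygon_perimeter(
            np.rint(rr).astype(int), np.rint(cc).astype(int), shape=ann.image_shape
        )
        mask[pr, pc] = True
    return mask


def save_mask_png(mask: np.ndarray, path: Path | str) -> None:
    """Write a binary mask as an 8-bit PNG with foreground = 255."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def load_mask_png(path: Path | str) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0
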