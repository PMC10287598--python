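"""Dense regression of proximity maps with a pyramid-decoder network.

A fully convolutional encoder produces feature maps at strides 4, 8, 16 and
32. The decoder projects each skip to a common width, upsamples them by
factors 1, 2, 4 and 8 to the stride-4 grid, sums them, applies spatial
dropout (training only) and further convolutions, upsamples by 4 back to the
input resolution, and squashes through a sigmoid — yielding a predicted
proximity map in (0, 1). Training minimizes the soft Dice loss between
predicted and target proximity patches with Adam.

Two encoders are provided: ``"tiny"``, a four-stage convolutional encoder
sized for desk-scale experiments and tests, and ``"large"``, a deeper/wider
variant of the same design. Pretrained classification backbones are outside
the scope of this package.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from . import nn
from .proximity import ProximityMap, threshold_map

__all__ = [
    "PatchPair",
    "AugmentParams",
    "RegressorSpec",
    "FPNRegressor",
    "extract_patches",
    "phantom_training_patches",
    "sample_augmentation",
    "apply_augmentation",
    "augment_patch",
    "build_regressor",
    "train_regressor",
    "predict_proximity",
    "patch_iou",
    "mean_patch_iou",
]


@dataclass(frozen=True)
class PatchPair:
    """An image patch with its target proximity patch."""

    image: np.ndarray
    target: np.ndarray
    source_id: str = ""
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.image.shape != self.target.shape:
            raise ValueError("image and target patches must share a shape")


def extract_patches(
    image: np.ndarray,
    target: np.ndarray,
    size: int = 512,
    stride: int = 480,
    require_annotation: bool = True,
    source_id: str = "",
) -> list[PatchPair]:
    """Sliding-window patch extraction.

    Windows start at offsets 0, stride, 2*stride, ...; when the last regular
    window does not reach the image border, one extra flush-to-border window
    is added per axis so the whole image is covered. Images smaller than the
    window are reflect-padded up to it. With ``require_annotation`` windows
    whose target patch is identically zero are dropped.
    """
    image = np.asarray(image, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if image.shape != target.shape:
        raise ValueError("image and target must share a shape")
    pad_r = max(0, size - image.shape[0])
    pad_c = max(0, size - image.shape[1])
    if pad_r or pad_c:
        image = np.pad(image, ((0, pad_r), (0, pad_c)), mode="reflect")
        target = np.pad(target, ((0, pad_r), (0, pad_c)), mode="reflect")

    def offsets(dim: int) -> list[int]:
        offs = list(range(0, dim - size + 1, stride))
        if offs[-1] + size < dim:
            offs.append(dim - size)
        return offs

    pairs: list[PatchPair] = []
    for r0 in offsets(image.shape[0]):
        for c0 in offsets(image.shape[1]):
            tgt = target[r0 : r0 + size, c0 : c0 + size]
            if require_annotation and not tgt.any():
                continue
            pairs.append(
                PatchPair(
                    image=image[r0 : r0 + size, c0 : c0 + size].copy(),
                    target=tgt.copy(),
                    source_id=source_id,
                    offset=(r0, c0),
                )
            )
    return pairs


def phantom_training_patches(
    n_patches: int = 20,
    size: int = 64,
    n_spots: int = 2,
    seed: int = 0,
    xi: float = 10.0,
    alpha: float = 1.0,
) -> list[PatchPair]:
    """Desk-scale training patches: one small phantom per patch.

    Each patch is an independently seeded phantom of ``size`` x ``size``
    pixels under the standard study conditions (spot amplitude 0.4, width
    1.5-2.5 px, pixel noise 0.01) with its proximity-function target.
    Generating patches directly keeps every planted object fully interior,
    unlike slicing windows out of a larger image.
    """
    from dataclasses import replace as _replace

    from .phantom import PhantomSpec, generate_phantom
    from .proximity import proximity_map

    ss = np.random.SeedSequence(seed)
    pairs = []
    for i, child in enumerate(ss.spawn(n_patches)):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = PhantomSpec(shape=(size, size), n_spots=n_spots,
                           background_correlation_px=10.0, seed=child_seed)
        img, _, truth, _ = generate_phantom(spec)
        target = proximity_map(truth, xi=xi, alpha=alpha).values
        pairs.append(PatchPair(image=img.pixels, target=target, source_id=f"phantom_{i}"))
    return pairs


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """One draw of the augmentation pipeline.

    Geometric members (flip/scale/translation) apply to image and target
    identically; photometric members (contrast/brightness/gamma) apply to
    the image only.
    """

    flip: bool = False
    scale: float = 1.0
    translation: tuple[int, int] = (0, 0)
    contrast: float = 1.0
    brightness: float = 0.0
    gamma: float = 1.0

    @classmethod
    def neutral(cls) -> "AugmentParams":
        return cls()


def sample_augmentation(
    rng: np.random.Generator,
    flip_p: float = 0.5,
    scale_range: tuple[float, float] = (0.9, 1.1),
    max_translation: int = 32,
    brightness_range: tuple[float, float] = (-0.1, 0.1),
    contrast_range: tuple[float, float] = (0.9, 1.1),
    gamma_range: tuple[float, float] = (0.8, 1.25),
) -> AugmentParams:
    return AugmentParams(
        flip=bool(rng.random() < flip_p),
        scale=float(rng.uniform(*scale_range)),
        translation=(
            int(rng.integers(-max_translation, max_translation + 1)),
            int(rng.integers(-max_translation, max_translation + 1)),
        ),
        contrast=float(rng.uniform(*contrast_range)),
        brightness=float(rng.uniform(*brightness_range)),
        gamma=float(rng.uniform(*gamma_range)),
    )


def _geometric(arr: np.ndarray, params: AugmentParams, out_size: int) -> np.ndarray:
    if params.flip:
        arr = arr[:, ::-1]
    if params.scale != 1.0:
        arr = ndi.zoom(arr, params.scale, order=1)
    # translated center crop, clipped to stay inside the array
    h, w = arr.shape
    r0 = (h - out_size) // 2 + params.translation[0]
    c0 = (w - out_size) // 2 + params.translation[1]
    r0 = min(max(r0, 0), h - out_size)
    c0 = min(max(c0, 0), w - out_size)
    return np.ascontiguousarray(arr[r0 : r0 + out_size, c0 : c0 + out_size])


def apply_augmentation(pair: PatchPair, params: AugmentParams, out_size: int = 320) -> PatchPair:
    """Apply a recorded augmentation draw to an (image, target) pair."""
    if min(pair.image.shape) < out_size:
        raise ValueError(f"input patch smaller than output size {out_size}")
    img = _geometric(pair.image, params, out_size)
    tgt = _geometric(pair.target, params, out_size)
    # photometric, image only; intensities kept in [0, 1]
    mean = img.mean()
    img = (img - mean) * params.contrast + mean + params.brightness
    img = np.clip(img, 0.0, 1.0) ** params.gamma
    return PatchPair(image=img, target=np.clip(tgt, 0.0, 1.0),
                     source_id=pair.source_id, offset=pair.offset)


def augment_patch(pair: PatchPair, rng: np.random.Generator, out_size: int = 320, **kw) -> PatchPair:
    """Sample a random augmentation and apply it (default output 320x320)."""
    max_t = kw.pop("max_translation", min(32, (min(pair.image.shape) - out_size) // 2))
    params = sample_augmentation(rng, max_translation=max(0, max_t), **kw)
    return apply_augmentation(pair, params, out_size=out_size)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

_ENCODER_WIDTHS = {
    "tiny": (8, 16, 24, 32, 32),
    "large": (16, 32, 48, 64, 64),
}


@dataclass
class RegressorSpec:
    """Architecture and training hyperparameters.

    Defaults follow the training protocol used on the mammography data:
    40 epochs of Adam (lr 1e-4, beta1 0.9, beta2 0.999, eps 1e-8), batch 8,
    soft Dice loss, best-validation-IoU checkpointing. The ``tiny`` preset
    scales the model and schedule down for desk-size experiments.
    """

    encoder: str = "large"
    decoder_channels: int = 32
    dropout: float = 0.1
    epochs: int = 40
    batch_size: int = 8
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps_opt: float = 1e-8
    seed: int = 0

    @classmethod
    def tiny(cls, seed: int = 0, epochs: int = 50) -> "RegressorSpec":
        return cls(encoder="tiny", decoder_channels=16, dropout=0.1,
                   epochs=epochs, batch_size=4, lr=1e-3, seed=seed)


class FPNRegressor:
    """Pyramid-decoder dense regressor mapping H x W images to (0,1) maps."""

    def __init__(self, spec: RegressorSpec):
        if spec.encoder not in _ENCODER_WIDTHS:
            raise ValueError(f"unknown encoder {spec.encoder!r}")
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        widths = _ENCODER_WIDTHS[spec.encoder]
        d = spec.decoder_channels
        rng = self.rng
        p: dict[str, nn.Tensor] = {}
        # encoder: five 3x3 conv stages, 2x2 average pool between stages;
        # skips taken after stages 2..5 (strides 4, 8, 16, 32)
        chans = (1,) + widths
        for i in range(5):
            p[f"enc{i}_w"] = nn.he_init(rng, (chans[i + 1], chans[i], 3, 3))
            p[f"enc{i}_b"] = nn.Tensor(np.zeros(chans[i + 1]), requires_grad=True)
        # decoder: 1x1 lateral projections + one 3x3 block per level
        for i, c in enumerate(widths[1:]):  # strides 4, 8, 16, 32
            p[f"lat{i}_w"] = nn.he_init(rng, (d, c, 1, 1))
            p[f"lat{i}_b"] = nn.Tensor(np.zeros(d), requires_grad=True)
            p[f"fpn{i}_w"] = nn.he_init(rng, (d, d, 3, 3))
            p[f"fpn{i}_b"] = nn.Tensor(np.zeros(d), requires_grad=True)
        p["head0_w"] = nn.he_init(rng, (d, d, 3, 3))
        p["head0_b"] = nn.Tensor(np.zeros(d), requires_grad=True)
        p["head1_w"] = nn.he_init(rng, (1, d, 3, 3))
        p["head1_b"] = nn.Tensor(np.zeros(1), requires_grad=True)
        self.params = p

    def parameters(self) -> list[nn.Tensor]:
        return list(self.params.values())

    def forward(self, x: np.ndarray, training: bool = False) -> nn.Tensor:
        """Run the network on a (N, H, W) or (H, W) float array.

        Each input is standardized to zero mean and unit variance before the
        encoder — mammographic brightness varies substantially between
        acquisition systems, and the proximity target is scale-free.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        n, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} must be divisible by 32")
        x = (x - x.mean(axis=(1, 2), keepdims=True)) / (
            x.std(axis=(1, 2), keepdims=True) + 1e-6
        )
        p = self.params
        t = nn.Tensor(x[:, None])  # N,1,H,W
        skips = []
        for i in range(5):
            t = nn.relu(nn.conv2d(t, p[f"enc{i}_w"], p[f"enc{i}_b"], padding=1))
            t = nn.avg_pool2(t)
            if i >= 1:  # strides 4, 8, 16, 32
                skips.append(t)
        levels = []
        for i, s in enumerate(skips):
            # 1x1 lateral projections carry no activation, as in standard
            # feature-pyramid decoders
            lat = nn.conv2d(s, p[f"lat{i}_w"], p[f"lat{i}_b"])
            blk = nn.relu(nn.conv2d(lat, p[f"fpn{i}_w"], p[f"fpn{i}_b"], padding=1))
            levels.append(nn.upsample_bilinear(blk, 2**i))
        merged = nn.add(*levels)
        merged = nn.spatial_dropout(merged, self.spec.dropout, self.rng, training)
        head = nn.relu(nn.conv2d(merged, p["head0_w"], p["head0_b"], padding=1))
        head = nn.conv2d(head, p["head1_w"], p["head1_b"], padding=1)
        return nn.sigmoid(nn.upsample_bilinear(head, 4))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Inference (dropout inactive); returns a (H, W) map in (0, 1)."""
        out = self.forward(image, training=False)
        return out.data[0, 0] if np.asarray(image).ndim == 2 else out.data[:, 0]

    # -- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()

    def save(self, path: Path | str) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"spec": self.spec, "state": self.state_dict()}, fh)

    @classmethod
    def load(cls, path: Path | str) -> "FPNRegressor":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        model = cls(payload["spec"])
        model.load_state_dict(payload["state"])
        return model


def build_regressor(spec: RegressorSpec) -> FPNRegressor:
    return FPNRegressor(spec)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def patch_iou(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    inter = np.logical_and(pred_mask, truth_mask).sum()
    union = np.logical_or(pred_mask, truth_mask).sum()
    return 1.0 if union == 0 else float(inter) / float(union)


def mean_patch_iou(
    model: FPNRegressor,
    pairs: Sequence[PatchPair],
    p_thr_grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean IoU per patch at the grid threshold that maximizes it.

    The reference mask of each patch is recovered from its proximity target
    as the P = 1 level set (proximity is exactly 1 on annotated pixels).
    The default threshold grid is dense near 1 because Dice-trained maps
    saturate: the informative level sets of a well-trained prediction sit
    close to the top of the (0, 1) range. Returns ``(best mean IoU, best
    p_thr)``.
    """
    if p_thr_grid is None:
        grid = np.concatenate([np.linspace(0.05, 0.95, 19),
                               1.0 - np.geomspace(0.03, 1e-4, 8)])
    else:
        grid = np.asarray(p_thr_grid)
    preds = [model.predict(p.image) for p in pairs]
    truths = [p.target >= 1.0 - 1e-9 for p in pairs]
    best_iou, best_thr = -1.0, float(grid[0])
    for thr in grid:
        ious = [patch_iou(pr >= thr, tr) for pr, tr in zip(preds, truths)]
        m = float(np.mean(ious))
        if m > best_iou:
            best_iou, best_thr = m, float(thr)
    return best_iou, best_thr


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    val_p_thr: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_regressor(
    model: FPNRegressor,
    train_pairs: Sequence[PatchPair],
    val_pairs: Sequence[PatchPair],
    spec: RegressorSpec | None = None,
) -> tuple[FPNRegressor, TrainingHistory]:
    """Train with soft Dice on proximity targets; keep the best-IoU epoch.

    Validation IoU per patch is evaluated each epoch at the threshold-grid
    optimum; the checkpoint with the highest validation IoU over all epochs
    is restored into the model before returning.
    """
    spec = spec or model.spec
    if len(train_pairs) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(spec.seed + 1)
    opt = nn.Adam(model.parameters(), lr=spec.lr, beta1=spec.beta1,
                  beta2=spec.beta2, eps=spec.eps_opt)
    history = TrainingHistory()
    best_state, best_iou = None, -1.0
    n = len(train_pairs)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            batch = [train_pairs[i] for i in order[start : start + spec.batch_size]]
            x = np.stack([b.image for b in batch])
            t = np.stack([b.target for b in batch])[:, None]
            opt.zero_grad()
            pred = model.forward(x, training=True)
            loss = nn.dice_loss(pred, t)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(losses)))
        if len(val_pairs) > 0:
            iou, thr = mean_patch_iou(model, val_pairs)
        else:
            iou, thr = -math.inf, float("nan")
        history.val_iou.append(iou)
        history.val_p_thr.append(thr)
        if iou > best_iou:
            best_iou = iou
            best_state = model.state_dict()
            history.best_epoch = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# full-image inference
# ---------------------------------------------------------------------------

def predict_proximity(
    model: FPNRegressor,
    image: np.ndarray,
    tile: int = 512,
    overlap: int = 64,
    xi: float = 10.0,
    alpha: float = 1.0,
) -> ProximityMap:
    """Tile a full image, predict per tile, and average the overlaps."""
    if tile % 32:
        raise ValueError("tile size must be divisible by 32")
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    ph, pw = max(tile, h), max(tile, w)
    padded = np.pad(image, ((0, ph - h), (0, pw - w)), mode="reflect")
    acc = np.zeros(padded.shape)
    cnt = np.zeros(padded.shape)
    step = tile - overlap

    def offsets(dim: int) -> list[int]:
        offs = list(range(0, dim - tile + 1, step))
        if offs[-1] + tile < dim:
            offs.append(dim - tile)
        return offs

    for r0 in offsets(ph):
        for c0 in offsets(pw):
            pred = model.predict(padded[r0 : r0 + tile, c0 : c0 + tile])
            acc[r0 : r0 + tile, c0 : c0 + tile] += pred
            cnt[r0 : r0 + tile, c0 : c0 + tile] += 1.0
    return ProximityMap(values=(acc / cnt)[:h, :w], xi=xi, alpha=alpha)
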