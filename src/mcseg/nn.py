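"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the dense-regression network needs: 2-D
convolution (stride 1, zero padding), ReLU, sigmoid, 2x2 average pooling,
nearest-neighbour upsampling, elementwise sum, spatial (channelwise)
dropout, and the soft Dice loss — plus Adam. Tensors are NCHW throughout.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv2d",
    "relu",
    "sigmoid",
    "avg_pool2",
    "upsample_nearest",
    "upsample_bilinear",
    "add",
    "spatial_dropout",
    "dice_loss",
    "Adam",
    "he_init",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: np.ndarray, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    def zero_grad(self) -> None:
        self.grad = None


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    t.grad = g if t.grad is None else t.grad + g


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
    return out


# ---------------------------------------------------------------------------
# ops
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, Hout*Wout) for stride-1 windows."""
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,Hout,Wout,kh,kw
    n, c, ho, wo = win.shape[:4]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), zero padding."""
    f, c, kh, kw = w.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xd, kh, kw)
    wmat = w.data.reshape(f, -1)
    out_data = np.einsum("fk,nkl->nfl", wmat, cols).reshape(-1, f, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, f, 1, 1)
    out = _node(out_data, (x, w) + ((b,) if b is not None else ()))

    def backward() -> None:
        g = out.grad.reshape(out.grad.shape[0], f, -1)  # N,F,L
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2)))
        _accumulate(w, np.einsum("nfl,nkl->fk", g, cols).reshape(w.shape))
        if x.requires_grad or x._parents:
            dcols = np.einsum("fk,nfl->nkl", wmat, g)  # N, C*kh*kw, L
            n = xd.shape[0]
            dxp = np.zeros_like(xd)
            dcols = dcols.reshape(n, c, kh, kw, ho, wo)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + ho, j : j + wo] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            _accumulate(x, dxp)

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))

    def backward() -> None:
        _accumulate(x, out.grad * (x.data > 0))

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = _node(s, (x,))

    def backward() -> None:
        _accumulate(x, out.grad * s * (1.0 - s))

    out._backward = backward
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 (spatial dims must be even)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = _node(r.mean(axis=(3, 5)), (x,))

    def backward() -> None:
        g = np.repeat(np.repeat(out.grad, 2, axis=2), 2, axis=3) / 4.0
        _accumulate(x, g)

    out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor."""
    if factor == 1:
        return x
    out = _node(np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3), (x,))

    def backward() -> None:
        n, c, h, w = out.grad.shape
        g = out.grad.reshape(n, c, h // factor, factor, w // factor, factor).sum(axis=(3, 5))
        _accumulate(x, g)

    out._backward = backward
    return out


def _bilinear_matrix(n_in: int, factor: int) -> np.ndarray:
    """(n_in*factor, n_in) interpolation weights, half-pixel-center mapping."""
    n_out = n_in * factor
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    src = np.clip(src, 0.0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    mat = np.zeros((n_out, n_in))
    mat[np.arange(n_out), lo] += 1.0 - frac
    mat[np.arange(n_out), hi] += frac
    return mat


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor (separable interpolation)."""
    if factor == 1:
        return x
    n, c, h, w = x.shape
    ah = _bilinear_matrix(h, factor)
    aw = _bilinear_matrix(w, factor)
    out = _node(np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True), (x,))

    def backward() -> None:
        _accumulate(x, np.einsum("oh,ncop,pw->nchw", ah, out.grad, aw, optimize=True))

    out._backward = backward
    return out


def add(*xs: Tensor) -> Tensor:
    out = _node(sum(x.data for x in xs), xs)

    def backward() -> None:
        for x in xs:
            _accumulate(x, out.grad)

    out._backward = backward
    return out


def spatial_dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Drop whole feature channels (per sample) with probability ``rate``."""
    if not training or rate <= 0.0:
        return x
    n, c = x.shape[:2]
    keep = (rng.random((n, c, 1, 1)) >= rate) / (1.0 - rate)
    out = _node(x.data * keep, (x,))

    def backward() -> None:
        _accumulate(x, out.grad * keep)

    out._backward = backward
    return out


def dice_loss(pred: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss between a predicted map and a fixed target array."""
    t = np.asarray(target, dtype=np.float64)
    if t.shape != pred.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {t.shape}")
    p = pred.data
    num = 2.0 * float((p * t).sum()) + eps
    den = float((p + t).sum()) + eps
    out = _node(np.array(1.0 - num / den), (pred,))

    def backward() -> None:
        g = float(out.grad)
        _accumulate(pred, g * (num / den**2 - 2.0 * t / den))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# parameters and optimization
# ---------------------------------------------------------------------------

def he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    """He-normal initialized weight tensor (fan-in from all but dim 0)."""
    fan_in = int(np.prod(shape[1:]))
    w = rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)
    return Tensor(w, requires_grad=True)


class Adam:
    """Adaptive moment estimation over a list of parameters."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
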