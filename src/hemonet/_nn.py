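"""Minimal NumPy neural-network primitives.

Dense and convolutional layers with explicit forward/backward passes, ReLU,
inverted dropout, and an Adam optimizer. Everything is seed-deterministic:
all randomness flows through a caller-supplied ``numpy.random.Generator``.

Shapes follow the (batch, channel, height, width) convention for fields and
(features,) for 1D profile vectors.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Adam",
    "he_init",
    "relu",
    "relu_grad",
    "dropout_mask",
    "conv3x3_forward",
    "conv3x3_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "convT2x2_forward",
    "convT2x2_backward",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            dtype=np.float64) -> np.ndarray:
    """Kaiming-normal initialization suited to ReLU networks."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


def dropout_mask(rng: np.random.Generator, shape, rate: float, dtype=np.float64):
    """Inverted-dropout multiplier: E[mask] = 1."""
    if rate <= 0.0:
        return None
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(dtype) / keep


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

        self._scratch = [np.empty_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v, t in zip(self.params, grads, self.m, self.v,
                                 self._scratch):
            m *= b1
            np.multiply(g, 1.0 - b1, out=t)
            m += t
            v *= b2
            np.multiply(g, g, out=t)
            t *= 1.0 - b2
            v += t
            np.divide(v, bias2, out=t)
            np.sqrt(t, out=t)
            t += self.eps
            np.divide(m, t, out=t)
            t *= self.lr / bias1
            p -= t


# ---------------------------------------------------------------------------
# 3x3 "same" convolution via im2col
# ---------------------------------------------------------------------------

def _im2col3(xp: np.ndarray, H: int, W: int) -> np.ndarray:
    """xp: zero-padded input (B, C, H+2, W+2) -> (B, C*9, H*W)."""
    B, C = xp.shape[:2]
    cols = np.empty((B, C, 9, H, W), dtype=xp.dtype)
    k = 0
    for ki in range(3):
        for kj in range(3):
            cols[:, :, k] = xp[:, :, ki:ki + H, kj:kj + W]
            k += 1
    return cols.reshape(B, C * 9, H * W)


def conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution.

    x: (B, C, H, Wd); W: (F, C*9); b: (F,). Returns y (B, F, H, Wd) and cache.
    """
    B, C, H, Wd = x.shape
    xp = np.zeros((B, C, H + 2, Wd + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1] = x
    cols = _im2col3(xp, H, Wd)                       # (B, C*9, HW)
    F, P = W.shape[0], H * Wd
    if P >= 16:      # batched GEMM wins for large spatial extents
        y = np.matmul(W[None], cols)
    else:
        y = np.ascontiguousarray(
            (W @ cols.transpose(1, 0, 2).reshape(C * 9, B * P))
            .reshape(F, B, P).transpose(1, 0, 2))
    y += b[None, :, None]
    return y.reshape(B, F, H, Wd), (cols, x.shape, W)


def conv3x3_backward(dy: np.ndarray, cache):
    cols, xshape, W = cache
    B, C, H, Wd = xshape
    F = W.shape[0]
    P = H * Wd
    dyf = np.ascontiguousarray(dy.reshape(B, F, P))
    dW = np.tensordot(dyf, cols, axes=([0, 2], [0, 2]))
    db = dyf.sum(axis=(0, 2))
    if P >= 16:
        dcols = np.matmul(W.T[None], dyf)
    else:
        dcols = np.ascontiguousarray(
            (W.T @ dyf.transpose(1, 0, 2).reshape(F, B * P))
            .reshape(C * 9, B, P).transpose(1, 0, 2))
    dcols = dcols.reshape(B, C, 9, H, Wd)
    dxp = np.zeros((B, C, H + 2, Wd + 2), dtype=dy.dtype)
    k = 0
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki:ki + H, kj:kj + Wd] += dcols[:, :, k]
            k += 1
    return dxp[:, :, 1:-1, 1:-1], dW, db


# ---------------------------------------------------------------------------
# 2x2 max pooling (stride 2)
# ---------------------------------------------------------------------------

def maxpool2_forward(x: np.ndarray):
    B, C, H, W = x.shape
    xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(B, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache):
    idx, xshape = cache
    B, C, H, W = xshape
    dxr = np.zeros((B, C, H // 2, W // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dxr = dxr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(B, C, H, W)


# ---------------------------------------------------------------------------
# 2x2 transposed convolution, stride 2 (non-overlapping upsampling)
# ---------------------------------------------------------------------------

def convT2x2_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (B, C, H, Wd); W: (F, 2, 2, C); b: (F,) -> y (B, F, 2H, 2Wd)."""
    B, C, H, Wd = x.shape
    F = W.shape[0]
    y4 = np.einsum("fpqc,bchw->bfpqhw", W, x, optimize=True)
    y = y4.transpose(0, 1, 4, 2, 5, 3).reshape(B, F, 2 * H, 2 * Wd).copy()
    y += b[None, :, None, None]
    return y, (x, W)


def convT2x2_backward(dy: np.ndarray, cache):
    x, W = cache
    B, C, H, Wd = x.shape
    F = W.shape[0]
    dy4 = dy.reshape(B, F, H, 2, Wd, 2).transpose(0, 1, 3, 5, 2, 4)
    dW = np.einsum("bfpqhw,bchw->fpqc", dy4, x, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dx = np.einsum("fpqc,bfpqhw->bchw", W, dy4, optimize=True)
    return dx, dW, db
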