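"""Minimal NumPy neural-network engine.

Implements exactly the primitives the slide pipeline needs — 3x3 "same"
convolutions via im2col, 2x2 max pooling, nearest-neighbour upsampling,
ReLU/sigmoid/softmax, and an Adam optimizer — with hand-written backward
passes.  Everything operates on float32 NHWC batches and is deterministic
for a fixed seed (no threading-dependent reductions beyond BLAS matmul).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Adam",
    "conv2d_forward",
    "conv2d_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "upsample2_forward",
    "upsample2_backward",
    "relu",
    "relu_backward",
    "sigmoid",
    "softmax",
    "glorot",
]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# convolution (3x3, stride 1, zero "same" padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix for a k x k same-padded conv."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    return np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, k * k * c)


def conv2d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """x (N,H,W,Cin), weight (k,k,Cin,Cout), bias (Cout,) -> (out, cache)."""
    k = weight.shape[0]
    n, h, w, _ = x.shape
    cout = weight.shape[-1]
    cols = _im2col(x, k)
    out = cols @ weight.reshape(-1, cout) + bias
    return out.reshape(n, h, w, cout), (cols, x.shape, k)


def conv2d_backward(dout: np.ndarray, weight: np.ndarray, cache):
    """Returns (dx, dweight, dbias)."""
    cols, x_shape, k = cache
    n, h, w, cin = x_shape
    cout = weight.shape[-1]
    dflat = dout.reshape(-1, cout)
    dw = (cols.T @ dflat).reshape(weight.shape)
    db = dflat.sum(axis=0)
    dcols = (dflat @ weight.reshape(-1, cout).T).reshape(n, h, w, k, k, cin)
    p = k // 2
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, cin), dtype=dout.dtype)
    for di in range(k):  # k*k slice-adds instead of a scatter: fast col2im
        for dj in range(k):
            dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, di, dj, :]
    dx = dxp[:, p:p + h, p:p + w, :]
    return dx, dw, db


# ---------------------------------------------------------------------------
# 2x2 max pooling / nearest upsampling
# ---------------------------------------------------------------------------

def maxpool2_forward(x: np.ndarray):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    # break ties toward the first maximal element so backward conserves gradient
    cum = np.cumsum(np.cumsum(mask, axis=2), axis=4)
    mask = mask & (cum == 1)
    return out, mask


def maxpool2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, hh, ww, c = dout.shape
    dxr = mask * dout[:, :, None, :, None, :]
    return dxr.reshape(n, hh * 2, ww * 2, c)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, out: np.ndarray) -> np.ndarray:
    return dout * (out > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
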