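"""Minimal 1-D convolutional network primitives (forward + backward).

Everything operates on float32 arrays shaped (batch, channels, time).
Convolutions are stride-1 with 'same' zero padding and odd kernel length;
the im2col buffers are reshaped so each convolution is a single GEMM, which
keeps full-night inference and desk-scale training fast on one CPU.

Gradients are exact (verified against central differences in the test
suite), not approximations.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv1d_forward",
    "conv1d_backward_input",
    "conv1d_backward_params",
    "relu",
    "relu_backward",
    "maxpool1d",
    "maxpool1d_backward",
    "upsample_nearest",
    "upsample_nearest_backward",
    "sigmoid",
    "bce_with_logits",
    "AdamState",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, T) -> (N*T, C*k) patch matrix with 'same' zero padding."""
    n, c, t = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)  # (N, C, T, k)
    return win.transpose(0, 2, 1, 3).reshape(n * t, c * k)


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded conv: x (N, C, T), w (F, C, k), b (F,) -> (N, F, T)."""
    n, c, t = x.shape
    f, c2, k = w.shape
    assert c == c2 and k % 2 == 1
    cols = _im2col(x, k)
    out = cols @ w.reshape(f, c * k).T
    out += b
    return out.reshape(n, t, f).transpose(0, 2, 1)


def conv1d_backward_params(
    x: np.ndarray, w_shape: tuple[int, int, int], dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients w.r.t. weights and bias. ``dout`` is (N, F, T)."""
    n, c, t = x.shape
    f, _, k = w_shape
    cols = _im2col(x, k)  # (N*T, C*k)
    dflat = dout.transpose(0, 2, 1).reshape(n * t, f)
    dw = (dflat.T @ cols).reshape(f, c, k)
    db = dflat.sum(axis=0)
    return dw, db


def conv1d_backward_input(w: np.ndarray, dout: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. the input: a same-padded conv with the transposed,
    time-flipped kernel."""
    wt = np.ascontiguousarray(w.transpose(1, 0, 2)[:, :, ::-1])
    f = wt.shape[0]
    return conv1d_forward(dout, wt, np.zeros(f, dtype=dout.dtype))


def relu(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    """Leaky rectifier.  The small negative slope keeps gradient flowing to
    early layers; with a hard rectifier the high end of the cyclic learning
    rate can kill most units of a small network irrecoverably."""
    return np.where(x > 0, x, slope * x)


def relu_backward(out: np.ndarray, dout: np.ndarray, slope: float = 0.01) -> np.ndarray:
    # leaky output preserves sign, so the mask can be read off the output
    return dout * np.where(out > 0, 1.0, slope).astype(dout.dtype)


def maxpool1d(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pool by factor p. Returns (pooled, argmax)."""
    n, c, t = x.shape
    if t % p:
        raise ValueError(f"length {t} not divisible by pool factor {p}")
    r = x.reshape(n, c, t // p, p)
    idx = r.argmax(axis=3)
    out = np.take_along_axis(r, idx[..., None], axis=3)[..., 0]
    return out, idx


def maxpool1d_backward(
    idx: np.ndarray, dout: np.ndarray, p: int
) -> np.ndarray:
    n, c, tp = dout.shape
    dx = np.zeros((n, c, tp, p), dtype=dout.dtype)
    np.put_along_axis(dx, idx[..., None], dout[..., None], axis=3)
    return dx.reshape(n, c, tp * p)


def upsample_nearest(x: np.ndarray, p: int) -> np.ndarray:
    return np.repeat(x, p, axis=2)


def upsample_nearest_backward(dout: np.ndarray, p: int) -> np.ndarray:
    n, c, t = dout.shape
    return dout.reshape(n, c, t // p, p).sum(axis=3)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross entropy on logits.

    Returns (mean loss, gradient w.r.t. z).
    """
    z = z.astype(np.float64, copy=False)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - y) / z.size
    return float(loss.mean()), dz.astype(np.float32)


class AdamState:
    """Adam optimizer state over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            params[k] -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
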