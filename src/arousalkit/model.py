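"""1-D U-net mapping a 3 x T PSG input at 50 Hz to a per-sample arousal
probability track of the same length.

Architecture
------------
A symmetric encoder/decoder with ``depth`` levels.  Each encoder level is a
double convolution (two same-padded convs with ReLU) followed by max
pooling by ``pool_factor``; each decoder level is nearest-neighbour
upsampling, concatenation with the skip from the matching encoder level,
and another double convolution.  With ``depth = 4`` this gives eight double
convolution blocks.  Filter counts start at ``base_filters`` and double per
level (capped).  A final 1x1 convolution with a sigmoid produces the
probability track, so output length always equals input length.

The network is implemented directly on NumPy primitives (see
``arousalkit._nn``); gradients are exact and checked numerically in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .preprocess import FS_MODEL, ProcessedInput

__all__ = ["UNetSpec", "UNet1D", "build_model", "predict"]


@dataclass(frozen=True)
class UNetSpec:
    """Shape hyperparameters of the U-net.

    Parameters
    ----------
    depth : encoder levels; the network has ``2 * depth`` double-conv blocks.
    base_filters : filters in the first encoder level, doubled per level.
    kernel : odd convolution kernel length in samples (21 at 50 Hz spans
        0.42 s, wide enough to see a spectral shift without dilation).
    pool_factor : pooling/upsampling factor per level; inputs must be
        divisible by ``pool_factor ** depth``.
    filters_cap : ceiling on per-level filter count.
    in_channels : input channels (EEG, EOG, EMG).
    """

    depth: int = 4
    base_filters: int = 16
    kernel: int = 21
    pool_factor: int = 4
    filters_cap: int = 256
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel length must be odd (same-length padding)")
        if self.pool_factor < 2:
            raise ValueError("pool_factor must be >= 2")

    @property
    def n_blocks(self) -> int:
        return 2 * self.depth

    @property
    def divisor(self) -> int:
        """Input length must be a multiple of this."""
        return self.pool_factor**self.depth

    def filters(self, level: int) -> int:
        return min(self.base_filters * 2**level, self.filters_cap)

    def param_shapes(self) -> dict[str, tuple[int, ...]]:
        """Name -> shape for every weight/bias, a pure function of the spec."""
        shapes: dict[str, tuple[int, ...]] = {}
        k = self.kernel
        c_in = self.in_channels
        for i in range(self.depth):
            f = self.filters(i)
            shapes[f"enc{i}a_w"] = (f, c_in, k)
            shapes[f"enc{i}a_b"] = (f,)
            shapes[f"enc{i}b_w"] = (f, f, k)
            shapes[f"enc{i}b_b"] = (f,)
            c_in = f
        up = self.filters(self.depth - 1)  # channels rising from the bottleneck
        for i in reversed(range(self.depth)):
            f = self.filters(i)
            shapes[f"dec{i}a_w"] = (f, up + f, k)
            shapes[f"dec{i}a_b"] = (f,)
            shapes[f"dec{i}b_w"] = (f, f, k)
            shapes[f"dec{i}b_b"] = (f,)
            up = f
        shapes["out_w"] = (1, self.filters(0), 1)
        shapes["out_b"] = (1,)
        return shapes

    def param_count(self) -> int:
        return sum(int(np.prod(s)) for s in self.param_shapes().values())


class UNet1D:
    """A trainable U-net instance: parameters + forward/backward passes."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for name, shape in spec.param_shapes().items():
            if name.endswith("_b"):
                self.params[name] = np.zeros(shape, dtype=np.float32)
            else:
                fan_in = int(np.prod(shape[1:]))
                std = math.sqrt(2.0 / fan_in)  # He init for ReLU stacks
                self.params[name] = rng.normal(0.0, std, size=shape).astype(np.float32)
        self._cache: dict[str, np.ndarray] = {}

    # -- forward -----------------------------------------------------------

    def _check_length(self, t: int) -> None:
        d = self.spec.divisor
        if t % d:
            raise ValueError(
                f"input length {t} not divisible by pool_factor**depth = {d}; "
                f"pad to a multiple of {d} (predict() does this automatically)"
            )

    def forward_logits(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """(N, 3, T) -> logits (N, T). Set ``keep_cache`` when training."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        self._check_length(x.shape[2])
        p = self.spec.pool_factor
        cache: dict[str, np.ndarray] = {"x": x}
        h = x
        for i in range(self.spec.depth):
            for half in "ab":
                pre = _nn.conv1d_forward(
                    h, self.params[f"enc{i}{half}_w"], self.params[f"enc{i}{half}_b"]
                )
                cache[f"enc{i}{half}_in"] = h
                h = _nn.relu(pre)
                cache[f"enc{i}{half}_out"] = h
            cache[f"skip{i}"] = h
            h, idx = _nn.maxpool1d(h, p)
            cache[f"pool{i}_idx"] = idx
        for i in reversed(range(self.spec.depth)):
            h = _nn.upsample_nearest(h, p)
            h = np.concatenate([h, cache[f"skip{i}"]], axis=1)
            for half in "ab":
                pre = _nn.conv1d_forward(
                    h, self.params[f"dec{i}{half}_w"], self.params[f"dec{i}{half}_b"]
                )
                cache[f"dec{i}{half}_in"] = h
                h = _nn.relu(pre)
                cache[f"dec{i}{half}_out"] = h
        z = _nn.conv1d_forward(h, self.params["out_w"], self.params["out_b"])
        cache["out_in"] = h
        if keep_cache:
            self._cache = cache
        return z[:, 0, :]

    def forward_proba(self, x: np.ndarray) -> np.ndarray:
        return _nn.sigmoid(self.forward_logits(x))

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients for every parameter given d(loss)/d(logits), (N, T).

        Requires the cache from the latest ``forward_logits(keep_cache=True)``.
        """
        if not self._cache:
            raise RuntimeError("run forward_logits(keep_cache=True) first")
        cache = self._cache
        spec = self.spec
        p = spec.pool_factor
        grads: dict[str, np.ndarray] = {}
        d = dlogits[:, None, :].astype(np.float32)

        dw, db = _nn.conv1d_backward_params(cache["out_in"], self.params["out_w"].shape, d)
        grads["out_w"], grads["out_b"] = dw, db
        d = _nn.conv1d_backward_input(self.params["out_w"], d)

        dskip: dict[int, np.ndarray] = {}
        for i in range(spec.depth):
            for half in "ba":
                d = _nn.relu_backward(cache[f"dec{i}{half}_out"], d)
                w = self.params[f"dec{i}{half}_w"]
                dw, db = _nn.conv1d_backward_params(cache[f"dec{i}{half}_in"], w.shape, d)
                grads[f"dec{i}{half}_w"], grads[f"dec{i}{half}_b"] = dw, db
                d = _nn.conv1d_backward_input(w, d)
            n_up = w.shape[1] - spec.filters(i)  # channels that came up
            dskip[i] = d[:, n_up:, :]
            d = _nn.upsample_nearest_backward(d[:, :n_up, :], p)
        for i in reversed(range(spec.depth)):
            d = _nn.maxpool1d_backward(cache[f"pool{i}_idx"], d, p)
            d = d + dskip[i]
            for half in "ba":
                d = _nn.relu_backward(cache[f"enc{i}{half}_out"], d)
                w = self.params[f"enc{i}{half}_w"]
                dw, db = _nn.conv1d_backward_params(cache[f"enc{i}{half}_in"], w.shape, d)
                grads[f"enc{i}{half}_w"], grads[f"enc{i}{half}_b"] = dw, db
                d = _nn.conv1d_backward_input(w, d)
        self._cache = {}
        return grads

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {f"spec_{k}": v for k, v in vars(self.spec).items()}
        np.savez(path, **self.params, **meta)

    @classmethod
    def load(cls, path: str | Path) -> "UNet1D":
        data = np.load(path)
        spec = UNetSpec(
            **{k[5:]: int(data[k]) for k in data.files if k.startswith("spec_")}
        )
        m = cls(spec)
        for name in m.params:
            m.params[name] = data[name].astype(np.float32)
        return m

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k] = v.copy()


def build_model(spec: UNetSpec, seed: int = 0) -> UNet1D:
    """Construct a U-net with deterministically seeded initial weights."""
    return UNet1D(spec, seed=seed)


def predict(
    model: UNet1D,
    x: ProcessedInput | np.ndarray,
    chunk_s: float = 4096 / FS_MODEL,
    fs: float = FS_MODEL,
) -> np.ndarray:
    """Full-record probability track via overlapping chunks.

    The record is cut into chunks of ``chunk_s`` seconds with 50 % overlap;
    each chunk's central half is kept (the first and last chunks also keep
    their outer edges), so every output sample comes from a chunk in which
    it is far from a padded boundary.  Output length always equals input
    length.
    """
    arr = x.x if isinstance(x, ProcessedInput) else np.asarray(x, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError("expected a (channels, T) array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in model input")
    t = arr.shape[1]
    chunk = int(round(chunk_s * fs))
    d = model.spec.divisor
    chunk = max(d, (chunk // d) * d)
    stride = chunk // 2
    t_pad = max(chunk, int(np.ceil(t / stride)) * stride)
    if t_pad > t:
        arr = np.pad(arr, ((0, 0), (0, t_pad - t)))
    out = np.zeros(t_pad, dtype=np.float32)
    q = chunk // 4
    starts = list(range(0, t_pad - chunk + 1, stride))
    for j, s in enumerate(starts):
        pr = model.forward_proba(arr[None, :, s : s + chunk])[0]
        lo = 0 if j == 0 else q
        hi = chunk if j == len(starts) - 1 else 3 * q
        out[s + lo : s + hi] = pr[lo:hi]
    return out[:t]
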