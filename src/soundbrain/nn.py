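"""Minimal NumPy layers for 1-D convolutional audio models.

Implements exactly the operators the backbone and encoding head need —
strided 1-D convolution, batch normalisation, ReLU, non-overlapping max
pooling — each with an explicit backward pass so models can be trained
end-to-end with a first-order optimiser.  Arrays are float32 throughout;
layout is (batch, channels, length).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "he_uniform",
]

# frames processed per im2col chunk; bounds peak memory of the unfolded view
_CHUNK = 1 << 18


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "decay")

    def __init__(self, data: np.ndarray, decay: bool = True):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        # whether weight decay applies (kernels yes, biases/affine no)
        self.decay = decay

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Fan-in-scaled uniform initialisation (He et al. style, gain sqrt(2))."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv1d:
    """Strided 1-D convolution (cross-correlation) with symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, *,
                 rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            he_uniform(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels), decay=False)
        self._x_padded: np.ndarray | None = None

    def out_length(self, length: int) -> int:
        n = (length + 2 * self.padding - self.kernel_size) // self.stride + 1
        return max(n, 0)

    def params(self) -> dict[str, Parameter]:
        return {"weight": self.weight, "bias": self.bias}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        l_out = self.out_length(length)
        if l_out == 0:
            return np.zeros((b, self.out_channels, 0), dtype=np.float32)
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        y = np.empty((b, self.out_channels, l_out), dtype=np.float32)
        k, s = self.kernel_size, self.stride
        w2 = self.weight.data.reshape(self.out_channels, -1)  # (Cout, Cin*K)
        for lo in range(0, l_out, _CHUNK):
            hi = min(lo + _CHUNK, l_out)
            seg = xp[:, :, lo * s: (hi - 1) * s + k]
            win = sliding_window_view(seg, k, axis=2)[:, :, ::s, :]
            # (B, Cin, n, K) -> (B, n, Cin*K)
            col = win.transpose(0, 2, 1, 3).reshape(b, hi - lo, -1)
            y[:, :, lo:hi] = (col @ w2.T).transpose(0, 2, 1)
        y += self.bias.data[None, :, None]
        if train:
            self._x_padded = xp
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._x_padded is None:
            raise RuntimeError("backward before forward(train=True)")
        xp = self._x_padded
        b, _, lp = xp.shape
        l_out = gy.shape[2]
        k, s, p = self.kernel_size, self.stride, self.padding
        self.bias.grad += gy.sum(axis=(0, 2))
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]  # (B,Cin,n,K)
        self.weight.grad += np.einsum("bon,bcnk->ock", gy, win, optimize=True)
        # scatter grad back onto the padded input, one kernel tap at a time
        gxp = np.zeros_like(xp)
        gw = np.einsum("bon,ock->bcnk", gy, self.weight.data, optimize=True)
        for j in range(k):
            gxp[:, :, j: j + l_out * s: s] += gw[:, :, :, j]
        self._x_padded = None
        return gxp[:, :, p: lp - p] if p else gxp


class BatchNorm1d:
    """Per-channel normalisation by *stored* statistics plus a trainable
    affine (gamma, beta).

    The stored mean/variance come from the weight archive (or the (0, 1)
    initialisation) and are never updated from data, so the layer is a pure
    function of its input in both frozen and fine-tuning regimes — the
    standard small-batch fine-tuning treatment of batch norm.  Gradients
    flow through the affine transform.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), decay=False)
        self.beta = Parameter(np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> dict[str, Parameter]:
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None]) * inv[None, :, None]
        y = self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]
        if train:
            self._cache = (xhat.astype(np.float32), inv.astype(np.float32))
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward before forward(train=True)")
        xhat, inv = self._cache
        self.beta.grad += gy.sum(axis=(0, 2))
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2))
        gx = gy * (self.gamma.data * inv)[None, :, None]
        self._cache = None
        return gx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> dict[str, Parameter]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward before forward(train=True)")
        gx = gy * self._mask
        self._mask = None
        return gx


class MaxPool1d:
    """Non-overlapping temporal max pooling (kernel == stride); trailing
    frames that do not fill a window are dropped."""

    def __init__(self, pool: int):
        self.pool = pool
        self._cache = None

    def out_length(self, length: int) -> int:
        return length // self.pool

    def params(self) -> dict[str, Parameter]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, length = x.shape
        n = length // self.pool
        xr = x[:, :, : n * self.pool].reshape(b, c, n, self.pool)
        y = xr.max(axis=3)
        if train:
            self._cache = (xr.argmax(axis=3), x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward before forward(train=True)")
        amax, shape = self._cache
        b, c, length = shape
        n = gy.shape[2]
        gx = np.zeros((b, c, n, self.pool), dtype=np.float32)
        bi, ci, ni = np.ogrid[:b, :c, :n]
        gx[bi, ci, ni, amax] = gy
        gx = gx.reshape(b, c, n * self.pool)
        if n * self.pool < length:
            gx = np.pad(gx, ((0, 0), (0, 0), (0, length - n * self.pool)))
        self._cache = None
        return gx
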