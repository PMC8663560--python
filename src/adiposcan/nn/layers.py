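"""Minimal NumPy layers with hand-derived backward passes.

Everything operates on float32 arrays shaped ``(N, C, D, H, W)`` for
volumetric data or ``(N, F)`` for flat features.  Each layer caches what its
backward pass needs during ``forward`` and releases it after ``backward``.
The backward pass propagates gradients all the way to the input volume,
which is what the gradients-x-input attribution consumes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "BatchNorm1d",
    "ELU",
    "MaxPool3d",
    "AvgPool3d",
    "Flatten",
    "Linear",
    "Dropout",
]


class Layer:
    """Base class: parameterised layers expose ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) -> (N, D'*H'*W', C*k^3) patch matrix, stride 1."""
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    n, c, d, h, w = win.shape[:5]
    # (N, D', H', W', C, k, k, k) then flatten patches
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, d * h * w, c * k**3)
    return np.ascontiguousarray(cols)


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' zero padding, via im2col + matmul.

    The input gradient is computed as a convolution of the (padded) output
    gradient with the spatially flipped, channel-transposed kernel, so the
    whole backward pass stays in matmul land.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel**3
        # He et al. initialization for ELU/ReLU-family activations
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel, kernel))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_ch, dtype=np.float32)}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, p = self.k, self.k // 2
        self._shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = _im2col(xp, k)
        self._cols = cols
        wmat = self.params["W"].reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.params["b"]
        n, _, d, h, w = x.shape
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, d, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, d, h, w = self._shape
        k, p = self.k, self.k // 2
        dmat = dout.reshape(n, self.out_ch, d * h * w).transpose(0, 2, 1)  # (N, V, out)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        dw = np.einsum("nvo,nvi->oi", dmat, self._cols, optimize=True)
        self.grads["W"] = dw.reshape(self.params["W"].shape).astype(np.float32)
        self.grads["b"] = dout.sum(axis=(0, 2, 3, 4)).astype(np.float32)
        del self._cols
        # dx: full correlation of dout with flipped kernels
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        wflip = self.params["W"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        cols = _im2col(dp, k)
        dx = cols @ wflip.reshape(self.in_ch, -1).T
        return dx.transpose(0, 2, 1).reshape(n, self.in_ch, d, h, w).astype(np.float32)


class _BatchNorm(Layer):
    """Shared batchnorm core; subclasses define the reduction axes."""

    axes: tuple[int, ...]

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(ch, dtype=np.float32), "beta": np.zeros(ch, dtype=np.float32)}
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def _bc(self, v: np.ndarray, ndim: int) -> np.ndarray:
        shape = [1] * ndim
        shape[1] = -1
        return v.reshape(shape)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        nd = x.ndim
        if train:
            mean = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mean, nd)) * self._bc(inv, nd)
        self._cache = (xhat, inv, train)
        return (self._bc(self.params["gamma"], nd) * xhat + self._bc(self.params["beta"], nd)).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        del self._cache
        nd = dout.ndim
        self.grads["gamma"] = (dout * xhat).sum(axis=self.axes).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=self.axes).astype(np.float32)
        g = self._bc(self.params["gamma"] * inv, nd)
        if not train:
            return (dout * g).astype(np.float32)
        m = float(np.prod([dout.shape[a] for a in self.axes]))
        dsum = self._bc(dout.sum(axis=self.axes), nd)
        dxhat_sum = self._bc((dout * xhat).sum(axis=self.axes), nd)
        return (g * (dout - dsum / m - xhat * dxhat_sum / m)).astype(np.float32)


class BatchNorm3d(_BatchNorm):
    axes = (0, 2, 3, 4)


class BatchNorm1d(_BatchNorm):
    axes = (0,)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.where(x > 0, x, self.alpha * np.expm1(x)).astype(np.float32)
        self._cache = (x > 0, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        pos, out = self._cache
        del self._cache
        return (dout * np.where(pos, 1.0, out + self.alpha)).astype(np.float32)


def _pad_to_even(x: np.ndarray, fill: float) -> np.ndarray:
    pads = [(0, 0), (0, 0)] + [(0, s % 2) for s in x.shape[2:]]
    if any(p[1] for p in pads):
        return np.pad(x, pads, constant_values=fill)
    return x


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2; odd dims padded with -inf."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        xp = _pad_to_even(x, -np.inf)
        n, c, d, h, w = xp.shape
        r = xp.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5, 7))
        self._mask = r == out[:, :, :, None, :, None, :, None]
        self._padded_shape = xp.shape
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._mask
        # distribute equally among ties so the gradient sums correctly
        counts = mask.sum(axis=(3, 5, 7))
        g = dout / counts
        dr = mask * g[:, :, :, None, :, None, :, None]
        n, c, d, h, w = self._padded_shape
        dx = dr.reshape(n, c, d, h, w)
        sl = tuple([slice(None), slice(None)] + [slice(0, s) for s in self._shape[2:]])
        del self._mask
        return dx[sl].astype(np.float32)


class AvgPool3d(Layer):
    """2x2x2 average pooling, stride 2; odd dims zero-padded (count includes pad)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        xp = _pad_to_even(x, 0.0)
        n, c, d, h, w = xp.shape
        self._padded_shape = xp.shape
        r = xp.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        return r.mean(axis=(3, 5, 7)).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._padded_shape
        g = np.broadcast_to(
            (dout / 8.0)[:, :, :, None, :, None, :, None],
            (n, c, d // 2, 2, h // 2, 2, w // 2, 2),
        )
        dx = g.reshape(n, c, d, h, w)
        sl = tuple([slice(None), slice(None)] + [slice(0, s) for s in self._shape[2:]])
        return np.ascontiguousarray(dx[sl], dtype=np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(out_f, in_f))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_f, dtype=np.float32)}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = (dout.T @ self._x).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        del self._x
        return (dout @ self.params["W"]).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Needs an rng per forward."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask
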