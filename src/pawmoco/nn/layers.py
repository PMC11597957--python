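"""Core layers: convolution (im2col), linear, ReLU, pooling, split batch norm.

Split batch normalization is the one non-standard layer: in training mode the
batch is partitioned into ``num_splits`` contiguous groups, each normalized
with its own statistics while sharing the affine parameters, emulating the
per-device statistics of multi-GPU training on a single device.  Running
statistics are aggregated as the arithmetic mean over splits and drive the
eval-mode path exactly like ordinary batch norm; ``num_splits=1`` *is*
ordinary batch norm.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter, grad_enabled


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_uniform_init(rng, (out_channels, in_channels,
                                                    kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32),
                              adapt=False, decay=False) if bias else None
        self._cache = None

    def _im2col(self, xp: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
        k, s = self.kernel_size, self.stride
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (B, C, out_h, out_w, k, k) -> (B*out_h*out_w, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(xp.shape[0] * out_h * out_w, -1)
        return np.ascontiguousarray(cols)

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        batch, _, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out_h = (h + 2 * p - k) // s + 1
        out_w = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, out_h, out_w)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        out = out.reshape(batch, out_h, out_w, self.out_channels).transpose(0, 3, 1, 2)
        if self.training and grad_enabled():
            self._cache = (cols, x.shape, xp.shape, out_h, out_w)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        cols, x_shape, xp_shape, out_h, out_w = self._cache
        self._cache = None
        batch = x_shape[0]
        k, s, p = self.kernel_size, self.stride, self.padding
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        self.weight.grad += (dmat.T @ cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dmat.sum(axis=0)
        dcols = dmat @ self.weight.data.reshape(self.out_channels, -1)
        dcols = dcols.reshape(batch, out_h, out_w, self.in_channels, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + out_h * s:s, j:j + out_w * s:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_uniform_init(rng, (out_features, in_features), in_features))
        self.bias = Parameter(_uniform_init(rng, (out_features,), in_features),
                              adapt=False, decay=False) if bias else None
        self._cache = None

    def forward(self, x):
        x = np.asarray(x, dtype=np.float32)
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        if self.training and grad_enabled():
            self._cache = x
        return out

    def backward(self, dout):
        x = self._cache
        self._cache = None
        self.weight.grad += dout.T @ x
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        out = np.maximum(x, 0.0)
        if self.training and grad_enabled():
            self._mask = x > 0
        return out

    def backward(self, dout):
        mask = self._mask
        self._mask = None
        return dout * mask


class BatchNorm2d(Module):
    """(Split) batch normalization over B×C×H×W feature maps.

    ``num_splits`` contiguous groups each get their own batch statistics in
    training mode; affine parameters are shared.  Running statistics are the
    mean over split statistics.  Eval mode normalizes with running statistics.
    """

    buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, num_splits: int = 1,
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        if num_splits < 1:
            raise ValueError("num_splits must be >= 1")
        self.num_features = num_features
        self.num_splits = num_splits
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_features, dtype=np.float32),
                                adapt=False, decay=False)
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32),
                              adapt=False, decay=False)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._cache = None

    def forward(self, x):
        x = np.asarray(x, dtype=np.float32)
        batch, c, h, w = x.shape
        g = self.weight.data[None, :, None, None]
        b = self.bias.data[None, :, None, None]
        if not self.training:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * inv_std[None, :, None, None]
            if grad_enabled():
                self._cache = ("eval", inv_std)
            return g * xhat + b
        s = self.num_splits
        if batch % s != 0:
            raise ValueError(
                f"batch size {batch} not divisible by num_splits {s} in training mode")
        xs = x.reshape(s, batch // s, c, h, w)
        mean = xs.mean(axis=(1, 3, 4))          # (S, C)
        var = xs.var(axis=(1, 3, 4))            # biased, (S, C)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xs - mean[:, None, :, None, None]) * inv_std[:, None, :, None, None]
        m = self.momentum
        self.running_mean[...] = (1 - m) * self.running_mean + m * mean.mean(axis=0)
        self.running_var[...] = (1 - m) * self.running_var + m * var.mean(axis=0)
        if grad_enabled():
            self._cache = ("train", xhat, inv_std)
        return g * xhat.reshape(batch, c, h, w) + b

    def backward(self, dout):
        cache = self._cache
        self._cache = None
        batch, c, h, w = dout.shape
        if cache[0] == "eval":
            # eval-mode backward serves frozen-feature use: input gradients
            # only, no affine-parameter gradients.
            _, inv_std = cache
            return dout * (self.weight.data * inv_std)[None, :, None, None]
        _, xhat, inv_std = cache
        s = self.num_splits
        ds = dout.reshape(s, batch // s, c, h, w)
        self.weight.grad += (ds * xhat).sum(axis=(0, 1, 3, 4))
        self.bias.grad += ds.sum(axis=(0, 1, 3, 4))
        dxhat = ds * self.weight.data[None, None, :, None, None]
        mean_d = dxhat.mean(axis=(1, 3, 4), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(1, 3, 4), keepdims=True)
        dxs = inv_std[:, None, :, None, None] * (dxhat - mean_d - xhat * mean_dx)
        return dxs.reshape(batch, c, h, w).astype(np.float32)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x):
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(*win.shape[:4], k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if self.training and grad_enabled():
            self._cache = (idx, x.shape, xp.shape, out.shape)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        idx, x_shape, xp_shape, out_shape = self._cache
        self._cache = None
        k, s, p = self.kernel_size, self.stride, self.padding
        batch, c, oh, ow = out_shape
        dxp = np.zeros(xp_shape, dtype=np.float32)
        ki, kj = np.divmod(idx, k)
        bi, ci, oi, oj = np.indices(out_shape)
        np.add.at(dxp, (bi, ci, oi * s + ki, oj * s + kj), dout)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Module):
    """Adaptive average pooling to 1×1 followed by flattening to (B, C)."""

    def __init__(self):
        super().__init__()
        self._hw = None

    def forward(self, x):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        h, w = self._hw
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               (*dout.shape, h, w)).astype(np.float32)


class L2Normalize(Module):
    """Row-wise projection onto the unit sphere (cosine-similarity geometry)."""

    def __init__(self, eps: float = 1e-12):
        super().__init__()
        self.eps = eps
        self._cache = None

    def forward(self, x):
        norm = np.maximum(np.linalg.norm(x, axis=1, keepdims=True), self.eps)
        y = x / norm
        if self.training and grad_enabled():
            self._cache = (y, norm)
        return y

    def backward(self, dout):
        y, norm = self._cache
        self._cache = None
        return (dout - y * (y * dout).sum(axis=1, keepdims=True)) / norm
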