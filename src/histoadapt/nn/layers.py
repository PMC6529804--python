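"""Minimal neural-network layers with explicit forward/backward passes.

All layers operate on float32 numpy arrays in NCHW layout (images) or NF
layout (feature vectors).  ``forward`` caches whatever ``backward`` needs;
``backward`` overwrites ``self.grads`` and returns the gradient with respect
to the layer input.  Calling :meth:`Layer.zero_grad` (or a fresh forward/
backward cycle) discards stale gradients, so optimizers can safely skip
parameters whose gradient is ``None``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    """Base class: parameter dict, gradient dict, forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray | None] = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = None


def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    return cols, ho, wo


def _col2im(gcols, x_shape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    gx = np.zeros((n, c, hp, wp), dtype=gcols.dtype)
    g = gcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad : pad + h, pad : pad + w]
    return gx


class Conv2d(Layer):
    def __init__(self, c_in, c_out, kernel, stride=1, pad=None, rng=None):
        super().__init__()
        if pad is None:
            pad = kernel // 2
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        self.params["W"] = he_normal(rng, (c_out, fan_in), fan_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.zero_grad()
        self._cache = None

    def out_size(self, size):
        return (size + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x, train=False, rng=None):
        cols, ho, wo = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        y = cols @ self.params["W"].T + self.params["b"]
        n = x.shape[0]
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gy):
        cols, x_shape, ho, wo = self._cache
        gyc = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.grads["W"] = gyc.T @ cols
        self.grads["b"] = gyc.sum(axis=0)
        gcols = gyc @ self.params["W"]
        return _col2im(
            gcols, x_shape, self.kernel, self.kernel, self.stride, self.pad, ho, wo
        )


class BatchNorm(Layer):
    """Batch normalization over N (2-d input) or N,H,W (4-d input)."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        # training-mode forwards update the running statistics unless a
        # caller (e.g. an auxiliary branch) temporarily turns this off
        self.update_running = True
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.zero_grad()
        self._cache = None

    @staticmethod
    def _bshape(x):
        return (1, -1, 1, 1) if x.ndim == 4 else (1, -1)

    def forward(self, x, train=False, rng=None):
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        bs = self._bshape(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self.update_running:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mu
                self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(bs)) * ivar.reshape(bs)
        y = self.params["gamma"].reshape(bs) * xhat + self.params["beta"].reshape(bs)
        count = x.size // self.channels
        self._cache = (xhat, ivar, axes, bs, count, train)
        return y.astype(x.dtype, copy=False)

    def backward(self, gy):
        xhat, ivar, axes, bs, m, trained = self._cache
        self.grads["gamma"] = (gy * xhat).sum(axis=axes)
        self.grads["beta"] = gy.sum(axis=axes)
        gscale = (self.params["gamma"] * ivar).reshape(bs)
        if not trained:
            return gy * gscale
        gb = self.grads["beta"].reshape(bs)
        gg = self.grads["gamma"].reshape(bs)
        return (gscale / m) * (m * gy - gb - xhat * gg)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Dropout(Layer):
    """Inverted dropout; active only in training mode with an rng supplied."""

    def __init__(self, rate=0.5):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = he_normal(rng, (n_out, n_in), n_in)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)
        self.zero_grad()

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, gy):
        self.grads["W"] = gy.T @ self._x
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"]


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None], self._shape) / (h * w)


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def param_layers(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.param_layers())
            elif layer.params:
                out.append(layer)
        return out


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
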