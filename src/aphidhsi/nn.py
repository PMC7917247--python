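"""A small reverse-mode neural-network engine on NumPy.

Implements exactly the operators the residual classifiers of this package
need: N-dimensional convolution (1-D/2-D/3-D), batch normalization, ReLU,
max pooling, residual addition with identity / zero-padded / 1x1-projection
shortcuts, global average pooling, dense layers and softmax cross-entropy.
Every layer caches what its backward pass needs, and the backward pass
propagates gradients all the way to the *input* tensor, which is what
gradient-saliency attribution differentiates.

Convolutions run as im2col: a single strided-window copy followed by one
batched channel-mixing matmul, which keeps the arithmetic in BLAS. Large
column matrices (3-D cubes) are rebuilt in the backward pass instead of
cached, bounding peak memory. Parameters and activations are float32; the
loss is accumulated in float64. Training is reproducible for a fixed seed
on a given BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32
_CACHE_LIMIT_BYTES = 96 * 2 ** 20  # above this, rebuild im2col columns in backward


def _tup(x, nd):
    return tuple(x) if isinstance(x, (tuple, list)) else (x,) * nd


def _dt(x) -> np.dtype:
    """Compute dtype: float64 inputs keep full precision (saliency probes),
    everything else runs in float32."""
    return np.float64 if x.dtype == np.float64 else DTYPE


class Layer:
    """Base class: ``forward(x, train)`` caches, ``backward(dout)`` returns dx."""

    def params(self) -> list[dict]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def xavier_uniform(shape, fan_in, fan_out, rng) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _windows(xp: np.ndarray, kernel, stride, nd):
    """Strided view (N, C, *out, *kernel) of the padded input."""
    w = sliding_window_view(xp, kernel, axis=tuple(range(2, 2 + nd)))
    sub = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)
    return w[sub]


class ConvNd(Layer):
    """N-dimensional convolution (cross-correlation) with zero padding."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, *, nd, rng):
        self.nd = nd
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = _tup(kernel, nd)
        self.stride = _tup(stride, nd)
        self.padding = _tup(padding, nd)
        fan_in = in_ch * int(np.prod(self.kernel))
        fan_out = out_ch * int(np.prod(self.kernel))
        self.w = xavier_uniform((out_ch, in_ch) + self.kernel, fan_in, fan_out, rng)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [{"value": self.w, "grad": self.dw}, {"value": self.b, "grad": self.db}]

    def _cols(self, xp):
        """(N, C*prod(kernel), P) column matrix; axes ordered (C, *K, P)."""
        win = _windows(xp, self.kernel, self.stride, self.nd)
        n = win.shape[0]
        out_spatial = win.shape[2:2 + self.nd]
        # (N, C, *out, *K) -> (N, C, *K, *out) -> (N, C*K, P)
        perm = (0, 1) + tuple(range(2 + self.nd, 2 + 2 * self.nd)) \
            + tuple(range(2, 2 + self.nd))
        cols = np.ascontiguousarray(win.transpose(perm)).reshape(
            n, self.in_ch * int(np.prod(self.kernel)), int(np.prod(out_spatial)))
        return cols, out_spatial

    def forward(self, x, train):
        nd = self.nd
        if x.ndim != nd + 2:
            raise ValueError(f"expected {nd + 2}-D input (N, C, spatial), got {x.ndim}-D")
        for d in range(nd):
            if x.shape[2 + d] + 2 * self.padding[d] < self.kernel[d]:
                raise ValueError("input smaller than the convolution kernel")
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        xp = np.pad(np.asarray(x, dtype=_dt(np.asarray(x))), pad)
        cols, out_spatial = self._cols(xp)
        self._xp = xp
        self._out_spatial = out_spatial
        self._cached_cols = cols if cols.nbytes <= _CACHE_LIMIT_BYTES else None
        wflat = self.w.reshape(self.out_ch, -1)
        out = wflat @ cols                              # (N, Cout, P)
        out += self.b[None, :, None]
        return out.reshape((x.shape[0], self.out_ch) + out_spatial)

    def backward(self, dout):
        xp, out_spatial = self._xp, self._out_spatial
        n = dout.shape[0]
        prod_out = int(np.prod(out_spatial))
        d2 = np.asarray(dout, dtype=xp.dtype).reshape(n, self.out_ch, prod_out)
        cols = self._cached_cols
        if cols is None:
            cols, _ = self._cols(xp)
        self.db[...] = d2.sum(axis=(0, 2))
        # dW = sum_n dout_n @ cols_n^T
        self.dw[...] = np.einsum("ncp,nkp->ck", d2, cols,
                                 optimize=True).reshape(self.dw.shape)
        wflat = self.w.reshape(self.out_ch, -1)
        dcols = (wflat.T @ d2).reshape((n, self.in_ch) + self.kernel + (prod_out,))
        dxp = np.zeros_like(xp)
        for offset in np.ndindex(*self.kernel):
            sl = (slice(None), slice(None)) + tuple(
                slice(offset[d], offset[d] + out_spatial[d] * self.stride[d],
                      self.stride[d]) for d in range(self.nd))
            dxp[sl] += dcols[(slice(None), slice(None)) + offset].reshape(
                (n, self.in_ch) + out_spatial)
        core = tuple(slice(p, dxp.shape[2 + d] - p) if p else slice(None)
                     for d, p in enumerate(self.padding))
        return dxp[(slice(None), slice(None)) + core]


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros(channels, dtype=DTYPE)
        self.dbeta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [{"value": self.gamma, "grad": self.dgamma},
                {"value": self.beta, "grad": self.dbeta}]

    def forward(self, x, train):
        x = np.asarray(x, dtype=_dt(np.asarray(x)))
        axes = (0,) + tuple(range(2, x.ndim))
        shp = (1, -1) + (1,) * (x.ndim - 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var.astype(np.float64) + self.eps)).astype(x.dtype)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._cache = (xhat, inv, axes, shp, train, x.shape)
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, dout):
        xhat, inv, axes, shp, train, xshape = self._cache
        dout = np.asarray(dout, dtype=xhat.dtype)
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        g = self.gamma.reshape(shp)
        if not train:
            return dout * g * inv.reshape(shp)
        m = xhat.dtype.type(np.prod([xshape[a] for a in axes]))
        dxhat = dout * g
        return (inv.reshape(shp) / m) * (
            m * dxhat
            - dxhat.sum(axis=axes).reshape(shp)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shp))


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPoolNd(Layer):
    """Max pooling, default kernel 3 / stride 2 / padding 1 (ResNet style)."""

    def __init__(self, kernel=3, stride=2, padding=1, *, nd):
        self.nd = nd
        self.kernel = _tup(kernel, nd)
        self.stride = _tup(stride, nd)
        self.padding = _tup(padding, nd)

    def forward(self, x, train):
        nd = self.nd
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        dt = _dt(np.asarray(x))
        xp = np.pad(np.asarray(x, dtype=dt), pad, constant_values=dt(-np.inf))
        win = _windows(xp, self.kernel, self.stride, nd)
        out_spatial = win.shape[2:2 + nd]
        flat = np.ascontiguousarray(win).reshape(win.shape[:2 + nd] + (-1,))
        arg = flat.argmax(axis=-1).astype(np.int16)
        out = np.take_along_axis(flat, arg[..., None].astype(np.intp), -1)[..., 0]
        self._cache = (xp.shape, arg, out_spatial)
        return out

    def backward(self, dout):
        xp_shape, arg, out_spatial = self._cache
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        for k, offset in enumerate(np.ndindex(*self.kernel)):
            sl = (slice(None), slice(None)) + tuple(
                slice(offset[d], offset[d] + out_spatial[d] * self.stride[d],
                      self.stride[d]) for d in range(self.nd))
            dxp[sl] += dout * (arg == k)
        core = tuple(slice(p, xp_shape[2 + d] - p) if p else slice(None)
                     for d, p in enumerate(self.padding))
        return dxp[(slice(None), slice(None)) + core]


class GlobalAvgPool(Layer):
    """Mean over all spatial axes -> (N, C)."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)), dtype=_dt(np.asarray(x)))

    def backward(self, dout):
        shape = self._shape
        m = float(np.prod(shape[2:]))
        return np.broadcast_to(
            np.asarray(dout).reshape(dout.shape + (1,) * (len(shape) - 2)),
            shape) / m


class Dense(Layer):
    def __init__(self, in_features, out_features, rng):
        self.w = xavier_uniform((out_features, in_features), in_features,
                                out_features, rng)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [{"value": self.w, "grad": self.dw}, {"value": self.b, "grad": self.db}]

    def forward(self, x, train):
        self._x = np.asarray(x, dtype=_dt(np.asarray(x)))
        return self._x @ self.w.T + self.b

    def backward(self, dout):
        dout = np.asarray(dout, dtype=self._x.dtype)
        self.dw[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ChannelPad(Layer):
    """Zero-pad the channel axis (parameter-free widening shortcut)."""

    def __init__(self, extra_channels):
        self.extra = extra_channels

    def forward(self, x, train):
        pad = [(0, 0), (0, self.extra)] + [(0, 0)] * (x.ndim - 2)
        return np.pad(x, pad)

    def backward(self, dout):
        return dout[:, : dout.shape[1] - self.extra]


class Identity(Layer):
    def forward(self, x, train):
        return x

    def backward(self, dout):
        return dout


class SpatialSubsample(Layer):
    """Stride-s spatial subsampling (used inside zero-pad shortcuts)."""

    def __init__(self, stride, nd):
        self.stride = _tup(stride, nd)
        self.nd = nd

    def forward(self, x, train):
        self._shape = x.shape
        sl = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in self.stride)
        return x[sl]

    def backward(self, dout):
        dx = np.zeros(self._shape, dtype=np.asarray(dout).dtype)
        sl = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in self.stride)
        dx[sl] = dout
        return dx


class ResidualBlock(Layer):
    """Two convolutions with batch norm plus a shortcut; ReLU on the sum.

    ``shortcut`` is one of ``"identity"``, ``"pad"`` (zero-padded channels,
    parameter-free) or ``"conv"`` (1x1 projection with batch norm).
    """

    def __init__(self, in_ch, out_ch, *, nd, rng, kernel=3, stride=1,
                 shortcut="identity"):
        k = _tup(kernel, nd)
        p = tuple(kk // 2 for kk in k)
        self.main = Sequential([
            ConvNd(in_ch, out_ch, k, stride=stride, padding=p, nd=nd, rng=rng),
            BatchNorm(out_ch),
            ReLU(),
            ConvNd(out_ch, out_ch, k, stride=1, padding=p, nd=nd, rng=rng),
            BatchNorm(out_ch),
        ])
        stride_t = _tup(stride, nd)
        if shortcut == "conv":
            self.shortcut = Sequential([
                ConvNd(in_ch, out_ch, _tup(1, nd), stride=stride, padding=0,
                       nd=nd, rng=rng),
                BatchNorm(out_ch),
            ])
        elif shortcut == "pad":
            layers = []
            if any(s != 1 for s in stride_t):
                layers.append(SpatialSubsample(stride, nd))
            if out_ch != in_ch:
                layers.append(ChannelPad(out_ch - in_ch))
            self.shortcut = Sequential(layers) if layers else Identity()
        elif shortcut == "identity":
            if out_ch != in_ch or any(s != 1 for s in stride_t):
                raise ValueError("identity shortcut requires matching shapes")
            self.shortcut = Identity()
        else:
            raise ValueError(f"unknown shortcut kind {shortcut!r}")
        self.relu = ReLU()

    def params(self):
        return self.main.params() + self.shortcut.params()

    def forward(self, x, train):
        y = self.main.forward(x, train) + self.shortcut.forward(x, train)
        return self.relu.forward(y, train)

    def backward(self, dout):
        dy = self.relu.backward(dout)
        return self.main.backward(dy) + self.shortcut.backward(dy)


# ---------------------------------------------------------------------------
# loss and parameter helpers
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy; returns ``(loss, dlogits)``."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(DTYPE)


def get_state(layer: Layer) -> list[np.ndarray]:
    """Copies of all learnable values plus batch-norm running statistics."""
    state = [p["value"].copy() for p in layer.params()]
    state += [bn.copy() for bn in _running_stats(layer)]
    return state


def set_state(layer: Layer, state: list[np.ndarray]) -> None:
    params = layer.params()
    for p, v in zip(params, state[: len(params)]):
        p["value"][...] = v
    for bn, v in zip(_running_stats(layer), state[len(params):]):
        bn[...] = v


def _running_stats(layer: Layer) -> list[np.ndarray]:
    out = []
    if isinstance(layer, BatchNorm):
        out += [layer.running_mean, layer.running_var]
    for sub in getattr(layer, "layers", []):
        out += _running_stats(sub)
    for attr in ("main", "shortcut", "relu"):
        sub = getattr(layer, attr, None)
        if isinstance(sub, Layer):
            out += _running_stats(sub)
    return out


def count_parameters(layer: Layer) -> int:
    return int(sum(p["value"].size for p in layer.params()))
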