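"""Minimal NHWC layer library with analytic backprop.

All tensors are float32 ``numpy`` arrays laid out ``(N, H, W, C)`` (dense
layers use ``(N, C)``).  Every layer caches what its backward pass needs
during ``forward`` and exposes ``params`` / ``grads`` dictionaries so an
optimizer can update them in place.  Convolutions use "same" padding with
the asymmetric (end-heavy) scheme common in mobile architectures, so that
an input of size ``s * k`` maps to exactly ``k`` under stride ``s``.

Weight fake-quantization for quantization-aware training is built into the
parametric layers: when ``qat`` is set, the forward pass rounds the weights
to a symmetric signed 8-bit grid and de-quantizes them, while the backward
pass passes gradients straight through to the float master weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .quant import fake_quantize_symmetric

F32 = np.float32


def _same_pad(in_size: int, k: int, stride: int) -> tuple[int, int, int]:
    out = -(-in_size // stride)
    total = max((out - 1) * stride + k - in_size, 0)
    beg = total // 2
    return out, beg, total - beg


class Layer:
    """Base class: parametric state plus cached-input backward."""

    kind = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.qat = False

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _weight(self, name: str) -> np.ndarray:
        w = self.params[name]
        if self.qat:
            return fake_quantize_symmetric(w)
        return w


class Conv2D(Layer):
    """k x k convolution, NHWC, same padding, optional bias."""

    kind = "conv"

    def __init__(self, c_in, c_out, kernel=3, stride=1, use_bias=False, rng=None):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * c_in
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, c_in, c_out)
        ).astype(F32)
        self.use_bias = use_bias
        if use_bias:
            self.params["b"] = np.zeros(c_out, F32)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        k, s = self.k, self.stride
        ho, pt, pb = _same_pad(h, k, s)
        wo, pl, pr = _same_pad(w, k, s)
        if k == 1 and s == 1:
            self._cache = (x, None, (n, h, w))
            y = x.reshape(-1, c) @ self._weight("w").reshape(c, self.c_out)
            y = y.reshape(n, h, w, self.c_out)
        else:
            xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
            # (N, H', W', C, k, k) -> strided to output grid
            win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
            cols = np.ascontiguousarray(np.moveaxis(win, 3, 5)).reshape(
                n * ho * wo, k * k * c
            )
            self._cache = (cols, (xp.shape, pt, pl, ho, wo), (n, h, w))
            y = (cols @ self._weight("w").reshape(k * k * c, self.c_out)).reshape(
                n, ho, wo, self.c_out
            )
        if self.use_bias:
            y = y + self.params["b"]
        return y.astype(F32, copy=False)

    def backward(self, gy):
        k, s, c = self.k, self.stride, self.c_in
        cols, padinfo, (n, h, w) = self._cache
        gy_flat = gy.reshape(-1, self.c_out)
        if self.use_bias:
            self.grads["b"] = gy_flat.sum(0)
        if k == 1 and s == 1:
            x = cols
            self.grads["w"] = (
                x.reshape(-1, c).T @ gy_flat
            ).reshape(1, 1, c, self.c_out)
            gx = gy_flat @ self._weight("w").reshape(c, self.c_out).T
            return gx.reshape(n, h, w, c).astype(F32, copy=False)
        self.grads["w"] = (cols.T @ gy_flat).reshape(k, k, c, self.c_out)
        (pshape, pt, pl, ho, wo) = padinfo
        gcols = (gy_flat @ self._weight("w").reshape(k * k * c, self.c_out).T).reshape(
            n, ho, wo, k, k, c
        )
        gxp = np.zeros(pshape, F32)
        for i in range(k):
            for j in range(k):
                gxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += gcols[:, :, :, i, j, :]
        return gxp[:, pt : pt + h, pl : pl + w, :]


class DepthwiseConv2D(Layer):
    kind = "depthwise_conv"

    def __init__(self, c_in, kernel=3, stride=1, use_bias=False, rng=None):
        super().__init__()
        self.c_in, self.k, self.stride = c_in, kernel, stride
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / (kernel * kernel)), (kernel, kernel, c_in)
        ).astype(F32)
        self.use_bias = use_bias
        if use_bias:
            self.params["b"] = np.zeros(c_in, F32)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        k, s = self.k, self.stride
        ho, pt, pb = _same_pad(h, k, s)
        wo, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        self._cache = (xp, (pt, pl, ho, wo), (n, h, w))
        wq = self._weight("w")
        y = np.zeros((n, ho, wo, c), F32)
        for i in range(k):  # shift-accumulate beats windowed einsum here
            for j in range(k):
                y += xp[:, i : i + s * ho : s, j : j + s * wo : s, :] * wq[i, j, :]
        if self.use_bias:
            y = y + self.params["b"]
        return y

    def backward(self, gy):
        xp, (pt, pl, ho, wo), (n, h, w) = self._cache
        k, s = self.k, self.stride
        if self.use_bias:
            self.grads["b"] = gy.reshape(-1, self.c_in).sum(0)
        gw = np.empty((k, k, self.c_in), F32)
        wq = self._weight("w")
        gxp = np.zeros(xp.shape, F32)
        for i in range(k):
            for j in range(k):
                sl = xp[:, i : i + s * ho : s, j : j + s * wo : s, :]
                gw[i, j] = (sl * gy).sum(axis=(0, 1, 2))
                gxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += gy * wq[i, j, :]
        self.grads["w"] = gw
        return gxp[:, pt : pt + h, pl : pl + w, :]


class Dense(Layer):
    kind = "dense"

    def __init__(self, c_in, c_out, use_bias=True, rng=None):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, c_out)).astype(F32)
        self.use_bias = use_bias
        if use_bias:
            self.params["b"] = np.zeros(c_out, F32)

    def forward(self, x, training=False):
        self._x = x
        y = x @ self._weight("w")
        if self.use_bias:
            y = y + self.params["b"]
        return y.astype(F32, copy=False)

    def backward(self, gy):
        self.grads["w"] = self._x.T @ gy
        if self.use_bias:
            self.grads["b"] = gy.sum(0)
        return (gy @ self._weight("w").T).astype(F32, copy=False)


class BatchNorm(Layer):
    """Batch normalization over N(,H,W); folded into convs at quantization."""

    kind = "batch_norm"

    def __init__(self, c, momentum=0.9, eps=1e-3):
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params["gamma"] = np.ones(c, F32)
        self.params["beta"] = np.zeros(c, F32)
        self.running_mean = np.zeros(c, F32)
        self.running_var = np.ones(c, F32)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            flat = x.reshape(-1, x.shape[-1])
            mean = flat.mean(0)
            var = np.maximum((flat * flat).mean(0) - mean * mean, 0.0)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean.astype(F32)) * inv
        self._cache = (xhat, inv, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, gy):
        xhat, inv, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads["gamma"] = (gy * xhat).sum(axes)
        self.grads["beta"] = gy.sum(axes)
        g = gy * self.params["gamma"]
        gx = inv * (g - g.mean(axes) - xhat * (g * xhat).mean(axes))
        return gx.astype(F32, copy=False)


class ReLU6(Layer):
    kind = "activation"

    def forward(self, x, training=False):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0, 6)

    def backward(self, gy):
        return gy * self._mask


class GlobalAvgPool(Layer):
    """Spatial mean; keeps a 1x1 spatial footprint."""

    kind = "global_avg_pool"

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2), keepdims=True)

    def backward(self, gy):
        n, h, w, c = self._shape
        return np.broadcast_to(gy / (h * w), self._shape).astype(F32)


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class TileToSpatial(Layer):
    """Broadcast a (N,1,1,C) squeeze vector onto a reference map's H x W grid.

    Takes two inputs (vector, reference); gradient flows to the vector only —
    the reference merely supplies the target shape.
    """

    kind = "tile"

    def forward(self, vec, ref, training=False):
        if vec.shape[1:3] != (1, 1):
            raise ValueError("tile expects a (N,1,1,C) squeeze vector")
        self._ref_shape = ref.shape
        n, h, w, _ = ref.shape
        return np.broadcast_to(vec, (n, h, w, vec.shape[3])).astype(F32)

    def backward(self, gy):
        return gy.sum(axis=(1, 2), keepdims=True), np.zeros(self._ref_shape, F32)


class Concat(Layer):
    kind = "concat"

    def forward(self, *xs, training=False):
        self._splits = np.cumsum([x.shape[-1] for x in xs])[:-1]
        return np.concatenate(xs, axis=-1)

    def backward(self, gy):
        return tuple(np.ascontiguousarray(g) for g in np.split(gy, self._splits, axis=-1))


class Identity(Layer):
    kind = "identity"

    def forward(self, x, training=False):
        return x

    def backward(self, gy):
        return gy


class Add(Layer):
    """Elementwise sum of two maps (residual connection; quantization-safe)."""

    kind = "add"

    def forward(self, a, b, training=False):
        return a + b

    def backward(self, gy):
        return gy, gy


class Multiply(Layer):
    """Elementwise product of two activation maps (classic SE gating).

    Present only so the quantization-friendliness audit has something real
    to detect; the shipped model never instantiates it.
    """

    kind = "multiply"

    def forward(self, a, b, training=False):
        self._ab = (a, b)
        return a * b

    def backward(self, gy):
        a, b = self._ab
        ga = gy * b
        gb = (gy * a).sum(axis=(1, 2), keepdims=True) if b.shape[1:3] == (1, 1) else gy * a
        return ga, gb


class BilinearUpsample(Layer):
    """Upsample by an integer factor with half-pixel-centre bilinear weights."""

    kind = "upsample_bilinear"

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def _grid(self, size_in: int):
        f = self.factor
        src = (np.arange(size_in * f) + 0.5) / f - 0.5
        i0 = np.floor(src).astype(int)
        t = (src - i0).astype(F32)
        i0c = np.clip(i0, 0, size_in - 1)
        i1c = np.clip(i0 + 1, 0, size_in - 1)
        return i0c, i1c, t

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        r0, r1, tr = self._grid(h)
        c0, c1, tc = self._grid(w)
        self._cache = (x.shape, r0, r1, tr, c0, c1, tc)
        top = x[:, r0][:, :, c0] * (1 - tc)[None, None, :, None] + x[:, r0][:, :, c1] * tc[None, None, :, None]
        bot = x[:, r1][:, :, c0] * (1 - tc)[None, None, :, None] + x[:, r1][:, :, c1] * tc[None, None, :, None]
        return (top * (1 - tr)[None, :, None, None] + bot * tr[None, :, None, None]).astype(F32)

    def backward(self, gy):
        shape, r0, r1, tr, c0, c1, tc = self._cache
        gx = np.zeros(shape, F32)
        wr0, wr1 = (1 - tr), tr
        wc0, wc1 = (1 - tc), tc
        for rs, wr in ((r0, wr0), (r1, wr1)):
            g = gy * wr[None, :, None, None]
            for cs, wc in ((c0, wc0), (c1, wc1)):
                np.add.at(gx, (slice(None), rs[:, None], cs[None, :]), g * wc[None, None, :, None])
        return gx


class Softmax(Layer):
    kind = "softmax"

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, gy):
        p = self._p
        return (p * (gy - (gy * p).sum(axis=-1, keepdims=True))).astype(F32, copy=False)
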