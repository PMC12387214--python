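"""Layer primitives with analytic forward/backward passes.

Tensors are NHWC ``float64`` arrays. Every layer caches what its backward
pass needs during ``forward`` and accumulates parameter gradients into
``Param.grad`` during ``backward`` (gradients are summed over the batch;
callers divide by the batch size in the loss gradient, not here).

Conventions that fix the parameter accounting:

* every convolution (standard, pointwise and depthwise) and every dense
  layer — including the squeeze-and-excitation and global-context
  projections — carries a bias vector;
* batch normalization holds 2 trainable values (gamma, beta) and 2
  non-trainable moving statistics per channel.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "DepthwiseConv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "GlobalAveragePool",
    "Dense",
    "Dropout",
    "SEBlock",
    "GCBlock",
    "Sequential",
    "ResidualBlock",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A named tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base class: subclasses implement forward/backward and expose params."""

    def __init__(self, name: str):
        self.name = name

    def params(self) -> list[tuple[str, Param]]:
        return []

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def param_counts(self) -> tuple[int, int]:
        trainable = sum(p.size for _, p in self.params() if p.trainable)
        frozen = sum(p.size for _, p in self.params() if not p.trainable)
        return trainable, frozen

    def zero_grads(self) -> None:
        for _, p in self.params():
            p.grad[...] = 0.0


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D(Layer):
    """k×k same-padding stride-1 convolution with bias (im2col + GEMM)."""

    def __init__(self, name, in_channels, out_channels, ksize=3, rng=None):
        super().__init__(name)
        if ksize % 2 != 1:
            raise ValueError("Conv2D supports odd kernel sizes only")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = in_channels, out_channels, ksize
        fan_in = ksize * ksize * in_channels
        self.w = Param(_he_normal(rng, (ksize, ksize, in_channels, out_channels), fan_in))
        self.b = Param(np.zeros(out_channels))
        self._cache = None

    def params(self):
        return [(f"{self.name}.w", self.w), (f"{self.name}.b", self.b)]

    def forward(self, x, training=False, rng=None):
        if x.shape[-1] != self.cin:
            raise ValueError(
                f"{self.name}: expected {self.cin} input channels, got {x.shape[-1]}"
            )
        n, h, w, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))  # N,H,W,C,k,k
        col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, self.k * self.k * self.cin
        )
        wm = self.w.value.reshape(self.k * self.k * self.cin, self.cout)
        y = (col @ wm).reshape(n, h, w, self.cout) + self.b.value
        self._cache = (col, (n, h, w))
        return y

    def backward(self, dy):
        col, (n, h, w) = self._cache
        dym = dy.reshape(n * h * w, self.cout)
        wm = self.w.value.reshape(-1, self.cout)
        self.w.grad += (col.T @ dym).reshape(self.w.value.shape)
        self.b.grad += dym.sum(axis=0)
        dcol = (dym @ wm.T).reshape(n, h, w, self.k, self.k, self.cin)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.cin))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcol[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class DepthwiseConv2D(Layer):
    """3×3 per-channel spatial convolution (same padding, stride 1) with bias."""

    def __init__(self, name, channels, rng=None):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.c = channels
        self.w = Param(_he_normal(rng, (3, 3, channels), 9))
        self.b = Param(np.zeros(channels))
        self._cache = None

    def params(self):
        return [(f"{self.name}.w", self.w), (f"{self.name}.b", self.b)]

    def forward(self, x, training=False, rng=None):
        if x.shape[-1] != self.c:
            raise ValueError(
                f"{self.name}: expected {self.c} input channels, got {x.shape[-1]}"
            )
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # N,H,W,C,3,3
        y = np.einsum("nhwcij,ijc->nhwc", win, self.w.value, optimize=True)
        self._cache = (win, x.shape)
        return y + self.b.value

    def backward(self, dy):
        win, (n, h, w, _) = self._cache
        self.w.grad += np.einsum("nhwcij,nhwc->ijc", win, dy, optimize=True)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dxp = np.zeros((n, h + 2, w + 2, self.c))
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + w, :] += dy * self.w.value[i, j]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class BatchNorm(Layer):
    """Channel-wise batch normalization with moving statistics.

    Training mode normalizes with batch statistics and updates the moving
    mean/variance; inference mode uses the moving statistics (the mode used
    in the forward pass determines the backward formula).
    """

    def __init__(self, name, channels, momentum=0.99, eps=1e-3):
        super().__init__(name)
        self.c = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.moving_mean = Param(np.zeros(channels), trainable=False)
        self.moving_var = Param(np.ones(channels), trainable=False)
        self._cache = None

    def params(self):
        return [
            (f"{self.name}.gamma", self.gamma),
            (f"{self.name}.beta", self.beta),
            (f"{self.name}.moving_mean", self.moving_mean),
            (f"{self.name}.moving_var", self.moving_var),
        ]

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean.value = m * self.moving_mean.value + (1 - m) * mean
            self.moving_var.value = m * self.moving_var.value + (1 - m) * var
        else:
            mean, var = self.moving_mean.value, self.moving_var.value
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        self._cache = (xhat, ivar, axes, training, int(np.prod([x.shape[a] for a in axes])))
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, ivar, axes, training, m = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        if not training:
            return dxhat * ivar
        # batch-statistics backward
        t1 = dxhat.sum(axis=axes)
        t2 = (dxhat * xhat).sum(axis=axes)
        return (dxhat - t1 / m - xhat * t2 / m) * ivar


class ReLU(Layer):
    def __init__(self, name):
        super().__init__(name)
        self._mask = None

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool2x2(Layer):
    """2×2 max-pool, stride 2, floor semantics (trailing odd row/col dropped)."""

    def __init__(self, name):
        super().__init__(name)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, : 2 * ho, : 2 * wo, :]
        v = xc.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, ho, wo, c, 4
        )
        idx = v.argmax(axis=-1)
        y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, h, w, c))
        return y

    def backward(self, dy):
        idx, (n, h, w, c) = self._cache
        ho, wo = h // 2, w // 2
        dv = np.zeros((n, ho, wo, c, 4))
        np.put_along_axis(dv, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, h, w, c))
        dx[:, : 2 * ho, : 2 * wo, :] = (
            dv.reshape(n, ho, wo, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, 2 * ho, 2 * wo, c)
        )
        return dx


class GlobalAveragePool(Layer):
    """Spatial mean per channel: NHWC → NC."""

    def __init__(self, name):
        super().__init__(name)
        self._shape = None

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), (n, h, w, c)).copy()


class Dense(Layer):
    def __init__(self, name, in_features, out_features, rng=None):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_normal(rng, (in_features, out_features), in_features))
        self.b = Param(np.zeros(out_features))
        self._x = None

    def params(self):
        return [(f"{self.name}.w", self.w), (f"{self.name}.b", self.b)]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, name, rate):
        super().__init__(name)
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate: sigmoid bottleneck scales in (0,1).

    Y = sigmoid(W2 relu(W1 GAP(X) + b1) + b2) ⊙ X with reduced width
    floor(C/r), which must be at least 1.
    """

    def __init__(self, name, channels, reduction=16, rng=None):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        reduced = channels // reduction
        if reduced < 1:
            raise ValueError(
                f"{name}: squeeze width floor({channels}/{reduction}) is 0; "
                "reduce the ratio or widen the block"
            )
        self.c, self.reduced = channels, reduced
        self.w1 = Param(_he_normal(rng, (channels, reduced), channels))
        self.b1 = Param(np.zeros(reduced))
        self.w2 = Param(_he_normal(rng, (reduced, channels), reduced))
        self.b2 = Param(np.zeros(channels))
        self._cache = None

    def params(self):
        return [
            (f"{self.name}.w1", self.w1),
            (f"{self.name}.b1", self.b1),
            (f"{self.name}.w2", self.w2),
            (f"{self.name}.b2", self.b2),
        ]

    def forward(self, x, training=False, rng=None):
        s = x.mean(axis=(1, 2))  # N,C
        z = np.maximum(s @ self.w1.value + self.b1.value, 0.0)
        g = sigmoid(z @ self.w2.value + self.b2.value)
        self._cache = (x, s, z, g)
        return x * g[:, None, None, :]

    def backward(self, dy):
        x, s, z, g = self._cache
        n, h, w, c = x.shape
        dg = (dy * x).sum(axis=(1, 2))
        dx = dy * g[:, None, None, :]
        dpre2 = dg * g * (1.0 - g)
        self.w2.grad += z.T @ dpre2
        self.b2.grad += dpre2.sum(axis=0)
        dz = dpre2 @ self.w2.value.T
        dpre1 = dz * (z > 0)
        self.w1.grad += s.T @ dpre1
        self.b1.grad += dpre1.sum(axis=0)
        ds = dpre1 @ self.w1.value.T
        dx += ds[:, None, None, :] / (h * w)
        return dx


class GCBlock(Layer):
    """Global-context channel gate: Y = (1 + sigmoid(Wg GAP(X) + bg)) ⊙ X.

    Per-channel scales lie strictly in (1, 2).
    """

    def __init__(self, name, channels, rng=None):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.c = channels
        self.wg = Param(_he_normal(rng, (channels, channels), channels))
        self.bg = Param(np.zeros(channels))
        self._cache = None

    def params(self):
        return [(f"{self.name}.wg", self.wg), (f"{self.name}.bg", self.bg)]

    def forward(self, x, training=False, rng=None):
        s = x.mean(axis=(1, 2))
        a = sigmoid(s @ self.wg.value + self.bg.value)
        self._cache = (x, s, a)
        return x * (1.0 + a)[:, None, None, :]

    def backward(self, dy):
        x, s, a = self._cache
        n, h, w, c = x.shape
        da = (dy * x).sum(axis=(1, 2))
        dx = dy * (1.0 + a)[:, None, None, :]
        dpre = da * a * (1.0 - a)
        self.wg.grad += s.T @ dpre
        self.bg.grad += dpre.sum(axis=0)
        ds = dpre @ self.wg.value.T
        dx += ds[:, None, None, :] / (h * w)
        return dx


class Sequential(Layer):
    """Ordered container; params are exposed with dotted sub-layer names."""

    def __init__(self, name, layers):
        super().__init__(name)
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            for pname, p in layer.params():
                out.append((f"{self.name}.{pname}", p))
        return out

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Layer):
    """Two 3×3 convolutions plus a 1×1 projected skip, summed with no
    activation after the addition (stride 1 throughout)."""

    def __init__(self, name, in_channels, out_channels, rng=None, bn_momentum=0.99):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2D("conv1", in_channels, out_channels, 3, rng=rng)
        self.bn1 = BatchNorm("bn1", out_channels, momentum=bn_momentum)
        self.relu = ReLU("relu")
        self.conv2 = Conv2D("conv2", out_channels, out_channels, 3, rng=rng)
        self.bn2 = BatchNorm("bn2", out_channels, momentum=bn_momentum)
        self.skip_conv = Conv2D("skip_conv", in_channels, out_channels, 1, rng=rng)
        self.skip_bn = BatchNorm("skip_bn", out_channels, momentum=bn_momentum)

    def _sublayers(self):
        return [
            self.conv1,
            self.bn1,
            self.relu,
            self.conv2,
            self.bn2,
            self.skip_conv,
            self.skip_bn,
        ]

    def params(self):
        out = []
        for layer in self._sublayers():
            for pname, p in layer.params():
                out.append((f"{self.name}.{pname}", p))
        return out

    def forward(self, x, training=False, rng=None):
        u = self.relu.forward(
            self.bn1.forward(self.conv1.forward(x, training, rng), training, rng),
            training,
            rng,
        )
        u = self.bn2.forward(self.conv2.forward(u, training, rng), training, rng)
        s = self.skip_bn.forward(self.skip_conv.forward(x, training, rng), training, rng)
        return u + s

    def backward(self, dy):
        d = self.conv2.backward(self.bn2.backward(dy))
        d = self.bn1.backward(self.relu.backward(d))
        dx = self.conv1.backward(d)
        dx += self.skip_conv.backward(self.skip_bn.backward(dy))
        return dx
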