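"""Functional forms of the network's building blocks.

These operate on a single H×W×C feature map with explicitly supplied
kernels, which makes them directly checkable against brute-force oracles;
the trainable layer classes in :mod:`fundusnet.nn` use the same code paths.

Batch-normalization parameters are passed as ``(gamma, beta, mean, var)``
tuples (per-channel vectors) applied in inference form
``gamma * (x - mean) / sqrt(var + eps) + beta``; ``None`` means identity
(no normalization).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .nn.layers import sigmoid
from .nn.network import stable_softmax

__all__ = [
    "gap",
    "depthwise_separable",
    "se_recalibrate",
    "gc_recalibrate",
    "residual_block",
    "softmax",
]

softmax = stable_softmax


def gap(x: np.ndarray) -> np.ndarray:
    """Global average pooling: spatial mean per channel (H×W×C → C)."""
    return np.asarray(x, dtype=np.float64).mean(axis=(0, 1))


def _bn(x, bn_params, eps=1e-3):
    if bn_params is None:
        return x
    gamma, beta, mean, var = (np.asarray(v, dtype=np.float64) for v in bn_params)
    return gamma * (x - mean) / np.sqrt(var + eps) + beta


def _conv_same(x, kernel, bias):
    """Dense k×k same-padding stride-1 convolution on one H×W×C map."""
    k = kernel.shape[0]
    p = k // 2
    xp = np.pad(x, ((p, p), (p, p), (0, 0))) if p else x
    win = sliding_window_view(xp, (k, k), axis=(0, 1))  # H,W,C,k,k
    y = np.einsum("hwcij,ijcf->hwf", win, kernel, optimize=True)
    return y + (0.0 if bias is None else bias)


def depthwise_separable(
    x: np.ndarray,
    depthwise_kernel: np.ndarray,
    pointwise_kernel: np.ndarray,
    depthwise_bias: np.ndarray | None = None,
    pointwise_bias: np.ndarray | None = None,
    bn1=None,
    bn2=None,
) -> np.ndarray:
    """Depthwise 3×3 then pointwise 1×1 convolution, each followed by
    (optional) batch normalization and ReLU: the DSConv block.

    ``depthwise_kernel``: 3×3×C; ``pointwise_kernel``: 1×1×C×F (or C×F).
    Output is H×W×F.
    """
    x = np.asarray(x, dtype=np.float64)
    c = x.shape[-1]
    if depthwise_kernel.shape != (3, 3, c):
        raise ValueError(
            f"depthwise kernel must be 3×3×{c}, got {depthwise_kernel.shape}"
        )
    pw = np.asarray(pointwise_kernel, dtype=np.float64)
    if pw.ndim == 4:
        pw = pw[0, 0]
    if pw.shape[0] != c:
        raise ValueError(f"pointwise kernel maps {pw.shape[0]} channels, input has {c}")
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(0, 1))  # H,W,C,3,3
    ydw = np.einsum("hwcij,ijc->hwc", win, depthwise_kernel, optimize=True)
    if depthwise_bias is not None:
        ydw = ydw + depthwise_bias
    ydw = np.maximum(_bn(ydw, bn1), 0.0)
    ypw = ydw @ pw
    if pointwise_bias is not None:
        ypw = ypw + pointwise_bias
    return np.maximum(_bn(ypw, bn2), 0.0)


def se_recalibrate(x, w1, b1, w2, b2) -> np.ndarray:
    """Squeeze-and-excitation gate on one map:
    ``sigmoid(W2 relu(W1 GAP(X) + b1) + b2) ⊙ X``; scales lie in (0,1)."""
    x = np.asarray(x, dtype=np.float64)
    c = x.shape[-1]
    w1 = np.asarray(w1, dtype=np.float64)
    if w1.shape[0] != c:
        # accept the (reduced, C) orientation as well
        if w1.shape[1] == c:
            w1 = w1.T
        else:
            raise ValueError(f"W1 must map {c} channels, got {w1.shape}")
    if w1.shape[1] < 1:
        raise ValueError("SE squeeze width must be at least 1")
    w2 = np.asarray(w2, dtype=np.float64)
    if w2.shape[0] != w1.shape[1]:
        w2 = w2.T
    s = gap(x)
    z = np.maximum(s @ w1 + b1, 0.0)
    g = sigmoid(z @ w2 + b2)
    return x * g


def gc_recalibrate(x, wg, bg=None) -> np.ndarray:
    """Global-context gate: ``(1 + sigmoid(Wg GAP(X) + bg)) ⊙ X``;
    scales lie in (1,2)."""
    x = np.asarray(x, dtype=np.float64)
    c = x.shape[-1]
    wg = np.asarray(wg, dtype=np.float64)
    if wg.shape != (c, c):
        raise ValueError(f"Wg must be {c}×{c}, got {wg.shape}")
    pre = gap(x) @ wg
    if bg is not None:
        pre = pre + bg
    return x * (1.0 + sigmoid(pre))


def residual_block(
    x: np.ndarray,
    conv1_kernel,
    conv2_kernel,
    skip_kernel,
    conv1_bias=None,
    conv2_bias=None,
    skip_bias=None,
    bn1=None,
    bn2=None,
    bn_skip=None,
) -> np.ndarray:
    """Residual block: main path 3×3 conv + BN + ReLU then 3×3 conv + BN;
    skip path 1×1 conv + BN; output is their sum with no trailing
    activation (stride 1, same padding)."""
    x = np.asarray(x, dtype=np.float64)
    u = np.maximum(_bn(_conv_same(x, np.asarray(conv1_kernel, dtype=np.float64), conv1_bias), bn1), 0.0)
    u = _bn(_conv_same(u, np.asarray(conv2_kernel, dtype=np.float64), conv2_bias), bn2)
    sk = np.asarray(skip_kernel, dtype=np.float64)
    if sk.ndim == 2:
        sk = sk[None, None]
    s = _bn(_conv_same(x, sk, skip_bias), bn_skip)
    return u + s
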