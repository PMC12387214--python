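"""Grad-CAM and Grad-CAM++ saliency maps with overlay rendering.

Both methods differentiate the pre-softmax class score y^c with respect to
the activations A^k of a chosen convolutional tap point (default: the
residual block's output before the final pool, the deepest spatial layer).

Grad-CAM weighs each channel by the spatial mean of ∂y^c/∂A^k and rectifies
the weighted sum. Grad-CAM++ weighs gradient contributions per position
with α_kij = g² / (2g² + Σ_ab A_ab g³) — the closed form obtained when the
second and third derivatives of exp(y^c) are expressed through the
first-order gradient g — and sums α·ReLU(g) per channel. Raw maps are
rectified, bilinearly upsampled to the input resolution and min–max
normalized to [0,1] (an identically-zero map stays zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn.network import Network

__all__ = ["SaliencyMap", "OverlayImage", "grad_cam", "grad_cam_pp", "overlay"]

_EPS = 1e-8


@dataclass
class SaliencyMap:
    values: np.ndarray  # H×W in [0,1] at input resolution
    source_layer: str
    class_index: int
    method: str


@dataclass
class OverlayImage:
    values: np.ndarray  # H×W×3 in [0,1]
    alpha: float


def _activations_and_gradient(
    model: Network, image: np.ndarray, class_index: int, layer: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward the image, then backprop the chosen pre-softmax logit down to
    the tap layer; returns (activations A, gradient dy/dA, logits)."""
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    logits = model.forward(x, training=False)
    n_classes = logits.shape[1]
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class_index {class_index} outside [0, {n_classes})")
    acts = model.stage_output(layer)
    if acts.ndim != 4:
        raise ValueError(
            f"layer {layer!r} has no spatial activations (shape {acts.shape}); "
            "choose a convolutional tap point"
        )
    dlogits = np.zeros_like(logits)
    dlogits[0, class_index] = 1.0
    model.zero_grads()
    grad = model.backward(dlogits, stop_after=layer)
    return acts[0], grad[0], logits[0]


def _finalize(raw: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    raw = np.maximum(raw, 0.0)
    up = resize(raw, out_shape, order=1, mode="edge", anti_aliasing=False,
                preserve_range=True)
    up = np.maximum(up, 0.0)
    span = up.max() - up.min()
    if span <= 0.0:
        return np.zeros(out_shape)
    return (up - up.min()) / span


def grad_cam(
    model: Network,
    image: np.ndarray,
    class_index: int,
    layer: str | None = None,
) -> SaliencyMap:
    """Class-conditional saliency: channel weights are the spatial means of
    ∂y^c/∂A^k; the map is ReLU(Σ_k α_k A^k) upsampled and normalized."""
    layer = layer or getattr(model, "default_cam_layer", "block4")
    acts, grad, _ = _activations_and_gradient(model, image, class_index, layer)
    alpha = grad.mean(axis=(0, 1))  # C
    raw = np.einsum("hwc,c->hw", acts, alpha)
    h, w = np.asarray(image).shape[-3:-1]
    return SaliencyMap(
        values=_finalize(raw, (h, w)),
        source_layer=layer,
        class_index=int(class_index),
        method="gradcam",
    )


def grad_cam_pp(
    model: Network,
    image: np.ndarray,
    class_index: int,
    layer: str | None = None,
) -> SaliencyMap:
    """Grad-CAM++ saliency with position-wise gradient weights."""
    layer = layer or getattr(model, "default_cam_layer", "block4")
    acts, grad, _ = _activations_and_gradient(model, image, class_index, layer)
    g2 = grad**2
    g3 = g2 * grad
    denom = 2.0 * g2 + np.sum(acts * g3, axis=(0, 1), keepdims=True)
    alpha = np.where(g2 > 0, g2 / np.where(np.abs(denom) > _EPS, denom, _EPS), 0.0)
    weights = np.sum(alpha * np.maximum(grad, 0.0), axis=(0, 1))  # C
    raw = np.einsum("hwc,c->hw", acts, weights)
    h, w = np.asarray(image).shape[-3:-1]
    return SaliencyMap(
        values=_finalize(raw, (h, w)),
        source_layer=layer,
        class_index=int(class_index),
        method="gradcampp",
    )


def overlay(
    image: np.ndarray,
    saliency: SaliencyMap | np.ndarray,
    alpha: float = 0.4,
    colormap: str = "jet",
) -> OverlayImage:
    """Blend a colormapped saliency map onto the image:
    ``(1 − alpha)·image + alpha·colormap(map)``, clipped to [0,1]."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colormaps

    img = np.asarray(image, dtype=np.float64)
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    if img.shape[:2] != values.shape:
        raise ValueError(
            f"image {img.shape[:2]} and saliency map {values.shape} resolutions differ"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    heat = colormaps[colormap](values)[..., :3]
    blended = np.clip((1.0 - alpha) * img + alpha * heat, 0.0, 1.0)
    return OverlayImage(values=blended, alpha=alpha)


def explanation_panel(
    model: Network,
    image: np.ndarray,
    class_index: int,
    path,
    layer: str | None = None,
    alpha: float = 0.4,
) -> dict:
    """Write a 3-row panel (original / Grad-CAM overlay / Grad-CAM++ overlay)
    as PNG and return the two saliency maps."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cam = grad_cam(model, image, class_index, layer)
    campp = grad_cam_pp(model, image, class_index, layer)
    rows = [
        ("original", np.asarray(image)),
        ("Grad-CAM", overlay(image, cam, alpha).values),
        ("Grad-CAM++", overlay(image, campp, alpha).values),
    ]
    fig, axes = plt.subplots(3, 1, figsize=(3, 9))
    for ax, (title, panel) in zip(axes, rows):
        ax.imshow(panel)
        ax.set_title(title, fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return {"gradcam": cam, "gradcampp": campp}
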