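"""Gradient-weighted class-activation mapping for the scalar score regressor.

For a regressor the "class" is the single continuous output: channel weights
are the spatial means of the output's gradient with respect to a chosen
convolutional feature map, the map is the rectified weighted activation sum,
bilinearly upsampled to the patch and max-normalised to [0, 1].

:func:`focus_fraction` turns the qualitative "does the model look at the
calcification?" question into a number: the fraction of the heatmap's
top-quantile pixels that fall inside the (optionally dilated) calcification
mask.  It is a declared proxy for reader-study focus judgments, not a
reproduction of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .regression import CNNRegressor, _as_array
from .roi import Patch

__all__ = ["Heatmap", "grad_cam", "focus_fraction", "save_overlay"]


@dataclass(frozen=True)
class Heatmap:
    """Non-negative saliency map in [0, 1], aligned to its patch."""

    values: np.ndarray
    target_layer: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or (v < 0).any() or (v > 1).any():
            raise ValueError("heatmap values must be a 2-D array in [0, 1]")


def grad_cam(model: CNNRegressor, patch, target_layer: str | None = None) -> Heatmap:
    """Gradient-weighted activation map of the scalar output.

    ``target_layer`` names a convolutional feature layer of the model
    (default: the last residual block).  An all-zero map (e.g. zero output
    gradient) stays all-zero rather than being normalised.
    """
    names = model.layer_names()
    if target_layer is None:
        target_layer = names[-1]
    if target_layer not in names:
        raise ValueError(f"unknown layer {target_layer!r}; available: {names}")

    x = _as_array([patch])
    model(x, train=False)
    model.backward(np.ones(1, dtype=np.float32))
    act = model._acts[target_layer][0]     # (C, h, w)
    grad = model._grads[target_layer][0]
    for p in model.parameters():  # discard gradients from the explanation pass
        p.zero_grad()

    weights = grad.mean(axis=(1, 2))
    cam = np.maximum(0.0, np.tensordot(weights, act, axes=1))
    H, W = np.asarray(patch.pixels if isinstance(patch, Patch) else patch).shape
    cam = _sk_resize(cam, (H, W), order=1, anti_aliasing=False, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    m = cam.max()
    if m > 0:
        cam = cam / m
    return Heatmap(values=cam.astype(np.float32), target_layer=target_layer)


def focus_fraction(h: Heatmap, calc_mask: np.ndarray, top_q: float = 0.1, dilation: int = 0) -> float:
    """Fraction of the heatmap's top-``top_q`` pixels inside the mask.

    ``calc_mask`` must already be mapped through the same crop/resize as the
    patch.  ``dilation`` grows the mask by that many binary dilation
    iterations before measuring.  Returns NaN (undefined) for an empty mask.
    """
    if not 0.0 < top_q <= 1.0:
        raise ValueError(f"top_q must be in (0, 1], got {top_q}")
    mask = np.asarray(calc_mask).astype(bool)
    if mask.shape != h.values.shape:
        raise ValueError(f"mask shape {mask.shape} != heatmap shape {h.values.shape}")
    if not mask.any():
        return float("nan")
    if dilation > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilation)
    flat = h.values.ravel()
    k = max(1, int(round(top_q * flat.size)))
    top_idx = np.argpartition(flat, -k)[-k:]
    return float(mask.ravel()[top_idx].mean())


def save_overlay(patch, heatmap: Heatmap, path: str | Path, alpha: float = 0.45) -> Path:
    """Write a PNG of the patch with the colormapped heatmap blended on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pixels = np.asarray(patch.pixels if isinstance(patch, Patch) else patch, dtype=float)
    lo, hi = pixels.min(), pixels.max()
    base = (pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(pixels)
    rgb = plt.get_cmap("gray")(base)[..., :3]
    heat = plt.get_cmap("jet")(heatmap.values)[..., :3]
    blend = (1 - alpha) * rgb + alpha * heat
    path = Path(path)
    plt.imsave(path, np.clip(blend, 0, 1))
    return path
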