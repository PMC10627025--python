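"""Grad-CAM++ wavelength attribution for 1D spectral CNNs.

For a trained CNN and a target class, the class score's gradient at the last
convolution block's (post-ReLU) feature maps is combined with the maps
themselves into a coarse non-negative localisation curve, which is linearly
interpolated up to the 181 retained wavelengths and max-normalised. The
position weights use the standard closed form in powers of the first-order
gradient g = dy/dA (exact for exponentiated linear scores):

    alpha = g^2 / (2 g^2 + sum_l A g^3)
    w_c   = sum_l alpha * relu(g)
    map_l = relu(sum_c w_c A_c[l])

Gradients are taken on the pre-softmax class score with batch norm in
evaluation mode and dropout disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import N_RETAINED_BANDS, WavelengthGrid
from .models import N_CLASSES, SpectralCNN, TrainedModel

__all__ = ["SaliencyCurve", "SaliencySummary", "gradcampp_1d",
           "saliency_summary", "top_band_regions"]


@dataclass(frozen=True)
class SaliencyCurve:
    """Per-wavelength attribution weights for one spectrum and class."""

    weights: np.ndarray          # (181,), >= 0, max 1 when normalized
    class_index: int
    normalized: bool = True
    coarse: np.ndarray | None = None   # feature-map-resolution curve

    def __post_init__(self):
        if len(self.weights) != N_RETAINED_BANDS:
            raise ValueError(f"saliency curve must have {N_RETAINED_BANDS} weights")
        if (self.weights < 0).any():
            raise ValueError("saliency weights must be non-negative")


@dataclass(frozen=True)
class SaliencySummary:
    """Bandwise mean and population-std curves per aging class."""

    classes: np.ndarray
    mean: np.ndarray   # (n_classes, 181)
    std: np.ndarray    # (n_classes, 181)


def gradcampp_1d(trained: TrainedModel | SpectralCNN, spectrum: np.ndarray,
                 class_index: int) -> SaliencyCurve:
    """Grad-CAM++ curve of one spectrum for one aging class."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    if not 0 <= class_index < N_CLASSES:
        raise ValueError(f"class index must be in [0, {N_CLASSES}), got {class_index}")
    x = np.asarray(spectrum, dtype=np.float64).reshape(1, 1, -1)
    if x.shape[-1] != model.spec.input_bands:
        raise ValueError(f"expected {model.spec.input_bands} bands, got {x.shape[-1]}")

    target = model.last_relu_index()
    feats = model.backbone.forward(x, training=False, keep_acts=True)
    logits = model.head.forward(feats, training=False)
    acts = model.backbone.activation(target)          # A: (1, C, Lf)

    one_hot = np.zeros_like(logits)
    one_hot[0, class_index] = 1.0
    model.zero_grad()
    grad_feats = model.head.backward(one_hot)
    grads = model.backbone.backward(grad_feats, from_layer=target + 1)
    model.zero_grad()

    a = acts[0]          # (C, Lf)
    g = grads[0]
    g2, g3 = g * g, g * g * g
    denom = 2.0 * g2 + a.sum(axis=1, keepdims=True) * g3
    alpha = np.divide(g2, denom, out=np.zeros_like(g2), where=np.abs(denom) > 1e-12)
    channel_w = (alpha * np.maximum(g, 0.0)).sum(axis=1)        # (C,)
    coarse = np.maximum((channel_w[:, None] * a).sum(axis=0), 0.0)   # (Lf,)

    lf = len(coarse)
    n = model.spec.input_bands
    if lf == 1:
        fine = np.full(n, coarse[0])
    else:
        fine = np.interp(np.arange(n), np.linspace(0.0, n - 1, lf), coarse)
    fine = np.maximum(fine, 0.0)
    peak = fine.max()
    if peak > 0:
        fine = fine / peak
    return SaliencyCurve(weights=fine, class_index=class_index,
                         normalized=True, coarse=coarse)


def saliency_summary(curves: list[SaliencyCurve]) -> SaliencySummary:
    """Group curves by class and take the bandwise mean and population std."""
    classes = np.unique([c.class_index for c in curves])
    means, stds = [], []
    for cls in classes:
        block = np.vstack([c.weights for c in curves if c.class_index == cls])
        if len(block) < 2:
            raise ValueError(f"class {cls} has fewer than 2 curves")
        means.append(block.mean(axis=0))
        stds.append(block.std(axis=0))
    return SaliencySummary(classes=classes, mean=np.vstack(means),
                           std=np.vstack(stds))


def top_band_regions(curve: SaliencyCurve | np.ndarray, grid: WavelengthGrid,
                     threshold: float = 0.5) -> list[tuple[float, float]]:
    """Maximal contiguous wavelength intervals where the weight reaches
    ``threshold`` times the curve maximum, as (lo_nm, hi_nm) pairs."""
    w = curve.weights if isinstance(curve, SaliencyCurve) else np.asarray(curve)
    if len(w) != len(grid.retained_nm):
        raise ValueError("curve length does not match the retained grid")
    high = w >= threshold * w.max()
    nm = grid.retained_nm
    regions: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(high):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append((float(nm[start]), float(nm[i - 1])))
            start = None
    if start is not None:
        regions.append((float(nm[start]), float(nm[-1])))
    return regions
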