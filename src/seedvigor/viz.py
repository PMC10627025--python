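"""Plot helpers: per-class mean +- std spectra and saliency-summary curves."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import CLASS_NAMES, WavelengthGrid
from .interpret import SaliencySummary
from .preprocess import ClassSpectralSummary

__all__ = ["plot_class_mean_std", "plot_saliency_summary"]


def plot_class_mean_std(summary: ClassSpectralSummary, grid: WavelengthGrid,
                        ax=None, title: str = ""):
    """Mean reflectance per aging class with a +-1 std shaded band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    nm = grid.retained_nm
    for row, cls in enumerate(summary.classes):
        mean, std = summary.mean[row], summary.std[row]
        ax.plot(nm, mean, label=CLASS_NAMES[int(cls)])
        ax.fill_between(nm, mean - std, mean + std, alpha=0.25)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_saliency_summary(summary: SaliencySummary, grid: WavelengthGrid,
                          axes=None, title: str = ""):
    """One panel per aging class: mean Grad-CAM++ weight with std shading."""
    n = len(summary.classes)
    if axes is None:
        _, axes = plt.subplots(n, 1, figsize=(7, 2.4 * n), sharex=True)
    axes = np.atleast_1d(axes)
    nm = grid.retained_nm
    for row, (cls, ax) in enumerate(zip(summary.classes, axes)):
        mean, std = summary.mean[row], summary.std[row]
        ax.plot(nm, mean)
        ax.fill_between(nm, np.maximum(mean - std, 0.0), mean + std, alpha=0.25)
        ax.set_ylabel(CLASS_NAMES[int(cls)])
    axes[-1].set_xlabel("wavelength (nm)")
    if title:
        axes[0].set_title(title)
    return axes
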