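"""Reflectance calibration, band trimming, ROI extraction and data splitting.

The preprocessing chain mirrors a standard NIR-HSI workflow: raw digital
numbers are converted to reflectance with white/dark reference frames,
R = (I - D) / (W - D); the noisy head and tail bands are removed, keeping the
998-1631 nm window (181 bands); seeds are segmented from the dark stage on the
band-mean image; each seed ROI is averaged into one spectral vector; and the
labelled vectors are split 4:1:1 (train:validation:test), stratified by class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .containers import (N_ALL_BANDS, Hypercube, ROIMask, SpectraMatrix,
                         SplitBundle, WavelengthGrid)

__all__ = [
    "ZeroDenominatorError", "calibrate_reflectance", "trim_bands",
    "segment_seeds", "extract_mean_spectra", "split_dataset",
    "class_mean_std", "ClassSpectralSummary",
]


class ZeroDenominatorError(ValueError):
    """White and dark reference coincide somewhere; calibration is undefined."""

    def __init__(self, coords: np.ndarray):
        self.coords = coords
        first = tuple(int(v) for v in coords[0])
        super().__init__(
            f"W - D vanishes or is negative at {len(coords)} location(s), "
            f"first at (row, col, band) = {first}")


def calibrate_reflectance(raw: np.ndarray | Hypercube, white: np.ndarray,
                          dark: np.ndarray,
                          grid: WavelengthGrid | None = None) -> Hypercube:
    """Reflectance calibration R = (I - D) / (W - D), elementwise."""
    if isinstance(raw, Hypercube):
        grid = raw.grid
        raw = raw.values
    if grid is None:
        raise ValueError("a WavelengthGrid is required")
    raw = np.asarray(raw, dtype=np.float64)
    white = np.asarray(white, dtype=np.float64)
    dark = np.asarray(dark, dtype=np.float64)
    if not raw.shape == white.shape == dark.shape:
        raise ValueError(
            f"shape mismatch: I {raw.shape}, W {white.shape}, D {dark.shape}")
    denom = white - dark
    bad = np.argwhere(denom <= 0)
    if len(bad):
        raise ZeroDenominatorError(bad)
    return Hypercube(values=(raw - dark) / denom, grid=grid, calibrated=True)


def trim_bands(data: Hypercube | SpectraMatrix | np.ndarray,
               grid: WavelengthGrid):
    """Restrict a 224-band object to the retained 181-band window.

    Already-trimmed input is rejected rather than passed through: trimming is
    a one-time step and silent idempotency would hide double application.
    """
    lo, hi = grid.retained_index_window
    sl = slice(lo, hi + 1)
    if isinstance(data, Hypercube):
        if data.n_bands != N_ALL_BANDS:
            raise ValueError(f"expected a {N_ALL_BANDS}-band cube, got {data.n_bands}")
        return Hypercube(values=data.values[:, :, sl], grid=grid,
                         calibrated=data.calibrated)
    if isinstance(data, SpectraMatrix):
        if data.n_bands != N_ALL_BANDS:
            raise ValueError(f"expected {N_ALL_BANDS}-band spectra, got {data.n_bands}")
        return SpectraMatrix(spectra=data.spectra[:, sl], labels=data.labels,
                             domain=data.domain)
    arr = np.asarray(data)
    if arr.shape[-1] != N_ALL_BANDS:
        raise ValueError(f"expected {N_ALL_BANDS} bands on the last axis, got {arr.shape[-1]}")
    return arr[..., sl]


def segment_seeds(cube: Hypercube, min_area: int = 12) -> list[ROIMask]:
    """Threshold the band-mean image (Otsu), label connected components,
    discard blobs below ``min_area`` pixels. Returns masks sorted by
    (row, col) of their centroid for a deterministic ordering."""
    if not cube.calibrated:
        raise ValueError("segmentation expects a calibrated cube")
    mean_img = cube.band_mean_image()
    if np.ptp(mean_img) == 0:  # blank scene: Otsu undefined
        return []
    thresh = threshold_otsu(mean_img)
    binary = mean_img > thresh
    labelled = cc_label(binary, connectivity=1)
    masks = []
    for lab in range(1, labelled.max() + 1):
        mask = labelled == lab
        if mask.sum() >= min_area:
            masks.append(mask)
    # deterministic order: scan position of the centroid
    def centroid_key(m):
        rr, cc = np.nonzero(m)
        return (float(rr.mean()), float(cc.mean()))
    masks.sort(key=centroid_key)
    return [ROIMask(mask=m, seed_id=i) for i, m in enumerate(masks)]


def extract_mean_spectra(cube: Hypercube, masks: list[ROIMask],
                         domain: str = "") -> SpectraMatrix:
    """Average the cube over each ROI: row i is the per-band pixel mean of
    mask i. Returns an unlabeled SpectraMatrix."""
    rows = []
    for roi in masks:
        if roi.mask.shape != cube.values.shape[:2]:
            raise ValueError("mask shape does not match cube")
        rows.append(cube.values[roi.mask].mean(axis=0))
    spectra = np.vstack(rows) if rows else np.empty((0, cube.n_bands))
    return SpectraMatrix(spectra=spectra, labels=None, domain=domain)


def split_dataset(data: SpectraMatrix | np.ndarray, rng: np.random.Generator,
                  seed: int | None = None) -> SplitBundle:
    """Stratified 4:1:1 split.

    Within each class of size n, validation and test each receive floor(n/6)
    members and train receives the rest (remainders go to train). Assignment
    within a class is a random permutation drawn from ``rng``.
    """
    labels = data.labels if isinstance(data, SpectraMatrix) else np.asarray(data)
    if labels is None:
        raise ValueError("split_dataset needs labels")
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n = len(idx)
        if n < 6:
            raise ValueError(f"class {cls} has only {n} members; need at least 6")
        n_val = n_test = n // 6
        perm = rng.permutation(idx)
        val.append(perm[:n_val])
        test.append(perm[n_val:n_val + n_test])
        train.append(perm[n_val + n_test:])
    return SplitBundle(train=np.sort(np.concatenate(train)),
                       val=np.sort(np.concatenate(val)),
                       test=np.sort(np.concatenate(test)),
                       seed=seed)


@dataclass(frozen=True)
class ClassSpectralSummary:
    """Per-class mean and population-std reflectance curves."""

    classes: np.ndarray
    mean: np.ndarray   # (n_classes, B)
    std: np.ndarray    # (n_classes, B)


def class_mean_std(data: SpectraMatrix) -> ClassSpectralSummary:
    """Per-class, per-band arithmetic mean and population standard deviation
    (the descriptive summary plotted as mean curves with std shading)."""
    if data.labels is None:
        raise ValueError("class_mean_std needs labels")
    classes = np.unique(data.labels)
    means, stds = [], []
    for cls in classes:
        block = data.spectra[data.labels == cls]
        if len(block) < 2:
            raise ValueError(f"class {cls} has fewer than 2 spectra")
        means.append(block.mean(axis=0))
        stds.append(block.std(axis=0))  # population (ddof=0)
    return ClassSpectralSummary(classes=classes, mean=np.vstack(means),
                                std=np.vstack(stds))
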