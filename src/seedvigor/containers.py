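"""Shared data containers for the seed-vigor pipeline.

The NIR camera produces hypercubes of shape (H, W, B): two spatial axes and a
spectral axis. After reflectance calibration and band trimming, each seed's
region of interest is averaged into a single length-181 reflectance vector;
those vectors, their 3-class aging labels (0 = not aged, 1 = aged 96 h,
2 = aged 192 h) and a variety tag form a :class:`SpectraMatrix`, the unit of
data every model in the package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_ALL_BANDS = 224
N_RETAINED_BANDS = 181
RETAINED_LO_NM = 998.0
RETAINED_HI_NM = 1631.0
#: index window (inclusive) of the retained bands within the full 224-band axis
RETAINED_INDEX_WINDOW = (28, 208)

CLASS_NAMES = ("not_aged", "aged_96h", "aged_192h")


@dataclass(frozen=True)
class WavelengthGrid:
    """The camera's 224-band wavelength axis and its retained 181-band window."""

    all_nm: np.ndarray
    retained_index_window: tuple[int, int]
    retained_nm: np.ndarray

    def __post_init__(self):
        if len(self.all_nm) != N_ALL_BANDS:
            raise ValueError(f"expected {N_ALL_BANDS} bands, got {len(self.all_nm)}")
        if len(self.retained_nm) != N_RETAINED_BANDS:
            raise ValueError(
                f"expected {N_RETAINED_BANDS} retained bands, got {len(self.retained_nm)}")
        if not np.all(np.diff(self.all_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def spacing_nm(self) -> float:
        return float(self.retained_nm[1] - self.retained_nm[0])


@dataclass
class Hypercube:
    """An (H, W, B) spectral image, raw digital numbers or calibrated reflectance."""

    values: np.ndarray
    grid: WavelengthGrid
    calibrated: bool = False

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("hypercube values must be (H, W, B)")
        b = self.values.shape[2]
        n_grid = (N_RETAINED_BANDS if b == N_RETAINED_BANDS else N_ALL_BANDS)
        if b != n_grid:
            raise ValueError(f"band count {b} is neither {N_ALL_BANDS} nor {N_RETAINED_BANDS}")
        if self.calibrated and not np.all(np.isfinite(self.values)):
            raise ValueError("calibrated cube contains non-finite values")

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def wavelengths_nm(self) -> np.ndarray:
        if self.n_bands == N_RETAINED_BANDS:
            return self.grid.retained_nm
        return self.grid.all_nm

    def band_mean_image(self) -> np.ndarray:
        return self.values.mean(axis=2)


@dataclass
class ROIMask:
    """Boolean pixel mask of a single seed."""

    mask: np.ndarray
    seed_id: int

    def __post_init__(self):
        if self.mask.dtype != bool or self.mask.ndim != 2:
            raise ValueError("ROI mask must be a 2D boolean array")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SpectraMatrix:
    """N mean seed spectra with aging-class labels and a variety (domain) tag."""

    spectra: np.ndarray
    labels: np.ndarray | None = None
    domain: str = ""

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be an (N, B) matrix")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain missing/non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.spectra):
                raise ValueError("labels length does not match spectra rows")
            if self.labels.size and not np.isin(self.labels, [0, 1, 2]).all():
                raise ValueError("labels must be in {0, 1, 2}")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]


@dataclass(frozen=True)
class SplitBundle:
    """Disjoint train/validation/test row indices covering a SpectraMatrix."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        parts = [set(self.train.tolist()), set(self.val.tolist()), set(self.test.tolist())]
        total = len(self.train) + len(self.val) + len(self.test)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split index sets overlap")

    @property
    def n(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)


@dataclass(frozen=True)
class GerminationRecord:
    """Germination-assay outcome for one variety x aging-time cohort."""

    variety: str
    aging_class: str
    n_total: int
    n_nonviable: int

    def __post_init__(self):
        if not 0 <= self.n_nonviable <= self.n_total:
            raise ValueError("need 0 <= n_nonviable <= n_total")
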