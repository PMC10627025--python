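"""Synthetic NIR hyperspectral seed data with the structure the analysis assumes.

The generator emulates a push-broom NIR camera imaging rice seeds on a dark
stage: a 224-band wavelength axis of which the 998-1631 nm window (181 bands)
is retained; per-seed reflectance spectra built from a smooth variety-specific
continuum minus Gaussian absorption dips at 1100, 1300 and 1450 nm (C-H second
overtone of carbohydrates, amide combination bands, and the amide A N-H first
overtone); aging-class signal expressed as monotonically deeper absorption in
the 1100-1200 and 1400-1450 nm regions; low across-seed variability near
1350-1400 nm; raw digital-number cubes tied to white/dark reference frames by
the sensor model I = D + R_true (W - D) + noise, so reflectance calibration
inverts the simulation exactly in the noiseless limit; and binomial
non-viability counts matching the published germination rates.

Every operation is deterministic given its ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (CLASS_NAMES, N_ALL_BANDS, N_RETAINED_BANDS,
                         RETAINED_HI_NM, RETAINED_INDEX_WINDOW, RETAINED_LO_NM,
                         GerminationRecord, SpectraMatrix, WavelengthGrid)
from .reference_tables import GERMINATION_TABLE, SEED_COUNTS

__all__ = [
    "VarietyStyle", "SceneSpec", "SimulatedScene", "NoiseConfig",
    "make_wavelength_grid", "continuum", "simulate_seed_spectrum",
    "simulate_hypercube", "simulate_germination_labels", "make_domain_dataset",
    "default_styles", "shifted_style", "style_pair",
]

# Gaussian dip widths (nm) for the three absorption features
FEATURE_WIDTHS_NM = {1100.0: 30.0, 1300.0: 40.0, 1450.0: 25.0}
#: wavelength at which per-seed smooth noise vanishes, producing the quiet
#: low-variability region observed at 1350-1400 nm
QUIET_NM = 1375.0


def make_wavelength_grid() -> WavelengthGrid:
    """The camera wavelength axis: 224 bands, retained window 998-1631 nm.

    The retained window (indices 28..208, 181 bands) is defined as uniformly
    spaced with both endpoints exact; the full axis extends that spacing to
    224 bands, covering the camera's nominal 900-1700 nm range.
    """
    lo, hi = RETAINED_INDEX_WINDOW
    retained = np.linspace(RETAINED_LO_NM, RETAINED_HI_NM, N_RETAINED_BANDS)
    spacing = (RETAINED_HI_NM - RETAINED_LO_NM) / (N_RETAINED_BANDS - 1)
    all_nm = np.empty(N_ALL_BANDS)
    all_nm[lo:hi + 1] = retained
    all_nm[:lo] = RETAINED_LO_NM - spacing * np.arange(lo, 0, -1)
    n_right = N_ALL_BANDS - hi - 1
    all_nm[hi + 1:] = RETAINED_HI_NM + spacing * np.arange(1, n_right + 1)
    return WavelengthGrid(all_nm=all_nm, retained_index_window=(lo, hi),
                          retained_nm=retained)


@dataclass(frozen=True)
class VarietyStyle:
    """Domain-level spectral 'style' of one rice variety.

    ``feature_depths`` maps a dip center (nm) to the three per-class depths
    (not aged, 96 h, 192 h); depths are non-decreasing with aging so that more
    aged seeds absorb more strongly at the class-informative bands.
    """

    name: str
    baseline_offset: float = 0.0
    scale: float = 1.0
    smooth_curve_coeffs: tuple[float, ...] = (0.0,)
    feature_depths: dict[float, tuple[float, float, float]] = field(
        default_factory=dict)

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("style scale must be positive")
        for center, depths in self.feature_depths.items():
            if not (depths[0] <= depths[1] <= depths[2]):
                raise ValueError(
                    f"feature depths at {center} nm must be monotone in aging class")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-seed spectral noise: white sensor noise, a smooth random trend that
    vanishes at ``QUIET_NM``, and multiplicative jitter of the dip depths."""

    white_sd: float = 0.012
    smooth_sd: float = 0.02
    depth_jitter: float = 0.12


def _resolve_class(aging_class: int | str) -> int:
    if isinstance(aging_class, str):
        if aging_class not in CLASS_NAMES:
            raise ValueError(f"unknown aging class {aging_class!r}")
        return CLASS_NAMES.index(aging_class)
    k = int(aging_class)
    if k not in (0, 1, 2):
        raise ValueError(f"aging class must be 0, 1 or 2, got {k}")
    return k


def _base_shape(t: np.ndarray) -> np.ndarray:
    # generic bright-seed NIR reflectance continuum on t = (nm-998)/633
    return 0.48 + 0.12 * t - 0.10 * t ** 2


def continuum(style: VarietyStyle, nm: np.ndarray) -> np.ndarray:
    """Dip-free, noise-free reflectance continuum of a variety."""
    t = (np.asarray(nm) - RETAINED_LO_NM) / (RETAINED_HI_NM - RETAINED_LO_NM)
    trend = np.polynomial.polynomial.polyval(t, np.asarray(style.smooth_curve_coeffs))
    return style.baseline_offset + style.scale * _base_shape(t) + trend


def _dips(style: VarietyStyle, class_idx: int, nm: np.ndarray,
          depth_factors: dict[float, float] | None = None) -> np.ndarray:
    total = np.zeros_like(nm, dtype=np.float64)
    for center, depths in style.feature_depths.items():
        width = FEATURE_WIDTHS_NM.get(center, 30.0)
        depth = depths[class_idx]
        if depth_factors is not None:
            depth = depth * depth_factors[center]
        total += depth * np.exp(-((nm - center) ** 2) / (2.0 * width ** 2))
    return total


def _spectrum_on(nm: np.ndarray, style: VarietyStyle, class_idx: int,
                 rng: np.random.Generator, noise: NoiseConfig) -> np.ndarray:
    t = (nm - RETAINED_LO_NM) / (RETAINED_HI_NM - RETAINED_LO_NM)
    t0 = (QUIET_NM - RETAINED_LO_NM) / (RETAINED_HI_NM - RETAINED_LO_NM)
    factors = None
    if noise.depth_jitter > 0:
        factors = {c: 1.0 + noise.depth_jitter * rng.standard_normal()
                   for c in style.feature_depths}
    spec = continuum(style, nm) - _dips(style, class_idx, nm, factors)
    if noise.smooth_sd > 0:
        b1, b2 = rng.normal(0.0, noise.smooth_sd, size=2)
        spec = spec + b1 * (t - t0) + b2 * (t - t0) ** 2
    if noise.white_sd > 0:
        spec = spec + rng.normal(0.0, noise.white_sd, size=nm.shape)
    return np.clip(spec, 1e-4, 1.2 - 1e-4)


def simulate_seed_spectrum(style: VarietyStyle, aging_class: int | str,
                           rng: np.random.Generator,
                           grid: WavelengthGrid | None = None,
                           noise: NoiseConfig = NoiseConfig()) -> np.ndarray:
    """One seed's mean reflectance spectrum on the 181 retained bands."""
    grid = grid or make_wavelength_grid()
    k = _resolve_class(aging_class)
    return _spectrum_on(grid.retained_nm, style, k, rng, noise)


# ---------------------------------------------------------------------------
# scene / hypercube simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Layout and sensor parameters for one simulated acquisition."""

    height: int = 64
    width: int = 64
    n_seeds: int = 6
    seed_semi_axes: tuple[float, float] = (4.0, 7.0)
    background_reflectance: float = 0.05
    noise_sd: float = 0.005
    max_attempts: int = 2000

    def __post_init__(self):
        if self.n_seeds < 0 or self.height < 4 or self.width < 4:
            raise ValueError("invalid scene geometry")


@dataclass
class SimulatedScene:
    """Raw cube plus reference frames and generating truth."""

    raw: np.ndarray            # I, (H, W, 224) digital numbers
    white: np.ndarray          # W, same shape
    dark: np.ndarray           # D, same shape
    r_true: np.ndarray         # generating reflectance cube
    masks: list[np.ndarray]    # per-seed boolean truth masks
    seed_spectra: np.ndarray   # (n_seeds, 224) generating spectra
    classes: np.ndarray        # (n_seeds,) aging classes
    grid: WavelengthGrid


def _place_ellipses(spec: SceneSpec, rng: np.random.Generator
                    ) -> list[tuple[float, float, float, float]]:
    """Non-overlapping axis-aligned ellipses; rejection sampling on centers."""
    placed: list[tuple[float, float, float, float]] = []
    lo, hi = spec.seed_semi_axes
    attempts = 0
    while len(placed) < spec.n_seeds:
        if attempts >= spec.max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_seeds} non-overlapping seeds in a "
                f"{spec.height}x{spec.width} scene after {spec.max_attempts} attempts")
        attempts += 1
        a = rng.uniform(lo, hi)   # row semi-axis
        b = rng.uniform(lo, hi)   # col semi-axis
        cr = rng.uniform(a + 1, spec.height - a - 1)
        cc = rng.uniform(b + 1, spec.width - b - 1)
        ok = True
        for (pr, pc, pa, pb) in placed:
            # conservative disjointness: bounding circles with a 1-px margin
            if np.hypot(cr - pr, cc - pc) < max(a, b) + max(pa, pb) + 1.0:
                ok = False
                break
        if ok:
            placed.append((cr, cc, a, b))
    return placed


def simulate_hypercube(scene: SceneSpec, style: VarietyStyle,
                       classes: np.ndarray | list[int],
                       rng: np.random.Generator,
                       grid: WavelengthGrid | None = None,
                       noise: NoiseConfig = NoiseConfig()) -> SimulatedScene:
    """Simulate one acquisition: raw cube I, references W and D, truth masks.

    The sensor model is ``I = D + R_true (W - D) + eta`` with white noise eta
    of standard deviation ``scene.noise_sd`` in reflectance units, so
    reflectance calibration recovers ``R_true`` exactly when the noise is zero.
    """
    grid = grid or make_wavelength_grid()
    classes = np.asarray([_resolve_class(c) for c in classes], dtype=np.int64)
    if len(classes) != scene.n_seeds:
        raise ValueError("need one aging class per seed")
    nm = grid.all_nm
    b = len(nm)
    h, w = scene.height, scene.width

    ellipses = _place_ellipses(scene, rng)
    r_true = np.full((h, w, b), scene.background_reflectance, dtype=np.float64)
    masks: list[np.ndarray] = []
    spectra = np.zeros((scene.n_seeds, b))
    rr, cc = np.mgrid[0:h, 0:w]
    for i, ((er, ec, a, bb), k) in enumerate(zip(ellipses, classes)):
        mask = ((rr - er) / a) ** 2 + ((cc - ec) / bb) ** 2 <= 1.0
        spec = _spectrum_on(nm, style, int(k), rng, noise=replace(noise, white_sd=0.0))
        masks.append(mask)
        spectra[i] = spec
        r_true[mask] = spec

    # reference frames: spatially flat, band-dependent illumination
    t = (nm - nm[0]) / (nm[-1] - nm[0])
    dark = np.broadcast_to(100.0 + 5.0 * t, (h, w, b)).copy()
    white = np.broadcast_to(3000.0 + 500.0 * t, (h, w, b)).copy()

    raw = dark + r_true * (white - dark)
    if scene.noise_sd > 0:
        raw = raw + scene.noise_sd * (white - dark) * rng.standard_normal(raw.shape)
    return SimulatedScene(raw=raw, white=white, dark=dark, r_true=r_true,
                          masks=masks, seed_spectra=spectra, classes=classes,
                          grid=grid)


# ---------------------------------------------------------------------------
# germination labels
# ---------------------------------------------------------------------------

def simulate_germination_labels(variety: str, aging_class: int | str,
                                n_total: int, rate: float,
                                rng: np.random.Generator) -> GerminationRecord:
    """Binomial non-viability count for one variety x aging cohort."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"non-viable rate must be in [0, 1], got {rate}")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    k = _resolve_class(aging_class)
    n_nonviable = int(rng.binomial(n_total, rate))
    return GerminationRecord(variety=variety, aging_class=CLASS_NAMES[k],
                             n_total=n_total, n_nonviable=n_nonviable)


def simulate_germination_table(rng: np.random.Generator
                               ) -> list[GerminationRecord]:
    """Binomial germination outcomes at the published cohort sizes and rates."""
    out = []
    for (variety, cls), (_, rate) in GERMINATION_TABLE.items():
        n_total = SEED_COUNTS[(variety, cls)]
        out.append(simulate_germination_labels(variety, cls, n_total, rate, rng))
    return out


# ---------------------------------------------------------------------------
# labelled datasets and style presets
# ---------------------------------------------------------------------------

def make_domain_dataset(style: VarietyStyle, n_per_class: int,
                        rng: np.random.Generator,
                        grid: WavelengthGrid | None = None,
                        noise: NoiseConfig = NoiseConfig()) -> SpectraMatrix:
    """Balanced 3-class spectra matrix for one variety (domain).

    Rows are blocked by class (all not-aged seeds first), which makes the
    label layout independent of the style: two styles generated from the same
    seed share the class structure but not the spectra.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    grid = grid or make_wavelength_grid()
    rows, labels = [], []
    for k in range(3):
        for _ in range(n_per_class):
            rows.append(_spectrum_on(grid.retained_nm, style, k, rng, noise))
            labels.append(k)
    return SpectraMatrix(spectra=np.vstack(rows), labels=np.asarray(labels),
                         domain=style.name)


def default_styles() -> dict[str, VarietyStyle]:
    """Style presets for the four varieties.

    Depth separations follow the published qualitative ordering: the first
    variety shows the largest between-class spectral differences and
    suxiangjing100 the smallest, with the class signal concentrated at the
    1100 and 1450 nm features.
    """
    return {
        "yongyou12": VarietyStyle(
            name="yongyou12", baseline_offset=0.0, scale=1.0,
            smooth_curve_coeffs=(0.0, 0.02, -0.015),
            feature_depths={1100.0: (0.050, 0.068, 0.086),
                            1300.0: (0.100, 0.105, 0.110),
                            1450.0: (0.090, 0.115, 0.140)}),
        "yongyou1540": VarietyStyle(
            name="yongyou1540", baseline_offset=0.02, scale=1.04,
            smooth_curve_coeffs=(0.0, -0.01, 0.02),
            feature_depths={1100.0: (0.050, 0.065, 0.080),
                            1300.0: (0.100, 0.104, 0.108),
                            1450.0: (0.085, 0.105, 0.125)}),
        "suxiangjing100": VarietyStyle(
            name="suxiangjing100", baseline_offset=-0.03, scale=0.92,
            smooth_curve_coeffs=(0.0, 0.03, 0.0),
            feature_depths={1100.0: (0.050, 0.057, 0.064),
                            1300.0: (0.100, 0.102, 0.104),
                            1450.0: (0.080, 0.092, 0.104)}),
        "longjingyou1212": VarietyStyle(
            name="longjingyou1212", baseline_offset=0.05, scale=1.10,
            smooth_curve_coeffs=(0.0, -0.02, -0.01),
            feature_depths={1100.0: (0.048, 0.062, 0.076),
                            1300.0: (0.095, 0.100, 0.105),
                            1450.0: (0.085, 0.103, 0.121)}),
    }


def shifted_style(base: VarietyStyle, shift: float,
                  name: str | None = None) -> VarietyStyle:
    """A style displaced from ``base`` by a domain-shift magnitude ``shift``.

    ``shift`` scales an additive baseline offset, a multiplicative gain and a
    curvature change simultaneously; 0 is identity, 1 is a large shift well
    beyond the between-variety differences of the default presets. The class
    structure (feature depths) is left untouched, so shifted pairs share the
    classification task but not the spectral style.
    """
    coeffs = tuple(np.asarray(base.smooth_curve_coeffs, dtype=float)
                   + shift * np.array([0.0, 0.08, -0.06]
                                      )[:len(base.smooth_curve_coeffs)])
    return replace(base,
                   name=name or f"{base.name}_shift{shift:g}",
                   baseline_offset=base.baseline_offset + 0.15 * shift,
                   scale=base.scale * (1.0 + 0.30 * shift),
                   smooth_curve_coeffs=coeffs)


def style_pair(shift: float, base: VarietyStyle | None = None
               ) -> tuple[VarietyStyle, VarietyStyle]:
    """A (source, target) style pair separated by ``shift``; the benchmark
    geometry for the cross-domain transfer experiments."""
    base = base or default_styles()["yongyou12"]
    return base, shifted_style(base, shift, name=f"{base.name}_target")
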