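"""Generator contracts: wavelength grid, spectra, scenes, labels, dials."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from seedvigor.containers import GerminationRecord
from seedvigor.preprocess import calibrate_reflectance
from seedvigor.synthetic import (NoiseConfig, SceneSpec, VarietyStyle,
                                 continuum, default_styles,
                                 make_domain_dataset, make_wavelength_grid,
                                 shifted_style, simulate_germination_labels,
                                 simulate_hypercube, simulate_seed_spectrum)

NOISELESS = NoiseConfig(white_sd=0.0, smooth_sd=0.0, depth_jitter=0.0)


class TestWavelengthGrid:
    def test_retained_window_constants(self, grid):
        assert len(grid.all_nm) == 224
        assert len(grid.retained_nm) == 181
        assert grid.retained_nm[0] == 998.0
        assert grid.retained_nm[180] == 1631.0

    def test_uniform_spacing(self, grid):
        # (1631 - 998) / 180 = 3.5167 nm to 4 dp
        assert round(grid.spacing_nm, 4) == 3.5167
        assert np.allclose(np.diff(grid.all_nm), grid.spacing_nm)

    def test_retained_slice_matches_window(self, grid):
        lo, hi = grid.retained_index_window
        assert (lo, hi) == (28, 208)
        np.testing.assert_array_equal(grid.all_nm[lo:hi + 1], grid.retained_nm)


class TestSeedSpectrum:
    def test_zero_noise_zero_depths_equals_continuum(self, grid):
        style = VarietyStyle(name="flat", feature_depths={})
        spec = simulate_seed_spectrum(style, 0, np.random.default_rng(0),
                                      grid=grid, noise=NOISELESS)
        np.testing.assert_array_equal(spec, continuum(style, grid.retained_nm))

    def test_determinism(self, grid, styles):
        a = simulate_seed_spectrum(styles["yongyou12"], 1,
                                   np.random.default_rng(42), grid=grid)
        b = simulate_seed_spectrum(styles["yongyou12"], 1,
                                   np.random.default_rng(42), grid=grid)
        np.testing.assert_array_equal(a, b)

    def test_class_mean_depth_ordering_at_1450(self, grid, styles):
        """More aged classes have deeper mean absorption at the 1450 nm dip."""
        rng = np.random.default_rng(7)
        band = int(np.argmin(np.abs(grid.retained_nm - 1450.0)))
        means = []
        for cls in range(3):
            spectra = np.vstack([
                simulate_seed_spectrum(styles["yongyou12"], cls, rng, grid=grid)
                for _ in range(500)])
            means.append(spectra[:, band].mean())
        # deeper absorption = lower reflectance at the dip
        assert means[0] > means[1] > means[2]

    def test_values_within_physical_range(self, grid, styles):
        rng = np.random.default_rng(3)
        for cls in range(3):
            spec = simulate_seed_spectrum(styles["longjingyou1212"], cls, rng,
                                          grid=grid)
            assert (spec > 0).all() and (spec < 1.2).all()

    def test_rejects_invalid_class(self, grid, styles):
        with pytest.raises(ValueError):
            simulate_seed_spectrum(styles["yongyou12"], 5,
                                   np.random.default_rng(0), grid=grid)


class TestHypercube:
    def test_noiseless_calibration_roundtrip(self, grid, styles):
        scene = SceneSpec(n_seeds=3, noise_sd=0.0)
        sim = simulate_hypercube(scene, styles["yongyou12"], [0, 1, 2],
                                 np.random.default_rng(5), grid=grid)
        cube = calibrate_reflectance(sim.raw, sim.white, sim.dark, grid=grid)
        np.testing.assert_allclose(cube.values, sim.r_true, atol=1e-12)

    def test_zero_seeds_gives_background_everywhere(self, grid, styles):
        scene = SceneSpec(n_seeds=0, noise_sd=0.0)
        sim = simulate_hypercube(scene, styles["yongyou12"], [],
                                 np.random.default_rng(0), grid=grid)
        cube = calibrate_reflectance(sim.raw, sim.white, sim.dark, grid=grid)
        assert np.allclose(cube.values, scene.background_reflectance)

    def test_noisy_calibration_close_on_seed_pixels(self, grid, styles):
        scene = SceneSpec(n_seeds=4, noise_sd=0.005)
        sim = simulate_hypercube(scene, styles["yongyou12"], [0, 1, 2, 0],
                                 np.random.default_rng(9), grid=grid)
        cube = calibrate_reflectance(sim.raw, sim.white, sim.dark, grid=grid)
        seed_px = np.zeros(sim.raw.shape[:2], dtype=bool)
        for m in sim.masks:
            seed_px |= m
        err = np.abs(cube.values[seed_px] - sim.r_true[seed_px])
        assert (err < 0.02).mean() >= 0.99

    def test_white_exceeds_dark_everywhere(self, grid, styles):
        sim = simulate_hypercube(SceneSpec(n_seeds=2), styles["yongyou12"],
                                 [0, 1], np.random.default_rng(1), grid=grid)
        assert (sim.white > sim.dark).all()

    def test_overcrowded_scene_rejected(self, grid, styles):
        scene = SceneSpec(height=24, width=24, n_seeds=30, max_attempts=50)
        with pytest.raises(RuntimeError):
            simulate_hypercube(scene, styles["yongyou12"], [0] * 30,
                               np.random.default_rng(0), grid=grid)


class TestGerminationLabels:
    @pytest.mark.parametrize("rate,expected", [(0.0, 0), (1.0, 600)])
    def test_degenerate_rates(self, rate, expected):
        rec = simulate_germination_labels("yongyou12", 0, 600, rate,
                                          np.random.default_rng(0))
        assert rec.n_nonviable == expected

    def test_binomial_mean_matches_published_cohort(self):
        """600 seeds at rate 0.4850: replicate mean within 3 SEs of 291."""
        rng = np.random.default_rng(123)
        counts = rng.binomial(600, 0.4850, size=10_000)
        se = np.sqrt(600 * 0.4850 * 0.5150) / np.sqrt(10_000)
        assert abs(counts.mean() - 291) < 3 * se
        rec = simulate_germination_labels("yongyou12", 1, 600, 0.4850,
                                          np.random.default_rng(4))
        assert isinstance(rec, GerminationRecord)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_germination_labels("x", 0, 10, 1.5, np.random.default_rng(0))


class TestDomainDataset:
    def test_row_counts(self, grid, styles):
        data = make_domain_dataset(styles["yongyou12"], 600,
                                   np.random.default_rng(0), grid=grid)
        assert len(data) == 1800

    def test_tiny_dataset_label_layout(self, grid, styles):
        data = make_domain_dataset(styles["yongyou12"], 2,
                                   np.random.default_rng(0), grid=grid)
        np.testing.assert_array_equal(data.labels, [0, 0, 1, 1, 2, 2])

    def test_style_isolation(self, grid, styles):
        a = make_domain_dataset(styles["yongyou12"], 5,
                                np.random.default_rng(8), grid=grid)
        b = make_domain_dataset(styles["suxiangjing100"], 5,
                                np.random.default_rng(8), grid=grid)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert not np.allclose(a.spectra, b.spectra)

    def test_determinism(self, grid, styles):
        a = make_domain_dataset(styles["yongyou1540"], 4,
                                np.random.default_rng(2), grid=grid)
        b = make_domain_dataset(styles["yongyou1540"], 4,
                                np.random.default_rng(2), grid=grid)
        np.testing.assert_array_equal(a.spectra, b.spectra)


def _lr_accuracy(train, test):
    scaler = StandardScaler().fit(train.spectra)
    clf = LogisticRegression(max_iter=2000).fit(
        scaler.transform(train.spectra), train.labels)
    return (clf.predict(scaler.transform(test.spectra)) == test.labels).mean()


class TestGeneratorDials:
    def test_separability_dial(self, grid):
        """Wider class depth separation raises a reference classifier's accuracy."""
        accs = []
        for sep in (0.2, 1.0, 3.0):
            style = VarietyStyle(
                name=f"sep{sep}",
                feature_depths={1450.0: (0.09, 0.09 + 0.01 * sep,
                                         0.09 + 0.02 * sep)})
            train = make_domain_dataset(style, 80, np.random.default_rng(21),
                                        grid=grid)
            test = make_domain_dataset(style, 40, np.random.default_rng(22),
                                       grid=grid)
            accs.append(_lr_accuracy(train, test))
        assert accs[0] < accs[1] < accs[2]

    def test_style_shift_dial(self, grid, styles):
        """Larger style divergence lowers naive cross-domain accuracy."""
        base = styles["yongyou12"]
        train = make_domain_dataset(base, 80, np.random.default_rng(31),
                                    grid=grid)
        accs = []
        for shift in (0.0, 0.05, 0.5):
            target = shifted_style(base, shift)
            test = make_domain_dataset(target, 40, np.random.default_rng(32),
                                       grid=grid)
            accs.append(_lr_accuracy(train, test))
        assert accs[0] > accs[1] > accs[2]
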