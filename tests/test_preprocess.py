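"""Calibration, trimming, segmentation, ROI averaging, splitting, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedvigor.containers import Hypercube, ROIMask, SpectraMatrix
from seedvigor.preprocess import (ZeroDenominatorError, calibrate_reflectance,
                                  class_mean_std, extract_mean_spectra,
                                  segment_seeds, split_dataset, trim_bands)
from seedvigor.synthetic import SceneSpec, simulate_hypercube


def _frames(grid, shape=(4, 5, 224)):
    rng = np.random.default_rng(0)
    dark = 100.0 + rng.random(shape)
    white = 3000.0 + rng.random(shape)
    return white, dark


class TestCalibration:
    def test_identity_points(self, grid):
        white, dark = _frames(grid)
        assert np.allclose(
            calibrate_reflectance(white, white, dark, grid=grid).values, 1.0)
        assert np.allclose(
            calibrate_reflectance(dark, white, dark, grid=grid).values, 0.0)
        mid = (white + dark) / 2
        assert np.allclose(
            calibrate_reflectance(mid, white, dark, grid=grid).values, 0.5)

    def test_zero_denominator_reported_with_coordinates(self, grid):
        white, dark = _frames(grid)
        white[1, 2, 3] = dark[1, 2, 3]
        with pytest.raises(ZeroDenominatorError) as err:
            calibrate_reflectance(dark, white, dark, grid=grid)
        assert (1, 2, 3) == tuple(err.value.coords[0])

    def test_shape_mismatch(self, grid):
        white, dark = _frames(grid)
        with pytest.raises(ValueError, match="shape"):
            calibrate_reflectance(dark[:2], white, dark, grid=grid)

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0),
           seed=st.integers(0, 2**20))
    def test_affine_invariance(self, grid, a, b, seed):
        """R is unchanged under I,W,D -> aI+b, aW+b, aD+b for a > 0."""
        rng = np.random.default_rng(seed)
        shape = (3, 3, 224)
        dark = 90 + 10 * rng.random(shape)
        white = 2500 + 100 * rng.random(shape)
        raw = dark + rng.random(shape) * (white - dark)
        r1 = calibrate_reflectance(raw, white, dark, grid=grid).values
        r2 = calibrate_reflectance(a * raw + b, a * white + b, a * dark + b,
                                   grid=grid).values
        np.testing.assert_allclose(r1, r2, rtol=1e-9, atol=1e-9)


class TestTrimBands:
    def test_cube_trim(self, grid):
        cube = Hypercube(values=np.random.default_rng(0).random((3, 3, 224)),
                         grid=grid)
        out = trim_bands(cube, grid)
        assert out.n_bands == 181
        assert out.wavelengths_nm[0] == 998.0
        assert out.wavelengths_nm[-1] == 1631.0

    def test_double_trim_rejected(self, grid):
        cube = Hypercube(values=np.zeros((2, 2, 224)), grid=grid)
        once = trim_bands(cube, grid)
        with pytest.raises(ValueError, match="224"):
            trim_bands(once, grid)

    def test_spectra_matrix_trim(self, grid):
        data = SpectraMatrix(spectra=np.ones((4, 224)), labels=[0, 1, 2, 0])
        out = trim_bands(data, grid)
        assert out.n_bands == 181
        np.testing.assert_array_equal(out.labels, data.labels)


class TestSegmentation:
    def test_blank_scene_yields_empty_list(self, grid):
        cube = Hypercube(values=np.full((16, 16, 181), 0.05), grid=grid,
                         calibrated=True)
        assert segment_seeds(cube) == []

    def test_recovers_simulated_seeds(self, grid, styles):
        scene = SceneSpec(n_seeds=5, noise_sd=0.005)
        sim = simulate_hypercube(scene, styles["yongyou12"], [0, 1, 2, 0, 1],
                                 np.random.default_rng(17), grid=grid)
        cube = trim_bands(
            calibrate_reflectance(sim.raw, sim.white, sim.dark, grid=grid),
            grid)
        masks = segment_seeds(cube)
        assert len(masks) == scene.n_seeds
        # each recovered mask overlaps some truth mask with Jaccard >= 0.8
        for roi in masks:
            best = max(
                (roi.mask & t).sum() / (roi.mask | t).sum() for t in sim.masks)
            assert best >= 0.8


class TestExtractMeanSpectra:
    def test_single_pixel_mask_verbatim(self, grid):
        values = np.random.default_rng(0).random((4, 4, 181))
        cube = Hypercube(values=values, grid=grid, calibrated=True)
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 3] = True
        out = extract_mean_spectra(cube, [ROIMask(mask=mask, seed_id=0)])
        np.testing.assert_array_equal(out.spectra[0], values[2, 3])

    def test_constant_region_gives_constant(self, grid):
        cube = Hypercube(values=np.full((4, 4, 181), 0.7), grid=grid,
                         calibrated=True)
        mask = np.ones((4, 4), dtype=bool)
        out = extract_mean_spectra(cube, [ROIMask(mask=mask, seed_id=0)])
        assert np.allclose(out.spectra[0], 0.7)

    def test_noiseless_simulator_roundtrip(self, grid, styles):
        """Segment + average a noiseless scene: exact generating spectra back."""
        scene = SceneSpec(n_seeds=3, noise_sd=0.0)
        sim = simulate_hypercube(scene, styles["yongyou1540"], [0, 1, 2],
                                 np.random.default_rng(23), grid=grid)
        cube = calibrate_reflectance(sim.raw, sim.white, sim.dark, grid=grid)
        rows = extract_mean_spectra(
            cube, [ROIMask(mask=m, seed_id=i) for i, m in enumerate(sim.masks)])
        np.testing.assert_allclose(rows.spectra, sim.seed_spectra, atol=1e-10)

    def test_mean_commutes_with_calibration_noiseless(self, grid, styles):
        scene = SceneSpec(n_seeds=2, noise_sd=0.0)
        sim = simulate_hypercube(scene, styles["yongyou12"], [0, 2],
                                 np.random.default_rng(29), grid=grid)
        masks = [ROIMask(mask=m, seed_id=i) for i, m in enumerate(sim.masks)]
        cal = calibrate_reflectance(sim.raw, sim.white, sim.dark, grid=grid)
        mean_then = extract_mean_spectra(cal, masks).spectra
        raw_means = np.vstack([sim.raw[m.mask].mean(axis=0) for m in masks])
        w = sim.white[0, 0]
        d = sim.dark[0, 0]
        then_mean = (raw_means - d) / (w - d)
        np.testing.assert_allclose(mean_then, then_mean, atol=1e-10)


class TestSplit:
    def test_balanced_1800(self):
        labels = np.repeat([0, 1, 2], 600)
        split = split_dataset(labels, np.random.default_rng(0))
        assert (len(split.train), len(split.val), len(split.test)) == (1200, 300, 300)

    @pytest.mark.parametrize("n,expected", [(6, (4, 1, 1)), (7, (5, 1, 1))])
    def test_remainder_to_train(self, n, expected):
        split = split_dataset(np.zeros(n, dtype=int), np.random.default_rng(0))
        assert (len(split.train), len(split.val), len(split.test)) == expected

    def test_class_too_small(self):
        with pytest.raises(ValueError, match="at least 6"):
            split_dataset(np.array([0] * 6 + [1] * 5), np.random.default_rng(0))

    @settings(max_examples=30, deadline=None)
    @given(sizes=st.lists(st.integers(6, 40), min_size=1, max_size=3),
           seed=st.integers(0, 2**20))
    def test_disjoint_cover_and_determinism(self, sizes, seed):
        labels = np.concatenate([np.full(n, k) for k, n in enumerate(sizes)])
        s1 = split_dataset(labels, np.random.default_rng(seed))
        s2 = split_dataset(labels, np.random.default_rng(seed))
        all_idx = np.sort(np.concatenate([s1.train, s1.val, s1.test]))
        np.testing.assert_array_equal(all_idx, np.arange(len(labels)))
        np.testing.assert_array_equal(s1.train, s2.train)
        np.testing.assert_array_equal(s1.test, s2.test)


class TestClassMeanStd:
    def test_identical_spectra_zero_std(self):
        spec = np.tile(np.linspace(0, 1, 181), (4, 1))
        data = SpectraMatrix(spectra=spec, labels=[0, 0, 1, 1])
        out = class_mean_std(data)
        assert np.allclose(out.std, 0.0)

    def test_symmetric_pair_zero_mean(self):
        v = np.linspace(-0.5, 0.5, 181)
        data = SpectraMatrix(spectra=np.vstack([v, -v]), labels=None)
        data.labels = np.array([0, 0])
        out = class_mean_std(data)
        assert np.allclose(out.mean, 0.0)

    def test_singleton_class_rejected(self):
        data = SpectraMatrix(spectra=np.zeros((3, 181)), labels=[0, 0, 1])
        with pytest.raises(ValueError, match="fewer than 2"):
            class_mean_std(data)

    def test_minimum_std_band_in_quiet_window(self, grid, styles):
        """The band of minimal class-mean std falls in 1350-1400 nm."""
        from seedvigor.synthetic import make_domain_dataset
        data = make_domain_dataset(styles["yongyou12"], 120,
                                   np.random.default_rng(41), grid=grid)
        out = class_mean_std(data)
        mean_std = out.std.mean(axis=0)
        nm = grid.retained_nm[np.argmin(mean_std)]
        assert 1350.0 <= nm <= 1400.0
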