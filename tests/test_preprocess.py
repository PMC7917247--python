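"""Preprocessing: calibration, 3-D Savitzky-Golay, trimming, derivatives,
RGB synthesis, resizing, standardization."""

import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aphidhsi import (
    RawHSI, ReflectanceHSI, calibrate_reflectance, first_derivative,
    make_wavelength_grid, mean_roi_spectrum, resize_sample, sg3d_stencil,
    sg_smooth_3d, standardize_sets, synthesize_rgb, trim_bands,
)

GRID128 = make_wavelength_grid(128, 376, 1044)


def _raw(cube, gray=None, grid=None):
    grid = grid or make_wavelength_grid(cube.shape[0], 400, 900)
    gray = np.full(cube.shape, 100.0) if gray is None else gray
    return RawHSI(cube=cube, grid=grid, gray_reference=gray)


class TestCalibration:
    def test_gray_panel_pixel_maps_to_half(self):
        gray = np.full((4, 3, 3), 123.0)
        refl = calibrate_reflectance(_raw(gray.copy(), gray))
        assert np.allclose(refl.cube, 0.5)

    @pytest.mark.parametrize("factor,expected", [(0.0, 0.0), (2.0, 1.0)])
    def test_formula_endpoints(self, factor, expected):
        gray = np.full((4, 3, 3), 50.0)
        refl = calibrate_reflectance(_raw(factor * gray, gray))
        assert np.allclose(refl.cube, expected)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_calibration_is_linear(self, a):
        rng = np.random.default_rng(0)
        cube = rng.random((4, 3, 3)) * 200
        gray = rng.random((4, 3, 3)) * 100 + 1
        one = calibrate_reflectance(_raw(cube, gray)).cube
        scaled = calibrate_reflectance(_raw(a * cube, gray)).cube
        assert np.allclose(scaled, a * one)

    def test_nonpositive_gray_rejected(self):
        gray = np.full((4, 3, 3), 100.0)
        gray[0, 0, 0] = 0.0
        with pytest.raises(ValueError):
            calibrate_reflectance(_raw(np.ones((4, 3, 3)), gray))


class TestSavitzkyGolay3D:
    def test_stencil_weights_sum_to_one_and_are_symmetric(self):
        w = sg3d_stencil(5, 3)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        for axis in range(3):
            assert np.allclose(w, np.flip(w, axis=axis))

    def test_constant_cube_unchanged_exactly(self):
        cube = np.full((6, 6, 6), 3.25)
        assert np.allclose(sg_smooth_3d(cube), cube, atol=1e-12)

    def test_total_degree_three_field_reproduced(self):
        """f(b,i,j) = b^3 + 2 i^2 j - j lies in the fit space, so interior
        voxels must pass through unchanged to machine precision."""
        b, i, j = np.mgrid[0:9, 0:9, 0:9].astype(float)
        cube = b ** 3 + 2 * i ** 2 * j - j
        out = sg_smooth_3d(cube)
        interior = (slice(2, -2),) * 3
        assert np.allclose(out[interior], cube[interior], atol=1e-8)

    def test_matches_normal_equations_oracle_at_random_voxels(self):
        """Brute-force least-squares polynomial fit as the independent oracle."""
        rng = np.random.default_rng(0)
        cube = rng.random((9, 9, 9))
        out = sg_smooth_3d(cube)
        offsets = np.array(list(itertools.product(range(-2, 3), repeat=3)), float)
        exps = [(a, b, c) for a in range(4) for b in range(4 - a)
                for c in range(4 - a - b)]
        X = np.stack([offsets[:, 0] ** a * offsets[:, 1] ** b * offsets[:, 2] ** c
                      for a, b, c in exps], axis=1)
        for _ in range(25):
            cb, ci, cj = rng.integers(2, 7, size=3)
            y = np.array([cube[cb + int(o[0]), ci + int(o[1]), cj + int(o[2])]
                          for o in offsets])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            fitted_center = beta[exps.index((0, 0, 0))]
            assert out[cb, ci, cj] == pytest.approx(fitted_center, rel=1e-8)

    @pytest.mark.parametrize("kernel,order", [(4, 3), (5, 5), (5, 7)])
    def test_invalid_kernel_configurations(self, kernel, order):
        with pytest.raises(ValueError):
            sg_smooth_3d(np.zeros((8, 8, 8)), kernel, order)

    def test_cube_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            sg_smooth_3d(np.zeros((4, 8, 8)))


class TestTrimBands:
    def test_default_trim_keeps_100_bands(self):
        hsi = ReflectanceHSI(np.zeros((128, 4, 4)), GRID128)
        trimmed = trim_bands(hsi)
        assert trimmed.cube.shape[0] == 100
        assert trimmed.grid.centers[0] >= 461 and trimmed.grid.centers[-1] <= 988

    def test_full_range_trim_is_identity(self):
        hsi = ReflectanceHSI(np.arange(128 * 4).reshape(128, 2, 2).astype(float),
                             GRID128)
        trimmed = trim_bands(hsi, 376, 1044)
        assert np.array_equal(trimmed.cube, hsi.cube)

    def test_single_band_closed_interval(self):
        hsi = ReflectanceHSI(np.zeros((128, 2, 2)), GRID128)
        nm = GRID128.centers[50]
        single = trim_bands(hsi, nm, nm)
        assert single.cube.shape[0] == 1
        assert single.grid.centers[0] == nm

    def test_trim_is_idempotent(self):
        hsi = ReflectanceHSI(np.random.default_rng(0).random((128, 2, 2)), GRID128)
        once = trim_bands(hsi)
        twice = trim_bands(once)
        assert np.array_equal(once.cube, twice.cube)

    def test_empty_selection_rejected(self):
        hsi = ReflectanceHSI(np.zeros((128, 2, 2)), GRID128)
        with pytest.raises(ValueError):
            trim_bands(hsi, 2000, 2100)

    def test_mean_spectrum_commutes_with_trimming(self):
        rng = np.random.default_rng(1)
        hsi = ReflectanceHSI(rng.random((128, 5, 5)), GRID128)
        mask = rng.random((5, 5)) > 0.4
        keep = GRID128.indices_in(461, 988)
        a = mean_roi_spectrum(trim_bands(hsi), mask)
        b = mean_roi_spectrum(hsi, mask)[keep]
        assert np.allclose(a, b)


class TestMeanRoiSpectrum:
    def test_uniform_cube(self):
        cube = np.full((6, 4, 4), 2.5)
        mask = np.ones((4, 4), bool)
        assert np.allclose(mean_roi_spectrum(cube, mask), 2.5)

    def test_single_pixel_mask(self):
        cube = np.random.default_rng(0).random((6, 4, 4))
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        assert np.allclose(mean_roi_spectrum(cube, mask), cube[:, 1, 2])

    def test_two_pixel_mean(self):
        cube = np.zeros((3, 2, 2))
        cube[:, 0, 0], cube[:, 1, 1] = 1.0, 3.0
        mask = np.eye(2, dtype=bool)
        assert np.allclose(mean_roi_spectrum(cube, mask), 2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mean_roi_spectrum(np.zeros((3, 2, 2)), np.zeros((2, 2), bool))


class TestFirstDerivative:
    TRIMMED = make_wavelength_grid(128, 376, 1044)

    def test_constant_spectrum_gives_zeros(self):
        g = make_wavelength_grid(10, 400, 900)
        assert np.allclose(first_derivative(np.full(10, 0.3), g), 0.0)

    def test_linear_ramp_gives_slope_everywhere(self):
        g = make_wavelength_grid(10, 400, 900)
        s = 0.004
        spectrum = s * g.centers + 1.0
        assert np.allclose(first_derivative(spectrum, g), s)

    def test_sine_derivative_matches_analytic_cosine(self):
        from aphidhsi.preprocess import trim_bands as _trim
        hsi = ReflectanceHSI(np.zeros((128, 2, 2)), self.TRIMMED)
        g = _trim(hsi).grid
        spectrum = np.sin(2 * np.pi * g.centers / 200.0)
        analytic = (2 * np.pi / 200.0) * np.cos(2 * np.pi * g.centers / 200.0)
        numeric = first_derivative(spectrum, g)
        assert np.max(np.abs(numeric - analytic)) < 0.002

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            first_derivative(np.array([1.0, 2.0]), make_wavelength_grid(2, 400, 500))


class TestSynthesizeRgb:
    def test_channel_assignment(self):
        cube = np.full((128, 4, 4), 0.1)
        g_idx = GRID128.band_index(548)
        cube[g_idx] = 0.9
        rgb = synthesize_rgb(ReflectanceHSI(cube, GRID128))
        means = rgb.pixels.mean(axis=(0, 1))
        assert means[1] >= means[0] and means[1] >= means[2]

    def test_spectrally_flat_cube_gives_identical_channels(self):
        rng = np.random.default_rng(0)
        frame = rng.random((4, 4))
        cube = np.broadcast_to(frame, (128, 4, 4)).copy()
        rgb = synthesize_rgb(ReflectanceHSI(cube, GRID128))
        assert np.allclose(rgb.pixels[..., 0], rgb.pixels[..., 1])
        assert np.allclose(rgb.pixels[..., 1], rgb.pixels[..., 2])

    def test_trimmed_grid_lacks_blue_band(self):
        """After trimming to 461-988 nm the nearest band to 461 nm is farther
        than half a spacing, so synthesis must refuse."""
        hsi = trim_bands(ReflectanceHSI(np.zeros((128, 2, 2)), GRID128))
        with pytest.raises(ValueError):
            synthesize_rgb(hsi)

    def test_channels_scaled_to_unit_interval(self):
        rng = np.random.default_rng(1)
        hsi = ReflectanceHSI(rng.random((128, 6, 6)), GRID128)
        rgb = synthesize_rgb(hsi)
        assert rgb.pixels.min() >= 0 and rgb.pixels.max() <= 1


class TestResize:
    def test_identity_resize_unchanged(self):
        arr = np.random.default_rng(0).random((5, 20, 20))
        assert np.allclose(resize_sample(arr, 20), arr)

    def test_constant_image_stays_constant(self):
        arr = np.full((3, 11, 17), 0.7)
        out = resize_sample(arr, 24)
        assert out.shape == (3, 24, 24)
        assert np.allclose(out, 0.7)

    def test_checkerboard_mean_preserved_within_one_percent(self):
        board = np.indices((64, 64)).sum(axis=0) % 2
        arr = board[None].astype(float)
        out = resize_sample(arr, 32)
        assert out.mean() == pytest.approx(arr.mean(), rel=0.01)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            resize_sample(np.zeros((3, 1, 5)), 8)


class TestStandardize:
    def test_train_statistics_and_no_leakage(self):
        rng = np.random.default_rng(0)
        tr, va, te = rng.random((30, 8)), rng.random((10, 8)) + 1.0, rng.random((10, 8))
        str_, sva, ste, (mean, sd) = standardize_sets(tr, va, te)
        assert np.allclose(str_.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(str_.std(axis=0), 1, atol=1e-9)
        # validation was shifted by +1, so its standardized mean is far from 0
        assert np.abs(sva.mean(axis=0)).min() > 0.5

    def test_degenerate_single_sample_floors_all_features(self, caplog):
        tr = np.ones((1, 4))
        with caplog.at_level(logging.WARNING):
            str_, sva, ste, (mean, sd) = standardize_sets(tr, tr, tr)
        assert np.all(sd == 1e-8)
        assert any("floored" in r.message for r in caplog.records)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            standardize_sets(np.zeros((0, 3)), np.zeros((1, 3)), np.zeros((1, 3)))
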