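"""Synthetic scene generator: grids, spectra, geometry, sensor model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aphidhsi import (
    GeneratorConfig, calibrate_reflectance, generate_dataset,
    make_gray_reference, make_wavelength_grid, reflectance_spectrum,
    render_raw_cube, simulate_scene,
)
from aphidhsi.io_utils import read_envi, write_envi
from aphidhsi.synthetic import HEALTHY, INFECTED, ROLES


@pytest.fixture(scope="module")
def cfg():
    return GeneratorConfig(height=48, width=64, seed=0)


@pytest.fixture(scope="module")
def grid():
    return make_wavelength_grid(128, 376, 1044)


class TestWavelengthGrid:
    def test_default_grid_spacing_and_span(self, grid):
        assert len(grid) == 128
        assert grid.centers[0] == 376 and grid.centers[-1] == 1044
        assert grid.spacing == pytest.approx((1044 - 376) / 127)
        assert grid.centers.min() >= 300 and grid.centers.max() <= 1100

    def test_exactly_100_bands_in_study_range(self, grid):
        # brute-force count of centres inside the closed interval
        count = sum(1 for c in grid.centers if 461 <= c <= 988)
        assert count == 100
        assert len(grid.indices_in(461, 988)) == 100

    def test_two_point_grid_is_its_endpoints(self):
        g = make_wavelength_grid(2, 0, 10)
        assert list(g.centers) == [0, 10]

    @pytest.mark.parametrize("args", [(1, 376, 1044), (0, 376, 1044),
                                      (128, 1044, 376), (128, 500, 500)])
    def test_invalid_grids_rejected(self, args):
        with pytest.raises(ValueError):
            make_wavelength_grid(*args)

    def test_band_index_respects_half_spacing(self, grid):
        assert grid.centers[grid.band_index(548)] == pytest.approx(549.57, abs=0.1)
        with pytest.raises(ValueError):
            make_wavelength_grid(10, 400, 900).band_index(360)


class TestReflectanceSpectrum:
    def test_green_bump_exceeds_red_trough(self, grid, cfg):
        lam = reflectance_spectrum("lamina", HEALTHY, grid, cfg)
        at = lambda nm: lam[np.argmin(np.abs(grid.centers - nm))]
        assert at(550) > at(680)

    def test_class_difference_confined_to_discriminative_range(self, grid, cfg):
        healthy = reflectance_spectrum("lamina", HEALTHY, grid, cfg)
        infected = reflectance_spectrum("lamina", INFECTED, grid, cfg)
        lo, hi = cfg.discriminative_band_range
        outside = (grid.centers < lo) | (grid.centers > hi)
        assert np.all(healthy[outside] == infected[outside])
        inside = (grid.centers > lo + 10) & (grid.centers < hi - 10)
        assert np.all(healthy[inside] > infected[inside])

    def test_secretion_brighter_than_lamina_in_visible(self, grid, cfg):
        vis = grid.centers <= 700
        secretion = reflectance_spectrum("secretion", INFECTED, grid, cfg)
        lamina = reflectance_spectrum("lamina", INFECTED, grid, cfg)
        assert secretion[vis].mean() > lamina[vis].mean()

    def test_all_roles_bounded(self, grid, cfg):
        for role in ROLES:
            for label in (HEALTHY, INFECTED):
                s = reflectance_spectrum(role, label, grid, cfg)
                assert np.all((s >= 0) & (s <= 1.2))

    def test_unknown_role_rejected(self, grid, cfg):
        with pytest.raises(ValueError):
            reflectance_spectrum("stem", HEALTHY, grid, cfg)


class TestSimulateScene:
    def test_healthy_scene_has_no_secretion(self, cfg):
        scene = simulate_scene(cfg, 1, HEALTHY, np.random.default_rng(3))
        assert scene.secretion_mask.sum() == 0

    def test_masks_nested_in_leaf(self, cfg):
        scene = simulate_scene(cfg, 1, INFECTED, np.random.default_rng(4))
        assert not np.any(scene.vein_mask & ~scene.leaf_mask)
        assert not np.any(scene.secretion_mask & ~scene.leaf_mask)
        assert not np.any(scene.edge_mask & ~scene.leaf_mask)
        assert scene.leaf_mask.any() and scene.vein_mask.any()

    def test_same_seed_gives_identical_scene(self, cfg):
        a = simulate_scene(cfg, 2, INFECTED, np.random.default_rng(11))
        b = simulate_scene(cfg, 2, INFECTED, np.random.default_rng(11))
        assert np.array_equal(a.leaf_mask, b.leaf_mask)
        assert np.array_equal(a.secretion_mask, b.secretion_mask)
        assert np.array_equal(a.true_reflectance, b.true_reflectance)

    def test_secretion_fraction_small_but_nonzero(self, cfg):
        fractions = []
        for k in range(50):
            scene = simulate_scene(cfg, 1, INFECTED, np.random.default_rng(k))
            fractions.append(scene.secretion_mask.sum() / scene.leaf_mask.sum())
        fractions = np.array(fractions)
        assert np.all(fractions > 0) and np.all(fractions < 0.4)

    def test_too_small_scene_rejected(self):
        small = GeneratorConfig(height=16, width=64)
        with pytest.raises(ValueError):
            simulate_scene(small, 1, HEALTHY, np.random.default_rng(0))


class TestSensorModel:
    def test_half_reflectance_matches_gray_counts(self, cfg, grid):
        noiseless = GeneratorConfig(**{**cfg.__dict__, "noise_sd": 0.0})
        scene = simulate_scene(noiseless, 1, HEALTHY, np.random.default_rng(0))
        scene.true_reflectance[:] = 0.5
        raw = render_raw_cube(scene, grid, noiseless, np.random.default_rng(0))
        assert np.allclose(raw.cube, raw.gray_reference)

    def test_zero_noise_roundtrip_is_exact(self, cfg, grid):
        noiseless = GeneratorConfig(**{**cfg.__dict__, "noise_sd": 0.0})
        scene = simulate_scene(noiseless, 1, INFECTED, np.random.default_rng(1))
        raw = render_raw_cube(scene, grid, noiseless, np.random.default_rng(1))
        refl = calibrate_reflectance(raw)
        assert np.allclose(refl.cube, scene.true_reflectance, atol=1e-12)

    def test_noise_propagates_at_predicted_level(self, cfg, grid):
        """Reflectance error sd should be noise_sd / (2 I_g) within 10%."""
        scene = simulate_scene(cfg, 1, HEALTHY, np.random.default_rng(2))
        raw = render_raw_cube(scene, grid, cfg, np.random.default_rng(2))
        refl = calibrate_reflectance(raw)
        err = (refl.cube - scene.true_reflectance) * 2.0 * raw.gray_reference
        # counts-domain residual over >=1e4 interior voxels; clipping at zero
        # only affects near-zero counts, excluded via the background level
        sample = err[:, scene.leaf_mask][:, :100].ravel()
        assert sample.size >= 10_000
        assert np.std(sample) == pytest.approx(cfg.noise_sd, rel=0.10)

    def test_gray_reference_strictly_positive(self, grid):
        gray = make_gray_reference(grid, 48, 64)
        assert np.all(gray > 0)


class TestGenerateDataset:
    def test_default_dataset_bookkeeping(self):
        ds = generate_dataset(GeneratorConfig())
        assert len(ds) == 256
        counts = ds.manifest.groupby("class").size()
        assert counts[0] == 125 and counts[1] == 131
        assert ds.manifest["session"].nunique() == 5

    def test_small_config_echoes_counts(self):
        cfg = GeneratorConfig(n_healthy_per_session=(2,), n_infected_per_session=(2,),
                              height=48, width=64, split_quotas=None)
        ds = generate_dataset(cfg)
        assert len(ds.manifest) == 4
        assert set(ds.manifest.columns) >= {"id", "class", "session", "seed", "path"}

    def test_zero_samples_rejected(self):
        cfg = GeneratorConfig(n_healthy_per_session=(0,), n_infected_per_session=(0,),
                              height=48, width=64, split_quotas=None)
        with pytest.raises(ValueError):
            generate_dataset(cfg)

    def test_manifests_reproducible_and_cubes_bit_identical(self):
        cfg = GeneratorConfig(n_healthy_per_session=(1,), n_infected_per_session=(1,),
                              height=48, width=64, split_quotas=None, seed=5)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert a.manifest.equals(b.manifest)
        ra, rb = a.sample(1)[0], b.sample(1)[0]
        assert np.array_equal(ra.cube, rb.cube)

    def test_config_json_roundtrip(self):
        cfg = GeneratorConfig(height=48, width=64, seed=9)
        again = GeneratorConfig.from_json(cfg.to_json())
        assert again == cfg


def test_envi_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    cube = rng.random((5, 7, 9)).astype(np.float32)
    wl = np.linspace(400, 800, 5)
    write_envi(tmp_path / "cube", cube, wl)
    back, wl2 = read_envi(tmp_path / "cube")
    assert np.array_equal(back, cube)
    assert np.allclose(wl2, wl)


@given(st.integers(min_value=2, max_value=200))
def test_grid_spacing_uniform(n_bands):
    g = make_wavelength_grid(n_bands, 400.0, 900.0)
    assert len(g) == n_bands
    assert np.allclose(np.diff(g.centers), (900 - 400) / (n_bands - 1))
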