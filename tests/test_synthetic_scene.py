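"""Synthetic scene generator: geometry, spectral model, determinism."""

import numpy as np
import pytest

from needlespec.chemometrics import default_grid, evaluate, fit_predict, make_split
from needlespec.hsi_core import band_index_range, paper_grid
from needlespec.spectra_extract import mean_spectrum
from needlespec.synthetic_scene import (
    EndmemberModel,
    SceneConfig,
    generate_dataset,
    needle_mask,
    needle_spectrum,
    render_cube,
)


class TestNeedleMask:
    def test_deterministic_under_seed(self):
        m1 = needle_mask(64, 64, 40, np.random.default_rng(0))
        m2 = needle_mask(64, 64, 40, np.random.default_rng(0))
        np.testing.assert_array_equal(m1, m2)

    def test_foreground_fraction_bounds(self):
        m = needle_mask(128, 128, 60, np.random.default_rng(1))
        assert 0.1 <= m.mean() <= 0.6

    def test_degenerate_stroke_count_rejected(self):
        with pytest.raises(ValueError):
            needle_mask(64, 64, 0, np.random.default_rng(0))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            needle_mask(8, 8, 5, np.random.default_rng(0))


class TestNeedleSpectrum:
    def test_high_nitrogen_darkens_450_600(self, grid):
        model = EndmemberModel()
        lo = needle_spectrum({"N": 8, "P": 1.2, "K": 8}, model, grid)
        hi = needle_spectrum({"N": 25, "P": 1.2, "K": 8}, model, grid)
        i0, i1 = band_index_range(grid, 450, 600)
        assert hi[i0:i1 + 1].mean() < lo[i0:i1 + 1].mean()

    def test_visible_mean_strictly_decreasing_in_nitrogen(self, grid):
        model = EndmemberModel()
        i0, i1 = band_index_range(grid, 450, 600)
        means = [
            needle_spectrum({"N": n, "P": 1.2, "K": 8}, model, grid)[
                i0:i1 + 1].mean()
            for n in np.linspace(8, 25, 10)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_zero_depth_equals_baseline(self, grid):
        model = EndmemberModel().zero_depth()
        s = needle_spectrum({"N": 25, "P": 1.6, "K": 12}, model, grid)
        np.testing.assert_array_equal(s, model.baseline(grid))

    def test_potassium_perturbs_only_its_windows(self, grid):
        model = EndmemberModel()
        a = needle_spectrum({"N": 15, "P": 1.2, "K": 4}, model, grid)
        b = needle_spectrum({"N": 15, "P": 1.2, "K": 12}, model, grid)
        diff = np.flatnonzero(np.abs(a - b) > 0)
        lam = grid.values
        in_windows = np.zeros(grid.n_bands, dtype=bool)
        for lo, hi, _ in model.k_windows:
            in_windows |= (lam >= lo) & (lam <= hi)
        assert set(diff) <= set(np.flatnonzero(in_windows))

    def test_red_edge_present(self, grid):
        s = needle_spectrum({"N": 15, "P": 1.2, "K": 8}, EndmemberModel(), grid)
        j0, j1 = band_index_range(grid, 750, 950)
        k0, k1 = band_index_range(grid, 600, 680)
        assert s[j0:j1 + 1].mean() > 2 * s[k0:k1 + 1].mean()

    def test_range_clipped(self, grid):
        s = needle_spectrum({"N": 25, "P": 1.6, "K": 12}, EndmemberModel(), grid)
        assert s.min() >= 0.005 and s.max() <= 0.95


class TestRenderCube:
    def test_noiseless_foreground_equals_needle_spectrum(self, grid):
        cfg = SceneConfig(noise_sd=0.0, scatter_mult=(1.0, 1.0),
                          scatter_add=(0.0, 0.0))
        labels = {"N": 15, "P": 1.2, "K": 8}
        mask = needle_mask(64, 64, 40, np.random.default_rng(0))
        cube = render_cube(mask, labels, cfg, np.random.default_rng(1), grid)
        expected = needle_spectrum(labels, cfg.model, grid)
        fg = cube.reflectance[mask]
        assert np.abs(fg - expected[None, :]).max() < 1e-6

    def test_deterministic_under_seed(self, grid):
        cfg = SceneConfig()
        labels = {"N": 15, "P": 1.2, "K": 8}
        mask = needle_mask(64, 64, 40, np.random.default_rng(0))
        c1 = render_cube(mask, labels, cfg, np.random.default_rng(5), grid)
        c2 = render_cube(mask, labels, cfg, np.random.default_rng(5), grid)
        np.testing.assert_array_equal(c1.reflectance, c2.reflectance)

    def test_mean_foreground_spectrum_close_to_noiseless(self, grid):
        """Averaging ≥1000 noisy pixels beats 3·sd/√n < 0.002 per band."""
        cfg = SceneConfig(height=128, width=128, stroke_count=60,
                          scatter_mult=(1.0, 1.0), scatter_add=(0.0, 0.0))
        labels = {"N": 15, "P": 1.2, "K": 8}
        mask = needle_mask(128, 128, 60, np.random.default_rng(2))
        assert mask.sum() >= 1000
        cube = render_cube(mask, labels, cfg, np.random.default_rng(3), grid)
        expected = needle_spectrum(labels, cfg.model, grid)
        got = mean_spectrum(cube, mask)
        assert np.abs(got - expected).max() < 0.002


class TestGenerateDataset:
    def test_deterministic_labels(self):
        cfg = SceneConfig(seed=7)
        _, _, l1 = generate_dataset(12, cfg)
        _, _, l2 = generate_dataset(12, cfg)
        assert l1.to_csv() == l2.to_csv()

    def test_labels_within_configured_ranges(self, small_dataset):
        cfg, _, _, labels = small_dataset
        assert labels["N_mg_g"].between(*cfg.ranges.N).all()
        assert labels["P_mg_g"].between(0.8, 1.6).all()
        assert labels["K_mg_g"].between(*cfg.ranges.K).all()

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            generate_dataset(5, SceneConfig())


class TestRecoverability:
    def test_plsr_recovers_labels_without_scatter_or_noise(self, grid):
        """The generative map is low-rank and linear in the scaled labels:
        with distortions off, PLSR on mean spectra must recover every
        nutrient almost exactly on held-out samples."""
        cfg = SceneConfig(seed=11, noise_sd=0.0, scatter_mult=(1.0, 1.0),
                          scatter_add=(0.0, 0.0), height=32, width=32,
                          stroke_count=15)
        cubes, masks, labels = generate_dataset(40, cfg, grid)
        X = np.vstack([mean_spectrum(c, m) for c, m in zip(cubes, masks)])
        split = make_split(40, 0.2, seed=0)
        tr, te = np.array(split.train_idx), np.array(split.test_idx)
        for col in ("N_mg_g", "P_mg_g", "K_mg_g"):
            y = labels[col].to_numpy()
            fit = fit_predict(default_grid("plsr", X.shape[1]), X[tr], y[tr],
                              X[te], cv_folds=10, seed=0)
            assert evaluate(y[te], fit.predictions).r2p >= 0.99
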