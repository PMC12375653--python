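"""Reconstruction network: band split, shapes, loss, patches, training."""

import numpy as np
import pytest

from needlespec.hsi_core import HyperCube, paper_grid
from needlespec.recon_model import (
    ReconModelConfig,
    TrainConfig,
    build_model,
    extract_patches,
    load_checkpoint,
    merge_bands,
    mrae_loss,
    reconstruct,
    save_checkpoint,
    split_bands,
    train,
)


class TestSplitBands:
    def test_halves_of_88_bands(self, grid, rng):
        cube = HyperCube(rng.random((4, 4, 176)), grid)
        vis, nir = split_bands(cube)
        assert vis.bands == nir.bands == 88

    def test_merge_restores_cube(self, grid, rng):
        cube = HyperCube(rng.random((4, 4, 176)), grid)
        merged = merge_bands(*split_bands(cube))
        np.testing.assert_array_equal(merged.reflectance, cube.reflectance)
        assert merged.grid == cube.grid

    def test_boundary_wavelengths(self, grid, rng):
        vis, nir = split_bands(HyperCube(rng.random((2, 2, 176)), grid))
        assert vis.grid.values[-1] == pytest.approx(698.2857, abs=1e-3)
        assert nir.grid.values[0] == pytest.approx(701.7143, abs=1e-3)

    def test_odd_band_count_rejected(self):
        from needlespec.hsi_core import make_wavelength_grid
        g = make_wavelength_grid(5, 400, 1000)
        with pytest.raises(ValueError):
            split_bands(HyperCube(np.zeros((2, 2, 5)), g))


class TestBuildModel:
    def test_shape_contract(self, rng):
        model = build_model(ReconModelConfig(channels=8, n_rrg=2,
                                             mrb_scales=3))
        out = model.forward(rng.random((1, 3, 32, 32)))
        assert out.shape == (1, 8, 32, 32)

    def test_out_channels_override(self, rng):
        model = build_model(ReconModelConfig(channels=8, out_channels=88))
        assert model.predict(rng.random((32, 32, 3))).shape == (32, 32, 88)

    def test_parameter_count_reported(self):
        model = build_model(ReconModelConfig(channels=8, out_channels=88))
        assert model.n_parameters() > 0

    def test_zero_input_finite_output(self):
        model = build_model(ReconModelConfig(channels=8))
        out = model.forward(np.zeros((1, 3, 16, 16)))
        assert np.all(np.isfinite(out.data))

    @pytest.mark.parametrize("kwargs", [
        {"channels": 2}, {"n_rrg": 0}, {"mrb_scales": 1},
        {"variant": "unknown"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ReconModelConfig(**kwargs)

    @pytest.mark.parametrize("variant", ["hrnet", "mprnet", "restormer"])
    def test_registry_slots_not_implemented(self, variant):
        with pytest.raises(NotImplementedError):
            build_model(ReconModelConfig(variant=variant))


class TestMraeLoss:
    def test_zero_for_identical(self, rng):
        x = rng.random((1, 4, 8, 8))
        assert mrae_loss(x, x) == 0.0

    def test_hand_calculation(self):
        target = np.full((1, 2, 4, 4), 0.5)
        pred = np.full((1, 2, 4, 4), 0.55)
        assert mrae_loss(pred, target) == pytest.approx(0.1)

    def test_epsilon_guard_active_at_zero_target(self):
        target = np.zeros((1, 1, 2, 2))
        pred = np.full((1, 1, 2, 2), 0.1)
        assert mrae_loss(pred, target, eps=1e-3) == pytest.approx(100.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mrae_loss(np.zeros((1, 2, 4, 4)), np.zeros((1, 2, 4, 5)))


class TestExtractPatches:
    def test_lattice_count(self, rng):
        rgb = rng.random((64, 64, 3))
        cube = rng.random((64, 64, 8))
        assert len(extract_patches(rgb, cube, 32, 16)) == 9

    def test_whole_image_patch(self, rng):
        rgb = rng.random((32, 32, 3))
        cube = rng.random((32, 32, 8))
        pairs = extract_patches(rgb, cube, 32, 16)
        assert len(pairs) == 1
        np.testing.assert_array_equal(pairs[0][0], rgb)

    def test_shuffle_deterministic_under_seed(self, rng):
        rgb, cube = rng.random((64, 64, 3)), rng.random((64, 64, 8))
        p1 = extract_patches(rgb, cube, 32, 16, np.random.default_rng(4))
        p2 = extract_patches(rgb, cube, 32, 16, np.random.default_rng(4))
        for (a, _), (b, _) in zip(p1, p2):
            np.testing.assert_array_equal(a, b)

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patches(rng.random((16, 16, 3)), rng.random((16, 16, 4)),
                            32, 8)


@pytest.fixture(scope="module")
def tiny_run(clean_scene):
    cube, mask, labels, rgb = clean_scene
    vis, _ = split_bands(cube)
    tc = TrainConfig(iterations=60, patch=32, stride=16, seed=0,
                     eval_every=20)
    model = build_model(ReconModelConfig(channels=4, out_channels=88), seed=0)
    trained = train(model, [(rgb, vis.reflectance.astype(np.float64))],
                    tc, half="vis")
    return tc, trained, rgb, vis


class TestTraining:
    def test_history_recorded(self, tiny_run):
        _, trained, _, _ = tiny_run
        assert len(trained.history["iteration"]) == 3
        assert all(np.isfinite(trained.history["val_mrae"]))

    def test_best_checkpoint_not_worse_than_final_epoch(self, tiny_run):
        _, trained, _, _ = tiny_run
        assert trained.best_val <= trained.history["val_mrae"][-1] + 1e-12

    def test_same_seed_same_trajectory(self, clean_scene):
        cube, _, _, rgb = clean_scene
        vis, _ = split_bands(cube)
        tc = TrainConfig(iterations=20, patch=32, stride=16, seed=1,
                         eval_every=10)
        runs = []
        for _ in range(2):
            model = build_model(ReconModelConfig(channels=4, out_channels=88),
                                seed=1)
            tr = train(model, [(rgb, vis.reflectance.astype(np.float64))],
                       tc, half="vis")
            runs.append(tr.history["train_mrae"])
        assert runs[0] == runs[1]

    def test_checkpoint_round_trip(self, tiny_run, tmp_path, rng):
        _, trained, rgb, _ = tiny_run
        path = save_checkpoint(trained, tmp_path / "ckpt.npz")
        back = load_checkpoint(path)
        assert back.half == "vis"
        np.testing.assert_array_equal(back.model.predict(rgb),
                                      trained.model.predict(rgb))

    def test_epsilon_schedule_anneals_geometrically(self):
        tc = TrainConfig(iterations=100, eps=1e-3, eps_start=1.0,
                         eps_anneal_frac=0.5)
        assert tc.eps_at(0) == pytest.approx(1.0)
        assert tc.eps_at(25) == pytest.approx(10 ** -1.5)
        assert tc.eps_at(50) == pytest.approx(1e-3)
        assert tc.eps_at(100) == pytest.approx(1e-3)

    def test_reconstruct_merges_to_176_bands(self, tiny_run, clean_scene):
        _, trained, rgb, _ = tiny_run
        import dataclasses
        nir_trained = dataclasses.replace(trained, half="nir")
        cube = reconstruct(trained, nir_trained, rgb)
        assert cube.bands == 176
        assert cube.reflectance.shape[:2] == rgb.shape[:2]
        assert cube.reflectance.min() >= 0.0  # negatives clipped

    def test_reconstruct_rejects_swapped_halves(self, tiny_run):
        _, trained, rgb, _ = tiny_run
        with pytest.raises(ValueError):
            reconstruct(trained, trained, rgb)

    def test_paper_scale_preset(self):
        tc = TrainConfig.paper_scale()
        assert (tc.iterations, tc.batch_size, tc.lr) == (200000, 2, 1e-4)
        assert (tc.patch, tc.stride) == (128, 8)
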