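"""End-to-end orchestration: simulate → render RGB → train/reconstruct →
extract spectra → preprocess → (CARS) → regress → report.

A single global seed fans out to per-stage seeds by fixed offsets, so any
stage can be re-run in isolation and the whole run is a pure function of
its config.  The regression report follows the paired layout: every
nutrient × preprocessing × model combination is evaluated twice, once on
ground-truth mean spectra and once on spectra extracted from the
reconstructed cubes over identical pixel sets, so the two columns differ
only by reconstruction fidelity.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import recon_eval
from .hsi_core import HyperCube, make_wavelength_grid, paper_grid
from .recon_model import (
    ReconModelConfig,
    TrainConfig,
    TrainedRecon,
    build_model,
    reconstruct,
    split_bands,
    train,
)
from .rgb_synthesis import render_rgb
from .spectra_extract import (
    build_spectra_matrix,
    crop_window,
    foreground_mask,
    mean_spectrum,
    MaskRule,
)
from .synthetic_scene import SceneConfig, generate_dataset

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run",
    "ablate_band_count",
    "relative_decrease",
    "STAGE_SEED_OFFSETS",
]

logger = logging.getLogger("needlespec")

NUTRIENTS = ("N", "P", "K")
LABEL_COLS = {"N": "N_mg_g", "P": "P_mg_g", "K": "K_mg_g"}

#: Fixed per-stage seed offsets from the global seed.
STAGE_SEED_OFFSETS = {
    "scene": 0,
    "split": 1_000,
    "recon": 2_000,
    "cars": 3_000,
    "cv": 4_000,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a full desk-scale analysis run."""

    n_samples: int = 120
    scene: SceneConfig | None = None  # derived from seed when None
    test_ratio: float = 0.2
    preprocess_methods: tuple[str, ...] = ("raw", "msc", "d1", "d1_msc")
    models: tuple[str, ...] = ("plsr",)
    all_models: tuple[str, ...] = ("plsr", "svr", "rf")
    do_reconstruction: bool = True
    recon_model: ReconModelConfig = field(
        default_factory=lambda: ReconModelConfig(channels=8, out_channels=88)
    )
    recon_train: TrainConfig = field(default_factory=TrainConfig)
    use_cars: bool = False
    cars: chem.CARSConfig = field(default_factory=chem.CARSConfig)
    cv_folds: int = 10
    analysis_window_nm: tuple[float, float] = (450.0, 950.0)
    mask_rule: MaskRule = field(default_factory=MaskRule)
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)

    def resolved_scene(self) -> SceneConfig:
        scene = self.scene or SceneConfig()
        return replace(scene, seed=self.stage_seed("scene"))


@dataclass
class RunReport:
    """All tabular outputs of one pipeline run."""

    regression: pd.DataFrame
    recon_metrics: pd.DataFrame | None
    cars_selections: dict
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.regression.to_csv(out_dir / "regression_results.csv", index=False)
        if self.recon_metrics is not None:
            self.recon_metrics.to_csv(out_dir / "recon_metrics.csv", index=False)
        if self.cars_selections:
            rows = [
                {"nutrient": k[0], "spectra_source": k[1], "preprocess": k[2],
                 "selected_wavelengths_nm": " ".join(f"{v:.1f}" for v in wl)}
                for k, wl in self.cars_selections.items()
            ]
            pd.DataFrame(rows).to_csv(out_dir / "cars_selections.csv", index=False)
        (out_dir / "manifest.yaml").write_text(yaml.safe_dump(self.manifest))
        return out_dir


def _log_stage(name: str, t0: float) -> None:
    logger.info("stage %-16s done in %.1f s", name, time.time() - t0)


def _train_half_models(
    cubes, rgbs, train_idx, config: PipelineConfig
) -> tuple[TrainedRecon, TrainedRecon]:
    pairs_vis, pairs_nir = [], []
    for i in train_idx:
        vis, nir = split_bands(cubes[i])
        pairs_vis.append((rgbs[i], vis.reflectance.astype(np.float64)))
        pairs_nir.append((rgbs[i], nir.reflectance.astype(np.float64)))
    tc = replace(config.recon_train, seed=config.stage_seed("recon"))
    trained = []
    for half, pairs in (("vis", pairs_vis), ("nir", pairs_nir)):
        model = build_model(config.recon_model, seed=config.stage_seed("recon"))
        trained.append(train(model, pairs, tc, half=half))
    return trained[0], trained[1]


def _spectra_from(cubes, masks, ids, grid):
    return build_spectra_matrix(
        [mean_spectrum(c, m) for c, m in zip(cubes, masks)], ids, grid
    )


def run(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages and return the collected report.

    The regression table contains one row per
    (nutrient × spectra source × preprocessing × model); models configured
    in ``all_models`` but absent from ``models`` appear with status
    ``skipped`` so the report grid is always complete.
    """
    grid = paper_grid()
    scene = config.resolved_scene()
    t0 = time.time()
    cubes, gen_masks, labels = generate_dataset(config.n_samples, scene, grid)
    _log_stage("simulate", t0)

    t0 = time.time()
    rgbs = [render_rgb(c).values for c in cubes]
    _log_stage("render-rgb", t0)

    split = chem.make_split(config.n_samples, config.test_ratio,
                            config.stage_seed("split"))

    recon_cubes = None
    recon_metrics = None
    vis_m = nir_m = None
    if config.do_reconstruction:
        t0 = time.time()
        vis_m, nir_m = _train_half_models(cubes, rgbs, split.train_idx, config)
        _log_stage("train-recon", t0)
        t0 = time.time()
        recon_cubes = [
            HyperCube(
                reconstruct(vis_m, nir_m, r, grid).reflectance.astype(np.float32),
                grid,
            )
            for r in rgbs
        ]
        rows = []
        for i in split.test_idx:
            m = recon_eval.evaluate_pair(cubes[i], recon_cubes[i])
            rows.append({"sample_id": labels["sample_id"].iloc[i],
                         "mrae": m.mrae, "rmse": m.rmse, "psnr": m.psnr})
        recon_metrics = pd.DataFrame(rows)
        _log_stage("reconstruct", t0)

    t0 = time.time()
    masks = [foreground_mask(c, config.mask_rule) for c in cubes]
    ids = list(labels["sample_id"])
    spectra_gt = crop_window(
        _spectra_from(cubes, masks, ids, grid), *config.analysis_window_nm
    )
    sources = {"ground_truth": spectra_gt}
    if recon_cubes is not None:
        sources["reconstructed"] = crop_window(
            _spectra_from(recon_cubes, masks, ids, grid),
            *config.analysis_window_nm,
        )
    _log_stage("extract-spectra", t0)

    t0 = time.time()
    results, cars_selections = [], {}
    for nutrient in NUTRIENTS:
        y = labels[LABEL_COLS[nutrient]].to_numpy()
        for source_name, spectra in sources.items():
            X = spectra.to_numpy()
            wl = spectra.columns.to_numpy(dtype=float)
            tr, te = np.array(split.train_idx), np.array(split.test_idx)
            for method in config.preprocess_methods:
                Xtr, Xte = chem.preprocess(X[tr], X[te], method, wl)
                if config.use_cars:
                    cars_cfg = replace(config.cars,
                                       seed=config.stage_seed("cars"))
                    sel = chem.cars_select(Xtr, y[tr], cars_cfg)
                    cols = list(sel.selected)
                    Xtr, Xte = Xtr[:, cols], Xte[:, cols]
                    cars_selections[(nutrient, source_name, method)] = wl[cols]
                for model_name in config.all_models:
                    if model_name not in config.models:
                        results.append({
                            "nutrient": nutrient, "spectra_source": source_name,
                            "preprocess": method, "model": model_name,
                            "r2p": np.nan, "rmsep": np.nan, "rpd": np.nan,
                            "n": 0, "status": "skipped",
                        })
                        continue
                    spec = chem.default_grid(model_name, Xtr.shape[1],
                                             config.stage_seed("cv"))
                    fit = chem.fit_predict(spec, Xtr, y[tr], Xte,
                                           cv_folds=config.cv_folds,
                                           seed=config.stage_seed("cv"))
                    ev = chem.evaluate(y[te], fit.predictions)
                    results.append({
                        "nutrient": nutrient, "spectra_source": source_name,
                        "preprocess": method, "model": model_name,
                        "r2p": ev.r2p, "rmsep": ev.rmsep, "rpd": ev.rpd,
                        "n": ev.n, "status": "ok",
                    })
    _log_stage("predict-nutrients", t0)

    manifest = {
        "seed": config.seed,
        "n_samples": config.n_samples,
        "test_ratio": config.test_ratio,
        "scene_seed": scene.seed,
        "image_size": [scene.height, scene.width],
        "models": list(config.models),
        "preprocess_methods": list(config.preprocess_methods),
        "use_cars": config.use_cars,
        "do_reconstruction": config.do_reconstruction,
        "analysis_window_nm": list(config.analysis_window_nm),
        "recon": {
            "channels": config.recon_model.channels,
            "out_channels": config.recon_model.n_out,
            "n_rrg": config.recon_model.n_rrg,
            "mrb_scales": config.recon_model.mrb_scales,
            "iterations": config.recon_train.iterations,
            "lr": config.recon_train.lr,
            "patch": config.recon_train.patch,
            "stride": config.recon_train.stride,
            "srgb_encoded_input": True,
        } if config.do_reconstruction else None,
    }
    return RunReport(
        regression=pd.DataFrame(results),
        recon_metrics=recon_metrics,
        cars_selections=cars_selections,
        manifest=manifest,
    )


def relative_decrease(full_value: float, reduced_value: float) -> float:
    """Percent decrease of ``reduced_value`` relative to ``full_value``:
    100 · (full − reduced) / full."""
    if full_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (full_value - reduced_value) / full_value


def _resample_cube(cube: HyperCube, target_grid) -> HyperCube:
    """Linear spectral resampling of a cube onto a coarser grid."""
    refl = cube.reflectance
    flat = refl.reshape(-1, refl.shape[2])
    out = np.stack(
        [np.interp(target_grid.values, cube.grid.values, px) for px in flat]
    ).astype(refl.dtype)
    return HyperCube(out.reshape(refl.shape[0], refl.shape[1], -1), target_grid)


def ablate_band_count(config: PipelineConfig) -> dict:
    """Compare the 176-band two-half pipeline against a 31-band single-model
    variant (400–700 nm at 10 nm — the original reconstruction grid).

    Both variants see the same scenes: the 31-band cubes are spectral
    resamplings of the 176-band cubes, and all downstream settings are kept
    identical.  Returns the two reports plus per-nutrient best-R²p relative
    changes (percent decrease of the 31-band variant from the 176-band one).
    """
    report_full = run(config)

    grid31 = make_wavelength_grid(31, 400.0, 700.0)
    scene = config.resolved_scene()
    grid = paper_grid()
    cubes, _, labels = generate_dataset(config.n_samples, scene, grid)
    rgbs = [render_rgb(c).values for c in cubes]
    cubes31 = [_resample_cube(c, grid31) for c in cubes]
    split = chem.make_split(config.n_samples, config.test_ratio,
                            config.stage_seed("split"))

    # single model over all 31 bands, no visible/NIR split
    tc = replace(config.recon_train, seed=config.stage_seed("recon"))
    mc = replace(config.recon_model, out_channels=31)
    model = build_model(mc, seed=config.stage_seed("recon"))
    pairs = [(rgbs[i], cubes31[i].reflectance.astype(np.float64))
             for i in split.train_idx]
    trained = train(model, pairs, tc, half="vis")
    recon31 = [
        HyperCube(np.clip(trained.model.predict(r), 0.0, None).astype(np.float32),
                  grid31)
        for r in rgbs
    ]

    masks = [foreground_mask(c, config.mask_rule) for c in cubes]
    ids = list(labels["sample_id"])
    lo, hi = config.analysis_window_nm
    spectra31 = crop_window(_spectra_from(recon31, masks, ids, grid31), lo, hi)

    results = []
    tr, te = np.array(split.train_idx), np.array(split.test_idx)
    X = spectra31.to_numpy()
    wl = spectra31.columns.to_numpy(dtype=float)
    for nutrient in NUTRIENTS:
        y = labels[LABEL_COLS[nutrient]].to_numpy()
        for method in config.preprocess_methods:
            Xtr, Xte = chem.preprocess(X[tr], X[te], method, wl)
            for model_name in config.models:
                spec = chem.default_grid(model_name, Xtr.shape[1],
                                         config.stage_seed("cv"))
                fit = chem.fit_predict(spec, Xtr, y[tr], Xte,
                                       cv_folds=config.cv_folds,
                                       seed=config.stage_seed("cv"))
                ev = chem.evaluate(y[te], fit.predictions)
                results.append({
                    "nutrient": nutrient, "spectra_source": "reconstructed_31",
                    "preprocess": method, "model": model_name,
                    "r2p": ev.r2p, "rmsep": ev.rmsep, "rpd": ev.rpd,
                    "n": ev.n, "status": "ok",
                })
    regression31 = pd.DataFrame(results)

    full_reg = report_full.regression
    full_rec = full_reg[(full_reg.spectra_source == "reconstructed")
                        & (full_reg.status == "ok")]
    changes = {}
    for nutrient in NUTRIENTS:
        best_full = full_rec[full_rec.nutrient == nutrient]["r2p"].max()
        best_31 = regression31[regression31.nutrient == nutrient]["r2p"].max()
        changes[nutrient] = {
            "r2p_176": float(best_full),
            "r2p_31": float(best_31),
            "percent_decrease": relative_decrease(best_full, best_31),
        }
    return {
        "report_176": report_full,
        "regression_31": regression31,
        "relative_changes": changes,
    }
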