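"""Synthetic pine-canopy scene generator.

Produces labeled hyperspectral scenes with the statistical structure the
downstream analysis assumes: needle-shaped foreground strokes on a
near-black background board, a vegetation-like reflectance baseline
(chlorophyll absorption in the blue and red, a green peak near 550 nm, the
red edge near 715 nm, an NIR plateau), nutrient-dependent absorption in
literature-reported sensitivity windows, per-sample multiplicative/additive
scatter (the distortion MSC corrects), and per-pixel sensor noise.

The nutrient windows are the regions reported for conifer/crop foliage:

* nitrogen  — 510–540, 670–690, 910–920, 985–995 nm
* phosphorus — 575–585, 620–635, 670–685, 685–700, 965–975 nm
* potassium — 505–515, 555–570, 590–605, 685–700, 920–930, 950–965 nm

Window depths are linear in the min–max-scaled concentration, so partial
least squares on mean spectra can recover the labels exactly in the
noiseless limit, and band selection has a planted ground truth.  Higher
nitrogen additionally deepens the chlorophyll absorption features, which
makes mean reflectance over 450–600 nm strictly decreasing in nitrogen —
the qualitative pattern seen in real canopies.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.draw import line as draw_line
from skimage.morphology import dilation

from .hsi_core import (
    HyperCube,
    WavelengthGrid,
    paper_grid,
    write_cube,
    write_labels,
)

__all__ = [
    "NutrientRanges",
    "EndmemberModel",
    "SceneConfig",
    "needle_mask",
    "needle_spectrum",
    "render_cube",
    "generate_dataset",
    "write_dataset",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Raised when a scene cannot be generated within the retry budget."""


@dataclass(frozen=True)
class NutrientRanges:
    """Concentration sampling ranges in mg/g.

    The phosphorus range 0.8–1.6 mg/g is the reported typical foliar range;
    the nitrogen and potassium ranges are generator defaults chosen to span
    deficient-to-sufficient conifer foliage.
    """

    N: tuple[float, float] = (8.0, 25.0)
    P: tuple[float, float] = (0.8, 1.6)
    K: tuple[float, float] = (4.0, 12.0)


# (lo_nm, hi_nm, depth in reflectance units at full-scale concentration)
_N_WINDOWS = ((510, 540, 0.06), (670, 690, 0.05), (910, 920, 0.08), (985, 995, 0.06))
_P_WINDOWS = (
    (575, 585, 0.04), (620, 635, 0.05), (670, 685, 0.03),
    (685, 700, 0.03), (965, 975, 0.08),
)
_K_WINDOWS = (
    (505, 515, 0.03), (555, 570, 0.05), (590, 605, 0.04),
    (685, 700, 0.03), (920, 930, 0.06), (950, 965, 0.07),
)


@dataclass(frozen=True)
class EndmemberModel:
    """Parametric needle-reflectance model on a wavelength grid.

    baseline(λ) = floor
                + (plateau − floor) · σ((λ − red_edge_nm) / red_edge_width)
                + green_amp · G(λ; 550, 22)
                − chl_blue · G(λ; 460, 18) − chl_red · G(λ; 650, 15)

    with σ the logistic function and G a unit Gaussian bump.  Nutrient
    effects subtract depth · scaled(concentration) inside each sensitivity
    window (boxcar on band centers); nitrogen also scales the chlorophyll
    bumps through ``n_chl_coupling``.  Output is clipped to [0.005, 0.95].
    """

    visible_floor: float = 0.10
    nir_plateau: float = 0.55
    red_edge_nm: float = 715.0
    red_edge_width: float = 12.0
    green_amp: float = 0.08
    chl_blue: float = 0.05
    chl_red: float = 0.04
    n_chl_coupling: float = 0.04
    n_windows: tuple = _N_WINDOWS
    p_windows: tuple = _P_WINDOWS
    k_windows: tuple = _K_WINDOWS
    ranges: NutrientRanges = field(default_factory=NutrientRanges)
    clip: tuple[float, float] = (0.005, 0.95)

    def zero_depth(self) -> "EndmemberModel":
        """Copy with all nutrient sensitivities switched off."""
        strip = lambda ws: tuple((lo, hi, 0.0) for lo, hi, _ in ws)
        return replace(
            self,
            n_windows=strip(self.n_windows),
            p_windows=strip(self.p_windows),
            k_windows=strip(self.k_windows),
            n_chl_coupling=0.0,
        )

    def baseline(self, grid: WavelengthGrid) -> np.ndarray:
        lam = grid.values
        edge = 1.0 / (1.0 + np.exp(-(lam - self.red_edge_nm) / self.red_edge_width))
        out = (
            self.visible_floor
            + (self.nir_plateau - self.visible_floor) * edge
            + self.green_amp * np.exp(-0.5 * ((lam - 550.0) / 22.0) ** 2)
            - self.chl_blue * np.exp(-0.5 * ((lam - 460.0) / 18.0) ** 2)
            - self.chl_red * np.exp(-0.5 * ((lam - 650.0) / 15.0) ** 2)
        )
        return np.clip(out, *self.clip)


def _scaled(value: float, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return (value - lo) / (hi - lo)


def needle_spectrum(
    labels: dict | pd.Series,
    model: EndmemberModel,
    grid: WavelengthGrid | None = None,
) -> np.ndarray:
    """Noise-free needle reflectance for one sample (length = grid bands).

    ``labels`` maps ``{"N": .., "P": .., "K": ..}`` in mg/g.  Depths are
    linear in the min–max-scaled concentrations, so the map from labels to
    spectrum is affine — deliberately recoverable by linear chemometrics.
    """
    grid = grid or paper_grid()
    lam = grid.values
    sn = _scaled(float(labels["N"]), model.ranges.N)
    sp = _scaled(float(labels["P"]), model.ranges.P)
    sk = _scaled(float(labels["K"]), model.ranges.K)

    out = model.baseline(grid).copy()
    # nitrogen–chlorophyll coupling: stronger absorption bumps for high N
    out -= model.n_chl_coupling * sn * (
        np.exp(-0.5 * ((lam - 460.0) / 18.0) ** 2)
        + np.exp(-0.5 * ((lam - 650.0) / 15.0) ** 2)
    )
    for windows, s in ((model.n_windows, sn), (model.p_windows, sp),
                       (model.k_windows, sk)):
        for lo, hi, depth in windows:
            out -= depth * s * ((lam >= lo) & (lam <= hi))
    return np.clip(out, *model.clip)


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry, distortion levels and label ranges for one dataset."""

    height: int = 64
    width: int = 64
    stroke_count: int = 40
    background_reflectance: float = 0.02
    scatter_mult: tuple[float, float] = (0.8, 1.2)
    scatter_add: tuple[float, float] = (-0.02, 0.02)
    noise_sd: float = 0.005
    ranges: NutrientRanges = field(default_factory=NutrientRanges)
    model: EndmemberModel = field(default_factory=EndmemberModel)
    seed: int = 0

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ValueError("scene must be at least 16×16")
        for lo, hi in (self.scatter_mult, self.scatter_add):
            if hi < lo:
                raise ValueError("invalid scatter range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


_FRACTION_BOUNDS = (0.1, 0.6)


def needle_mask(
    height: int,
    width: int,
    stroke_count: int,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> np.ndarray:
    """Random needle-like foreground: thin elongated strokes.

    Foreground fraction is kept inside [0.1, 0.6]; strokes are line
    segments (some dilated to 2 px) with lengths 0.3–0.7 of the short side.
    """
    if height < 16 or width < 16:
        raise ValueError("mask must be at least 16×16")
    if stroke_count < 1:
        raise ValueError("stroke_count must be >= 1")
    short = min(height, width)
    for attempt in range(max_retries):
        mask = np.zeros((height, width), dtype=bool)
        for _ in range(stroke_count):
            r0 = rng.integers(0, height)
            c0 = rng.integers(0, width)
            length = rng.uniform(0.3, 0.7) * short
            angle = rng.uniform(0, np.pi)
            r1 = int(np.clip(r0 + length * np.sin(angle), 0, height - 1))
            c1 = int(np.clip(c0 + length * np.cos(angle), 0, width - 1))
            rr, cc = draw_line(int(r0), int(c0), r1, c1)
            mask[rr, cc] = True
            if rng.random() < 0.5:  # some needles are 2 px wide
                thick = np.zeros_like(mask)
                thick[rr, cc] = True
                mask |= dilation(thick)
        frac = mask.mean()
        if _FRACTION_BOUNDS[0] <= frac <= _FRACTION_BOUNDS[1]:
            return mask
    raise GenerationError(
        f"could not reach foreground fraction in {_FRACTION_BOUNDS} with "
        f"{stroke_count} strokes after {max_retries} tries"
    )


def render_cube(
    mask: np.ndarray,
    labels: dict | pd.Series,
    config: SceneConfig,
    rng: np.random.Generator,
    grid: WavelengthGrid | None = None,
) -> HyperCube:
    """Render one scene: foreground = scattered needle spectrum, background
    = flat board reflectance; per-pixel Gaussian noise; clipped to [0, 1]."""
    grid = grid or paper_grid()
    if mask.shape != (config.height, config.width):
        raise ValueError("mask shape does not match config")
    spectrum = needle_spectrum(labels, config.model, grid)
    mult = rng.uniform(*config.scatter_mult)
    add = rng.uniform(*config.scatter_add)
    refl = np.full(
        (config.height, config.width, grid.n_bands),
        config.background_reflectance,
        dtype=np.float64,
    )
    refl[mask] = mult * spectrum + add
    if config.noise_sd > 0:
        refl += rng.normal(0.0, config.noise_sd, size=refl.shape)
    np.clip(refl, 0.0, 1.0, out=refl)
    return HyperCube(reflectance=refl.astype(np.float32), grid=grid)


def generate_dataset(
    n_samples: int,
    config: SceneConfig,
    grid: WavelengthGrid | None = None,
) -> tuple[list[HyperCube], list[np.ndarray], pd.DataFrame]:
    """Generate ``n_samples`` scenes: (cubes, masks, label table).

    Labels are sampled uniformly within the configured ranges.  The whole
    dataset is a deterministic function of (config, grid) via
    ``config.seed``.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    grid = grid or paper_grid()
    rng = np.random.default_rng(config.seed)
    rows, cubes, masks = [], [], []
    for i in range(n_samples):
        labels = {
            "N": rng.uniform(*config.ranges.N),
            "P": rng.uniform(*config.ranges.P),
            "K": rng.uniform(*config.ranges.K),
        }
        mask = needle_mask(config.height, config.width, config.stroke_count, rng)
        cube = render_cube(mask, labels, config, rng, grid)
        rows.append({"sample_id": f"s{i:04d}", "N_mg_g": labels["N"],
                     "P_mg_g": labels["P"], "K_mg_g": labels["K"]})
        cubes.append(cube)
        masks.append(mask)
    return cubes, masks, pd.DataFrame(rows)


def write_dataset(
    out_dir: str | Path,
    cubes: list[HyperCube],
    masks: list[np.ndarray],
    labels: pd.DataFrame,
    config: SceneConfig,
    fmt: str = "npz",
) -> Path:
    """Persist a dataset as cubes + labels.csv + manifest.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, cube, mask in zip(labels["sample_id"], cubes, masks):
        if fmt == "npz":
            write_cube(cube, out_dir / f"{sid}.npz")
        else:
            write_cube(cube, out_dir / f"{sid}.hdr")
        np.save(out_dir / f"{sid}_mask.npy", mask)
    write_labels(labels, out_dir / "labels.csv")
    manifest = {
        "n_samples": len(cubes),
        "seed": config.seed,
        "height": config.height,
        "width": config.width,
        "stroke_count": config.stroke_count,
        "background_reflectance": config.background_reflectance,
        "scatter_mult": list(config.scatter_mult),
        "scatter_add": list(config.scatter_add),
        "noise_sd": config.noise_sd,
        "ranges": {
            "N": list(config.ranges.N),
            "P": list(config.ranges.P),
            "K": list(config.ranges.K),
        },
        "format": fmt,
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return out_dir
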