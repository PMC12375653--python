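"""Reconstruction quality metrics, per-band error heatmaps, and the
Gaussian-blur robustness probe.

Metrics, per image pair (ground truth I_G, reconstruction I_R):

* MRAE = mean over pixels and bands of |I_R − I_G| / max(I_G, ε)
* RMSE = √(mean over pixels and bands of (I_G − I_R)²)
* PSNR = 10 · log10(peak² / RMSE²)  [dB]

MRAE is a ratio metric: it is invariant to a common rescaling of both
cubes and, with a near-black background, much larger over a full image
than over the foreground alone (dark pixels amplify relative error);
reports should state which region was averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .hsi_core import HyperCube
from .recon_model import TrainedRecon, reconstruct

__all__ = [
    "ReconMetrics",
    "ErrorMap",
    "BlurProbeResult",
    "mrae",
    "rmse",
    "psnr",
    "evaluate_pair",
    "error_heatmap",
    "save_heatmap_png",
    "gaussian_blur_region",
    "blur_probe",
]


def _check_pair(ig: HyperCube, ir: HyperCube) -> None:
    if ig.reflectance.shape != ir.reflectance.shape:
        raise ValueError(
            f"shape mismatch: {ig.reflectance.shape} vs {ir.reflectance.shape}"
        )


def mrae(ig: HyperCube, ir: HyperCube, eps: float = 1e-3,
         mask: np.ndarray | None = None) -> float:
    """Mean relative absolute error of ``ir`` against ground truth ``ig``.

    ``mask`` restricts the average to foreground pixels.
    """
    _check_pair(ig, ir)
    if eps <= 0:
        raise ValueError("eps must be positive")
    g = ig.reflectance.astype(np.float64)
    rel = np.abs(ir.reflectance - g) / np.maximum(g, eps)
    if mask is not None:
        rel = rel[mask]
    return float(rel.mean())


def rmse(ig: HyperCube, ir: HyperCube, mask: np.ndarray | None = None) -> float:
    """Root-mean-square error in reflectance units."""
    _check_pair(ig, ir)
    d = (ig.reflectance.astype(np.float64) - ir.reflectance) ** 2
    if mask is not None:
        d = d[mask]
    return float(np.sqrt(d.mean()))


def psnr(rmse_value: float, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for a perfect reconstruction."""
    if rmse_value < 0:
        raise ValueError("rmse must be nonnegative")
    if peak <= 0:
        raise ValueError("peak must be positive")
    if rmse_value == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / rmse_value**2))


@dataclass(frozen=True)
class ReconMetrics:
    """MRAE/RMSE/PSNR triple for one image pair."""

    mrae: float
    rmse: float
    psnr: float
    peak: float = 1.0


def evaluate_pair(ig: HyperCube, ir: HyperCube, eps: float = 1e-3,
                  mask: np.ndarray | None = None) -> ReconMetrics:
    r = rmse(ig, ir, mask=mask)
    return ReconMetrics(
        mrae=mrae(ig, ir, eps, mask=mask), rmse=r, psnr=psnr(r, ig.peak),
        peak=ig.peak,
    )


def summarize_metrics(per_image: "list[ReconMetrics]") -> dict:
    """Set-level aggregates of per-image metrics.

    Both conventions are reported because they differ slightly:
    ``psnr_mean`` averages per-image PSNR (the default headline number),
    while ``psnr_pooled`` is the PSNR of the pooled RMSE
    (√mean(RMSE²) over images).
    """
    if not per_image:
        raise ValueError("no metrics to summarize")
    mraes = np.array([m.mrae for m in per_image])
    rmses = np.array([m.rmse for m in per_image])
    psnrs = np.array([m.psnr for m in per_image])
    pooled = float(np.sqrt(np.mean(rmses**2)))
    return {
        "mrae_mean": float(mraes.mean()),
        "rmse_mean": float(rmses.mean()),
        "psnr_mean": float(psnrs.mean()),
        "rmse_pooled": pooled,
        "psnr_pooled": psnr(pooled, per_image[0].peak),
    }


@dataclass(frozen=True)
class ErrorMap:
    """Per-pixel relative absolute error at one wavelength."""

    values: np.ndarray
    wavelength_nm: float
    band_index: int


def error_heatmap(
    ig: HyperCube, ir: HyperCube, wavelength_nm: float, eps: float = 1e-3
) -> ErrorMap:
    """Relative-error map at the band nearest ``wavelength_nm``.

    The mean of the returned map equals the single-band MRAE at that band.
    """
    _check_pair(ig, ir)
    grid = ig.grid
    if not (grid.lo_nm <= wavelength_nm <= grid.hi_nm):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside grid span "
            f"[{grid.lo_nm}, {grid.hi_nm}]"
        )
    b = int(np.argmin(np.abs(grid.values - wavelength_nm)))
    g = ig.reflectance[:, :, b].astype(np.float64)
    rel = np.abs(ir.reflectance[:, :, b] - g) / np.maximum(g, eps)
    return ErrorMap(values=rel, wavelength_nm=float(grid.values[b]), band_index=b)


def save_heatmap_png(
    emap: ErrorMap, path: str | Path, vmax: float | None = None
) -> Path:
    """Render an error map to PNG with a fixed color scale (for comparable
    figure sets pass the same ``vmax`` to every map)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(emap.values, cmap="inferno", vmin=0.0, vmax=vmax)
    ax.set_title(f"relative error @ {emap.wavelength_nm:.1f} nm")
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# Gaussian-blur robustness probe
# ---------------------------------------------------------------------------


def _sigma_for_kernel(k: int) -> float:
    # the conventional size->sigma mapping for discrete Gaussian kernels
    return 0.3 * ((k - 1) * 0.5 - 1) + 0.8


def gaussian_blur_region(
    rgb: np.ndarray, kernel_size: int, region: tuple[int, int, int, int]
) -> np.ndarray:
    """Blur ``region`` = (row0, col0, height, width) of an RGB array with a
    k×k Gaussian; k = 1 is the identity."""
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel size must be odd and >= 1")
    r0, c0, h, w = region
    if r0 < 0 or c0 < 0 or r0 + h > rgb.shape[0] or c0 + w > rgb.shape[1]:
        raise ValueError("region outside image")
    if kernel_size == 1:
        return rgb.copy()
    sigma = _sigma_for_kernel(kernel_size)
    radius = (kernel_size - 1) // 2
    out = rgb.copy()
    sub = rgb[r0 : r0 + h, c0 : c0 + w]
    blurred = np.stack(
        [
            gaussian_filter(sub[:, :, c], sigma=sigma, radius=radius,
                            mode="nearest")
            for c in range(sub.shape[2])
        ],
        axis=2,
    )
    out[r0 : r0 + h, c0 : c0 + w] = blurred
    return out


@dataclass(frozen=True)
class BlurProbeResult:
    """MRAE of the reconstruction inside a region as blur strength grows."""

    kernel_sizes: tuple[int, ...]
    mrae_per_size: tuple[float, ...]
    baseline_mrae: float
    region: tuple[int, int, int, int]


def central_region(height: int, width: int, fraction: float = 0.5):
    """Central fraction×fraction sub-rectangle of an H×W image."""
    h, w = int(round(height * fraction)), int(round(width * fraction))
    return ((height - h) // 2, (width - w) // 2, h, w)


def blur_probe(
    vis_model: TrainedRecon,
    nir_model: TrainedRecon,
    rgb: np.ndarray,
    ig: HyperCube,
    sizes: tuple[int, ...] = (5, 15, 25, 35),
    region: tuple[int, int, int, int] | None = None,
    eps: float = 1e-3,
) -> BlurProbeResult:
    """Degrade the central region of the RGB input with growing Gaussian
    blur, reconstruct, and track the region's MRAE against ground truth.

    The probe mimics depth-of-field degradation: blur destroys the spatial
    cues the network uses, so the error should not fall below the unblurred
    baseline.
    """
    if any(k % 2 == 0 for k in sizes):
        raise ValueError("kernel sizes must be odd")
    if list(sizes) != sorted(sizes):
        raise ValueError("kernel sizes must be increasing")
    if region is None:
        region = central_region(ig.height, ig.width)
    r0, c0, h, w = region
    region_mask = np.zeros((ig.height, ig.width), dtype=bool)
    region_mask[r0 : r0 + h, c0 : c0 + w] = True

    def region_mrae(image: np.ndarray) -> float:
        ir = reconstruct(vis_model, nir_model, image, grid=ig.grid)
        return mrae(ig, ir, eps, mask=region_mask)

    baseline = region_mrae(rgb)
    results = tuple(
        region_mrae(gaussian_blur_region(rgb, k, region)) for k in sizes
    )
    return BlurProbeResult(
        kernel_sizes=tuple(sizes), mrae_per_size=results,
        baseline_mrae=baseline, region=region,
    )
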