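"""ROI masking and mean-spectrum extraction.

Each sample contributes one spectrum: the arithmetic mean reflectance of
its foreground (needle) pixels per band — 176 values on the camera grid —
assembled into an n_samples × n_bands matrix for regression.  The noisy
grid edges (400–450 and 950–1000 nm) are cropped before chemometrics,
leaving the 146-band 450–950 nm analysis window.

Foreground segmentation exploits the NIR plateau: vegetation reflects
strongly at 750–900 nm while a black background board stays near zero, so
a simple threshold on the NIR band-mean separates needles robustly under
illumination changes.  Masks are computed on ground-truth cubes and reused
for the corresponding reconstructed cubes, so ground-truth and
reconstructed spectra are averaged over identical pixel sets and differ
only spectrally, not by segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import remove_small_objects

from .hsi_core import HyperCube, WavelengthGrid, band_index_range, validate_mask

__all__ = [
    "ExtractionError",
    "MaskRule",
    "foreground_mask",
    "mean_spectrum",
    "build_spectra_matrix",
    "crop_window",
    "ANALYSIS_WINDOW_NM",
]

#: Wavelength window retained for chemometric analysis.
ANALYSIS_WINDOW_NM = (450.0, 950.0)


class ExtractionError(RuntimeError):
    """Raised when no foreground can be extracted."""


@dataclass(frozen=True)
class MaskRule:
    """Thresholding rule for foreground segmentation.

    A pixel is foreground when its mean reflectance over
    [``nir_lo``, ``nir_hi``] exceeds ``tau``; connected components smaller
    than ``min_size`` pixels are removed as noise.
    """

    tau: float = 0.15
    nir_lo: float = 750.0
    nir_hi: float = 900.0
    min_size: int = 5


def foreground_mask(cube: HyperCube, rule: MaskRule = MaskRule()) -> np.ndarray:
    """Segment needle foreground from a dark background.

    Raises :class:`ExtractionError` when the rule selects nothing.
    """
    i0, i1 = band_index_range(cube.grid, rule.nir_lo, rule.nir_hi)
    nir_mean = cube.reflectance[:, :, i0 : i1 + 1].mean(axis=2)
    mask = nir_mean > rule.tau
    if rule.min_size > 1:
        # 8-connectivity: needles are thin diagonal strokes
        mask = remove_small_objects(mask, max_size=rule.min_size - 1,
                                    connectivity=2)
    if not mask.any():
        raise ExtractionError(
            f"no foreground above tau={rule.tau} in [{rule.nir_lo}, "
            f"{rule.nir_hi}] nm"
        )
    return mask


def mean_spectrum(cube: HyperCube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean reflectance over masked pixels."""
    validate_mask(mask, cube)
    if not mask.any():
        raise ExtractionError("mask selects no pixels")
    return cube.reflectance[mask].mean(axis=0, dtype=np.float64)


def build_spectra_matrix(
    spectra: list[np.ndarray], sample_ids: list[str], grid: WavelengthGrid
) -> pd.DataFrame:
    """Assemble spectra into a DataFrame: rows = samples, columns = band
    wavelengths (nm, as floats)."""
    if len(spectra) != len(sample_ids):
        raise ValueError("spectra and sample_ids differ in length")
    mat = np.vstack(spectra)
    if mat.shape[1] != grid.n_bands:
        raise ValueError("spectrum length does not match grid")
    return pd.DataFrame(mat, index=pd.Index(sample_ids, name="sample_id"),
                        columns=np.asarray(grid.values))


def crop_window(
    spectra: pd.DataFrame,
    lo_nm: float = ANALYSIS_WINDOW_NM[0],
    hi_nm: float = ANALYSIS_WINDOW_NM[1],
) -> pd.DataFrame:
    """Retain bands whose centers lie in [lo, hi] nm (closed interval).

    On the camera grid the default window keeps 146 of 176 bands.
    Idempotent: cropping a cropped matrix changes nothing.
    """
    if not lo_nm < hi_nm:
        raise ValueError("need lo_nm < hi_nm")
    wl = spectra.columns.to_numpy(dtype=float)
    keep = (wl >= lo_nm - 1e-9) & (wl <= hi_nm + 1e-9)
    if not keep.any():
        raise ValueError(f"no bands inside [{lo_nm}, {hi_nm}] nm")
    return spectra.loc[:, spectra.columns[keep]]
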