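"""Core data model and file I/O for hyperspectral cubes, RGB images, masks
and nutrient label tables.

Conventions used throughout the package:

* arrays are indexed ``(row, col) = (height, width)``, 0-based;
* reflectance is dimensionless, expected in ``[0, peak]`` with ``peak``
  defaulting to 1.0 (values above ``peak`` are tolerated but flagged);
* the working wavelength grid is uniform and inclusive of both endpoints.
  The camera grid used in this work is 176 bands over 400–1000 nm, i.e. a
  step of 600/175 ≈ 3.4286 nm (usually quoted rounded as "3.4 nm").
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "RGBImage",
    "FormatError",
    "make_wavelength_grid",
    "paper_grid",
    "band_index_range",
    "read_cube",
    "write_cube",
    "read_labels",
    "write_labels",
    "validate_mask",
]

#: Band count / span of the hyperspectral camera emulated here.
N_BANDS = 176
LO_NM = 400.0
HI_NM = 1000.0


class FormatError(ValueError):
    """Raised when an on-disk cube does not match its declared layout."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, inclusive grid of band-center wavelengths in nm."""

    n_bands: int
    lo_nm: float
    hi_nm: float
    values: np.ndarray = field(repr=False)

    @property
    def step(self) -> float:
        return (self.hi_nm - self.lo_nm) / (self.n_bands - 1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.n_bands == other.n_bands
            and self.lo_nm == other.lo_nm
            and self.hi_nm == other.hi_nm
            and np.array_equal(self.values, other.values)
        )


def make_wavelength_grid(n_bands: int, lo_nm: float, hi_nm: float) -> WavelengthGrid:
    """Build a uniform inclusive wavelength grid.

    ``values[k] = lo + k * (hi - lo) / (n_bands - 1)``, so both endpoints are
    band centers.  For the camera grid ``(176, 400, 1000)`` the step is
    600/175 ≈ 3.42857 nm.
    """
    if n_bands < 2:
        raise ValueError(f"n_bands must be >= 2, got {n_bands}")
    if not hi_nm > lo_nm:
        raise ValueError(f"need hi_nm > lo_nm, got [{lo_nm}, {hi_nm}]")
    values = lo_nm + np.arange(n_bands) * ((hi_nm - lo_nm) / (n_bands - 1))
    # pin the endpoints exactly despite float accumulation
    values[0], values[-1] = lo_nm, hi_nm
    values.setflags(write=False)
    return WavelengthGrid(n_bands=n_bands, lo_nm=lo_nm, hi_nm=hi_nm, values=values)


def paper_grid() -> WavelengthGrid:
    """The 176-band 400–1000 nm camera grid."""
    return make_wavelength_grid(N_BANDS, LO_NM, HI_NM)


def band_index_range(
    grid: WavelengthGrid, lo_nm: float, hi_nm: float
) -> tuple[int, int]:
    """Inclusive index interval of bands whose centers lie in ``[lo, hi]``.

    Selection is by band center with a closed interval (ranges in the
    analysis are stated as wavelength windows, not band edges).  On the
    camera grid, ``(450, 950)`` gives indices 15..160 (146 bands) and
    ``(400, 700)`` gives 0..87 (the 88 visible bands).
    """
    if not lo_nm < hi_nm:
        raise ValueError(f"need lo_nm < hi_nm, got [{lo_nm}, {hi_nm}]")
    tol = 1e-9 * max(abs(lo_nm), abs(hi_nm), 1.0)
    inside = (grid.values >= lo_nm - tol) & (grid.values <= hi_nm + tol)
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        raise ValueError(
            f"no band centers inside [{lo_nm}, {hi_nm}] nm on grid "
            f"[{grid.lo_nm}, {grid.hi_nm}]"
        )
    return int(idx[0]), int(idx[-1])


@dataclass
class HyperCube:
    """H×W×B reflectance image on a wavelength grid.

    ``peak`` is the signal ceiling used by PSNR; reflectance above ``peak``
    is physically suspicious but tolerated (a warning is emitted by
    :meth:`validate`).
    """

    reflectance: np.ndarray
    grid: WavelengthGrid
    peak: float = 1.0

    @property
    def height(self) -> int:
        return self.reflectance.shape[0]

    @property
    def width(self) -> int:
        return self.reflectance.shape[1]

    @property
    def bands(self) -> int:
        return self.reflectance.shape[2]

    def validate(self) -> "HyperCube":
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be H×W×B")
        if self.bands != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.bands} bands but grid has {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if self.peak <= 0:
            raise ValueError("peak must be positive")
        if float(self.reflectance.max(initial=0.0)) > self.peak:
            warnings.warn(
                "reflectance exceeds the declared peak; values are kept as-is",
                stacklevel=2,
            )
        return self


@dataclass
class RGBImage:
    """H×W×3 image with values in [0, 1].

    ``encoding`` records whether the channel values are linear-light or
    sRGB-encoded; the two differ by the sRGB transfer curve only.
    """

    values: np.ndarray
    encoding: str = "srgb"  # "linear" | "srgb"

    def validate(self) -> "RGBImage":
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("RGB image must be H×W×3")
        if self.encoding not in ("linear", "srgb"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("RGB values must lie in [0, 1]")
        return self


def validate_mask(mask: np.ndarray, cube: HyperCube | None = None) -> np.ndarray:
    """Check a boolean foreground mask (H×W), optionally against a cube."""
    if mask.ndim != 2 or mask.dtype != bool:
        raise ValueError("mask must be a 2-D boolean array")
    if cube is not None and mask.shape != (cube.height, cube.width):
        raise ValueError("mask shape does not match cube")
    return mask


# ---------------------------------------------------------------------------
# Cube I/O: ENVI-style header + raw BSQ binary, or a .npz archive container.
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8")}
_ENVI_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5}


def write_cube(cube: HyperCube, path: str | Path) -> Path:
    """Write a cube to ``path``.

    ``.npz`` paths use the package archive container (compressed arrays:
    reflectance, wavelengths, peak).  Any other path is treated as an ENVI
    header path (``.hdr`` appended if missing) with a raw BSQ binary next to
    it.  Round-trips are bit-exact for float32/float64 cubes.
    """
    cube.validate()
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            reflectance=cube.reflectance,
            wavelengths=np.asarray(cube.grid.values),
            peak=np.float64(cube.peak),
        )
        return path
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    raw = hdr.with_suffix(".raw")
    data = cube.reflectance
    if data.dtype not in _ENVI_CODES:
        data = data.astype(np.float32)
    code = _ENVI_CODES[data.dtype]
    wl = ", ".join(repr(float(v)) for v in cube.grid.values)
    hdr.write_text(
        "ENVI\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {cube.bands}\n"
        f"data type = {code}\n"
        "interleave = BSQ\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    # BSQ: band-sequential, each band a full H×W plane
    np.ascontiguousarray(np.moveaxis(data, 2, 0)).tofile(raw)
    return hdr


def _parse_envi_header(text: str) -> dict:
    fields: dict = {}
    braces = re.findall(r"(\w[\w ]*?)\s*=\s*\{([^}]*)\}", text, flags=re.S)
    for key, val in braces:
        fields[key.strip().lower()] = val
    for line in text.splitlines():
        if "=" in line and "{" not in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip()
    return fields


def read_cube(path: str | Path) -> HyperCube:
    """Read a cube written by :func:`write_cube` (archive or ENVI)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            refl = z["reflectance"]
            wl = z["wavelengths"]
            peak = float(z["peak"])
        grid = _grid_from_wavelengths(wl)
        return HyperCube(reflectance=refl, grid=grid, peak=peak).validate()

    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    fields = _parse_envi_header(hdr.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing field: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no wavelength list")
    wl = np.array([float(t) for t in fields["wavelength"].replace(",", " ").split()])
    if wl.size != bands:
        raise FormatError(f"wavelength list has {wl.size} entries for {bands} bands")
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {code}")
    dtype = _ENVI_DTYPES[code]
    raw = hdr.with_suffix(".raw")
    data = np.fromfile(raw, dtype=dtype)
    if data.size != samples * lines * bands:
        raise FormatError(
            f"binary holds {data.size} values, header declares "
            f"{samples * lines * bands}"
        )
    refl = np.moveaxis(data.reshape(bands, lines, samples), 0, 2)
    return HyperCube(reflectance=refl, grid=_grid_from_wavelengths(wl)).validate()


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid:
    if wl.size < 2 or np.any(np.diff(wl) <= 0):
        raise FormatError("wavelength list must be strictly increasing")
    step = np.diff(wl)
    if not np.allclose(step, step[0], rtol=1e-6, atol=1e-9):
        raise FormatError("wavelength list is not uniform")
    grid = make_wavelength_grid(wl.size, float(wl[0]), float(wl[-1]))
    return grid


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ["sample_id", "N_mg_g", "P_mg_g", "K_mg_g"]


def write_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    """Write a label table as CSV with header sample_id,N_mg_g,P_mg_g,K_mg_g."""
    _check_labels(labels)
    path = Path(path)
    labels.loc[:, LABEL_COLUMNS].to_csv(path, index=False)
    return path


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_labels(df)
    return df


def _check_labels(df: pd.DataFrame) -> None:
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"label table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError("sample_ids must be unique")
    conc = df[LABEL_COLUMNS[1:]].to_numpy(dtype=float)
    if not np.all(conc > 0):
        raise FormatError("all concentrations must be positive (mg/g)")
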