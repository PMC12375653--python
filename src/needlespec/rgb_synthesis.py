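"""Colorimetric RGB rendering of reflectance cubes.

RGB inputs for the reconstruction network are synthesized from hyperspectral
reflectance using the CIE 1931 2° standard observer and illuminant D65
(CCT ≈ 6504 K, i.e. average midday daylight).  Per pixel,

    X = k · Σ_b R(λ_b) S(λ_b) x̄(λ_b) Δλ      (likewise Y with ȳ, Z with z̄)
    k = 1 / Σ_b S(λ_b) ȳ(λ_b) Δλ

so a perfect white diffuser (R ≡ 1) has Y = 1 by construction.  XYZ is then
mapped to sRGB primaries (D65 white) and, by default, passed through the
sRGB transfer curve so the output resembles a consumer-camera image.
Out-of-gamut values are hard-clipped to [0, 1].

The observer and illuminant are embedded as the classic 10 nm summary
tables (380–780 nm) and linearly interpolated to the cube grid; the color
matching functions are zero outside 380–780 nm, which is exactly why any
variation confined to the near-infrared is invisible in RGB — the
ill-posedness the reconstruction network has to overcome with spatial
context.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .hsi_core import HyperCube, RGBImage, WavelengthGrid

__all__ = [
    "cmf_on_grid",
    "d65_on_grid",
    "cube_to_xyz",
    "xyz_to_rgb",
    "render_rgb",
    "srgb_encode",
    "srgb_decode",
    "write_png",
    "read_png",
    "CMF_SUPPORT_NM",
]

#: Wavelength support of the standard observer; bands beyond this are
#: colorimetrically invisible.
CMF_SUPPORT_NM = (380.0, 780.0)

# CIE 1931 2° color matching functions, 380–780 nm at 10 nm.
_CIE_WL = np.arange(380.0, 781.0, 10.0)
_CIE_XYZ = np.array([
    # x̄       ȳ       z̄
    [0.0014, 0.0000, 0.0065],  # 380
    [0.0042, 0.0001, 0.0201],
    [0.0143, 0.0004, 0.0679],  # 400
    [0.0435, 0.0012, 0.2074],
    [0.1344, 0.0040, 0.6456],
    [0.2839, 0.0116, 1.3856],
    [0.3483, 0.0230, 1.7471],
    [0.3362, 0.0380, 1.7721],  # 450
    [0.2908, 0.0600, 1.6692],
    [0.1954, 0.0910, 1.2876],
    [0.0956, 0.1390, 0.8130],
    [0.0320, 0.2080, 0.4652],
    [0.0049, 0.3230, 0.2720],  # 500
    [0.0093, 0.5030, 0.1582],
    [0.0633, 0.7100, 0.0782],
    [0.1655, 0.8620, 0.0422],
    [0.2904, 0.9540, 0.0203],
    [0.4334, 0.9950, 0.0087],  # 550
    [0.5945, 0.9950, 0.0039],
    [0.7621, 0.9520, 0.0021],
    [0.9163, 0.8700, 0.0017],
    [1.0263, 0.7570, 0.0011],
    [1.0622, 0.6310, 0.0008],  # 600
    [1.0026, 0.5030, 0.0003],
    [0.8544, 0.3810, 0.0002],
    [0.6424, 0.2650, 0.0000],
    [0.4479, 0.1750, 0.0000],
    [0.2835, 0.1070, 0.0000],  # 650
    [0.1649, 0.0610, 0.0000],
    [0.0874, 0.0320, 0.0000],
    [0.0468, 0.0170, 0.0000],
    [0.0227, 0.0082, 0.0000],
    [0.0114, 0.0041, 0.0000],  # 700
    [0.0058, 0.0021, 0.0000],
    [0.0029, 0.0010, 0.0000],
    [0.0014, 0.0005, 0.0000],
    [0.0007, 0.0002, 0.0000],
    [0.0003, 0.0001, 0.0000],  # 750
    [0.0002, 0.0001, 0.0000],
    [0.0001, 0.0000, 0.0000],
    [0.0000, 0.0000, 0.0000],  # 780
])

# CIE illuminant D65 relative spectral power, 380–780 nm at 10 nm
# (normalized to 100 at 560 nm).
_D65_SPD = np.array([
    49.98, 54.65, 82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81,
    114.86, 115.92, 108.81, 109.35, 107.80, 104.79, 107.69, 104.41,
    104.05, 100.00, 96.33, 95.79, 88.69, 90.01, 89.60, 87.70, 83.29,
    83.70, 80.03, 80.21, 82.28, 78.28, 69.72, 71.61, 74.35, 61.60,
    69.89, 75.09, 63.59, 46.42, 66.81, 63.38,
])

# XYZ (D65 white) -> linear sRGB, IEC 61966-2-1
_XYZ_TO_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


def cmf_on_grid(grid: WavelengthGrid) -> np.ndarray:
    """x̄, ȳ, z̄ resampled to ``grid`` (n_bands × 3); zero outside 380–780 nm."""
    out = np.stack(
        [np.interp(grid.values, _CIE_WL, _CIE_XYZ[:, i], left=0.0, right=0.0)
         for i in range(3)],
        axis=1,
    )
    return out


def d65_on_grid(grid: WavelengthGrid) -> np.ndarray:
    """D65 relative spectral power resampled to ``grid`` (zero outside table)."""
    return np.interp(grid.values, _CIE_WL, _D65_SPD, left=0.0, right=0.0)


def cube_to_xyz(
    cube: HyperCube,
    cmf: np.ndarray | None = None,
    spd: np.ndarray | None = None,
) -> np.ndarray:
    """Tristimulus image (H×W×3) of a reflectance cube under D65.

    ``cmf``/``spd`` default to the embedded tables resampled onto
    ``cube.grid``; pass them explicitly to reuse across many cubes.
    """
    if cmf is None:
        cmf = cmf_on_grid(cube.grid)
    if spd is None:
        spd = d65_on_grid(cube.grid)
    if cmf.shape != (cube.bands, 3) or spd.shape != (cube.bands,):
        raise ValueError("CMF/SPD not sampled on the cube grid")
    # Δλ is uniform, so it cancels between numerator and normalizer
    weights = spd[:, None] * cmf              # B×3
    k = spd @ cmf[:, 1]
    if k <= 0:
        raise ValueError("illuminant has no power inside the observer support")
    return np.einsum("hwb,bc->hwc", cube.reflectance, weights) / k


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Linear light -> sRGB-encoded, per IEC 61966-2-1."""
    linear = np.clip(linear, 0.0, 1.0)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1.0 / 2.4) - 0.055,
    )


def srgb_decode(encoded: np.ndarray) -> np.ndarray:
    encoded = np.clip(encoded, 0.0, 1.0)
    return np.where(
        encoded <= 0.04045,
        encoded / 12.92,
        np.power((encoded + 0.055) / 1.055, 2.4),
    )


def xyz_to_rgb(xyz: np.ndarray, encode: bool = True) -> RGBImage:
    """Map XYZ to sRGB primaries; hard-clip out-of-gamut values to [0, 1]."""
    if not np.all(np.isfinite(xyz)):
        raise ValueError("XYZ contains non-finite values")
    linear = np.einsum("hwc,dc->hwd", xyz, _XYZ_TO_SRGB)
    linear = np.clip(linear, 0.0, 1.0)
    if encode:
        return RGBImage(values=srgb_encode(linear), encoding="srgb").validate()
    return RGBImage(values=linear, encoding="linear").validate()


def render_rgb(
    cube: HyperCube,
    encode: bool = True,
    cmf: np.ndarray | None = None,
    spd: np.ndarray | None = None,
) -> RGBImage:
    """D65 rendering of a cube: :func:`cube_to_xyz` then :func:`xyz_to_rgb`."""
    return xyz_to_rgb(cube_to_xyz(cube, cmf=cmf, spd=spd), encode=encode)


def write_png(image: RGBImage, path: str | Path, bit_depth: int = 8) -> Path:
    """Write an RGB image as 8- or 16-bit PNG (deterministic bytes).

    8-bit goes through imageio; 48-bit-per-pixel RGB PNGs are not supported
    by the Pillow backend, so the 16-bit path emits the PNG chunks directly.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    scale = (1 << bit_depth) - 1
    q = np.round(image.values * scale)
    if bit_depth == 8:
        iio.imwrite(path, q.astype(np.uint8), extension=".png")
    else:
        path.write_bytes(_encode_png16(q.astype(np.uint16)))
    return path


def _png_chunk(tag: bytes, payload: bytes) -> bytes:
    import struct
    import zlib

    return (
        struct.pack(">I", len(payload)) + tag + payload
        + struct.pack(">I", zlib.crc32(tag + payload) & 0xFFFFFFFF)
    )


def _encode_png16(arr: np.ndarray) -> bytes:
    import struct
    import zlib

    h, w, _ = arr.shape
    ihdr = struct.pack(">IIBBBBB", w, h, 16, 2, 0, 0, 0)  # RGB, 16-bit
    raw = arr.astype(">u2").tobytes()
    stride = w * 6
    scanlines = b"".join(
        b"\x00" + raw[r * stride : (r + 1) * stride] for r in range(h)
    )
    return (
        b"\x89PNG\r\n\x1a\n"
        + _png_chunk(b"IHDR", ihdr)
        + _png_chunk(b"IDAT", zlib.compress(scanlines, 9))
        + _png_chunk(b"IEND", b"")
    )


def _decode_png16(data: bytes) -> np.ndarray:
    import struct
    import zlib

    assert data[:8] == b"\x89PNG\r\n\x1a\n"
    pos, idat, w = 8, b"", 0
    while pos < len(data):
        (length,) = struct.unpack(">I", data[pos : pos + 4])
        tag = data[pos + 4 : pos + 8]
        payload = data[pos + 8 : pos + 8 + length]
        if tag == b"IHDR":
            w, h, depth, color = struct.unpack(">IIBB", payload[:10])
            if depth != 16 or color != 2:
                raise ValueError("not a 16-bit RGB PNG")
        elif tag == b"IDAT":
            idat += payload
        pos += 12 + length
    raw = zlib.decompress(idat)
    stride = w * 6
    rows = []
    for r in range(h):
        line = raw[r * (stride + 1) : (r + 1) * (stride + 1)]
        if line[0] != 0:
            raise ValueError("unsupported PNG filter type")
        rows.append(np.frombuffer(line[1:], dtype=">u2"))
    return np.vstack(rows).reshape(h, w, 3)


def read_png(path: str | Path, encoding: str = "srgb") -> RGBImage:
    path = Path(path)
    data = path.read_bytes()
    # our 16-bit RGB container first; anything else through imageio
    try:
        arr = _decode_png16(data)
        scale = 65535.0
    except (ValueError, AssertionError):
        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=2)
        scale = 255.0 if arr.dtype == np.uint8 else 65535.0
    return RGBImage(values=arr[..., :3] / scale, encoding=encoding).validate()
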