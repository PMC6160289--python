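"""Pixel raster types, color-space conversions and coordinate conventions.

Every pipeline stage exchanges the small set of raster types defined here:
``RgbImage`` (camera frames), ``HlsImage`` (hue/lightness/saturation rasters
on the 8-bit half-degree hue convention, H in [0, 180)), ``GrayImage``
(BT.601 luma) and ``BinaryMask`` ({0,1} matrices).  Coordinates are 0-based
with x = column and y = row; centers are reported as ``PixelCoord(x, y)``.

The half-degree hue scale is used throughout because the vegetation hue
window the segmenter relies on (35 < H < 99) is stated on that scale: it
spans hue angles 70°-198°, i.e. green through cyan/blue, which covers both
the green canopy periphery and the blue-shifted canopy center.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image

__all__ = [
    "RgbImage",
    "HlsImage",
    "GrayImage",
    "BinaryMask",
    "PixelCoord",
    "rgb_to_hls",
    "hls_to_rgb",
    "rgb_to_gray",
    "apply_mask",
    "rgb_to_hls_float",
    "hls_to_rgb_float",
]

#: Hue values occupy [0, HUE_SCALE) — the 8-bit "half degree" convention.
HUE_SCALE = 180


@dataclass(frozen=True)
class PixelCoord:
    """A pixel location; ``x`` is the column index, ``y`` the row index."""

    x: int
    y: int

    def distance_to(self, other: "PixelCoord") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))


def _validate_raster(pixels: np.ndarray, channels: int, name: str) -> np.ndarray:
    arr = np.asarray(pixels)
    want_ndim = 2 if channels == 1 else 3
    if arr.ndim != want_ndim or (channels > 1 and arr.shape[2] != channels):
        raise ValueError(f"{name}: expected a H×W{'×' + str(channels) if channels > 1 else ''} raster, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.size == 0:
        raise ValueError(f"{name}: empty image")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.rint(arr)):
            raise ValueError(f"{name}: non-integer pixel values")
        arr = np.rint(arr).astype(np.int64)
    return arr


@dataclass(frozen=True, eq=False)
class RgbImage:
    """H×W×3 integer raster with R, G, B channels in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = _validate_raster(self.pixels, 3, "RgbImage")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("RgbImage: channel values outside [0, 255]")
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr, dtype=np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]

    @classmethod
    def open(cls, path: Union[str, Path]) -> "RgbImage":
        with Image.open(path) as im:
            return cls(np.asarray(im.convert("RGB")))

    def save(self, path: Union[str, Path]) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path)


@dataclass(frozen=True, eq=False)
class HlsImage:
    """H×W×3 integer raster: H in [0, 180), L and S in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = _validate_raster(self.pixels, 3, "HlsImage")
        h, l, s = arr[..., 0], arr[..., 1], arr[..., 2]
        if h.min() < 0 or h.max() >= HUE_SCALE:
            raise ValueError(f"HlsImage: hue outside [0, {HUE_SCALE})")
        if min(l.min(), s.min()) < 0 or max(l.max(), s.max()) > 255:
            raise ValueError("HlsImage: L or S outside [0, 255]")
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr, dtype=np.uint8))

    height = RgbImage.height
    width = RgbImage.width
    shape = RgbImage.shape


@dataclass(frozen=True, eq=False)
class GrayImage:
    """H×W integer raster of gray levels in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = _validate_raster(self.pixels, 1, "GrayImage")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("GrayImage: values outside [0, 255]")
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr, dtype=np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass(frozen=True, eq=False)
class BinaryMask:
    """H×W matrix over {0, 1}; the currency passed between pipeline stages."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        arr = _validate_raster(arr, 1, "BinaryMask")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("BinaryMask: values must be 0 or 1")
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr, dtype=np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def area(self) -> int:
        """Number of 1-pixels."""
        return int(self.pixels.sum())

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)

    @classmethod
    def zeros(cls, shape: tuple) -> "BinaryMask":
        return cls(np.zeros(shape, dtype=np.uint8))

    @classmethod
    def open(cls, path: Union[str, Path]) -> "BinaryMask":
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
        return cls((arr > 127).astype(np.uint8))

    def save(self, path: Union[str, Path]) -> None:
        Image.fromarray(self.pixels * np.uint8(255), mode="L").save(path)


# ---------------------------------------------------------------------------
# Color conversions
# ---------------------------------------------------------------------------

def rgb_to_hls_float(rgb: np.ndarray) -> np.ndarray:
    """Vectorized RGB→HLS on unit-scaled floats.

    ``rgb`` is (..., 3) in [0, 1]; returns (..., 3) with hue in [0, 1),
    lightness and saturation in [0, 1].  Matches ``colorsys.rgb_to_hls``
    per pixel; achromatic pixels get hue 0 and saturation 0.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = rgb.max(axis=-1)
    minc = rgb.min(axis=-1)
    lum = (maxc + minc) / 2.0
    crange = maxc - minc
    chromatic = crange > 0

    sat = np.zeros_like(lum)
    denom = np.where(lum <= 0.5, maxc + minc, 2.0 - maxc - minc)
    np.divide(crange, denom, out=sat, where=chromatic & (denom > 0))

    safe = np.where(chromatic, crange, 1.0)
    rc = (maxc - r) / safe
    gc = (maxc - g) / safe
    bc = (maxc - b) / safe
    hue = np.where(r == maxc, bc - gc, np.where(g == maxc, 2.0 + rc - bc, 4.0 + gc - rc))
    hue = (hue / 6.0) % 1.0
    hue = np.where(chromatic, hue, 0.0)
    return np.stack([hue, lum, sat], axis=-1)


def hls_to_rgb_float(hls: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hls_float` on unit-scaled floats."""
    hls = np.asarray(hls, dtype=np.float64)
    h, lum, s = hls[..., 0], hls[..., 1], hls[..., 2]
    m2 = np.where(lum <= 0.5, lum * (1.0 + s), lum + s - lum * s)
    m1 = 2.0 * lum - m2

    def ramp(hue: np.ndarray) -> np.ndarray:
        hue = hue % 1.0
        out = np.where(
            hue < 1.0 / 6.0,
            m1 + (m2 - m1) * hue * 6.0,
            np.where(
                hue < 0.5,
                m2,
                np.where(hue < 2.0 / 3.0, m1 + (m2 - m1) * (2.0 / 3.0 - hue) * 6.0, m1),
            ),
        )
        return out

    r = ramp(h + 1.0 / 3.0)
    g = ramp(h)
    b = ramp(h - 1.0 / 3.0)
    rgb = np.stack([r, g, b], axis=-1)
    return np.where(s[..., None] == 0, lum[..., None], rgb)


def rgb_to_hls(img: RgbImage) -> HlsImage:
    """Convert a frame to the HLS color space used by the segmenter.

    Hue is quantized to the half-degree scale [0, 180); lightness and
    saturation to [0, 255].
    """
    f = rgb_to_hls_float(img.pixels / 255.0)
    h = np.rint(f[..., 0] * HUE_SCALE).astype(np.int64) % HUE_SCALE
    l = np.rint(f[..., 1] * 255.0).astype(np.int64)
    s = np.rint(f[..., 2] * 255.0).astype(np.int64)
    return HlsImage(np.stack([h, l, s], axis=-1))


def hls_to_rgb(img: HlsImage) -> RgbImage:
    """Map a quantized HLS raster back to RGB (lossy: quantization only)."""
    p = img.pixels.astype(np.float64)
    f = np.stack([p[..., 0] / HUE_SCALE, p[..., 1] / 255.0, p[..., 2] / 255.0], axis=-1)
    rgb = np.clip(np.rint(hls_to_rgb_float(f) * 255.0), 0, 255)
    return RgbImage(rgb.astype(np.uint8))


#: BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def rgb_to_gray(img: RgbImage) -> GrayImage:
    """BT.601 luma: Y = round(0.299 R + 0.587 G + 0.114 B)."""
    y = np.rint(img.pixels.astype(np.float64) @ LUMA_WEIGHTS)
    return GrayImage(np.clip(y, 0, 255).astype(np.uint8))


_ImageT = Union[RgbImage, HlsImage, GrayImage, BinaryMask]


def apply_mask(img: _ImageT, mask: BinaryMask) -> _ImageT:
    """Zero every pixel where ``mask`` is 0; keep pixels where it is 1.

    Works for any raster type and returns the same type.  This is the
    element-wise product ROI = I(x, y) · Mask(x, y) that carries a region
    of interest from one stage to the next.
    """
    if img.shape[:2] != mask.shape:
        raise ValueError(f"apply_mask: image shape {img.shape[:2]} != mask shape {mask.shape}")
    m = mask.pixels
    if img.pixels.ndim == 3:
        m = m[..., None]
    return type(img)(img.pixels * m)
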