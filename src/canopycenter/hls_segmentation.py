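"""Global vegetation segmentation in the HLS color space.

The first pipeline stage removes soil and other non-vegetation background
with an interval threshold on hue, lightness and saturation.  The default
window — 35 < H < 99, 0 < L < 255, 0 < S < 255 on the half-degree hue
scale — keeps green-through-blue vegetation (hue angles 70°-198°) while
rejecting brown soil whose hue falls well below the window.  All bounds are
strict, so fully black (L = 0) and fully saturated (S = 255) pixels are
excluded.

An excess-green (Ex-G) color-index baseline with Otsu thresholding is also
provided; it is the classical vegetation-index segmenter the HLS+SVM
pipeline is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .imaging_core import BinaryMask, HlsImage, RgbImage, apply_mask

__all__ = [
    "HlsThresholds",
    "compute_hls_mask",
    "extract_vegetation",
    "exg_baseline_mask",
]


@dataclass(frozen=True)
class HlsThresholds:
    """Open intervals (min, max) per HLS channel; a pixel passes only if it
    lies strictly inside all three."""

    h_min: float = 35
    h_max: float = 99
    l_min: float = 0
    l_max: float = 255
    s_min: float = 0
    s_max: float = 255

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.h_min, self.h_max, "hue"),
            (self.l_min, self.l_max, "lightness"),
            (self.s_min, self.s_max, "saturation"),
        ):
            if not lo < hi:
                raise ValueError(f"HlsThresholds: {name} bounds must satisfy min < max")


def compute_hls_mask(img: HlsImage, t: HlsThresholds = HlsThresholds()) -> BinaryMask:
    """Interval-threshold vegetation mask.

    mask(x, y) = 1 iff h_min < H < h_max and l_min < L < l_max and
    s_min < S < s_max (all strict), else 0.
    """
    h = img.pixels[..., 0].astype(np.int64)
    l = img.pixels[..., 1].astype(np.int64)
    s = img.pixels[..., 2].astype(np.int64)
    keep = (
        (h > t.h_min) & (h < t.h_max)
        & (l > t.l_min) & (l < t.l_max)
        & (s > t.s_min) & (s < t.s_max)
    )
    return BinaryMask(keep.astype(np.uint8))


def extract_vegetation(img: HlsImage, mask: BinaryMask) -> HlsImage:
    """Zero the background, keeping the vegetation region of the HLS frame."""
    return apply_mask(img, mask)


def exg_baseline_mask(img: RgbImage) -> BinaryMask:
    """Excess-green baseline: ExG = 2g − r − b on chromaticity-normalized
    channels, thresholded by Otsu.

    Returns an all-zero mask for images where ExG is constant (e.g. a gray
    frame), since no threshold separates anything there.
    """
    rgb = img.pixels.astype(np.float64)
    total = rgb.sum(axis=-1)
    safe = np.where(total > 0, total, 1.0)
    r = rgb[..., 0] / safe
    g = rgb[..., 1] / safe
    b = rgb[..., 2] / safe
    exg = 2.0 * g - r - b
    if np.ptp(exg) == 0:
        return BinaryMask.zeros(exg.shape)
    thr = threshold_otsu(exg)
    return BinaryMask((exg > thr).astype(np.uint8))
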