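"""Canopy center localization from the grayscale gradient law.

Viewed from above, the gray level of a maize canopy increases monotonically
from the whorl outward — a consequence of the chlorophyll and illumination
structure of the young plant.  The center is therefore the darkest compact
region of the post-processed ROI.  Detection proceeds in three steps:
threshold the ROI gray image at T (default 30, strict: gray < T), keep the
largest connected sub-threshold component, and take its centroid.

Two diagnostics support the gradient-law assumption: ``band_quantize``
slices the gray range into the standard 17 isohypse bands (cut points at
multiples of 15) for visualization, and ``radial_gradient_check`` verifies
that ring-mean gray is non-decreasing with radius about a candidate center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .imaging_core import BinaryMask, GrayImage, PixelCoord
from .postprocessing import area_filter

__all__ = [
    "DEFAULT_ISOHYPSE_LEVELS",
    "DEFAULT_GRAY_THRESHOLD",
    "IsohypseBands",
    "CenterResult",
    "band_quantize",
    "radial_gradient_check",
    "threshold_center",
    "centroid",
    "detect_center",
]

#: Gray cut points dividing [0, 255] into 17 bands.
DEFAULT_ISOHYPSE_LEVELS = (15, 30, 45, 60, 75, 90, 105, 120, 135, 150, 165, 180, 195, 210, 225, 240, 255)

#: Default center threshold: canopy-center gray concentrates in 0–30.
DEFAULT_GRAY_THRESHOLD = 30


@dataclass(frozen=True)
class IsohypseBands:
    """Ascending gray cut points; band i is [level[i−1], level[i]) with the
    final band closed at 255."""

    levels: tuple = DEFAULT_ISOHYPSE_LEVELS

    def __post_init__(self) -> None:
        lv = tuple(self.levels)
        if len(lv) < 1 or any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("IsohypseBands: levels must be strictly ascending")
        if lv[-1] != 255:
            raise ValueError("IsohypseBands: last level must be 255")
        object.__setattr__(self, "levels", lv)

    @property
    def band_count(self) -> int:
        return len(self.levels)


@dataclass(frozen=True, eq=False)
class CenterResult:
    """Outcome of center detection; ``found=False`` is the degenerate case."""

    found: bool
    center: Optional[PixelCoord] = None
    center_mask: Optional[BinaryMask] = None
    center_area: int = 0


def band_quantize(
    gray: GrayImage,
    bands: IsohypseBands = IsohypseBands(),
    domain: Optional[BinaryMask] = None,
) -> np.ndarray:
    """Map each domain pixel to its isohypse band index; outside → −1."""
    levels = np.asarray(bands.levels)
    idx = np.digitize(gray.pixels, levels).astype(np.int64)
    np.clip(idx, 0, bands.band_count - 1, out=idx)  # close the final band at 255
    if domain is not None:
        if domain.shape != gray.shape:
            raise ValueError("band_quantize: domain shape mismatch")
        idx[domain.pixels == 0] = -1
    return idx


@dataclass(frozen=True, eq=False)
class RadialProfile:
    ring_means: np.ndarray
    monotone: bool
    spearman: float


def radial_gradient_check(
    gray: GrayImage,
    domain: BinaryMask,
    center: PixelCoord,
    n_rings: int = 8,
) -> RadialProfile:
    """Ring-mean gray about ``center`` and a monotonicity verdict.

    Domain pixels are split into ``n_rings`` equal-width annuli out to the
    farthest domain pixel.  The verdict is true when ring means never
    decrease outward.  Spearman correlation of ring index vs. mean gray is
    reported as a softer summary; it is 0 when undefined (constant input).
    This is a diagnostic of the gradient law, not a gate.
    """
    if domain.shape != gray.shape:
        raise ValueError("radial_gradient_check: domain shape mismatch")
    if domain.pixels[center.y, center.x] == 0:
        raise ValueError("radial_gradient_check: center outside domain")
    ys, xs = np.nonzero(domain.pixels)
    r = np.hypot(xs - center.x, ys - center.y)
    r_max = r.max()
    if r_max == 0:
        raise ValueError("radial_gradient_check: domain has a single pixel")
    ring = np.minimum((r / r_max * n_rings).astype(int), n_rings - 1)
    vals = gray.pixels[ys, xs].astype(np.float64)
    means = []
    for i in range(n_rings):
        sel = ring == i
        if sel.any():
            means.append(vals[sel].mean())
    if len(means) < 2:
        raise ValueError("radial_gradient_check: fewer than 2 non-empty rings")
    means = np.array(means)
    monotone = bool(np.all(np.diff(means) >= -1e-9))
    if np.ptp(means) == 0:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(np.arange(len(means)), means).statistic)
        if np.isnan(rho):
            rho = 0.0
    return RadialProfile(ring_means=means, monotone=monotone, spearman=rho)


def threshold_center(
    gray: GrayImage,
    domain: BinaryMask,
    T: float = DEFAULT_GRAY_THRESHOLD,
) -> BinaryMask:
    """Sub-threshold mask: 1 where domain = 1 and gray < T (strict)."""
    if domain.shape != gray.shape:
        raise ValueError("threshold_center: domain shape mismatch")
    return BinaryMask(((gray.pixels < T) & (domain.pixels == 1)).astype(np.uint8))


def centroid(mask: BinaryMask) -> Optional[PixelCoord]:
    """Mean 1-pixel coordinate, rounded to the nearest pixel; None if empty."""
    ys, xs = np.nonzero(mask.pixels)
    if len(ys) == 0:
        return None
    return PixelCoord(x=int(round(xs.mean())), y=int(round(ys.mean())))


def detect_center(
    gray: GrayImage,
    roi: BinaryMask,
    T: float = DEFAULT_GRAY_THRESHOLD,
    adaptive: bool = False,
) -> CenterResult:
    """Locate the canopy center inside the post-processed ROI.

    Thresholds the gray image at T, keeps the largest sub-threshold
    component (robust to stray dark pixels), and returns its centroid.
    With ``adaptive=True`` the threshold becomes (min gray inside ROI) + T,
    compensating a global illumination shift; the default is the absolute
    threshold.  Returns ``found=False`` when no ROI pixel is below the
    threshold.
    """
    if roi.shape != gray.shape:
        raise ValueError("detect_center: roi shape mismatch")
    thr = T
    if adaptive:
        inside = gray.pixels[roi.pixels == 1]
        if inside.size:
            thr = float(inside.min()) + T
    sub = threshold_center(gray, roi, thr)
    if sub.area == 0:
        return CenterResult(found=False)
    largest = area_filter(sub, policy="keep-largest")
    c = centroid(largest)
    return CenterResult(found=True, center=c, center_mask=largest, center_area=largest.area)
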