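"""Seeded generator of top-down maize-canopy-like images with ground truth.

No public dataset accompanies the recognition method, so the test bench is
a parametric image model that reproduces the statistical structure every
pipeline stage relies on:

* a rosette of elliptical leaves radiating from the plant center over a
  brown soil background;
* the **gradient law** — gray level grows linearly with radius from a dark
  floor (< 30) at the whorl, so the center is recoverable by thresholding;
* a **green periphery / blue-shifted center** color split in HLS space
  (periphery hue 45–75, center hue 80–98 on the half-degree scale, center
  more saturated), making ROI vs. N-ROI linearly separable by design;
* **weed blobs** whose hue range (40–95) straddles both canopy regions, so
  the SVM cannot fully remove them and area filtering is required; some
  weeds overlap the canopy boundary (occlusion);
* signal-dependent Gaussian pixel noise (dim pixels are less noisy, as for
  a photon-limited sensor) and a multiplicative illumination gain.

A *hard mode* renders weeds as decoy rosettes with the canopy's own size
and color statistics, emulating the frames where plant and weed are
indistinguishable and the pipeline is expected to fail gracefully.

Colors are synthesized luma-first: a pixel's RGB is its target gray level
times a hue-dependent unit-luma direction, so the gradient law holds
exactly before noise and hue is independent of brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .imaging_core import (
    LUMA_WEIGHTS,
    BinaryMask,
    PixelCoord,
    RgbImage,
    hls_to_rgb_float,
)

__all__ = [
    "FixtureParams",
    "CanopyGroundTruth",
    "STUDY_RANGES",
    "generate_canopy_image",
    "generate_dataset",
    "hard_mode_params",
    "training_nroi_mask",
]


@dataclass(frozen=True)
class FixtureParams:
    """Scene parameters for one synthetic canopy frame.

    Hue bounds are on the half-degree scale ([0, 180)); gray quantities in
    8-bit gray levels; lengths in pixels.
    """

    height: int = 256
    width: int = 256
    center: Optional[Tuple[float, float]] = None  # (cx, cy); None → near middle
    canopy_radius: float = 80.0
    leaf_count: int = 10
    roi_fraction: float = 0.30       # ROI disc radius as a fraction of canopy radius
    gray_floor: float = 8.0          # gray at the whorl; must stay below the T=30 threshold
    gradient_slope: float = 1.5      # gray units per px of radius
    canopy_hue: Tuple[float, float] = (45.0, 75.0)   # green periphery
    center_hue: Tuple[float, float] = (80.0, 98.0)   # blue-shifted whorl
    periphery_mix: float = 0.30      # white admixture → lower saturation
    center_mix: float = 0.10         # whorl is more saturated
    weed_count: int = 4
    weed_radius: Tuple[float, float] = (4.0, 12.0)
    weed_hue: Tuple[float, float] = (40.0, 95.0)     # straddles both canopy regions
    weed_gray: Tuple[float, float] = (60.0, 160.0)
    weed_mix: float = 0.20
    weed_overlap_prob: float = 0.30  # chance a weed touches the canopy boundary
    soil_rgb: Tuple[float, float, float] = (115.0, 88.0, 62.0)
    noise_sd: float = 2.0            # per-channel Gaussian sd at full brightness
    illumination_offset: float = 0.0  # gray-level shift at mid-tone, applied as gain
    hard_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("FixtureParams: image too small")
        if not 0 < self.roi_fraction < 1:
            raise ValueError("FixtureParams: roi_fraction must be in (0, 1)")
        for lo, hi, name in (
            (*self.canopy_hue, "canopy_hue"),
            (*self.center_hue, "center_hue"),
            (*self.weed_hue, "weed_hue"),
        ):
            if not (0 <= lo <= hi < 180):
                raise ValueError(f"FixtureParams: {name} must lie within [0, 180)")
        if self.canopy_radius >= min(self.height, self.width) / 2:
            raise ValueError("FixtureParams: canopy does not fit inside the image")
        if self.gray_floor < 0 or self.gray_floor >= 30:
            raise ValueError("FixtureParams: gray_floor must lie in [0, 30)")


@dataclass(frozen=True, eq=False)
class CanopyGroundTruth:
    """Per-fixture truth: vegetation and ROI masks, weed masks, center."""

    vegetation: BinaryMask
    roi: BinaryMask
    weed_masks: List[BinaryMask]
    center: PixelCoord


#: Parameter ranges of the default study conditions used by the evaluation
#: benches: canopy radius 40–120 px, illumination offset ±20 gray levels,
#: 0–8 weed blobs, noise sd up to 5.
STUDY_RANGES: Dict[str, Tuple[float, float]] = {
    "canopy_radius": (40.0, 120.0),
    "illumination_offset": (-20.0, 20.0),
    "weed_count": (0, 8),
    "noise_sd": (0.0, 5.0),
}


def _unit_luma_direction(hue_half_deg: np.ndarray, mix: float) -> np.ndarray:
    """RGB direction of the given hue with unit BT.601 luma.

    ``mix`` blends the fully saturated hue with white (higher mix → lower
    saturation) without changing the hue or the luma normalization.
    """
    h = np.asarray(hue_half_deg, dtype=np.float64) / 180.0
    hls = np.stack([h, np.full_like(h, 0.5), np.ones_like(h)], axis=-1)
    pure = hls_to_rgb_float(hls)  # chroma-1 colors, max=1, min=0
    d = (1.0 - mix) * pure + mix
    luma = d @ LUMA_WEIGHTS
    return d / luma[..., None]


def _ellipse_mask(shape, cx, cy, a, b, theta):
    hh, ww = shape
    yy, xx = np.mgrid[0:hh, 0:ww]
    u = np.cos(theta) * (xx - cx) + np.sin(theta) * (yy - cy)
    v = -np.sin(theta) * (xx - cx) + np.cos(theta) * (yy - cy)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _rosette_mask(shape, cx, cy, radius, leaf_count, roi_radius, rng):
    """Union of a solid central disc and ``leaf_count`` radiating leaves."""
    hh, ww = shape
    yy, xx = np.mgrid[0:hh, 0:ww]
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    mask = r2 <= (roi_radius * 1.25) ** 2
    for i in range(leaf_count):
        theta = 2 * np.pi * i / leaf_count + rng.normal(0, 0.12)
        mid = 0.52 * radius
        lx = cx + mid * np.cos(theta)
        ly = cy + mid * np.sin(theta)
        a = 0.52 * radius * rng.uniform(0.9, 1.0)
        b = radius * rng.uniform(0.14, 0.20)
        mask |= _ellipse_mask(shape, lx, ly, a, b, theta)
    # leaves never extend past the nominal canopy radius
    mask &= r2 <= radius**2
    return mask


def _paint(rgb: np.ndarray, where: np.ndarray, gray: np.ndarray, hue: np.ndarray, mix: float) -> None:
    """Composite luma-first color ``gray × direction(hue)`` into ``rgb``."""
    d = _unit_luma_direction(hue, mix)
    px = gray[:, None] * d
    peak = px.max(axis=1)
    scale = np.minimum(1.0, 252.0 / np.maximum(peak, 1e-9))
    rgb[where] = px * scale[:, None]


def generate_canopy_image(p: FixtureParams) -> Tuple[RgbImage, CanopyGroundTruth]:
    """Render one canopy frame and its ground truth, deterministically.

    The same params (including seed) always produce a bit-identical image
    and truth.
    """
    rng = np.random.default_rng(p.seed)
    hh, ww = p.height, p.width
    R = p.canopy_radius
    roi_R = p.roi_fraction * R
    gain = (128.0 + p.illumination_offset) / 128.0

    if p.center is not None:
        cx, cy = p.center
    else:
        jitter = max(0.0, min(8.0, min(hh, ww) / 2 - R - 2))
        cx = ww / 2 + rng.uniform(-jitter, jitter)
        cy = hh / 2 + rng.uniform(-jitter, jitter)
    if min(cx, cy, ww - 1 - cx, hh - 1 - cy) < R:
        raise ValueError("generate_canopy_image: canopy does not fit inside the image")

    yy, xx = np.mgrid[0:hh, 0:ww]
    r = np.hypot(xx - cx, yy - cy)

    canopy = _rosette_mask((hh, ww), cx, cy, R, p.leaf_count, roi_R, rng)
    roi = canopy & (r <= roi_R)

    # soil background
    rgb = np.empty((hh, ww, 3), dtype=np.float64)
    rgb[:] = np.asarray(p.soil_rgb) * gain

    # canopy: gradient-law gray, hue split between whorl and periphery
    gray_field = np.clip((p.gray_floor + p.gradient_slope * r) * gain, 1.0, 255.0)
    periph = canopy & ~roi
    for region, hue_rng, mix in (
        (roi, p.center_hue, p.center_mix),
        (periph, p.canopy_hue, p.periphery_mix),
    ):
        k = int(region.sum())
        if k:
            hues = rng.uniform(hue_rng[0], hue_rng[1], size=k)
            _paint(rgb, region, gray_field[region], hues, mix)

    # weeds, composited after the canopy (occlusion)
    weed_masks: List[BinaryMask] = []
    guard = roi_R + 4.0
    for _ in range(p.weed_count):
        if p.hard_mode:
            wr = R * rng.uniform(0.80, 1.05)
            dist = rng.uniform(1.6 * R, 2.3 * R)
        else:
            wr = rng.uniform(*p.weed_radius)
            if rng.random() < p.weed_overlap_prob:
                dist = R + wr * rng.uniform(-0.3, 0.5)  # touches the canopy boundary
            else:
                dist = rng.uniform(R + wr + 4.0, max(R + wr + 5.0, 0.7 * max(hh, ww)))
        ang = rng.uniform(0, 2 * np.pi)
        wx = cx + dist * np.cos(ang)
        wy = cy + dist * np.sin(ang)
        if np.hypot(wx - cx, wy - cy) <= guard + wr:
            continue  # never let a weed reach the ROI
        if p.hard_mode:
            wmask = _rosette_mask((hh, ww), wx, wy, wr, p.leaf_count, p.roi_fraction * wr, rng)
            if not wmask.any():
                continue
            wr_field = np.hypot(xx - wx, yy - wy)
            wgray = np.clip((p.gray_floor + p.gradient_slope * wr_field) * gain, 1.0, 255.0)
            w_roi = wmask & (wr_field <= p.roi_fraction * wr)
            for region, hue_rng, mix in (
                (w_roi, p.center_hue, p.center_mix),
                (wmask & ~w_roi, p.canopy_hue, p.periphery_mix),
            ):
                k = int(region.sum())
                if k:
                    hues = rng.uniform(hue_rng[0], hue_rng[1], size=k)
                    _paint(rgb, region, wgray[region], hues, mix)
        else:
            theta = rng.uniform(0, np.pi)
            wmask = _ellipse_mask((hh, ww), wx, wy, wr, wr * rng.uniform(0.6, 1.0), theta)
            k = int(wmask.sum())
            if k == 0:
                continue
            base_gray = rng.uniform(*p.weed_gray)
            wgray = np.clip((base_gray + rng.normal(0, 6.0, size=k)) * gain, 20.0, 255.0)
            hues = rng.uniform(*p.weed_hue, size=k)
            _paint(rgb, wmask, wgray, hues, p.weed_mix)
        weed_masks.append(BinaryMask(wmask.astype(np.uint8)))

    # photon-limited sensor noise: sd scales with sqrt(signal), with a small
    # read-noise floor; noise_sd is the per-channel sd at full scale
    if p.noise_sd > 0:
        luma = rgb @ LUMA_WEIGHTS
        sd = p.noise_sd * np.clip(np.sqrt(luma / 255.0), 0.1, 1.0)
        rgb = rgb + rng.normal(0.0, 1.0, size=rgb.shape) * sd[..., None]

    img = RgbImage(np.clip(np.rint(rgb), 0, 255).astype(np.uint8))
    vegetation = canopy.copy()
    for wm in weed_masks:
        vegetation |= wm.astype_bool()
    truth = CanopyGroundTruth(
        vegetation=BinaryMask(vegetation.astype(np.uint8)),
        roi=BinaryMask(roi.astype(np.uint8)),
        weed_masks=weed_masks,
        center=PixelCoord(x=int(round(cx)), y=int(round(cy))),
    )
    return img, truth


def training_nroi_mask(truth: CanopyGroundTruth) -> BinaryMask:
    """The candidate N-ROI region for training: vegetation minus the ROI
    and minus weeds.

    Mirrors manual candidate-region selection, which labels surrounding
    canopy leaves — not weeds — as the negative class.
    """
    out = truth.vegetation.astype_bool() & ~truth.roi.astype_bool()
    for wm in truth.weed_masks:
        out &= ~wm.astype_bool()
    return BinaryMask(out.astype(np.uint8))


def hard_mode_params(seed: int = 0, **overrides) -> FixtureParams:
    """Conditions where weeds mimic the plant: decoy rosettes of comparable
    size and identical color statistics."""
    base = dict(
        canopy_radius=52.0,
        weed_count=2,
        hard_mode=True,
        seed=seed,
    )
    base.update(overrides)
    return FixtureParams(**base)


_INT_PARAMS = {"weed_count", "leaf_count", "height", "width"}


def generate_dataset(
    n: int,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
    base: FixtureParams = FixtureParams(),
) -> Tuple[List[Tuple[RgbImage, CanopyGroundTruth]], pd.DataFrame]:
    """Draw ``n`` fixtures with parameters sampled uniformly from ``ranges``.

    ``ranges`` maps FixtureParams field names to (lo, hi) bounds (defaults
    to :data:`STUDY_RANGES`); integer-valued fields are drawn on the
    inclusive integer range.  Returns the fixtures and a manifest recording
    every drawn parameter.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("generate_dataset: n must be >= 1")
    if ranges is None:
        ranges = STUDY_RANGES
    for name, (lo, hi) in ranges.items():
        if not hasattr(base, name):
            raise ValueError(f"generate_dataset: unknown parameter {name!r}")
        if lo > hi:
            raise ValueError(f"generate_dataset: invalid range for {name!r}: ({lo}, {hi})")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n + 1)]
    rng = np.random.default_rng(child_seeds[0])
    fixtures = []
    rows = []
    for i in range(n):
        draws = {}
        for name, (lo, hi) in ranges.items():
            if name in _INT_PARAMS:
                draws[name] = int(rng.integers(int(lo), int(hi) + 1))
            else:
                draws[name] = float(rng.uniform(lo, hi))
        p = replace(base, seed=child_seeds[i + 1], **draws)
        img, truth = generate_canopy_image(p)
        fixtures.append((img, truth))
        row = {"index": i, "seed": p.seed, "center_x": truth.center.x, "center_y": truth.center.y}
        row.update(draws)
        rows.append(row)
    return fixtures, pd.DataFrame(rows)
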