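"""Diagnostic overlays: isohypse band coloring and the detected center.

``band_overlay`` colors each of the 17 gray bands of the ROI with the
tab20 qualitative palette, reproducing the usual visualization of the
gradient law; ``draw_center`` marks the detected center with a circle.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from PIL import Image, ImageDraw

from .center_detection import IsohypseBands, band_quantize
from .imaging_core import BinaryMask, GrayImage, PixelCoord, RgbImage

__all__ = ["band_overlay", "draw_center"]


def _tab20_palette(n: int) -> np.ndarray:
    cmap = colormaps["tab20"]
    return (np.array([cmap(i % 20)[:3] for i in range(n)]) * 255).astype(np.uint8)


def band_overlay(
    base: RgbImage,
    gray: GrayImage,
    domain: BinaryMask,
    bands: IsohypseBands = IsohypseBands(),
) -> RgbImage:
    """Color the domain's isohypse bands over the base frame."""
    idx = band_quantize(gray, bands, domain)
    out = base.pixels.copy()
    palette = _tab20_palette(bands.band_count)
    inside = idx >= 0
    out[inside] = palette[idx[inside]]
    return RgbImage(out)


def draw_center(img: RgbImage, center: PixelCoord, radius: int = 8) -> RgbImage:
    """Mark the detected canopy center with a red circle."""
    im = Image.fromarray(img.pixels, mode="RGB")
    draw = ImageDraw.Draw(im)
    bbox = [center.x - radius, center.y - radius, center.x + radius, center.y + radius]
    draw.ellipse(bbox, outline=(255, 0, 0), width=2)
    return RgbImage(np.asarray(im))
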