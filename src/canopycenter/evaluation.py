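"""Segmentation-quality (Qseg) and center-recognition-rate statistics.

Qseg is the intersection-over-union (Jaccard index) between an automatic
mask A and a manual/truth reference B:

    Qseg = |A ∩ B| / |A ∪ B|

It rewards consistency of both the segmented region and the background and
is reported per image, then summarized as a mean and standard deviation in
percent.  A frame's center detection counts as recognized when a center was
found and its Euclidean distance to the truth center is within a pixel
tolerance; the recognition rate is the percentage of recognized frames,
optionally broken down by acquisition group.  The default tolerance of
20 px is stated at a 1242×931 reference frame and scaled by image diagonal
for other sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .center_detection import CenterResult
from .imaging_core import BinaryMask, PixelCoord

__all__ = [
    "QsegReport",
    "RecognitionReport",
    "qseg",
    "summarize_quality",
    "recognition_rate",
    "scaled_tolerance",
]

#: Reference frame (height, width) at which the default tolerance is stated.
REFERENCE_FRAME = (931, 1242)
DEFAULT_CENTER_TOLERANCE = 20.0


def qseg(A: BinaryMask, B: BinaryMask) -> float:
    """Jaccard segmentation-quality factor in [0, 1].

    Two empty masks agree perfectly on the absence of the region and
    score 1.
    """
    if A.shape != B.shape:
        raise ValueError(f"qseg: shape mismatch {A.shape} vs {B.shape}")
    a = A.astype_bool()
    b = B.astype_bool()
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return inter / union


@dataclass(frozen=True)
class QsegReport:
    """Per-image qualities plus their mean and SD, in percent."""

    values: tuple
    mean_pct: float
    sd_pct: float
    n: int


def summarize_quality(values: Sequence[float], sample_sd: bool = False) -> QsegReport:
    """Mean and (population, by default) standard deviation, in percent."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("summarize_quality: empty value list")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("summarize_quality: qseg values must lie in [0, 1]")
    ddof = 1 if sample_sd and vals.size > 1 else 0
    return QsegReport(
        values=tuple(float(v) for v in vals),
        mean_pct=float(vals.mean() * 100.0),
        sd_pct=float(vals.std(ddof=ddof) * 100.0),
        n=int(vals.size),
    )


@dataclass(frozen=True)
class RecognitionReport:
    """Recognition counts and rate (percent), optionally per group."""

    n: int
    recognized: int
    rate_pct: float
    distances: tuple
    per_group: Optional[Dict[object, float]] = None


def recognition_rate(
    detected: Sequence[CenterResult],
    truth: Sequence[PixelCoord],
    tol: float = DEFAULT_CENTER_TOLERANCE,
    groups: Optional[Sequence] = None,
) -> RecognitionReport:
    """Fraction of frames whose detected center lies within ``tol`` px of
    the truth center.

    A frame with ``found=False`` never counts as recognized.  ``groups``
    optionally assigns each frame to a batch; per-group rates are then
    reported alongside the overall rate.
    """
    if len(detected) != len(truth):
        raise ValueError("recognition_rate: detected and truth lists differ in length")
    if groups is not None and len(groups) != len(truth):
        raise ValueError("recognition_rate: groups length mismatch")
    hits = []
    dists = []
    for det, t in zip(detected, truth):
        if det.found and det.center is not None:
            d = det.center.distance_to(t)
        else:
            d = float("inf")
        dists.append(d)
        hits.append(d <= tol)
    hits = np.asarray(hits)
    n = len(hits)
    rate = 100.0 * hits.sum() / n if n else 0.0
    per_group = None
    if groups is not None:
        per_group = {}
        for g in dict.fromkeys(groups):  # preserve first-seen order
            sel = np.asarray([gi == g for gi in groups])
            per_group[g] = float(100.0 * hits[sel].mean()) if sel.any() else 0.0
    return RecognitionReport(
        n=n,
        recognized=int(hits.sum()),
        rate_pct=float(rate),
        distances=tuple(dists),
        per_group=per_group,
    )


def scaled_tolerance(
    shape: tuple,
    base_tol: float = DEFAULT_CENTER_TOLERANCE,
    base_shape: tuple = REFERENCE_FRAME,
) -> float:
    """Scale the pixel tolerance from the reference frame to ``shape``
    (height, width) proportionally to the image diagonal."""
    return base_tol * float(np.hypot(*shape)) / float(np.hypot(*base_shape))
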