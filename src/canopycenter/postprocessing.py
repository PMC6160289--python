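"""Post-processing of the SVM mask: area filtering and erosion.

The SVM stage leaves two kinds of residue: isolated weed blobs whose color
overlaps the canopy center's, and a ragged ROI boundary where canopy and
weeds occlude each other.  Both are handled here.  Weed blobs are removed
by connected-component area filtering (by default keeping only the largest
component, since the canopy ROI dominates the frame); the boundary is
smoothed by morphological erosion with a 3×3 all-ones structuring element,
the binary specialization of the grayscale erosion
min{M(x+x′, y+y′) − K(x′, y′)}: a pixel survives only if its whole 3×3
neighborhood lies inside the region.  Out-of-image neighbors count as 0,
so regions also shrink away from the frame border.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .imaging_core import BinaryMask

__all__ = [
    "ConnectedComponent",
    "ErosionKernel",
    "connected_components",
    "area_filter",
    "erode",
]

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True, eq=False)
class ConnectedComponent:
    """One connected region of 1-pixels."""

    label: int
    area: int
    bbox: tuple  # (min_row, min_col, max_row, max_col), max exclusive
    coords: np.ndarray  # (area, 2) array of (row, col)

    def mask(self, shape: tuple) -> BinaryMask:
        out = np.zeros(shape, dtype=np.uint8)
        out[self.coords[:, 0], self.coords[:, 1]] = 1
        return BinaryMask(out)


@dataclass(frozen=True, eq=False)
class ErosionKernel:
    """Structuring element for erosion; defaults to the 3×3 all-ones block."""

    K: np.ndarray = field(default_factory=lambda: np.ones((3, 3), dtype=np.uint8))

    def __post_init__(self) -> None:
        arr = np.asarray(self.K)
        if arr.ndim != 2 or not np.isin(arr, (0, 1)).all() or arr.sum() == 0:
            raise ValueError("ErosionKernel: K must be a nonempty 2-D 0/1 array")
        object.__setattr__(self, "K", arr.astype(np.uint8))


def _label(mask: BinaryMask, connectivity: int):
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    return ndimage.label(mask.pixels, structure=structure)


def connected_components(mask: BinaryMask, connectivity: int = 8) -> List[ConnectedComponent]:
    """Disjoint labeling of the 1-pixels; labels are scan-order (1-based)."""
    labeled, n = _label(mask, connectivity)
    comps = []
    slices = ndimage.find_objects(labeled)
    for lab, sl in zip(range(1, n + 1), slices):
        sub = labeled[sl] == lab
        rows, cols = np.nonzero(sub)
        coords = np.stack([rows + sl[0].start, cols + sl[1].start], axis=1)
        comps.append(
            ConnectedComponent(
                label=lab,
                area=int(len(coords)),
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                coords=coords,
            )
        )
    return comps


def area_filter(
    mask: BinaryMask,
    policy: str = "keep-largest",
    min_area: Optional[int] = None,
    connectivity: int = 8,
) -> BinaryMask:
    """Remove small connected components.

    ``keep-largest`` retains only the maximum-area component (area ties
    broken by smallest scan-order label, so the result is deterministic);
    ``min-area`` retains every component with area >= ``min_area``.  An
    empty mask passes through unchanged.
    """
    labeled, n = _label(mask, connectivity)
    if n == 0:
        return BinaryMask.zeros(mask.shape)
    areas = np.bincount(labeled.ravel())[1:]  # area per label, label-1 indexed
    if policy == "keep-largest":
        keep = {int(np.argmax(areas)) + 1}
    elif policy == "min-area":
        if min_area is None:
            raise ValueError("area_filter: min-area policy requires min_area")
        keep = {int(l) + 1 for l in np.flatnonzero(areas >= min_area)}
    else:
        raise ValueError(f"area_filter: unknown policy {policy!r}")
    out = np.isin(labeled, sorted(keep)) & (labeled > 0)
    return BinaryMask(out.astype(np.uint8))


def erode(mask: BinaryMask, kernel: ErosionKernel = ErosionKernel(), passes: int = 1) -> BinaryMask:
    """Binary erosion: a pixel survives iff the kernel fits inside the region.

    Out-of-image pixels are treated as background, so the region also
    erodes at the frame border.  ``passes`` repeats the operation.
    """
    if passes < 0:
        raise ValueError("erode: passes must be >= 0")
    if passes == 0:
        return BinaryMask(mask.pixels.copy())
    out = ndimage.binary_erosion(
        mask.pixels.astype(bool),
        structure=kernel.K.astype(bool),
        iterations=passes,
        border_value=0,
    )
    return BinaryMask(out.astype(np.uint8))
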