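"""Tumor shape convexity with pleural-attachment slice exclusion.

The convexity of a tumor cross-section is the ratio of the area inside the
tumor perimeter to the area of its convex hull: 1 for a shape with no
concavities along its border, below 1 in proportion to protuberances and
depressions (spiculation, lobulation). The tumor-level score is the mean
over slices, excluding slices where the tumor presses against the pleural
wall — detected as more than half of the tumor perimeter pixels lying on
the lung-field perimeter — because pleural flattening smooths the apparent
margin and would inflate the score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io import AlignmentError, MaskVolume
from .morphology import convex_hull_mask, perimeter_mask

logger = logging.getLogger(__name__)

__all__ = [
    "SliceConvexity",
    "ConvexityResult",
    "slice_convexity",
    "pleural_overlap_fraction",
    "tumor_convexity",
]


@dataclass(frozen=True)
class SliceConvexity:
    slice_index: int
    score: float  # in (0, 1]
    overlap_fraction: float  # fraction of tumor perimeter on the lung perimeter
    excluded: bool


@dataclass
class ConvexityResult:
    """Per-slice convexity scores and the tumor-level mean.

    ``mean_convexity`` is the arithmetic mean over non-excluded slices; NaN
    when every tumor-bearing slice was excluded by the pleural rule.
    """

    per_slice: list[SliceConvexity] = field(default_factory=list)
    mean_convexity: float = math.nan

    @property
    def n_excluded(self) -> int:
        return sum(s.excluded for s in self.per_slice)


def _shoelace_area(verts: np.ndarray) -> float:
    r, c = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def slice_convexity(
    tumor_slice_mask: np.ndarray,
    hull_area: Literal["raster", "polygon"] = "raster",
) -> float:
    """Convexity of a single tumor cross-section.

    ``raster`` (default) divides the tumor pixel count by the pixel count of
    the rasterized hull (center-in-polygon, boundary inclusive), so convex
    pixel sets score exactly 1. ``polygon`` divides by the continuous
    shoelace area of the hull polygon, a sensitivity-analysis variant.
    """
    mask = np.asarray(tumor_slice_mask).astype(bool)
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise ValueError("convexity of an empty slice mask is undefined")
    verts, hull = convex_hull_mask(mask)
    if hull_area == "polygon":
        area = _shoelace_area(verts.astype(float))
        if area == 0.0:  # degenerate (collinear) hull
            return 1.0
        return n_fg / area
    return n_fg / int(hull.sum())


def pleural_overlap_fraction(
    tumor_slice_mask: np.ndarray,
    lung_slice_mask: np.ndarray,
    tolerance_px: int = 0,
) -> float:
    """Fraction of tumor-perimeter pixels that lie on the lung perimeter.

    Overlap is tested on exact pixel coordinates by default; ``tolerance_px``
    dilates the lung perimeter by that many pixels before intersecting, for
    clinical masks that do not align to the pixel.
    """
    tumor = np.asarray(tumor_slice_mask).astype(bool)
    lung = np.asarray(lung_slice_mask).astype(bool)
    if tumor.shape != lung.shape:
        raise AlignmentError("tumor and lung slice masks differ in shape")
    t_per = perimeter_mask(tumor)
    n = int(t_per.sum())
    if n == 0:
        raise ValueError("empty tumor perimeter")
    l_per = perimeter_mask(lung)
    if tolerance_px > 0:
        from .morphology import dilate, disk_element

        l_per = dilate(l_per, disk_element(tolerance_px))
    return int((t_per & l_per).sum()) / n


def tumor_convexity(
    tumor_seg: MaskVolume,
    lung_seg: MaskVolume | None = None,
    overlap_threshold: float = 0.5,
    hull_area: Literal["raster", "polygon"] = "raster",
    tolerance_px: int = 0,
) -> ConvexityResult:
    """Tumor-level convexity: per-slice scores with pleural exclusion.

    Every slice with tumor foreground is scored; slices whose perimeter
    overlap with the lung perimeter exceeds ``overlap_threshold`` (strictly)
    are excluded from the mean, per the more-than-half rule. Exactly-half
    overlap is retained. Without a lung mask (or with an empty lung slice)
    the overlap is 0 and a warning is logged.
    """
    if lung_seg is not None:
        lung_seg.validate_against(tumor_seg)
    per_slice: list[SliceConvexity] = []
    for z in range(tumor_seg.n_slices):
        t = tumor_seg.voxels[z].astype(bool)
        if not t.any():
            continue
        score = slice_convexity(t, hull_area=hull_area)
        if lung_seg is None or not lung_seg.voxels[z].any():
            if lung_seg is not None:
                logger.warning("slice %d: tumor present but lung mask empty; overlap set to 0", z)
            frac = 0.0
        else:
            frac = pleural_overlap_fraction(t, lung_seg.voxels[z], tolerance_px=tolerance_px)
        per_slice.append(SliceConvexity(z, score, frac, frac > overlap_threshold))
    if not per_slice:
        raise ValueError("tumor mask has no foreground voxels")
    included = [s.score for s in per_slice if not s.excluded]
    if included:
        mean = float(np.mean(included))
    else:
        logger.warning("all %d tumor slices excluded by the pleural rule; mean undefined", len(per_slice))
        mean = math.nan
    return ConvexityResult(per_slice=per_slice, mean_convexity=mean)
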