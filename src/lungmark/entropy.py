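"""Core/boundary entropy-ratio descriptor of intratumor density variation.

Pipeline per tumor-bearing slice:

1. the tumor mask is dilated with a disk of radius 3 px; eroding the dilated
   mask with a disk of radius 5 px gives the *core*; the set difference
   (dilated minus core) is the doughnut-shaped *boundary* ring;
2. HU values are min-max normalized over the dilated region of interest into
   256 integer bins;
3. a local Shannon entropy E = -sum_i p_i log2 p_i (bits) is computed for
   every pixel over the histogram of its 7x7 neighborhood (windows clipped
   at the image border);
4. entropies are pooled over all slices; the feature is the ratio of the
   mean boundary entropy to the mean core entropy.

A ratio near 1 means the texture diversity is consistent between the tumor
interior and its margin; larger ratios flag tumors whose rim is texturally
busier than their core.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import CTVolume, MaskVolume
from .morphology import dilate, disk_element, erode

logger = logging.getLogger(__name__)

__all__ = [
    "EntropyParams",
    "RegionMasks",
    "EntropyResult",
    "normalize_intensities",
    "local_entropy",
    "core_boundary_masks",
    "tumor_entropy_ratio",
]


@dataclass(frozen=True)
class EntropyParams:
    """Tunable parameters of the entropy-ratio feature.

    Defaults are the reference configuration: 256 intensity bins, a 7x7
    entropy window, dilation radius 3 px and erosion radius 5 px.
    """

    n_bins: int = 256
    window: int = 7
    r_dilate: int = 3
    r_erode: int = 5
    norm_scope: Literal["roi", "slice", "volume"] = "roi"

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.r_dilate < 1 or self.r_erode < 1:
            raise ValueError("structuring-element radii must be >= 1")


@dataclass(frozen=True)
class RegionMasks:
    """Core and boundary sub-region masks of one slice (disjoint; their
    union is the dilated tumor mask)."""

    core: np.ndarray
    boundary: np.ndarray

    @property
    def core_empty(self) -> bool:
        return not self.core.any()


@dataclass
class EntropyResult:
    """Pooled mean local entropies of the two sub-regions and their ratio."""

    entropy_core: float
    entropy_boundary: float
    entropy_ratio: float  # NaN when the core is empty or has zero entropy
    n_core_pixels: int
    n_boundary_pixels: int
    n_slices: int = 0
    n_slices_core_empty: int = 0
    entropy_maps: dict[int, np.ndarray] | None = None


def normalize_intensities(ct_slice: np.ndarray, roi: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Min-max bin a HU slice into ``n_bins`` integer levels over a ROI.

    The affine map sends the ROI minimum to bin 0 and the ROI maximum to bin
    ``n_bins - 1`` (values at an exact bin edge round down); pixels outside
    the ROI's HU range are clipped into ``[0, n_bins - 1]``. A constant ROI
    maps every pixel to bin 0.
    """
    img = np.asarray(ct_slice, float)
    roi = np.asarray(roi).astype(bool)
    if not roi.any():
        raise ValueError("normalization ROI is empty")
    lo = img[roi].min()
    hi = img[roi].max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.int64)
    scaled = np.floor((img - lo) / (hi - lo) * (n_bins - 1))
    return np.clip(scaled, 0, n_bins - 1).astype(np.int64)


def local_entropy(binned_slice: np.ndarray, window: int = 7, eval_mask: np.ndarray | None = None) -> np.ndarray:
    """Local Shannon entropy map in bits over a sliding window.

    For every pixel in ``eval_mask`` (default: all pixels) the entropy
    -sum p_i log2 p_i of the histogram of *all* pixels in its
    ``window x window`` neighborhood is computed, with the window clipped at
    the image border (border histograms are over fewer pixels). Pixels
    outside ``eval_mask`` are 0 in the returned map.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    binned = np.asarray(binned_slice)
    if binned.min() < 0:
        raise ValueError("binned slice must be non-negative integers")
    h, w = binned.shape
    if eval_mask is None:
        eval_mask = np.ones((h, w), bool)
    eval_mask = np.asarray(eval_mask).astype(bool)
    rows, cols = np.nonzero(eval_mask)
    out = np.zeros((h, w), float)
    if len(rows) == 0:
        return out
    r = window // 2
    nb = int(binned.max()) + 1
    padded = np.full((h + 2 * r, w + 2 * r), -1, dtype=np.int64)
    padded[r : r + h, r : r + w] = binned
    windows = sliding_window_view(padded, (window, window))
    vals = windows[rows, cols].reshape(len(rows), -1)  # (n_eval, window^2), -1 marks off-image
    valid = vals >= 0
    counts = np.zeros((len(rows), nb), dtype=np.int64)
    row_idx = np.broadcast_to(np.arange(len(rows))[:, None], vals.shape)
    np.add.at(counts, (row_idx[valid], vals[valid]), 1)
    totals = valid.sum(axis=1, keepdims=True)
    p = counts / totals
    p_safe = np.where(p > 0, p, 1.0)  # log2(1) = 0, zero bins contribute nothing
    out[rows, cols] = -(p_safe * np.log2(p_safe)).sum(axis=1)
    return out


def core_boundary_masks(tumor_slice_mask: np.ndarray, r_dilate: int = 3, r_erode: int = 5) -> RegionMasks:
    """Construct the core and boundary sub-regions of one tumor slice.

    The mask is dilated with a disk of radius ``r_dilate``; the dilated mask
    eroded with a disk of radius ``r_erode`` is the core; boundary = dilated
    minus core. On convex masks the ring is about ``r_erode`` pixels wide,
    straddling the original tumor border (``r_dilate`` outside it,
    ``r_erode - r_dilate`` inside). Tumors thinner than the erosion yield
    an empty core
    (``RegionMasks.core_empty``); the downstream ratio is undefined for
    such a slice.
    """
    mask = np.asarray(tumor_slice_mask).astype(bool)
    if not mask.any():
        raise ValueError("tumor slice mask is empty")
    dilated = dilate(mask, disk_element(r_dilate))
    core = erode(dilated, disk_element(r_erode))
    boundary = dilated & ~core
    return RegionMasks(core=core, boundary=boundary)


def tumor_entropy_ratio(
    ct: CTVolume,
    tumor_seg: MaskVolume,
    params: EntropyParams = EntropyParams(),
    keep_maps: bool = False,
) -> EntropyResult:
    """Volume-level entropy ratio: pooled boundary mean over pooled core mean.

    Entropy coefficients from every tumor-bearing slice are pooled into one
    core ensemble and one boundary ensemble; the feature is the ratio of
    their means. Slices whose core erodes away contribute boundary pixels
    only (logged). Raises if no usable core pixels exist in the whole tumor.
    """
    tumor_seg.validate_against(ct)
    core_vals: list[np.ndarray] = []
    boundary_vals: list[np.ndarray] = []
    maps: dict[int, np.ndarray] = {}
    n_slices = 0
    n_core_empty = 0

    if params.norm_scope == "volume":
        vol_lo = ct.voxels.min()
        vol_hi = ct.voxels.max()

    for z in range(tumor_seg.n_slices):
        mask = tumor_seg.voxels[z].astype(bool)
        if not mask.any():
            continue
        n_slices += 1
        regions = core_boundary_masks(mask, params.r_dilate, params.r_erode)
        dilated = regions.core | regions.boundary
        img = ct.voxels[z]
        if params.norm_scope == "roi":
            binned = normalize_intensities(img, dilated, params.n_bins)
        elif params.norm_scope == "slice":
            binned = normalize_intensities(img, np.ones(img.shape, bool), params.n_bins)
        else:  # volume
            if vol_hi == vol_lo:
                binned = np.zeros(img.shape, np.int64)
            else:
                binned = np.clip(
                    np.floor((img - vol_lo) / (vol_hi - vol_lo) * (params.n_bins - 1)), 0, params.n_bins - 1
                ).astype(np.int64)
        emap = local_entropy(binned, params.window, eval_mask=dilated)
        if regions.core_empty:
            n_core_empty += 1
            logger.info("slice %d: core eroded away; contributing boundary pixels only", z)
        else:
            core_vals.append(emap[regions.core])
        boundary_vals.append(emap[regions.boundary])
        if keep_maps:
            maps[z] = emap

    if n_slices == 0:
        raise ValueError("tumor mask has no foreground voxels")
    n_core = int(sum(v.size for v in core_vals))
    n_boundary = int(sum(v.size for v in boundary_vals))
    if n_core == 0:
        raise ValueError("no usable core pixels in the whole tumor; entropy ratio undefined")
    e_core = float(np.concatenate(core_vals).mean())
    e_boundary = float(np.concatenate(boundary_vals).mean()) if n_boundary else math.nan
    ratio = e_boundary / e_core if e_core > 0 else math.nan
    if e_core == 0:
        logger.warning("core entropy is exactly 0; entropy ratio undefined")
    return EntropyResult(
        entropy_core=e_core,
        entropy_boundary=e_boundary,
        entropy_ratio=ratio,
        n_core_pixels=n_core,
        n_boundary_pixels=n_boundary,
        n_slices=n_slices,
        n_slices_core_empty=n_core_empty,
        entropy_maps=maps if keep_maps else None,
    )
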