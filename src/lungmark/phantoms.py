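"""Synthetic CT phantoms with known ground truth.

The generator emulates the inputs the feature pipeline consumes, with the
ground truth that real cohorts lack:

* **shape** — slice-stacked tumor masks with a radial boundary
  ``r(theta) = R0 * (1 + a cos(k theta))``: ``a = 0`` gives digital disks
  (convexity 1), growing spike amplitude ``a`` carves concavities so the
  expected convexity ordering across an ``a``-sweep is known by
  construction;
* **texture** — core and boundary regions painted with discrete HU levels
  drawn uniformly from a controllable number of levels, so the expected
  window-histogram diversity (hence the core/boundary entropy contrast) is
  ordered by construction;
* **pleural contact** — a lung field whose flat wall clips the tumor along
  a chord, with the realized perimeter-overlap fraction measured and
  reported as ground truth;
* **test-retest pairs** — a second realization with small translation,
  mask-boundary jitter and independent HU noise, emulating repeat scans
  acquired minutes apart.

Identical specs and seeds reproduce volumes bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .convexity import pleural_overlap_fraction
from .entropy import core_boundary_masks
from .io import CTVolume, MaskVolume
from .morphology import perimeter_mask

__all__ = [
    "ShapeSpec",
    "TextureSpec",
    "PleuralPhantom",
    "radial_tumor_mask",
    "textured_tumor_image",
    "lung_field_with_attachment",
    "test_retest_pair",
    "make_phantom_case",
]


@dataclass(frozen=True)
class ShapeSpec:
    """Radial tumor-shape specification.

    ``spike_amplitude`` (a) in [0, 0.6] and ``lobe_count`` (k) control the
    boundary perturbation ``R0 (1 + a cos k theta)``; ``slice_profile``
    tapers the per-slice radius ("constant", or "elliptic" for a
    sphere-like cap profile).
    """

    base_radius: float = 20.0
    spike_amplitude: float = 0.0
    lobe_count: int = 8
    n_slices: int = 3
    slice_profile: Literal["constant", "elliptic"] = "constant"

    def __post_init__(self):
        if not 0.0 <= self.spike_amplitude <= 0.6:
            raise ValueError("spike_amplitude must be in [0, 0.6]")
        if self.base_radius * (1.0 - self.spike_amplitude) <= 0:
            raise ValueError("radius must stay positive for all angles")
        if self.n_slices < 1 or self.lobe_count < 0:
            raise ValueError("n_slices >= 1 and lobe_count >= 0 required")

    def slice_scale(self, z: int) -> float:
        if self.slice_profile == "constant" or self.n_slices == 1:
            return 1.0
        # elliptic cap, clamped so end slices keep a usable cross-section
        u = 2.0 * z / (self.n_slices - 1) - 1.0
        return max(np.sqrt(max(1.0 - 0.75 * u * u, 0.0)), 0.5)


@dataclass(frozen=True)
class TextureSpec:
    """Discrete-level texture for one tumor sub-region.

    Pixels are drawn uniformly from ``bins_used`` evenly spaced HU levels
    spanning ``level_span`` HU above ``base_HU`` (one level when
    ``bins_used == 1``), plus Gaussian noise of sd ``noise_sd``. Discrete
    levels keep the expected local-window histograms — hence the expected
    entropies — analytically tractable.
    """

    bins_used: int = 32
    base_HU: float = -50.0
    noise_sd: float = 0.0
    level_span: float = 200.0

    def __post_init__(self):
        if not 1 <= self.bins_used <= 256:
            raise ValueError("bins_used must be in [1, 256]")

    def levels(self) -> np.ndarray:
        if self.bins_used == 1:
            return np.array([self.base_HU])
        return self.base_HU + np.arange(self.bins_used) * (self.level_span / (self.bins_used - 1))


@dataclass
class PleuralPhantom:
    """Lung field plus the tumor flattened against its wall."""

    lung: MaskVolume
    tumor: MaskVolume
    realized_fractions: list[float]  # per tumor-bearing slice, mid-slice order
    target_fraction: float

    @property
    def realized_fraction(self) -> float:
        return float(np.mean(self.realized_fractions)) if self.realized_fractions else 0.0


def radial_tumor_mask(spec: ShapeSpec, grid_size: int = 96) -> MaskVolume:
    """Rasterize the radial shape model into a slice-stacked binary mask."""
    r_max = spec.base_radius * (1.0 + spec.spike_amplitude)
    if 2 * r_max + 2 >= grid_size:
        raise ValueError(f"shape of extent {2 * r_max:.1f} px does not fit a {grid_size}-px grid")
    c = (grid_size - 1) / 2.0
    rows, cols = np.mgrid[0:grid_size, 0:grid_size]
    dr = rows - c
    dc = cols - c
    rad = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    slices = []
    for z in range(spec.n_slices):
        limit = spec.base_radius * spec.slice_scale(z) * (1.0 + spec.spike_amplitude * np.cos(spec.lobe_count * theta))
        slices.append(rad <= limit)
    return MaskVolume(np.stack(slices).astype(np.uint8), kind="tumor")


def textured_tumor_image(
    mask: MaskVolume,
    core: TextureSpec,
    boundary: TextureSpec,
    background_HU: float = -800.0,
    background_noise_sd: float = 0.0,
    r_dilate: int = 3,
    r_erode: int = 5,
    apron_px: int = 3,
    seed: int = 0,
) -> CTVolume:
    """Paint a CT volume with region-specific discrete-level textures.

    The core/boundary painting regions are the same morphological
    sub-regions the entropy feature measures (dilate ``r_dilate``, erode
    ``r_erode``), so the constructed texture contrast lands exactly on the
    measured regions. The boundary texture additionally extends an
    ``apron_px``-wide apron beyond the dilated mask (default: the entropy
    window radius), so local windows centered on ring pixels sample ring
    texture rather than the flat background — without it the boundary
    entropy of even a symmetric construction is biased low by the
    background. Background elsewhere is a constant plus optional Gaussian
    noise. Reproducible under ``seed``.
    """
    from .morphology import dilate as _dilate, disk_element

    rng = np.random.default_rng(seed)
    vox = np.empty(mask.voxels.shape, float)
    core_levels = core.levels()
    boundary_levels = boundary.levels()
    for z in range(mask.n_slices):
        sl = np.full(mask.voxels.shape[1:], background_HU, float)
        if background_noise_sd > 0:
            sl += rng.normal(0.0, background_noise_sd, sl.shape)
        m = mask.voxels[z].astype(bool)
        if m.any():
            regions = core_boundary_masks(m, r_dilate, r_erode)
            ring = regions.boundary
            if apron_px > 0:
                dilated = regions.core | regions.boundary
                ring = ring | (_dilate(dilated, disk_element(apron_px)) & ~dilated)
            n_core = int(regions.core.sum())
            n_ring = int(ring.sum())
            if n_core:
                sl[regions.core] = rng.choice(core_levels, n_core)
                if core.noise_sd > 0:
                    sl[regions.core] += rng.normal(0.0, core.noise_sd, n_core)
            if n_ring:
                sl[ring] = rng.choice(boundary_levels, n_ring)
                if boundary.noise_sd > 0:
                    sl[ring] += rng.normal(0.0, boundary.noise_sd, n_ring)
        vox[z] = sl
    return CTVolume(vox, mask.pixel_spacing, mask.slice_thickness)


def _ellipse_mask(shape, center, semi_r, semi_c):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rows - center[0]) / semi_r) ** 2 + ((cols - center[1]) / semi_c) ** 2 <= 1.0


def lung_field_with_attachment(tumor: MaskVolume, attach: float = 0.0) -> PleuralPhantom:
    """Build a lung field and flatten the tumor against its wall.

    The lung is a large ellipse whose right wall is a flat chord (a plane
    pleural facet). For ``attach > 0`` the facet is cut into the tumor so
    that about the requested fraction of tumor-perimeter pixels coincide
    with the lung perimeter; the cut depth is searched on the widest tumor
    slice and the realized per-slice fractions are measured and reported.
    If the request exceeds what the shape admits, the maximum achievable
    cut is used with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    if not 0.0 <= attach <= 1.0:
        raise ValueError("attach must be in [0, 1]")
    shape = tumor.voxels.shape[1:]
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    semi_r = shape[0] / 2.0 - 1.5
    semi_c = shape[1] / 2.0 - 1.5
    ellipse = _ellipse_mask(shape, center, semi_r, semi_c)

    fg_counts = tumor.voxels.sum(axis=(1, 2))
    if not fg_counts.any():
        raise ValueError("tumor mask is empty")
    mid = int(np.argmax(fg_counts))
    mid_mask = tumor.voxels[mid].astype(bool)
    col_max = int(np.argwhere(mid_mask)[:, 1].max())
    col_min = int(np.argwhere(mid_mask)[:, 1].min())

    def realized(cut_col: int) -> float:
        lung_sl = ellipse & (np.arange(shape[1])[None, :] <= cut_col)
        t = mid_mask & lung_sl
        if not t.any() or not perimeter_mask(t).any():
            return np.nan
        return pleural_overlap_fraction(t, lung_sl)

    if attach == 0.0:
        cut = shape[1] - 1  # wall beyond the tumor: no contact
    else:
        candidates = range(col_min + 1, col_max + 1)
        fracs = {c: realized(c) for c in candidates}
        fracs = {c: f for c, f in fracs.items() if np.isfinite(f)}
        best_max = max(fracs.values(), default=0.0)
        if best_max < attach:
            logger.warning("requested attachment %.2f exceeds achievable %.2f; using maximum", attach, best_max)
            cut = max((c for c, f in fracs.items() if f == best_max), default=col_max)
        else:
            cut = min(fracs, key=lambda c: (abs(fracs[c] - attach), c))

    lung_vox = np.empty_like(tumor.voxels)
    tum_vox = np.empty_like(tumor.voxels)
    fractions = []
    wall = np.arange(shape[1])[None, :] <= cut
    for z in range(tumor.n_slices):
        lung_sl = ellipse & wall
        t = tumor.voxels[z].astype(bool) & lung_sl
        lung_vox[z] = lung_sl
        tum_vox[z] = t
        if t.any():
            fractions.append(pleural_overlap_fraction(t, lung_sl))
    lung = MaskVolume(lung_vox, kind="lung", pixel_spacing=tumor.pixel_spacing, slice_thickness=tumor.slice_thickness)
    tum = MaskVolume(tum_vox, kind="tumor", pixel_spacing=tumor.pixel_spacing, slice_thickness=tumor.slice_thickness)
    return PleuralPhantom(lung=lung, tumor=tum, realized_fractions=fractions, target_fraction=attach)


def _int_shift(arr: np.ndarray, dz_rc: tuple[int, int], fill) -> np.ndarray:
    """Shift each slice by integer (drow, dcol), filling with ``fill``."""
    out = np.full_like(arr, fill)
    dr, dc = dz_rc
    h, w = arr.shape[1:]
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[:, dst_r, dst_c] = arr[:, src_r, src_c]
    return out


def _jitter_mask(mask2d: np.ndarray, rounds: int, rng: np.random.Generator, flip_p: float = 0.3) -> np.ndarray:
    """Morphological boundary jitter: randomly drop perimeter pixels and add
    background pixels 4-adjacent to the foreground, ``rounds`` times."""
    from scipy import ndimage

    m = mask2d.astype(bool).copy()
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    for _ in range(rounds):
        per = perimeter_mask(m)
        shell = ndimage.binary_dilation(m, cross) & ~m
        drop = per & (rng.random(m.shape) < flip_p)
        add = shell & (rng.random(m.shape) < flip_p)
        m = (m & ~drop) | add
        if not m.any():  # never annihilate the mask entirely
            m = mask2d.astype(bool).copy()
    return m


def test_retest_pair(
    ct: CTVolume,
    tumor: MaskVolume,
    lung: MaskVolume | None = None,
    translation_px: float = 0.5,
    jitter_px: int = 1,
    hu_noise_sd: float = 5.0,
    seed: int = 0,
    background_HU: float = -800.0,
) -> tuple[CTVolume, MaskVolume, MaskVolume | None]:
    """Second (retest) realization of a phantom case.

    Applies one shared sub-pixel translation (rounded to the voxel grid) to
    image and masks, independent Gaussian HU noise, and ``jitter_px`` rounds
    of random boundary jitter to the tumor mask.
    """
    rng = np.random.default_rng(seed)
    dr = int(round(rng.uniform(-translation_px, translation_px)))
    dc = int(round(rng.uniform(-translation_px, translation_px)))
    vox = _int_shift(ct.voxels, (dr, dc), fill=background_HU)
    if hu_noise_sd > 0:
        vox = vox + rng.normal(0.0, hu_noise_sd, vox.shape)
    tum = _int_shift(tumor.voxels, (dr, dc), fill=0)
    if jitter_px > 0:
        tum = np.stack([
            _jitter_mask(tum[z], jitter_px, rng) if tum[z].any() else tum[z].astype(bool)
            for z in range(tum.shape[0])
        ]).astype(np.uint8)
    ct2 = CTVolume(vox, ct.pixel_spacing, ct.slice_thickness)
    tumor2 = MaskVolume(tum, kind="tumor", pixel_spacing=tumor.pixel_spacing, slice_thickness=tumor.slice_thickness)
    lung2 = None
    if lung is not None:
        lung2 = MaskVolume(
            _int_shift(lung.voxels, (dr, dc), fill=0),
            kind="lung",
            pixel_spacing=lung.pixel_spacing,
            slice_thickness=lung.slice_thickness,
        )
    return ct2, tumor2, lung2


def make_phantom_case(
    shape: ShapeSpec = ShapeSpec(),
    core: TextureSpec = TextureSpec(bins_used=8),
    boundary: TextureSpec = TextureSpec(bins_used=8),
    attach: float = 0.0,
    grid_size: int = 96,
    seed: int = 0,
) -> tuple[CTVolume, MaskVolume, MaskVolume, PleuralPhantom]:
    """One complete phantom case: image, tumor mask, lung mask."""
    tumor = radial_tumor_mask(shape, grid_size)
    pleural = lung_field_with_attachment(tumor, attach)
    ct = textured_tumor_image(pleural.tumor, core, boundary, seed=seed)
    return ct, pleural.tumor, pleural.lung, pleural
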