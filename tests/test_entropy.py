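"""Entropy-ratio descriptor: intensity binning, local entropy filter,
core/boundary construction, and pooled ratio."""

import math

import numpy as np
import pytest

from lungmark.entropy import (
    EntropyParams,
    core_boundary_masks,
    local_entropy,
    normalize_intensities,
    tumor_entropy_ratio,
)
from lungmark.io import CTVolume, MaskVolume
from lungmark.phantoms import ShapeSpec, TextureSpec, radial_tumor_mask, textured_tumor_image

from conftest import brute_local_entropy


# --- normalization ---------------------------------------------------------

def test_min_max_binning_maps_roi_range_onto_bins():
    sl = np.array([[-100.0, 0.0, 100.0]])
    roi = np.ones((1, 3), bool)
    binned = normalize_intensities(sl, roi, 256)
    # midpoint 0 HU maps to 127 (exact bin edges round down)
    assert binned.tolist() == [[0, 127, 255]]


def test_binning_clips_values_outside_roi_range():
    sl = np.array([[0.0, 10.0, -50.0, 60.0]])
    roi = np.array([[True, True, False, False]])
    binned = normalize_intensities(sl, roi, 256)
    assert binned[0, 2] == 0 and binned[0, 3] == 255


def test_constant_roi_maps_everything_to_bin_zero():
    binned = normalize_intensities(np.full((4, 4), 37.0), np.ones((4, 4), bool), 256)
    assert (binned == 0).all()


def test_two_bin_binning():
    binned = normalize_intensities(np.array([[0.0, 1.0]]), np.ones((1, 2), bool), 2)
    assert binned.tolist() == [[0, 1]]


def test_empty_roi_rejected():
    with pytest.raises(ValueError):
        normalize_intensities(np.zeros((3, 3)), np.zeros((3, 3), bool))


# --- local entropy ---------------------------------------------------------

def test_constant_neighborhood_has_zero_entropy():
    assert local_entropy(np.full((9, 9), 5), 7)[4, 4] == 0.0


def test_two_bin_window_entropy_matches_closed_form():
    # 25 pixels of one bin, 24 of another in a 7x7 window
    vals = np.array([0] * 25 + [1] * 24).reshape(7, 7)
    e = local_entropy(vals, 7)[3, 3]
    expected = -(25 / 49) * math.log2(25 / 49) - (24 / 49) * math.log2(24 / 49)
    assert e == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.99970, abs=5e-5)


def test_all_distinct_window_is_uniform_entropy():
    vals = np.arange(49).reshape(7, 7)
    assert local_entropy(vals, 7)[3, 3] == pytest.approx(math.log2(49), abs=1e-12)


def test_entropy_map_matches_brute_force_histograms(rng):
    """Implementation vs naive per-pixel histogram oracle, borders included."""
    for _ in range(10):
        binned = rng.integers(0, 16, (16, 16))
        assert np.allclose(local_entropy(binned, 7), brute_local_entropy(binned, 7), atol=1e-12)
        assert np.allclose(local_entropy(binned, 5), brute_local_entropy(binned, 5), atol=1e-12)


def test_entropy_bounded_by_window_and_bin_capacity(rng):
    binned = rng.integers(0, 256, (20, 20))
    e = local_entropy(binned, 7)
    assert (e >= 0).all()
    assert (e <= math.log2(49) + 1e-12).all()


def test_eval_mask_restricts_computation(rng):
    binned = rng.integers(0, 8, (10, 10))
    mask = np.zeros((10, 10), bool)
    mask[3, 4] = True
    e = local_entropy(binned, 7, eval_mask=mask)
    assert e[3, 4] > 0
    assert (e[~mask] == 0).all()


def test_even_or_tiny_window_rejected():
    with pytest.raises(ValueError):
        local_entropy(np.zeros((5, 5), int), 4)


# --- core/boundary construction --------------------------------------------

def test_disk_core_and_ring_match_euclidean_prediction(disk_mask):
    """On a radius-20 digital disk: dilate r=3 then erode r=5 leaves a core
    about radius 18 and a ring about 8 px wide."""
    regions = core_boundary_masks(disk_mask, 3, 5)
    assert not (regions.core & regions.boundary).any()
    dilated = regions.core | regions.boundary
    assert (disk_mask & ~dilated).sum() == 0  # tumor inside dilated
    # core approximates the analytic Euclidean disk of radius 18
    rr, cc = np.mgrid[0:51, 0:51]
    dist = np.hypot(rr - 25, cc - 25)
    assert (regions.core & (dist > 19)).sum() == 0
    assert (~regions.core & (dist <= 17)).sum() == 0
    # ring spans radii (18, 23]: width r_erode +/- 1 along the axis
    left_run = np.flatnonzero(regions.boundary[25, :25]).size
    assert 4 <= left_run <= 6


def test_thin_tumor_over_erodes_to_empty_core():
    m = np.zeros((20, 20), bool)
    m[9:12, 9:12] = True  # 3x3: dilated radius ~4.5 < erosion radius 5
    regions = core_boundary_masks(m, 3, 5)
    assert regions.core_empty
    assert regions.boundary.any()


def test_full_frame_mask_ring_confined_to_image_rim():
    m = np.ones((30, 30), bool)
    regions = core_boundary_masks(m, 3, 5)
    assert regions.boundary[8:22, 8:22].sum() == 0
    assert regions.boundary.any()


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        core_boundary_masks(np.zeros((5, 5), bool))


# --- pooled tumor-level ratio ----------------------------------------------

def _phantom(core_bins, boundary_bins, n_slices=2, seed=0):
    mask = radial_tumor_mask(ShapeSpec(base_radius=20, n_slices=n_slices), 96)
    ct = textured_tumor_image(
        mask, TextureSpec(bins_used=core_bins), TextureSpec(bins_used=boundary_bins), seed=seed
    )
    return ct, mask


def test_symmetric_texture_gives_ratio_near_one():
    ct, mask = _phantom(8, 8, seed=1)
    res = tumor_entropy_ratio(ct, mask)
    assert 0.95 <= res.entropy_ratio <= 1.05


def test_boundary_diversity_contrast_pushes_ratio_up():
    ct, mask = _phantom(2, 64, seed=2)
    res = tumor_entropy_ratio(ct, mask)
    assert res.entropy_ratio > 1.3
    assert res.entropy_boundary > res.entropy_core


def test_ratio_strictly_increasing_in_boundary_diversity():
    for seed in (0, 1, 2):
        ratios = []
        for bb in (2, 4, 8, 16, 64):
            ct, mask = _phantom(4, bb, seed=seed)
            ratios.append(tumor_entropy_ratio(ct, mask).entropy_ratio)
        assert all(x < y for x, y in zip(ratios, ratios[1:]))


def test_intensity_shift_invariance():
    ct, mask = _phantom(4, 16, seed=3)
    shifted = CTVolume(ct.voxels + 500.0, ct.pixel_spacing, ct.slice_thickness)
    a = tumor_entropy_ratio(ct, mask)
    b = tumor_entropy_ratio(shifted, mask)
    assert a.entropy_core == b.entropy_core
    assert a.entropy_boundary == b.entropy_boundary


def test_single_slice_pooling_equals_single_slice_computation():
    ct, mask = _phantom(4, 16, n_slices=1, seed=4)
    res = tumor_entropy_ratio(ct, mask)
    assert res.n_slices == 1
    assert res.entropy_ratio == pytest.approx(res.entropy_boundary / res.entropy_core)


def test_flat_texture_yields_zero_entropy_and_undefined_ratio():
    mask = radial_tumor_mask(ShapeSpec(base_radius=15, n_slices=1), 64)
    ct = textured_tumor_image(mask, TextureSpec(bins_used=1), TextureSpec(bins_used=1), seed=0)
    res = tumor_entropy_ratio(ct, mask)
    assert res.entropy_core == 0.0
    assert res.entropy_boundary == 0.0
    assert math.isnan(res.entropy_ratio)


def test_thin_tumor_everywhere_has_no_core_and_raises():
    vox = np.zeros((1, 20, 20), np.uint8)
    vox[0, 9:12, 9:12] = 1
    mask = MaskVolume(vox)
    ct = CTVolume(np.zeros((1, 20, 20)))
    with pytest.raises(ValueError):
        tumor_entropy_ratio(ct, mask)


def test_entropy_maps_returned_on_request():
    ct, mask = _phantom(4, 8, n_slices=2, seed=5)
    res = tumor_entropy_ratio(ct, mask, keep_maps=True)
    assert set(res.entropy_maps) == {0, 1}
    assert res.entropy_maps[0].shape == ct.voxels.shape[1:]


def test_params_validation():
    with pytest.raises(ValueError):
        EntropyParams(window=6)
    with pytest.raises(ValueError):
        EntropyParams(n_bins=1)
    with pytest.raises(ValueError):
        EntropyParams(r_dilate=0)
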