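"""Thresholding, smoothing, cropping and shape-based slice interpolation."""

import numpy as np
import pytest
from scipy import ndimage

from foci3d.grids import GrayVolume, SliceLabelStack
from foci3d.phantom import PhantomConfig, generate_phantom
from foci3d.segmentation import (TissueMask, crop_subvolume,
                                 estimate_paraffin_threshold,
                                 interpolate_missing_slices, segment_tissue,
                                 smooth_mask)


def _disc(r, shape=(40, 40), c=None):
    c = c or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (((yy - c[0]) ** 2 + (xx - c[1]) ** 2) <= r * r).astype(np.int32)


class TestParaffinThreshold:
    def test_uniform_roi_mean(self):
        vol = GrayVolume(np.full((4, 4, 4), 100.0), spacing_um=8.0)
        with pytest.warns(UserWarning, match="ROI"):
            thr = estimate_paraffin_threshold(vol, ((0, 4), (0, 4), (0, 4)))
        assert thr == 100.0

    def test_two_level_roi_mean(self):
        data = np.empty((2, 4, 4))
        data[0], data[1] = 90.0, 110.0
        vol = GrayVolume(data, spacing_um=8.0)
        thr = estimate_paraffin_threshold(vol, ((0, 2), (0, 4), (0, 4)),
                                          min_volume_mm3=0.0)
        assert thr == 100.0

    def test_noisy_one_mm3_roi_recovers_paraffin_mean(self, rng):
        # 125^3 voxels at 8 um is 1 mm^3; SE of the mean is ~0.004 gray levels
        data = rng.normal(80.0, 5.0, (125, 125, 125))
        vol = GrayVolume(data, spacing_um=8.0)
        thr = estimate_paraffin_threshold(vol, ((0, 125), (0, 125), (0, 125)))
        assert abs(thr - 80.0) < 1.0

    def test_roi_outside_volume_rejected(self):
        vol = GrayVolume(np.zeros((4, 4, 4)), spacing_um=8.0)
        with pytest.raises(ValueError, match="outside"):
            estimate_paraffin_threshold(vol, ((0, 5), (0, 4), (0, 4)))


class TestSegmentTissue:
    def test_all_below_threshold_gives_empty_mask(self):
        vol = GrayVolume(np.full((3, 3, 3), 50.0), spacing_um=8.0)
        assert not segment_tissue(vol, 50.0).data.any()  # strict >

    def test_max_threshold_gives_empty_mask(self, rng):
        vol = GrayVolume(rng.random((4, 4, 4)), spacing_um=8.0)
        assert not segment_tissue(vol, float(vol.data.max())).data.any()

    def test_noise_free_phantom_segments_exactly(self):
        cfg = PhantomConfig(shape=(32, 48, 48), noise_sigma=0.0, focus_density=5.0,
                            focus_volume_range=(1.6e4, 1e5), airspace_fraction=0.1,
                            seed=6)
        gray, labels, truth = generate_phantom(cfg)
        # threshold between paraffin (80) and focus (120): tissue+foci survive
        mask = segment_tissue(gray, 100.0)
        expected = (gray.data == cfg.intensity_tissue) | (gray.data == cfg.intensity_focus)
        assert np.array_equal(mask.data, expected)
        assert mask.data.sum() * cfg.spacing_um ** 3 / 1e9 == pytest.approx(
            truth.tissue_volume_mm3)

    def test_monotone_in_threshold(self, rng):
        vol = GrayVolume(rng.normal(100, 20, (10, 10, 10)), spacing_um=8.0)
        lower = segment_tissue(vol, 90.0).data
        higher = segment_tissue(vol, 110.0).data
        assert not (higher & ~lower).any()  # raising threshold never adds voxels


class TestSmoothMask:
    def _mask(self, data):
        return TissueMask(data, spacing_um=8.0, threshold_used=0.0)

    def test_solid_cube_unchanged(self):
        m = np.zeros((14, 14, 14), bool)
        m[2:12, 2:12, 2:12] = True
        out = smooth_mask(self._mask(m))
        assert np.array_equal(out.data, m)

    def test_isolated_voxel_removed(self):
        m = np.zeros((7, 7, 7), bool)
        m[3, 3, 3] = True
        assert not smooth_mask(self._mask(m)).data.any()

    def test_changes_only_where_strict_majority_disagrees(self, rng):
        # direct per-voxel vote over the 7-voxel cross neighborhood
        m = rng.random((12, 12, 12)) < 0.5
        out = smooth_mask(self._mask(m)).data
        p = np.pad(m, 1).astype(int)
        counts = (p[1:-1, 1:-1, 1:-1] + p[:-2, 1:-1, 1:-1] + p[2:, 1:-1, 1:-1]
                  + p[1:-1, :-2, 1:-1] + p[1:-1, 2:, 1:-1]
                  + p[1:-1, 1:-1, :-2] + p[1:-1, 1:-1, 2:])
        assert np.array_equal(out, counts > 3)  # majority of 7, no ties possible
        changed = out != m
        assert ((counts > 3) != m)[changed].all()  # flips only against majority

    def test_pinhole_filled(self):
        m = np.ones((7, 7, 7), bool)
        m[3, 3, 3] = False
        assert smooth_mask(self._mask(m)).data.all()

    def test_idempotent_on_smooth_solids(self):
        m = np.zeros((16, 16, 16), bool)
        m[3:13, 2:14, 4:11] = True
        once = smooth_mask(self._mask(m))
        twice = smooth_mask(once)
        assert np.array_equal(once.data, twice.data)


class TestCrop:
    def test_full_range_is_identity(self, rng):
        vol = GrayVolume(rng.random((5, 6, 7)), spacing_um=8.0)
        out = crop_subvolume(vol, (0, 5), (0, 6), (0, 7))
        assert np.array_equal(out.data, vol.data)

    def test_depth_crop_at_8um_gives_1mm(self, rng):
        vol = GrayVolume(rng.random((200, 8, 8)), spacing_um=8.0)
        sub = crop_subvolume(vol, (0, 125), (0, 8), (0, 8))
        assert sub.data.shape[0] * sub.spacing_um == 1000.0

    def test_origin_shifts_with_crop(self, rng):
        vol = GrayVolume(rng.random((6, 6, 6)), spacing_um=8.0)
        sub = crop_subvolume(vol, (2, 5), (1, 6), (0, 6))
        assert np.array_equal(sub.origin_um, [16.0, 8.0, 0.0])

    def test_empty_range_rejected(self, rng):
        vol = GrayVolume(rng.random((6, 6, 6)), spacing_um=8.0)
        with pytest.raises(ValueError, match="crop range"):
            crop_subvolume(vol, (5, 5), (0, 6), (0, 6))

    def test_no_voxels_created_or_lost(self, rng):
        m = rng.random((10, 10, 10)) < 0.4
        mask = TissueMask(m, spacing_um=8.0, threshold_used=0.0)
        parts = [crop_subvolume(mask, (a, b), (0, 10), (0, 10)).data.sum()
                 for a, b in [(0, 4), (4, 10)]]
        assert sum(parts) == m.sum()


class TestInterpolateMissingSlices:
    def test_constant_cross_section_restored_exactly(self):
        sq = np.zeros((20, 20), np.int32)
        sq[5:12, 4:15] = 3
        stack = SliceLabelStack([(0, sq), (2, sq)], (20, 20), 8.0)
        out = interpolate_missing_slices(stack)
        assert np.array_equal(out.data[1], sq)
        assert np.array_equal(out.data[0], sq)  # present slices verbatim

    def test_disc_radii_interpolate_to_mid_radius(self):
        stack = SliceLabelStack([(0, _disc(4)), (2, _disc(8))], (40, 40), 8.0)
        out = interpolate_missing_slices(stack)
        r_eff = np.sqrt(out.data[1].astype(bool).sum() / np.pi)
        assert abs(r_eff - 6.0) <= 1.0

    def test_label_absent_from_a_bounding_slice_stays_absent(self):
        below = np.zeros((20, 20), np.int32)
        above = _disc(5, (20, 20)) * 2
        stack = SliceLabelStack([(0, below), (2, above)], (20, 20), 8.0)
        out = interpolate_missing_slices(stack)
        assert not out.data[1].any()

    def test_wide_gap_left_empty_with_warning(self):
        stack = SliceLabelStack([(0, _disc(6)), (6, _disc(6))], (40, 40), 8.0)
        with pytest.warns(UserWarning, match="max_gap"):
            out = interpolate_missing_slices(stack, max_gap=3)
        assert not out.data[1:6].any()

    def test_cone_slice_recovered_within_area_tolerance(self):
        # digital cone: radius falls linearly with depth; drop each interior
        # slice in turn and compare the reconstruction to the analytic cone
        radii = {z: 12 - z for z in range(9)}  # 12 .. 4
        for missing in range(1, 8):
            entries = [(z, _disc(radii[z], (30, 30))) for z in range(9) if z != missing]
            out = interpolate_missing_slices(
                SliceLabelStack(entries, (30, 30), 8.0))
            got = out.data[missing].astype(bool).sum()
            want = _disc(radii[missing], (30, 30)).sum()
            assert abs(got - want) <= 0.15 * want

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            interpolate_missing_slices(
                SliceLabelStack([], (4, 4), 8.0))
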