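"""Multilevel Otsu, calcification segmentation and partial-volume correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valve3d import (ImageVolume, PipelineConfig, calc_volume_fraction,
                     multilevel_otsu, pooled_thresholds, pve_decompose,
                     segment_calcification)
from valve3d.reference import exhaustive_multiotsu

from helpers import random_histogram


def _vol(data, voxel_um=14.0):
    return ImageVolume(np.asarray(data, np.uint8), voxel_um)


class TestMultilevelOtsu:
    def test_four_spike_histogram_matches_exhaustive(self):
        hist = np.zeros(256)
        hist[[40, 120, 200, 250]] = [100, 80, 60, 40]
        assert multilevel_otsu(hist, 3) == exhaustive_multiotsu(hist, 3)

    def test_two_spikes_single_threshold(self):
        hist = np.zeros(256)
        hist[[40, 200]] = [100, 50]
        t = multilevel_otsu(hist, 1)
        assert t == exhaustive_multiotsu(hist, 1)
        assert 40 < t[0] <= 200

    def test_single_occupied_bin_errors(self):
        hist = np.zeros(256)
        hist[100] = 50
        with pytest.raises(ValueError, match="degenerate"):
            multilevel_otsu(hist, 1)

    def test_too_few_bins_for_three_thresholds(self):
        hist = np.zeros(256)
        hist[[10, 20, 30]] = 1
        with pytest.raises(ValueError, match="degenerate"):
            multilevel_otsu(hist, 3)

    @pytest.mark.parametrize("n_thresholds", [1, 2, 3])
    def test_matches_exhaustive_on_random_histograms(self, rng, n_thresholds):
        for _ in range(15):
            hist = random_histogram(rng)
            assert multilevel_otsu(hist, n_thresholds) == \
                exhaustive_multiotsu(hist, n_thresholds)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.integers(0, 255), st.integers(1, 500)),
                    min_size=4, max_size=12, unique_by=lambda t: t[0]))
    def test_property_matches_exhaustive(self, spikes):
        hist = np.zeros(256)
        for b, c in spikes:
            hist[b] = c
        assert multilevel_otsu(hist, 3) == exhaustive_multiotsu(hist, 3)

    def test_thresholds_strictly_increasing(self, rng):
        hist = random_histogram(rng)
        t = multilevel_otsu(hist, 3)
        assert t[0] < t[1] < t[2]


class TestPooledThresholds:
    def test_pooling_rounds_component_means(self):
        means, sds = pooled_thresholds([(74, 138, 196), (76, 140, 198)])
        assert means == (75, 139, 197)
        assert sds == pytest.approx((np.sqrt(2),) * 3)

    def test_single_triple_is_itself(self):
        means, sds = pooled_thresholds([(75, 139, 197)])
        assert means == (75, 139, 197)
        assert sds == (0.0, 0.0, 0.0)

    def test_non_increasing_pool_errors(self):
        with pytest.raises(ValueError, match="increasing"):
            pooled_thresholds([(100, 100, 150)])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            pooled_thresholds([])


class TestSegmentCalcification:
    def test_lower_bound_75_inclusive(self):
        data = np.full((2, 4, 4), 60, np.uint8)
        data[0, 0, 0] = 80
        data[0, 0, 1] = 75
        data[0, 0, 2] = 74
        cusp = np.ones(data.shape, bool)
        mask = segment_calcification(_vol(data), cusp)
        assert mask[0, 0, 0] and mask[0, 0, 1] and not mask[0, 0, 2]
        assert mask.sum() == 2

    def test_outside_cusp_excluded(self):
        data = np.full((2, 4, 4), 250, np.uint8)
        cusp = np.zeros(data.shape, bool)
        cusp[0] = True
        mask = segment_calcification(_vol(data), cusp)
        assert mask[0].all() and not mask[1].any()


class TestCalcVolumeFraction:
    def test_full_and_empty(self):
        cusp = np.ones((3, 3, 3), bool)
        assert calc_volume_fraction(cusp, cusp) == 1.0
        assert calc_volume_fraction(np.zeros_like(cusp), cusp) == 0.0

    def test_empty_cusp_errors(self):
        with pytest.raises(ZeroDivisionError):
            calc_volume_fraction(np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool))


class TestPveDecompose:
    def test_hand_traced_hd_block(self):
        """A 3x3x3 HD block in a uniform cusp: HD dilates to 5x5x5; MD/LD empty."""
        data = np.full((20, 20, 20), 40, np.uint8)
        data[8:11, 8:11, 8:11] = 220
        cusp = np.ones(data.shape, bool)
        dm = pve_decompose(_vol(data), cusp)
        assert int(dm.hd.sum()) == 125
        assert dm.hd[7:12, 7:12, 7:12].all()
        assert int(dm.md.sum()) == 0 and int(dm.ld.sum()) == 0

    def test_no_calcification(self):
        data = np.full((4, 6, 6), 50, np.uint8)
        dm = pve_decompose(_vol(data), np.ones(data.shape, bool))
        assert not (dm.hd.any() or dm.md.any() or dm.ld.any())
        assert dm.volume_loss_fraction == 0.0

    def test_classes_disjoint_and_inside_cusp(self, rng):
        data = rng.integers(0, 256, (10, 24, 24)).astype(np.uint8)
        cusp = np.zeros(data.shape, bool)
        cusp[2:8, 4:20, 4:20] = True
        dm = pve_decompose(_vol(data), cusp)
        assert not (dm.hd & dm.md).any()
        assert not (dm.hd & dm.ld).any()
        assert not (dm.md & dm.ld).any()
        for m in (dm.hd, dm.md, dm.ld):
            assert not (m & ~cusp).any()

    def test_unblurred_isolated_classes_equal_gt_dilated_once(self):
        """Without blur, each corrected class is its ground-truth block dilated by 1."""
        from valve3d.morphology import dilate_by_voxels
        data = np.full((30, 40, 40), 40, np.uint8)
        blocks = {"hd": (np.s_[5:10, 5:12, 5:12], 220),
                  "md": (np.s_[15:20, 20:28, 20:28], 165),
                  "ld": (np.s_[22:27, 5:13, 25:33], 95)}
        gt = {}
        for name, (sl, gray) in blocks.items():
            data[sl] = gray
            m = np.zeros(data.shape, bool)
            m[sl] = True
            gt[name] = m
        dm = pve_decompose(_vol(data), np.ones(data.shape, bool))
        for name, mask in (("hd", dm.hd), ("md", dm.md), ("ld", dm.ld)):
            assert (mask == dilate_by_voxels(gt[name], 1)).all(), name

    def test_loss_fraction_invariant_under_transforms(self, rng):
        """Loss fraction is unchanged by translation and in-plane 90-degree rotation.

        The cusp must stay interior to the array (a cusp clipped by the
        scanned field of view is a different physical situation), and with
        slice-wise opening kernels the symmetry rotation is about the Z axis.
        """
        data = np.zeros((20, 22, 24), np.uint8)
        cusp = np.zeros(data.shape, bool)
        data[5:15, 6:16, 7:17] = rng.integers(30, 256, (10, 10, 10))
        cusp[5:15, 6:16, 7:17] = True
        base = pve_decompose(_vol(data), cusp).volume_loss_fraction

        rot = pve_decompose(_vol(np.rot90(data, axes=(1, 2)).copy()),
                            np.rot90(cusp, axes=(1, 2)).copy()).volume_loss_fraction
        assert rot == pytest.approx(base)

        shift = (2, -3, 1)
        trans = pve_decompose(_vol(np.roll(data, shift, axis=(0, 1, 2))),
                              np.roll(cusp, shift, axis=(0, 1, 2))).volume_loss_fraction
        assert trans == pytest.approx(base)
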