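"""3D local thickness: oracle equivalence, analytic cases, summaries."""

import numpy as np
import pytest
from scipy import ndimage

from valve3d import local_thickness, thickness_calc_overlay, thickness_summary
from valve3d.reference import brute_force_thickness

from helpers import digital_ball, random_blob_mask

VOX_MM = 1000.0  # 1 mm voxels: thickness in mm equals thickness in voxels


class TestLocalThickness:
    def test_slab_thickness_equals_height(self):
        mask = np.zeros((15, 40, 40), bool)
        mask[3:12] = True  # 9-voxel slab, wide in XY
        t = local_thickness(mask, VOX_MM)
        interior = t.data_mm[3:12, 15:25, 15:25]
        assert np.allclose(interior, 9.0)

    def test_zero_outside_mask(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        t = local_thickness(mask, VOX_MM)
        assert (t.data_mm[~mask] == 0).all()
        assert (t.data_mm[mask] > 0).all()

    def test_empty_mask(self):
        t = local_thickness(np.zeros((4, 4, 4), bool), VOX_MM)
        assert (t.data_mm == 0).all()

    def test_ball_max_matches_oracle(self):
        ball = digital_ball(8)
        t = local_thickness(ball, VOX_MM)
        oracle = brute_force_thickness(ball)
        assert np.allclose(t.data_mm, oracle)

    def test_matches_oracle_on_random_masks(self, rng):
        for shape in [(12, 12, 12), (20, 16, 10), (24, 24, 24)]:
            mask = random_blob_mask(rng, shape, occupancy=rng.uniform(0.2, 0.6))
            t = local_thickness(mask, VOX_MM)
            assert np.allclose(t.data_mm, brute_force_thickness(mask))

    def test_digital_ball_mean_within_10pct_of_diameter(self):
        for d in (8, 13, 20):
            ball = digital_ball(d / 2)
            t = local_thickness(ball, VOX_MM)
            mean = t.data_mm[t.data_mm > 0].mean()
            assert abs(mean - d) / d < 0.10, d

    def test_erosion_never_increases_thickness(self, rng):
        mask = random_blob_mask(rng, (18, 18, 18), occupancy=0.5)
        eroded = ndimage.binary_erosion(mask)
        t_full = local_thickness(mask, VOX_MM).data_mm
        t_eroded = local_thickness(eroded, VOX_MM).data_mm
        assert (t_eroded[eroded] <= t_full[eroded] + 1e-9).all()

    def test_invariance_translation_rotation(self, rng):
        mask = np.zeros((16, 16, 16), bool)
        mask[4:12, 4:12, 4:12] = random_blob_mask(rng, (8, 8, 8), occupancy=0.5)
        base = np.sort(local_thickness(mask, VOX_MM).data_mm[mask])
        rolled = np.roll(mask, (1, 2, -2), axis=(0, 1, 2))
        rotated = np.rot90(mask, axes=(0, 1)).copy()
        assert np.allclose(np.sort(local_thickness(rolled, VOX_MM).data_mm[rolled]), base)
        assert np.allclose(np.sort(local_thickness(rotated, VOX_MM).data_mm[rotated]), base)

    def test_scales_with_voxel_size(self):
        mask = digital_ball(5)
        t1 = local_thickness(mask, 14.0).data_mm
        t2 = local_thickness(mask, 28.0).data_mm
        assert np.allclose(t2, 2 * t1)


class TestThicknessSummary:
    def _slab(self, height_vox, shape=(30, 20, 20)):
        mask = np.zeros(shape, bool)
        mask[2:2 + height_vox] = True
        return mask

    def test_thin_slab_entirely_below_threshold(self):
        # 0.5 mm slab at 0.1 mm voxels
        t = local_thickness(self._slab(5), 100.0)
        s = thickness_summary(t, thin_threshold_mm=0.7)
        assert s["fraction_below_threshold"] == 1.0

    def test_thick_slab_entirely_above_threshold(self):
        """A 1.0 mm slab has no thin volume (evaluated on interior columns:
        the lateral rim of a finite slab is genuinely thin under the
        outside-is-background convention)."""
        from valve3d.thickness import ThicknessMap
        t = local_thickness(self._slab(10, shape=(30, 40, 40)), 100.0)
        interior = ThicknessMap(t.data_mm[:, 12:28, 12:28].copy(), 100.0)
        s = thickness_summary(interior, thin_threshold_mm=0.7)
        assert s["fraction_below_threshold"] == 0.0

    def test_two_joined_slabs_half_below(self):
        """Two equal-volume slabs of 0.5 and 1.0 mm: about half the volume is thin."""
        mask = np.zeros((16, 64, 22), bool)
        mask[2:7, 2:42, 1:21] = True      # 0.5 mm slab: 40 x 20 columns, 5 thick
        mask[2:12, 42:62, 1:21] = True    # 1.0 mm slab: 20 x 20 columns, 10 thick
        t = local_thickness(mask, 100.0)
        s = thickness_summary(t, thin_threshold_mm=0.7)
        assert s["fraction_below_threshold"] == pytest.approx(0.5, abs=0.05)

    def test_histogram_fractions_sum_to_one(self, rng):
        mask = random_blob_mask(rng, (14, 14, 14), occupancy=0.5)
        t = local_thickness(mask, 100.0)
        s = thickness_summary(t, bin_width_mm=0.1)
        assert sum(s["histogram_fraction"]) == pytest.approx(1.0, abs=1e-9)
        assert s["mean_thickness_mm"] <= s["max_thickness_mm"]

    def test_empty_map_errors(self):
        t = local_thickness(np.zeros((3, 3, 3), bool), 100.0)
        with pytest.raises(ValueError, match="empty"):
            thickness_summary(t)


class TestOverlayExport:
    def test_values_round_trip_bit_exact(self, tmp_path, rng):
        import tifffile
        mask = random_blob_mask(rng, (6, 16, 16), occupancy=0.5)
        t = local_thickness(mask, 100.0)
        out = thickness_calc_overlay(t, mask, z_index=3,
                                     out_png=str(tmp_path / "o.png"),
                                     out_values_tiff=str(tmp_path / "o.tiff"))
        back = tifffile.imread(out["values_tiff"])
        assert (back == t.data_mm[3]).all()

    def test_z_out_of_range(self, tmp_path):
        mask = np.ones((3, 4, 4), bool)
        t = local_thickness(mask, 100.0)
        with pytest.raises(IndexError):
            thickness_calc_overlay(t, mask, z_index=5, out_png=str(tmp_path / "o.png"))
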