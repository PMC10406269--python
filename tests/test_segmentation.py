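import warnings

import numpy as np
import pytest

from cedflow.imaging import ImageGrid, VolumeImage
from cedflow.phantom import case_adc
from cedflow.segmentation import (LesionMask, SegmentationParams, auto_params,
                                  build_speed_image, mask_stats, segment_lesion)

from conftest import dice


def sphere_image(radius_vox=10.0, shape=(32, 32, 32), inside=200.0, outside=100.0):
    grid = ImageGrid.isotropic(shape)
    world = grid.world_coordinates()
    d = np.linalg.norm(world, axis=-1)
    values = np.where(d <= radius_vox, inside, outside)
    return VolumeImage(grid, values, "T2W")


class TestParams:
    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            SegmentationParams(lower_threshold=5.0, upper_threshold=5.0)

    def test_smoothing_weight_maps_to_cadence(self):
        mk = lambda w: SegmentationParams(0.0, 1.0, smoothing_weight=w)
        assert mk(0.0).smoothing_every == 0
        assert mk(0.5).smoothing_every == 2
        assert mk(0.8).smoothing_every == 1
        with pytest.raises(ValueError):
            mk(1.5)


class TestSpeedImage:
    def test_band_interior_is_one_and_exterior_zero(self):
        grid = ImageGrid.isotropic((3, 3, 3))
        vals = np.array([50.0, 100.0, 150.0, 200.0, 250.0, 300.0] + [175.0] * 21)
        v = VolumeImage(grid, vals.reshape(3, 3, 3), "T2W")
        params = SegmentationParams(100.0, 250.0)
        speed = build_speed_image(v, params).values.ravel()
        assert speed[0] == 0.0    # below the band
        assert speed[1] == 0.0    # exactly at the lower threshold
        assert speed[3] == 1.0    # mid band
        assert speed[4] == 0.0    # exactly at the upper threshold
        assert speed[5] == 0.0    # above the band

    def test_ramp_half_height(self):
        grid = ImageGrid.isotropic((1, 1, 1))
        # gap 100 -> ramp width 5; half-way up the lower ramp at lo + 2.5
        v = VolumeImage(grid, np.array([[[102.5]]]), "T2W")
        speed = build_speed_image(v, SegmentationParams(100.0, 200.0))
        assert speed.values[0, 0, 0] == pytest.approx(0.5)

    def test_out_of_range_thresholds_warn(self):
        v = sphere_image()
        with pytest.warns(UserWarning, match="outside the image intensity"):
            build_speed_image(v, SegmentationParams(1000.0, 2000.0))


class TestSegmentLesion:
    def test_sphere_volume_within_5pct_of_analytic(self):
        """Radius-10 sphere: analytic volume 4/3*pi*1000 mm^3 = 4.18879 ml."""
        v = sphere_image(radius_vox=10.0)
        params = SegmentationParams(150.0, 300.0, seeds=[((0.0, 0.0, 0.0), 2.0)])
        mask = segment_lesion(v, params)
        assert mask.volume_ml == pytest.approx(4.18879, rel=0.05)
        assert not mask.leaked

    def test_noise_free_blurred_recovery_is_voxel_exact(self, noisefree_blurred_case):
        """Midpoint thresholds put the contour on the true tumor boundary."""
        case = noisefree_blurred_case
        t2 = case.pre_session["T2W"]
        params = auto_params(t2, case.truth["nawm_mask"], case.truth["seed_point_mm"])
        mask = segment_lesion(t2, params)
        assert dice(mask.mask, case.truth["tumor_mask_pre"]) >= 0.98

    def test_default_noise_recovery(self, noisy_shifted_case):
        case = noisy_shifted_case
        t2 = case.pre_session["T2W"]
        params = auto_params(t2, case.truth["nawm_mask"], case.truth["seed_point_mm"])
        mask = segment_lesion(t2, params)
        assert dice(mask.mask, case.truth["tumor_mask_pre"]) >= 0.9

    def test_widening_the_band_never_shrinks_the_region(self, noisefree_blurred_case):
        case = noisefree_blurred_case
        t2 = case.pre_session["T2W"]
        base = auto_params(t2, case.truth["nawm_mask"], case.truth["seed_point_mm"])
        narrow = segment_lesion(t2, base)
        wide = segment_lesion(t2, SegmentationParams(
            base.lower_threshold - 10.0, base.upper_threshold + 10.0, seeds=base.seeds))
        assert np.all(wide.mask[narrow.mask])

    def test_result_is_one_component_containing_seed(self, noisy_shifted_case):
        from scipy import ndimage
        case = noisy_shifted_case
        t2 = case.pre_session["T2W"]
        params = auto_params(t2, case.truth["nawm_mask"], case.truth["seed_point_mm"])
        mask = segment_lesion(t2, params)
        _, n = ndimage.label(mask.mask, ndimage.generate_binary_structure(3, 1))
        assert n == 1
        seed_idx = tuple(np.round(
            t2.grid.world_to_index(np.asarray(case.truth["seed_point_mm"]))[0]).astype(int))
        assert mask.mask[seed_idx]

    def test_volume_field_consistent_with_voxel_count(self, noisy_shifted_case):
        case = noisy_shifted_case
        t2 = case.pre_session["T2W"]
        params = auto_params(t2, case.truth["nawm_mask"], case.truth["seed_point_mm"])
        mask = segment_lesion(t2, params)
        assert mask.volume_ml == pytest.approx(
            mask.voxel_count * t2.grid.voxel_volume_mm3 / 1000.0)
        assert mask.voxel_count == int(mask.mask.sum())

    def test_inadmissible_seed_raises(self):
        v = sphere_image()
        params = SegmentationParams(500.0, 600.0, seeds=[((0.0, 0.0, 0.0), 2.0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="no admissible seed"):
                segment_lesion(v, params)

    def test_border_leak_is_flagged(self):
        grid = ImageGrid.isotropic((12, 12, 12))
        v = VolumeImage(grid, np.full(grid.shape, 200.0), "T2W")
        params = SegmentationParams(150.0, 300.0, seeds=[((0.0, 0.0, 0.0), 1.5)])
        with pytest.warns(UserWarning, match="border"):
            mask = segment_lesion(v, params)
        assert mask.leaked


class TestMaskStatsAndAutoParams:
    def test_known_mean_and_sample_sd(self):
        grid = ImageGrid.isotropic((2, 2, 2))
        ref = VolumeImage(grid, np.arange(8, dtype=float).reshape(2, 2, 2), "ADC")
        sel = np.zeros((2, 2, 2), dtype=bool)
        sel[0, 0, 0] = sel[0, 0, 1] = True  # values 0 and 1... pick 0 and 2
        sel[0, 0, 1] = False
        sel[0, 1, 0] = True                 # values {0, 2}
        mask = LesionMask(grid, sel, 2, 0.002, 0.0, 0.0, "T2W")
        out = mask_stats(mask, ref)
        assert out.intensity_mean == pytest.approx(1.0)
        assert out.intensity_sd == pytest.approx(np.sqrt(2.0))  # sample SD of {0, 2}
        assert out.reference_modality == "ADC"
        assert out.volume_ml == mask.volume_ml  # volumetry untouched

    def test_constant_region_has_zero_sd(self):
        v = sphere_image()
        params = SegmentationParams(150.0, 300.0, seeds=[((0.0, 0.0, 0.0), 2.0)])
        mask = segment_lesion(v, params)
        assert mask.intensity_mean == pytest.approx(200.0)
        assert mask.intensity_sd == 0.0

    def test_mismatched_grid_and_empty_mask_rejected(self):
        grid = ImageGrid.isotropic((2, 2, 2))
        other = VolumeImage(ImageGrid.isotropic((3, 3, 3)), np.zeros((3, 3, 3)), "ADC")
        mask = LesionMask(grid, np.ones((2, 2, 2), bool), 8, 0.008, 0.0, 0.0, "T2W")
        with pytest.raises(ValueError):
            mask_stats(mask, other)
        empty = LesionMask(grid, np.zeros((2, 2, 2), bool), 0, 0.0, 0.0, 0.0, "T2W")
        with pytest.raises(ValueError):
            mask_stats(empty, VolumeImage(grid, np.zeros((2, 2, 2)), "ADC"))

    def test_auto_params_midpoint_rule(self, noisefree_blurred_case):
        case = noisefree_blurred_case
        t2 = case.pre_session["T2W"]
        lv = case.spec.levels.t2w
        params = auto_params(t2, case.truth["nawm_mask"], case.truth["seed_point_mm"])
        assert params.lower_threshold == pytest.approx((lv["nawm"] + lv["tumor"]) / 2, rel=0.02)
        assert params.upper_threshold == pytest.approx((lv["tumor"] + lv["csf"]) / 2, rel=0.02)

    def test_auto_params_rejects_dark_seed(self, noisefree_blurred_case):
        case = noisefree_blurred_case
        t2 = case.pre_session["T2W"]
        # a seed in NAWM is not brighter than the reference: no threshold fits
        with pytest.raises(ValueError, match="not brighter"):
            auto_params(t2, case.truth["nawm_mask"], (30.0, 0.0, 0.0))

    def test_phantom_tumor_adc_mean_matches_scene(self, noisefree_blurred_case):
        case = noisefree_blurred_case
        adc = case_adc(case, "pre")
        params = auto_params(adc, case.truth["nawm_mask"], case.truth["seed_point_mm"])
        mask = segment_lesion(adc, params)
        assert mask.intensity_mean == pytest.approx(
            case.spec.levels.diffusion["tumor"], rel=0.02)
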