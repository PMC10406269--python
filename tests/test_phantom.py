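import numpy as np
import pytest

from cedflow.imaging import ImageGrid, VolumeImage
from cedflow.phantom import (PhantomSpec, add_rician_noise, case_adc,
                             generate_case, generate_cohort)
from cedflow.transforms import RigidTransform

from conftest import dice


class TestSpec:
    def test_rim_voxel_count_matches_vi(self):
        spec = PhantomSpec(vi_ml=4.4)
        assert spec.rim_voxel_count == 4400  # 1 mm isotropic grid

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(vi_ml=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(noise_sigma=-1.0)
        with pytest.raises(ValueError):
            PhantomSpec(infusate_center_mm=(50.0, 0.0, 0.0))  # outside the tumor

    def test_analytic_tumor_volume(self):
        spec = PhantomSpec()
        a, b, c = spec.tumor_semiaxes_mm
        assert spec.tumor_volume_analytic_ml == pytest.approx(
            4.0 / 3.0 * np.pi * a * b * c / 1000.0)


class TestGenerateCase:
    def test_truth_invariants(self, ideal_case):
        truth = ideal_case.truth
        tumor = truth["tumor_mask_pre"]
        rim = truth["rim_mask"]
        soaked = truth["tumor_plus_infusate_mask"]
        assert not (tumor & rim).any()
        assert np.array_equal(soaked, tumor | rim)
        # rim voxel count realizes Vi exactly on this grid
        assert rim.sum() == ideal_case.spec.rim_voxel_count
        assert truth["vi_true_ml"] == pytest.approx(ideal_case.spec.vi_ml, abs=1e-9)
        # NAWM reference stays clear of the lesion and is non-trivial
        assert not (truth["nawm_mask"] & soaked).any()
        assert truth["nawm_mask"].sum() > 1000

    def test_voxelized_tumor_volume_near_analytic(self, ideal_case):
        spec = ideal_case.spec
        vox_ml = ideal_case.truth["tumor_mask_pre"].sum() * spec.grid.voxel_volume_mm3 / 1000.0
        # voxelization + ventricle carve-out keeps it within a few percent
        assert vox_ml == pytest.approx(spec.tumor_volume_analytic_ml, rel=0.03)

    def test_same_seed_is_bit_identical(self):
        spec = PhantomSpec(seed=42)
        a = generate_case(spec)
        b = generate_case(spec)
        for mod in a.pre_session:
            assert np.array_equal(a.pre_session[mod].values, b.pre_session[mod].values)
            assert np.array_equal(a.post_session[mod].values, b.post_session[mod].values)

    def test_different_seeds_differ(self):
        a = generate_case(PhantomSpec(seed=1))
        b = generate_case(PhantomSpec(seed=2))
        assert not np.array_equal(a.pre_session["T2W"].values, b.pre_session["T2W"].values)

    def test_noise_free_adc_support_equals_soaked_truth(self, ideal_case):
        """Post-minus-pre ADC changes exactly on the soaked region, nowhere else."""
        diff = case_adc(ideal_case, "post").values - case_adc(ideal_case, "pre").values
        changed = np.abs(diff) > 1e-6
        assert np.array_equal(changed, ideal_case.truth["tumor_plus_infusate_mask"])

    def test_noise_free_adc_reads_scene_diffusivities(self, ideal_case):
        adc = case_adc(ideal_case, "pre").values
        truth = ideal_case.truth
        lv = ideal_case.spec.levels.diffusion
        assert adc[truth["tumor_mask_pre"]].mean() == pytest.approx(lv["tumor"], rel=1e-6)
        assert adc[truth["nawm_mask"]].mean() == pytest.approx(lv["nawm"], rel=1e-6)

    def test_t1w_unchanged_by_infusion_when_sessions_align(self, ideal_case):
        """T1W carries no infusate contrast: identical sessions give identical T1W."""
        assert np.array_equal(ideal_case.pre_session["T1W"].values,
                              ideal_case.post_session["T1W"].values)
        # while T2W clearly differs inside the lesion
        assert not np.array_equal(ideal_case.pre_session["T2W"].values,
                                  ideal_case.post_session["T2W"].values)

    def test_shifted_post_session_renders_same_scene(self):
        """The post scene is the pre scene observed through the rigid shift."""
        shift = RigidTransform([0.0, 0.0, 0.0], [3.0, 0.0, 0.0])
        case = generate_case(PhantomSpec(noise_sigma=0.0, pv_blur_sigma_vox=0.0,
                                         session_shift=shift, seed=5))
        pre = case.pre_session["T1W"].values
        post = case.post_session["T1W"].values
        # post grid index i sees the scene at world x+3: post[i] == pre[i+3]
        assert np.array_equal(post[:-3], pre[3:])

    def test_noisy_case_tissue_means_near_levels(self, noisy_shifted_case):
        truth = noisy_shifted_case.truth
        t2 = noisy_shifted_case.pre_session["T2W"].values
        want = noisy_shifted_case.spec.levels.t2w["nawm"]
        # Rician bias at SNR 20 is ~sigma^2/(2 x 100) = 0.125: stay loose
        assert t2[truth["nawm_mask"]].mean() == pytest.approx(want, rel=0.02)


class TestRicianNoise:
    def test_sigma_zero_is_identity(self):
        v = VolumeImage(ImageGrid.isotropic((4, 4, 4)), np.full((4, 4, 4), 7.0), "T2W")
        assert add_rician_noise(v, 0.0) is v

    def test_negative_sigma_rejected(self):
        v = VolumeImage(ImageGrid.isotropic((4, 4, 4)), np.zeros((4, 4, 4)), "T2W")
        with pytest.raises(ValueError):
            add_rician_noise(v, -1.0)

    def test_background_is_rayleigh(self):
        """On zero signal the magnitude is Rayleigh: mean sigma*sqrt(pi/2)."""
        grid = ImageGrid.isotropic((64, 64, 32))
        v = VolumeImage(grid, np.zeros(grid.shape), "T2W")
        out = add_rician_noise(v, 10.0, seed=3)
        expected = 10.0 * np.sqrt(np.pi / 2.0)
        assert out.values.mean() == pytest.approx(expected, rel=0.01)
        assert out.values.min() >= 0.0

    def test_high_snr_mean_approaches_signal(self):
        grid = ImageGrid.isotropic((64, 64, 32))
        v = VolumeImage(grid, np.full(grid.shape, 1000.0), "T2W")
        out = add_rician_noise(v, 5.0, seed=4)
        # Rician mean at SNR 200 is x + sigma^2/(2x) = 1000.0125
        assert out.values.mean() == pytest.approx(1000.0125, abs=0.1)


class TestCohort:
    def test_cohort_truth_table_and_ranges(self, phantom_cohort):
        cases, truth_table = phantom_cohort
        assert len(cases) == 12
        assert len(truth_table) == 12
        assert (truth_table["vi_true_ml"] >= 3.8).all()
        assert (truth_table["vi_true_ml"] <= 5.7).all()
        for case, vi in zip(cases, truth_table["vi_true_ml"]):
            assert case.vi_true_ml == pytest.approx(vi)

    def test_fixed_seed_reproduces_cohort_specs(self):
        _, t1 = generate_cohort(3, seed=99)
        _, t2 = generate_cohort(3, seed=99)
        assert np.allclose(t1["vi_true_ml"], t2["vi_true_ml"])
        assert np.allclose(t1["tumor_volume_true_ml"], t2["tumor_volume_true_ml"])

    def test_degenerate_range_pins_value(self):
        cases, table = generate_cohort(
            3, spec_ranges={"vi_ml": (5.0, 5.0), "tumor_scale": (1.0, 1.0)}, seed=0)
        assert np.allclose(table["vi_true_ml"], 5.0)

    def test_empty_range_and_bad_count_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0)
        with pytest.raises(ValueError):
            generate_cohort(2, spec_ranges={"vi_ml": (5.0, 4.0)})


def test_blurred_case_keeps_truth_masks(noisefree_blurred_case, ideal_case):
    """Blur changes the images, not the geometry: truth masks match the ideal case."""
    a = noisefree_blurred_case.truth["tumor_mask_pre"]
    b = ideal_case.truth["tumor_mask_pre"]
    assert dice(a, b) == pytest.approx(1.0)
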