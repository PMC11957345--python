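import numpy as np
import pytest
from dataclasses import replace

from thgswell.detect import label_objects
from thgswell.io import AcquisitionGeometry
from thgswell.synthetic import (
    Label,
    MS_PRESET,
    NONMS_PRESET,
    apply_depth_attenuation,
    apply_noise,
    generate_axon_field,
    plant_swellings,
    sample_donor_densities,
    simulate_timelapse,
)
from thgswell.synthetic import _render_axons


@pytest.fixture
def geometry():
    return AcquisitionGeometry(fov_um=40.0, grid_px=100, z_step_um=0.4)


QUIET = replace(
    MS_PRESET, noise_shot_scale=0.0, noise_additive_sd=0.0,
    psf_fwhm_lateral_um=0.0, psf_fwhm_axial_um=0.0,
    cell_hole_density_per_mm3=0.0, lipid_body_density_per_mm3=0.0,
    attenuation_length_um={"GM": 1e9, "WM": 1e9},
)


class TestAxonField:
    def test_zero_density_gives_pure_background(self, geometry):
        preset = replace(QUIET, axon_areal_density=0.0)
        field = generate_axon_field(preset, geometry, 20, seed=0)
        assert np.all(field.labels == Label.BACKGROUND)
        assert np.allclose(field.intensity, preset.intensity_background)

    def test_same_seed_is_deterministic(self, geometry):
        a = generate_axon_field(QUIET, geometry, 20, seed=5)
        b = generate_axon_field(QUIET, geometry, 20, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_single_tube_shell_fraction_matches_annulus(self):
        # fine grid so voxelization error is small
        geometry = AcquisitionGeometry(fov_um=20.0, grid_px=100, z_step_um=0.2)
        n_z = 50
        axon = {
            "anchor": np.array([5.0, 10.0, 10.0]),
            "direction": np.array([0.0, 0.0, 1.0]),  # along x
            "r_out": 2.0,
            "r_in": 1.6,
        }
        labels, _ = _render_axons([axon], QUIET, geometry, n_z)
        shell_fraction = np.mean(labels == Label.SHEATH)
        annulus_area = np.pi * (2.0 ** 2 - 1.6 ** 2)  # µm² per unit length
        cross_section = 20.0 * (n_z * 0.2)  # y extent × z extent
        assert shell_fraction == pytest.approx(annulus_area / cross_section, rel=0.10)

    def test_degenerate_geometry_rejected(self):
        tiny = AcquisitionGeometry(fov_um=10.0, grid_px=25, z_step_um=0.4)
        with pytest.raises(ValueError):
            generate_axon_field(QUIET, tiny, 20, seed=0)


class TestPlantSwellings:
    def test_zero_density_plants_nothing(self, geometry):
        preset = replace(QUIET, swelling_density_per_mm3=0.0)
        field = generate_axon_field(preset, geometry, 20, seed=1)
        _, _, truth = plant_swellings(field, preset, seed=2)
        assert truth["count"] == 0
        assert truth["density_per_mm3"] == 0.0

    def test_no_axons_with_positive_density_rejected(self, geometry):
        preset = replace(QUIET, axon_areal_density=0.0)
        field = generate_axon_field(preset, geometry, 20, seed=1)
        with pytest.raises(ValueError):
            plant_swellings(field, preset, seed=2, count=3)

    def test_poisson_count_mean(self, geometry):
        """Planted count is Poisson(density × volume): check the mean over
        many seeds against dV within 3 standard errors."""
        preset = replace(QUIET, swelling_density_per_mm3=1.0e5)
        field = generate_axon_field(preset, geometry, 20, seed=3)
        volume = geometry.imaged_volume_mm3(20)
        expected = preset.swelling_density_per_mm3 * volume
        seeds = np.random.default_rng(0).integers(2 ** 31, size=500)
        counts = [plant_swellings(field, preset, seed=int(s))[2]["count"]
                  for s in seeds]
        se = np.sqrt(expected / 500)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_truth_density_is_count_over_volume(self, geometry):
        field = generate_axon_field(QUIET, geometry, 20, seed=4)
        _, _, truth = plant_swellings(field, QUIET, seed=5, count=7)
        volume = geometry.imaged_volume_mm3(20)
        assert truth["density_per_mm3"] == pytest.approx(7 / volume, rel=1e-9)

    def test_planted_cavity_is_round(self, geometry):
        """A planted swelling rasterized alone passes the roundness rule."""
        field = generate_axon_field(QUIET, geometry, 25, seed=6)
        labels, _, truth = plant_swellings(field, QUIET, seed=7, count=1)
        mask = labels == Label.SWELLING
        assert mask.any()
        objects = label_objects(mask, geometry)
        assert max(o.sphericity for o in objects) >= 0.8


class TestDepthAttenuation:
    def test_surface_plane_unchanged(self, geometry):
        volume = np.full((20, 10, 10), 0.8)
        out = apply_depth_attenuation(volume, geometry, "WM")
        np.testing.assert_allclose(out[0], volume[0])

    def test_one_attenuation_length_gives_e_fold(self):
        geometry = AcquisitionGeometry(fov_um=10.0, grid_px=25, z_step_um=1.0)
        volume = np.ones((121, 5, 5))
        out = apply_depth_attenuation(volume, geometry, "GM",
                                      {"GM": 120.0, "WM": 60.0})
        assert np.median(out[120]) == pytest.approx(np.exp(-1), rel=1e-9)

    def test_white_matter_attenuates_faster(self, geometry):
        volume = np.ones((20, 5, 5))
        wm = apply_depth_attenuation(volume, geometry, "WM")
        gm = apply_depth_attenuation(volume, geometry, "GM")
        assert np.all(wm[1:] < gm[1:])

    def test_unknown_tissue_rejected(self, geometry):
        with pytest.raises(ValueError):
            apply_depth_attenuation(np.ones((2, 5, 5)), geometry, "bone")


class TestNoise:
    def test_zero_noise_is_identity(self):
        preset = replace(MS_PRESET, noise_shot_scale=0.0, noise_additive_sd=0.0)
        volume = np.random.default_rng(0).uniform(0, 1, (5, 10, 10)).astype(np.float32)
        np.testing.assert_array_equal(apply_noise(volume, preset, seed=1), volume)

    def test_variance_follows_shot_plus_read_model(self):
        preset = replace(MS_PRESET, noise_shot_scale=0.004, noise_additive_sd=0.01)
        volume = np.full((50, 50, 50), 0.5, dtype=np.float32)  # 1.25e5 voxels
        noisy = apply_noise(volume, preset, seed=2)
        expected_var = 0.004 * 0.5 + 0.01 ** 2
        assert noisy.var() == pytest.approx(expected_var, rel=0.10)

    def test_same_seed_reproducible(self):
        volume = np.full((4, 8, 8), 0.3, dtype=np.float32)
        a = apply_noise(volume, MS_PRESET, seed=9)
        b = apply_noise(volume, MS_PRESET, seed=9)
        np.testing.assert_array_equal(a, b)


class TestTimelapse:
    def test_static_scene_truth_constant(self, geometry):
        stack, truth = simulate_timelapse(QUIET, geometry, 20, [0, 30, 60],
                                          seed=11, count=5)
        assert stack.n_t == 3
        assert np.all(truth.true_density_per_mm3 == truth.true_density_per_mm3[0])
        np.testing.assert_allclose(truth.applied_shifts_px, 0.0)
        np.testing.assert_array_equal(stack.voxels[0], stack.voxels[1])

    def test_drift_shift_is_velocity_times_time(self, geometry):
        preset = replace(QUIET, drift_velocity_um_per_min=(0.1, -0.05))
        stack, truth = simulate_timelapse(preset, geometry, 20, [0, 60],
                                          seed=12, count=3)
        # 0.1 µm/min × 60 min = 6 µm = 15 px at 0.4 µm/px
        np.testing.assert_allclose(truth.applied_shifts_px[1], (15.0, -7.5))

    def test_linear_radius_growth(self, geometry):
        preset = replace(QUIET, swelling_growth_rate_um_per_min=0.01)
        _, truth = simulate_timelapse(preset, geometry, 20, [0, 60], seed=13,
                                      count=4)
        np.testing.assert_allclose(
            truth.swelling_radii_um[1], truth.swelling_radii_um[0] + 0.6,
            rtol=1e-9,
        )

    def test_labels_partition_volume(self, geometry):
        _, truth = simulate_timelapse(MS_PRESET, geometry, 20, [0.0], seed=14)
        labels = truth.labels[0]
        assert labels.shape == (20, 100, 100)
        valid = {Label.BACKGROUND, Label.SHEATH, Label.LUMEN, Label.SWELLING,
                 Label.LIPID, Label.CELL_HOLE}
        assert set(np.unique(labels)) <= valid

    def test_empty_timestamps_rejected(self, geometry):
        with pytest.raises(ValueError):
            simulate_timelapse(QUIET, geometry, 20, [], seed=0)


class TestDonorDensities:
    def test_lognormal_moments_match(self):
        draws = sample_donor_densities(3.17e5, 1.6e5, 20000, seed=1)
        assert np.mean(draws) == pytest.approx(3.17e5, rel=0.02)
        assert np.std(draws) == pytest.approx(1.6e5, rel=0.05)

    def test_sem_interpretation_scales_by_sqrt_n(self):
        sd_draws = sample_donor_densities(1e5, 2e4, 50000, seed=2)
        sem_draws = sample_donor_densities(1e5, 2e4 / np.sqrt(5), 50000, seed=2,
                                           spread_is_sd=False, group_n=5)
        assert np.std(sem_draws) == pytest.approx(np.std(sd_draws), rel=0.05)

    def test_presets_carry_group_conditions(self):
        assert MS_PRESET.swelling_density_per_mm3 > NONMS_PRESET.swelling_density_per_mm3
        assert MS_PRESET.spread_is_sd and NONMS_PRESET.spread_is_sd
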