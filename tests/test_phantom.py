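import numpy as np
import pytest

from pcmrca.flow_data import FlowDataError
from pcmrca.phantom import (
    PhantomConfig,
    generate_phantom,
    truth_endpoint_error,
    write_phantom,
)
from pcmrca.preprocess import magnitude_noise_mask, velocity_outlier_mask
from pcmrca.registration import DisplacementField, jacobian_determinant

from conftest import small_phantom_config


class TestConfigValidation:
    def test_excessive_contraction_rejected(self):
        with pytest.raises(FlowDataError, match="contraction"):
            PhantomConfig(contraction_amplitude=0.9)

    def test_peak_speed_above_suppression_limit_rejected(self):
        with pytest.raises(FlowDataError, match="1.5"):
            PhantomConfig(peak_vessel_speed_cms=200.0, venc_cms=120.0)

    def test_reference_frame_range_checked(self):
        with pytest.raises(FlowDataError):
            PhantomConfig(reference_frame=25, n_frames=20)


class TestGeneration:
    def test_same_config_and_seed_bit_identical(self):
        cfg = small_phantom_config(noise_seed=7)
        ds1, truth1 = generate_phantom(cfg)
        ds2, truth2 = generate_phantom(cfg)
        np.testing.assert_array_equal(ds1.magnitude, ds2.magnitude)
        np.testing.assert_array_equal(ds1.velocity, ds2.velocity)
        np.testing.assert_array_equal(truth1.chamber_mask, truth2.chamber_mask)

    def test_different_seed_differs(self):
        ds1, _ = generate_phantom(small_phantom_config(noise_seed=0))
        ds2, _ = generate_phantom(small_phantom_config(noise_seed=1))
        assert not np.array_equal(ds1.velocity, ds2.velocity)

    def test_vessel_peak_speed_matches_config(self, small_phantom):
        cfg, ds, truth = small_phantom
        speeds = ds.speed()
        lumen_speeds = speeds[truth.vessel_mask]
        assert lumen_speeds.max() == pytest.approx(
            cfg.peak_vessel_speed_cms, rel=0.02
        )

    def test_chamber_peak_speed_matches_config(self, small_phantom):
        cfg, ds, truth = small_phantom
        chamber_speeds = ds.speed()[truth.chamber_mask]
        assert chamber_speeds.max() == pytest.approx(
            cfg.peak_chamber_speed_cms, rel=0.02
        )

    def test_deformation_zero_at_reference_frame(self, small_phantom):
        cfg, ds, truth = small_phantom
        ref_field = truth.deformation_to_reference[truth.reference_frame]
        assert np.all(ref_field.vectors == 0.0)

    def test_truth_fields_are_diffeomorphic(self, small_phantom):
        cfg, ds, truth = small_phantom
        for field in truth.deformation_to_reference:
            det = jacobian_determinant(field)
            assert np.all(det[2:-2, 2:-2, 2:-2] > 0)

    def test_masks_pairwise_disjoint(self, small_phantom):
        _, _, truth = small_phantom
        assert not np.any(truth.chamber_mask & truth.vessel_mask)
        assert not np.any(truth.chamber_mask & truth.air_mask)
        assert not np.any(truth.vessel_mask & truth.air_mask)

    def test_flow_divergence_small_in_straightest_tube_section(self, small_phantom):
        """The parabolic through-plane profile is divergence-free where the
        tube runs straight (mid-z, where the bend's slope vanishes)."""
        cfg, ds, truth = small_phantom
        t = (cfg.reference_frame + cfg.n_frames // 2) % cfg.n_frames  # peak flow
        vel = ds.velocity[t]
        div = sum(np.gradient(vel[i], axis=i) for i in range(3))
        nz = cfg.grid[2]
        core = truth.vessel_mask[t].copy()
        core[:, :, : nz // 2 - 2] = False
        core[:, :, nz // 2 + 3 :] = False
        # interior of the lumen only: the profile's cutoff at the wall is not
        # divergence-free at discrete resolution
        from scipy.ndimage import binary_erosion

        core &= binary_erosion(truth.vessel_mask[t], iterations=1)
        assert np.abs(div[core]).max() < 0.1 * cfg.peak_vessel_speed_cms

    def test_write_phantom_emits_dataset_truth_and_config(self, tmp_path):
        cfg = small_phantom_config(n_frames=3)
        write_phantom(cfg, tmp_path)
        assert (tmp_path / "magnitude.nii").exists()
        assert (tmp_path / "meta.yaml").exists()
        assert (tmp_path / "truth" / "truth_fields.nii").exists()
        assert (tmp_path / "truth" / "chamber_mask.nii").exists()
        assert (tmp_path / "phantom_config.yaml").exists()


class TestSuppressionInteraction:
    def test_suppression_removes_outliers_and_no_lumen_voxels(self, small_phantom):
        cfg, ds, truth = small_phantom
        v_mask = velocity_outlier_mask(ds)
        m_mask = magnitude_noise_mask(ds)
        # every injected wrap-like outlier is caught by the velocity rule
        outliers = np.any(np.abs(ds.velocity) > 1.5 * cfg.venc_cms, axis=1)
        assert outliers.sum() == truth.n_injected_outliers
        caught = outliers & ~v_mask.keep
        assert caught.sum() >= 0.95 * truth.n_injected_outliers
        # no true lumen voxel is suppressed by either rule
        lumen = truth.chamber_mask | truth.vessel_mask
        keep = v_mask.keep & m_mask.keep
        assert np.all(keep[lumen])

    def test_velocity_rule_suppression_fraction_is_small(self, small_phantom):
        _, ds, _ = small_phantom
        v_mask = velocity_outlier_mask(ds)
        fraction = v_mask.n_suppressed_velocity / ds.magnitude.size
        assert fraction < 0.05


class TestEndpointError:
    def test_identical_fields_give_zero(self, small_phantom):
        _, _, truth = small_phantom
        f = truth.deformation_to_reference[0]
        mask = np.ones(f.spatial_shape, dtype=bool)
        assert truth_endpoint_error(f, f, mask) == 0.0

    def test_constant_offset_gives_offset_norm(self):
        shape = (6, 6, 6)
        truth_f = DisplacementField(vectors=np.zeros((3,) + shape))
        offset = DisplacementField(vectors=np.zeros((3,) + shape))
        offset.vectors[0] = 1.0
        mask = np.ones(shape, dtype=bool)
        assert truth_endpoint_error(offset, truth_f, mask) == pytest.approx(1.0)

    def test_zero_field_vs_truth_equals_mean_truth_norm(self, small_phantom):
        _, _, truth = small_phantom
        t = truth.reference_frame + 2
        tf = truth.deformation_to_reference[t]
        zero = DisplacementField.zeros(tf.spatial_shape)
        mask = truth.foreground_mask()
        expected = np.sqrt(np.sum(tf.vectors**2, axis=0))[mask].mean()
        assert truth_endpoint_error(zero, tf, mask) == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        f = DisplacementField.zeros((4, 4, 4))
        with pytest.raises(FlowDataError, match="empty"):
            truth_endpoint_error(f, f, np.zeros((4, 4, 4), dtype=bool))
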