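import numpy as np
import pytest

from pcmrca.flow_data import FlowDataError
from pcmrca.registration import (
    DisplacementField,
    RegistrationParams,
    compose,
    inverse_consistency_error,
    jacobian_determinant,
    register,
    warp,
)


def _grid(shape):
    return np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")


def _blob(shape, center, widths):
    coords = _grid(shape)
    return np.exp(
        -sum(((c - c0) / w) ** 2 for c, c0, w in zip(coords, center, widths))
    )


@pytest.fixture(scope="module")
def blob_pair():
    """A smooth blob and the same blob translated by +2 voxels along x."""
    shape = (48, 48, 48)
    fixed = _blob(shape, (24, 24, 24), (6, 7, 5))
    moving = _blob(shape, (26, 24, 24), (6, 7, 5))
    return fixed, moving


class TestRegister:
    def test_self_registration_yields_zero_field(self, blob_pair):
        fixed, _ = blob_pair
        field = register(fixed, fixed)
        assert field.norm().max() < 0.05

    def test_constant_images_short_circuit_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            field = register(np.ones((16, 16, 16)), np.ones((16, 16, 16)))
        assert np.all(field.vectors == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FlowDataError, match="mismatch"):
            register(np.zeros((8, 8, 8)), np.zeros((8, 8, 9)))

    def test_known_translation_recovered(self, blob_pair):
        fixed, moving = blob_pair
        field = register(fixed, moving)
        mask = fixed > 0.3
        mean_dx = field.vectors[0][mask].mean()
        assert 1.75 <= mean_dx <= 2.25
        # no systematic displacement along the untranslated axes
        assert abs(field.vectors[1][mask].mean()) < 0.2
        assert abs(field.vectors[2][mask].mean()) < 0.2

    def test_sinusoidal_warp_recovered_below_one_voxel(self):
        shape = (48, 48, 48)
        x, y, z = _grid(shape)
        # textured image so every region carries phase information
        image = (
            _blob(shape, (24, 24, 24), (12, 14, 10))
            * (1.0 + 0.3 * np.sin(x) * np.sin(0.8 * y))
        )
        amp = 3.0
        truth = np.zeros((3,) + shape)
        truth[0] = amp * np.sin(2 * np.pi * y / shape[1]) * np.sin(
            2 * np.pi * z / shape[2]
        )
        truth_field = DisplacementField(vectors=truth)
        moving = warp(image, truth_field)  # moving(x) sampled at x + truth(x)
        # registering (fixed=warped, moving=image) should recover `truth`
        field = register(moving, image)
        mask = image > 0.3
        err = np.sqrt(np.sum((field.vectors - truth) ** 2, axis=0))
        assert err[mask].mean() < 1.0

    def test_translation_covariance(self, blob_pair):
        """Shifting fixed and moving identically leaves the field unchanged."""
        fixed, moving = blob_pair
        field = register(fixed, moving)
        shift = 3
        field_shifted = register(
            np.roll(fixed, shift, axis=1), np.roll(moving, shift, axis=1)
        )
        mask = fixed > 0.3
        diff = field_shifted.vectors[:, :, shift:, :] - field.vectors[:, :, :-shift, :]
        assert np.abs(diff[:, mask[:, :-shift, :]]).mean() < 0.1

    def test_deterministic(self, blob_pair):
        fixed, moving = blob_pair
        a = register(fixed, moving)
        b = register(fixed, moving)
        np.testing.assert_array_equal(a.vectors, b.vectors)


class TestWarp:
    def test_zero_field_is_identity(self, blob_pair):
        fixed, _ = blob_pair
        zero = DisplacementField.zeros(fixed.shape)
        np.testing.assert_array_equal(warp(fixed, zero, "nearest"), fixed)
        np.testing.assert_allclose(warp(fixed, zero, "linear"), fixed, atol=1e-12)

    def test_integer_translation_nearest_matches_index_shift(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(size=(10, 10, 10))
        field = DisplacementField(vectors=np.zeros((3, 10, 10, 10)))
        field.vectors[0] = 2.0  # sample from x + 2
        shifted = warp(vol, field, "nearest")
        np.testing.assert_array_equal(shifted[:-2], vol[2:])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FlowDataError):
            warp(np.zeros((4, 4, 4)), DisplacementField.zeros((5, 5, 5)))

    def test_border_policy_replicates_edge(self):
        vol = np.zeros((6, 6, 6))
        vol[-1] = 7.0
        field = DisplacementField(vectors=np.zeros((3, 6, 6, 6)))
        field.vectors[0] = 3.0  # samples beyond the far x border
        out = warp(vol, field, "nearest")
        assert np.all(out[-3:] == 7.0)


class TestCompose:
    def test_zero_is_identity_element(self):
        rng = np.random.default_rng(1)
        b = DisplacementField(vectors=rng.normal(0, 0.5, size=(3, 12, 12, 12)))
        zero = DisplacementField.zeros((12, 12, 12))
        np.testing.assert_allclose(compose(zero, b).vectors, b.vectors, atol=1e-12)
        np.testing.assert_allclose(compose(b, zero).vectors, b.vectors, atol=1e-12)

    def test_constant_translations_add(self):
        t1 = DisplacementField(vectors=np.full((3, 10, 10, 10), 0.7))
        t2_vec = np.zeros((3, 10, 10, 10))
        t2_vec[1] = -0.4
        t2 = DisplacementField(vectors=t2_vec)
        comp = compose(t1, t2)
        interior = (slice(None), slice(2, -2), slice(2, -2), slice(2, -2))
        expected = np.full((3, 10, 10, 10), 0.7)
        expected[1] += -0.4
        np.testing.assert_allclose(comp.vectors[interior], expected[interior], atol=1e-9)

    def test_matches_sequential_warping(self):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter

        # smooth volume: linear-interpolation error then stays second order
        vol = gaussian_filter(np.cumsum(rng.uniform(size=(16, 16, 16)), axis=0), 1.5)

        a = DisplacementField(
            vectors=gaussian_filter(rng.normal(0, 1.0, (3, 16, 16, 16)), 2.0)
        )
        b = DisplacementField(
            vectors=gaussian_filter(rng.normal(0, 1.0, (3, 16, 16, 16)), 2.0)
        )
        via_compose = warp(vol, compose(a, b))
        sequential = warp(warp(vol, a), b)
        interior = (slice(3, -3),) * 3
        np.testing.assert_allclose(
            via_compose[interior], sequential[interior], atol=0.05
        )

    def test_associative_within_interpolation_tolerance(self):
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter

        fields = [
            DisplacementField(
                vectors=gaussian_filter(rng.normal(0, 0.8, (3, 14, 14, 14)), 2.0)
            )
            for _ in range(3)
        ]
        a, b, c = fields
        left = compose(compose(a, b), c).vectors
        right = compose(a, compose(b, c)).vectors
        interior = (slice(None),) + (slice(3, -3),) * 3
        np.testing.assert_allclose(left[interior], right[interior], atol=0.02)


class TestDiagnostics:
    def test_jacobian_positive_for_smooth_small_field(self):
        rng = np.random.default_rng(4)
        from scipy.ndimage import gaussian_filter

        field = DisplacementField(
            vectors=gaussian_filter(rng.normal(0, 1.5, (3, 20, 20, 20)), 3.0)
        )
        det = jacobian_determinant(field)
        assert np.all(det[2:-2, 2:-2, 2:-2] > 0)

    def test_inverse_consistency_zero_fields(self):
        img = np.random.default_rng(5).uniform(size=(16, 16, 16))
        zero = DisplacementField.zeros(img.shape)
        assert inverse_consistency_error(img, zero, zero) == 0.0

    def test_inverse_consistency_rejects_unnormalized_image(self):
        img = np.full((16, 16, 16), 2.0)
        zero = DisplacementField.zeros(img.shape)
        with pytest.raises(FlowDataError, match=r"\[0, 1\]"):
            inverse_consistency_error(img, zero, zero)

    def test_round_trip_of_inverse_translations_is_small(self, blob_pair):
        fixed, _ = blob_pair
        fwd = DisplacementField(vectors=np.zeros((3,) + fixed.shape))
        bwd = DisplacementField(vectors=np.zeros((3,) + fixed.shape))
        fwd.vectors[0] = 1.3
        bwd.vectors[0] = -1.3
        err = inverse_consistency_error(fixed / fixed.max(), bwd, fwd)
        assert err < 1e-3


class TestParams:
    @pytest.mark.parametrize(
        "kw", [{"n_scales": 0}, {"iterations_per_scale": 0}, {"sigma_fluid": -1.0}]
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            RegistrationParams(**kw)
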