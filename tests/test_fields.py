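"""Numerical substrate: sampling, resizing, warping, SVF integration, Jacobians."""

import numpy as np
import pytest
from scipy.linalg import expm

from synthreg import fields
from synthreg.fields import (
    compose,
    folding_fraction,
    integrate_svf,
    jacobian_determinant,
    lowres_shape,
    sample_lowres_gaussian,
    upsample_field,
    warp,
)

from conftest import smooth_field


class TestLowresSampling:
    @pytest.mark.parametrize(
        "shape,r,expected",
        [
            ((160, 160, 192), "1:32", (5, 5, 6)),
            ((160, 160, 192), "1:40", (4, 4, 5)),
            ((32, 32), 1, (32, 32)),
            ((64, 64), "1:16", (4, 4)),
        ],
    )
    def test_ceil_rule(self, shape, r, expected):
        assert lowres_shape(shape, r) == expected

    def test_zero_sd_gives_zero_field(self, rng):
        field = sample_lowres_gaussian((32, 32), 1, 0.0, channels=2, rng=rng)
        assert field.shape == (32, 32, 2)
        assert np.all(field == 0)

    def test_moments_match_declared_distribution(self):
        rng = np.random.default_rng(7)
        field = sample_lowres_gaussian((64, 64), "1:4", 2.0, channels=40, rng=rng)
        n = field.size
        assert n >= 10_000
        se_mean = 2.0 / np.sqrt(n)
        assert abs(field.mean()) < 3 * se_mean
        se_sd = 2.0 / np.sqrt(2 * (n - 1))
        assert abs(field.std(ddof=1) - 2.0) < 3 * se_sd

    def test_invalid_arguments(self, rng):
        with pytest.raises(ValueError):
            sample_lowres_gaussian((0, 4), 1, 1.0, rng=rng)
        with pytest.raises(ValueError):
            sample_lowres_gaussian((4, 4), 0, 1.0, rng=rng)
        with pytest.raises(ValueError):
            sample_lowres_gaussian((4, 4), 1, -1.0, rng=rng)

    def test_deterministic_given_rng_state(self):
        a = sample_lowres_gaussian((8, 8), "1:2", 1.0, rng=np.random.default_rng(3))
        b = sample_lowres_gaussian((8, 8), "1:2", 1.0, rng=np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestUpsampling:
    def test_constant_scalar_field_preserved(self):
        field = np.full((4, 4), 3.5)
        out = upsample_field(field, (9, 9))
        assert np.allclose(out, 3.5)

    def test_hand_linear_interpolation(self):
        out = upsample_field(np.array([[0.0], [1.0]]), (3, 1))
        assert np.allclose(out[:, 0], [0.0, 0.5, 1.0])

    def test_value_scaling_converts_units(self):
        field = np.ones((4, 4, 2))
        out = upsample_field(field, (8, 8), scale_values=True)
        assert out.shape == (8, 8, 2)
        assert np.allclose(out, 2.0)

    def test_shrinking_rejected(self):
        with pytest.raises(ValueError):
            upsample_field(np.zeros((8, 8)), (4, 4))


class TestWarp:
    def test_zero_displacement_is_identity(self, rng):
        img = rng.normal(size=(10, 12))
        u = np.zeros((10, 12, 2))
        assert np.array_equal(warp(img, u, "linear"), img)
        labels = rng.integers(0, 4, size=(10, 12))
        assert np.array_equal(warp(labels, u, "nearest"), labels)

    def test_integer_translation_with_fill(self, rng):
        img = rng.normal(size=(6, 6)) + 5.0
        u = np.zeros((6, 6, 2))
        u[..., 0] = 1.0  # sample from one row below: shift content up
        out = warp(img, u, "linear", fill=0.0)
        assert np.allclose(out[:-1], img[1:])
        assert np.all(out[-1] == 0.0)

    def test_nearest_never_invents_labels(self, rng):
        for _ in range(20):
            labels = rng.integers(1, 3, size=(8, 8))
            u = rng.normal(scale=2.0, size=(8, 8, 2))
            out = warp(labels, u, "nearest", fill=0)
            assert set(np.unique(out)) <= set(np.unique(labels)) | {0}

    def test_linear_in_volume_argument(self, rng):
        a, b = rng.normal(size=(8, 8)), rng.normal(size=(8, 8))
        u = rng.normal(scale=1.5, size=(8, 8, 2))
        lhs = warp(2.0 * a + 3.0 * b, u)
        rhs = 2.0 * warp(a, u) + 3.0 * warp(b, u)
        assert np.allclose(lhs, rhs)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            warp(np.zeros((4, 4)), np.zeros((4, 4, 2)), interp="cubic")


class TestCompose:
    def test_identity_element(self, rng):
        u = rng.normal(scale=1.0, size=(8, 8, 2))
        zero = np.zeros_like(u)
        assert np.allclose(compose(zero, u), u)
        assert np.allclose(compose(u, zero), u)

    def test_translation_group_in_interior(self):
        t1 = np.full((12, 12, 2), 0.5)
        t2 = np.full((12, 12, 2), 1.0)
        out = compose(t1, t2)
        assert np.allclose(out[2:-2, 2:-2], 1.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose(np.zeros((4, 4, 2)), np.zeros((5, 5, 2)))


class TestIntegration:
    def test_zero_field_maps_to_zero(self):
        v = np.zeros((8, 8, 2))
        for steps in (0, 1, 5):
            assert np.all(integrate_svf(v, steps) == 0)

    def test_zero_steps_returns_field_unchanged(self, rng):
        v = rng.normal(size=(8, 8, 2))
        assert np.allclose(integrate_svf(v, 0), v)

    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError):
            integrate_svf(np.zeros((4, 4, 2)), -1)

    def test_linear_field_matches_matrix_exponential(self):
        """For v(x) = A(x - c), the exact flow is x + (expm(A) - I)(x - c)."""
        mat = np.array([[0.0, 0.05], [-0.05, 0.0]])  # small skew-symmetric
        center = np.array([15.5, 15.5])
        grid = np.stack(np.meshgrid(*[np.arange(32.0)] * 2, indexing="ij"), -1)
        v = (grid - center) @ mat.T
        u = integrate_svf(v, 5)
        truth = (grid - center) @ (expm(mat) - np.eye(2)).T
        interior = (slice(8, 24),) * 2
        assert np.abs(u - truth)[interior].max() < 1e-3

    def test_agrees_with_forward_euler(self):
        """Scaling-and-squaring vs brute-force ODE integration (2^5 substeps)."""
        v = smooth_field((32, 32), "1:8", 0.5)
        u_euler = np.zeros_like(v)
        for _ in range(32):
            u_euler = u_euler + warp(v, u_euler) / 32.0
        u = integrate_svf(v, 5)
        interior = (slice(6, 26),) * 2
        assert np.abs(u - u_euler)[interior].max() < 1e-2

    def test_inverse_consistency(self, small_smooth_svf):
        v = small_smooth_svf
        u = compose(integrate_svf(v), integrate_svf(-v))
        interior = (slice(6, 26),) * 2
        assert np.abs(u[interior]).max() < 1e-2

    def test_more_steps_never_increase_folding(self):
        v = smooth_field((32, 32), "1:8", 3.0, seed=5)
        fractions = [folding_fraction(integrate_svf(v, s)) for s in (1, 2, 4, 8)]
        assert all(b <= a + 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_integrated_pair_warps_rarely_fold(self):
        """Pair-deformation magnitudes yield diffeomorphisms by construction."""
        from synthreg.shapes import sample_random_svf

        rng = np.random.default_rng(11)
        clean = sum(
            folding_fraction(integrate_svf(sample_random_svf((32, 32), "1:16", 3.0, rng=rng))) == 0
            for _ in range(50)
        )
        assert clean >= 50 * 0.99


class TestJacobian:
    def test_identity_everywhere_for_zero_field(self):
        u = np.zeros((6, 6, 2))
        assert np.allclose(jacobian_determinant(u), 1.0)
        assert folding_fraction(u) == 0.0

    def test_affine_map_determinant(self):
        mat = np.array([[1.2, 0.1], [-0.2, 0.9]])
        grid = np.stack(np.meshgrid(*[np.arange(16.0)] * 2, indexing="ij"), -1)
        u = grid @ (mat - np.eye(2)).T
        det = jacobian_determinant(u)
        assert np.allclose(det[1:-1, 1:-1], np.linalg.det(mat), atol=1e-9)

    def test_axis_reflection_folds(self):
        grid = np.stack(np.meshgrid(*[np.arange(8.0)] * 2, indexing="ij"), -1)
        u = np.zeros((8, 8, 2))
        u[..., 0] = 7.0 - 2.0 * grid[..., 0]  # reflect axis 0 about midline
        assert folding_fraction(u) > 0
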