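"""Image synthesis: GMM intensities, blur, bias, normalization, LUT remap."""

import numpy as np
import pytest
from scipy import stats

from synthreg.synth import (
    SynthConfig,
    apply_bias,
    blur_anisotropic,
    lut_contrast_augment,
    normalize_gamma,
    sample_gmm_image,
    synth_image,
)


def two_label_map(n=64):
    s = np.ones((n, n), dtype=np.int32)
    s[:, n // 2:] = 2
    return s


class TestGmm:
    def test_degenerate_config_gives_constant_image(self, rng):
        cfg = SynthConfig(a_mu=100.0, b_mu=100.0 + 1e-9, a_sigma=1e-12, b_sigma=1e-9)
        img, _ = sample_gmm_image(two_label_map(8), cfg, rng)
        assert np.allclose(img, 100.0, atol=1e-6)

    def test_moment_recovery_per_label(self):
        rng = np.random.default_rng(3)
        s = two_label_map(64)
        img, draw = sample_gmm_image(s, SynthConfig(), rng)
        for lab, mu, sd in zip(draw.labels, draw.means, draw.sds):
            values = img[s == lab]
            n = values.size
            assert abs(values.mean() - mu) < 3 * sd / np.sqrt(n)
            assert abs(values.std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * (n - 1))

    def test_within_label_distribution_is_normal(self):
        """Kolmogorov-Smirnov non-rejection at alpha = 0.01 on a large label."""
        rng = np.random.default_rng(8)
        s = two_label_map(64)
        img, draw = sample_gmm_image(s, SynthConfig(), rng)
        values = img[s == draw.labels[0]]
        _, pval = stats.kstest(values, "norm", args=(draw.means[0], draw.sds[0]))
        assert pval > 0.01

    def test_identical_seeds_identical_images(self):
        s = two_label_map(16)
        a, _ = sample_gmm_image(s, SynthConfig(), np.random.default_rng(4))
        b, _ = sample_gmm_image(s, SynthConfig(), np.random.default_rng(4))
        assert np.array_equal(a, b)


class TestBlur:
    def test_zero_kernel_bound_is_identity(self, rng):
        img = rng.normal(size=(16, 16))
        out = blur_anisotropic(img, SynthConfig(b_K=0.0), rng)
        assert np.array_equal(out, img)

    def test_constant_image_unchanged(self, rng):
        img = np.full((16, 16), 2.5)
        out = blur_anisotropic(img, SynthConfig(b_K=3.0), rng)
        assert np.allclose(out, 2.5)

    def test_impulse_response_matches_sampled_gaussian(self):
        """Isotropic unit-SD blur of an impulse equals the separable
        normalized discrete Gaussian kernel."""
        from scipy.ndimage import gaussian_filter1d

        img = np.zeros((17, 17))
        img[8, 8] = 1.0
        out = gaussian_filter1d(
            gaussian_filter1d(img, 1.0, axis=0, mode="reflect", truncate=3.0),
            1.0, axis=1, mode="reflect", truncate=3.0)
        radius = 3
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * x**2)
        kernel /= kernel.sum()
        expected = np.outer(kernel, kernel)
        assert np.abs(out[8 - radius:8 + radius + 1, 8 - radius:8 + radius + 1] - expected).max() < 1e-6


class TestBias:
    def test_zero_bias_bound_is_identity(self, rng):
        img = rng.normal(size=(20, 20)) + 5
        out = apply_bias(img, SynthConfig(b_B=0.0), rng)
        assert np.allclose(out, img)

    def test_bias_field_strictly_positive(self, rng):
        img = np.ones((40, 40))
        for _ in range(10):
            out = apply_bias(img, SynthConfig(b_B=1.0), rng)
            assert np.all(out > 0)

    def test_log_ratio_recovers_smooth_field(self):
        """Inverting the construction: log(out/in) is the upsampled field."""
        from synthreg.fields import sample_lowres_gaussian, upsample_field

        seed = 31
        img = np.full((40, 40), 2.0)
        cfg = SynthConfig(b_B=0.5)
        out = apply_bias(img, cfg, np.random.default_rng(seed))
        replay = np.random.default_rng(seed)
        sigma = replay.uniform(0.0, cfg.b_B)
        low = sample_lowres_gaussian((40, 40), cfg.r_B, sigma, channels=1, rng=replay)
        field = upsample_field(low[..., 0], (40, 40))
        assert np.allclose(np.log(out / img), field, atol=1e-12)


class TestNormalizeGamma:
    def test_zero_gamma_is_plain_minmax(self, rng):
        img = rng.normal(size=(16, 16))
        out = normalize_gamma(img, SynthConfig(sigma_gamma=0.0), rng)
        expected = (img - img.min()) / (img.max() - img.min())
        assert np.allclose(out, expected)

    def test_endpoints_fixed_under_any_gamma(self, rng):
        img = rng.normal(size=(16, 16))
        out = normalize_gamma(img, SynthConfig(sigma_gamma=2.0), rng)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_known_gamma_squares_midpoint(self):
        img = np.full((4, 4), 0.5)
        img[0, 0], img[-1, -1] = 0.0, 1.0
        normed = (img - img.min()) / (img.max() - img.min())
        assert np.allclose(normed[1, 1] ** np.exp(np.log(2.0)), 0.25)

    def test_constant_image_returns_zeros(self, rng):
        out = normalize_gamma(np.full((8, 8), 3.0), SynthConfig(), rng)
        assert np.all(out == 0)


class TestFullChain:
    def test_output_range_and_determinism(self):
        s = two_label_map(32)
        a, _ = synth_image(s, SynthConfig(), np.random.default_rng(9))
        b, _ = synth_image(s, SynthConfig(), np.random.default_rng(9))
        assert a.min() >= 0.0 and a.max() <= 1.0
        assert np.array_equal(a, b)

    def test_disabled_augmentations_give_piecewise_constant(self, rng):
        cfg = SynthConfig(a_mu=25, b_mu=225, a_sigma=1e-12, b_sigma=1e-9,
                          b_K=0.0, b_B=0.0, sigma_gamma=0.0)
        s = two_label_map(16)
        img, _ = synth_image(s, cfg, rng)
        # vanishing within-label noise: min-max scaled label means remain
        assert len(np.unique(np.round(img, 6))) <= 2
        assert img.min() == 0.0 and img.max() == 1.0

    def test_contrast_decorrelated_between_draws(self):
        """Label-mean rank order differs between two renderings of one map
        in most trials: geometry is shared, contrast is not."""
        rng = np.random.default_rng(12)
        s = np.ones((48, 48), dtype=np.int32)
        s[:16] = 2
        s[16:32, :24] = 3
        differs = 0
        trials = 100
        for _ in range(trials):
            a, _ = synth_image(s, SynthConfig(), rng)
            b, _ = synth_image(s, SynthConfig(), rng)
            order_a = np.argsort([a[s == j].mean() for j in (1, 2, 3)])
            order_b = np.argsort([b[s == j].mean() for j in (1, 2, 3)])
            differs += not np.array_equal(order_a, order_b)
        assert differs > 0.9 * trials * (1 - 1 / 6)  # 5/6 chance if independent


class TestLut:
    def test_constant_image_stays_constant(self, rng):
        out = lut_contrast_augment(np.full((8, 8), 0.4), 64.0, rng)
        assert np.allclose(out, out.flat[0])

    def test_pure_intensity_transform(self, rng):
        img = np.round(np.random.default_rng(2).uniform(size=(16, 16)), 2)
        out = lut_contrast_augment(img, 64.0, rng)
        for val in np.unique(img):
            assert np.allclose(out[img == val], out[img == val].flat[0])

    def test_table_variance_shrinks_with_smoothing(self):
        """Heavier smoothing collapses the table towards a constant."""
        spans = []
        for sigma in (4.0, 16.0, 64.0, 256.0):
            rng = np.random.default_rng(77)
            out = lut_contrast_augment(np.linspace(0, 1, 256).reshape(16, 16), sigma, rng)
            spans.append(out.std())
        assert all(b < a for a, b in zip(spans, spans[1:]))

    def test_invalid_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            lut_contrast_augment(np.zeros((4, 4)), 0.0, rng)
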