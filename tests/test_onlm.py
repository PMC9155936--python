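import numpy as np
import pytest

from ctdenoise import (
    NLMParams,
    NoiseSpec,
    ONLMParams,
    adaptive_kappa1_sq,
    compute_metrics,
    corrupt,
    gaussian_kernel,
    gaussian_prefilter,
    gradient_angle,
    neighborhood_gradient,
    nlm_denoise,
    onlm_denoise,
    onlm_weights,
    pixel_gradient,
)

from oracles import (
    naive_neighborhood_gradient,
    naive_onlm,
    naive_prefilter,
)

SMALL = ONLMParams(search_radius=2, patch_radius=1, kernel_std=1.0,
                   prefilter_radius=1, prefilter_std=1.0)


class TestPrefilter:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 42.0)
        assert np.allclose(gaussian_prefilter(img, 2, 1.0), img, atol=1e-12)

    def test_zero_radius_is_identity(self, random_image):
        img = random_image((8, 8), seed=1)
        assert np.array_equal(gaussian_prefilter(img, 0, 1.0), img)

    def test_impulse_response_equals_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = gaussian_prefilter(img, 1, 1.0)
        assert np.allclose(out[3:6, 3:6], gaussian_kernel(1, 1.0), atol=1e-14)
        assert np.allclose(out[0, :], 0.0, atol=1e-14)

    def test_matches_naive_convolution(self, random_image):
        img = random_image((9, 9), seed=2)
        assert np.allclose(gaussian_prefilter(img, 2, 0.8), naive_prefilter(img, 2, 0.8),
                           atol=1e-11)


class TestGradients:
    def test_constant_image_has_zero_gradient(self):
        img = np.full((7, 7), 3.0)
        assert np.allclose(pixel_gradient(img, (3, 3)), 0.0)
        assert np.allclose(neighborhood_gradient(img, (3, 3), 1), 0.0)

    def test_column_ramp_has_horizontal_gradient(self):
        img = 3.0 * np.tile(np.arange(9.0), (9, 1))
        for p in [(4, 4), (2, 6), (4, 0)]:
            g = pixel_gradient(img, p)
            if p[1] > 0:  # interior columns see the full central difference
                assert g == pytest.approx([3.0, 0.0], abs=1e-12)
        assert neighborhood_gradient(img, (4, 4), 2) == pytest.approx([3.0, 0.0], abs=1e-12)

    def test_pixel_gradient_hand_computation(self, random_image):
        img = random_image((5, 5), seed=3)
        g = pixel_gradient(img, (2, 2))
        assert g[0] == pytest.approx((img[2, 3] - img[2, 1]) / 2, abs=1e-14)
        assert g[1] == pytest.approx((img[3, 2] - img[1, 2]) / 2, abs=1e-14)

    def test_neighborhood_gradient_is_mean_of_pixel_gradients(self, random_image):
        img = random_image((7, 7), seed=4)
        grads = [pixel_gradient(img, (3 + dy, 3 + dx))
                 for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
        expected = np.mean(grads, axis=0)
        assert np.allclose(neighborhood_gradient(img, (3, 3), 1), expected, atol=1e-12)
        naive = naive_neighborhood_gradient(img, 3, 3, 1)
        assert np.allclose(neighborhood_gradient(img, (3, 3), 1), naive, atol=1e-12)

    @pytest.mark.parametrize(
        "g1,g2,expected",
        [((1.0, 2.0), (1.0, 2.0), 0.0),
         ((1.0, 0.0), (0.0, 1.0), np.pi / 2),
         ((1.0, 0.0), (-1.0, 0.0), np.pi),
         ((0.0, 0.0), (1.0, 1.0), 0.0),
         ((1e-15, 0.0), (1.0, 0.0), 0.0)],
    )
    def test_gradient_angle(self, g1, g2, expected):
        assert gradient_angle(np.array(g1), np.array(g2)) == pytest.approx(expected, abs=1e-12)


class TestAdaptiveBandwidth:
    def test_alpha_zero_gives_constant_c(self, random_image):
        img = random_image((9, 9), seed=5)
        params = ONLMParams(2, 1, 1.0, alpha=0.0, c=7.0)
        pref = gaussian_prefilter(img, params.prefilter_radius, params.prefilter_std)
        assert adaptive_kappa1_sq(pref, (4, 4), params) == pytest.approx(7.0, abs=1e-12)

    def test_constant_image_gives_c(self):
        params = ONLMParams(2, 1, 1.0, alpha=3.0, c=11.0)
        assert adaptive_kappa1_sq(np.full((9, 9), 4.0), (4, 4), params) == pytest.approx(11.0)

    def test_matches_independent_window_mean(self, random_image):
        img = random_image((9, 9), seed=6)
        params = ONLMParams(2, 1, 1.0, alpha=1.0, c=1.0, prefilter_radius=0)
        kern = gaussian_kernel(1, 1.0)
        q = np.pad(img, 3, mode="symmetric")
        # independent loop over the 25 window distances at pixel (4, 4)
        total = 0.0
        for dy in range(-2, 3):
            for dx in range(-2, 3):
                a = q[4 + 3 - 1 : 4 + 3 + 2, 4 + 3 - 1 : 4 + 3 + 2]
                b = q[4 + dy + 3 - 1 : 4 + dy + 3 + 2, 4 + dx + 3 - 1 : 4 + dx + 3 + 2]
                total += float((kern * (a - b) ** 2).sum())
        expected = total / 25.0 + 1.0
        assert adaptive_kappa1_sq(img, (4, 4), params) == pytest.approx(expected, abs=1e-10)


class TestWeights:
    def test_constant_image_gives_uniform_weights(self):
        img = np.full((9, 9), 8.0)
        pref = gaussian_prefilter(img, 1, 1.0)
        wm = onlm_weights(img, pref, (4, 4), SMALL)
        assert np.allclose(wm.weights, 1.0 / 25.0, atol=1e-12)

    def test_term_elimination_reduces_to_nlm_weights(self, random_image):
        from ctdenoise import nlm_weights

        img = random_image((11, 11), seed=7)
        params = ONLMParams(2, 1, 1.0, prefilter_radius=1, prefilter_std=1.0,
                            kappa2=np.inf, tau=np.inf, alpha=0.0, c=100.0)
        pref = gaussian_prefilter(img, 1, 1.0)
        wm = onlm_weights(img, pref, (5, 5), params)
        ref = nlm_weights(pref, (5, 5), NLMParams(2, 1, 1.0, kappa=10.0))
        assert np.allclose(wm.weights, ref.weights, atol=1e-12)

    def test_weights_normalized(self, random_image):
        img = random_image((11, 11), seed=8)
        pref = gaussian_prefilter(img, 1, 1.0)
        wm = onlm_weights(img, pref, (3, 7), SMALL)
        assert wm.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert (wm.weights >= 0).all() and (wm.weights <= 1).all()


class TestDenoise:
    def test_constant_image_is_fixed_point(self):
        img = np.full((12, 12), 42.0)
        assert np.allclose(onlm_denoise(img, SMALL), 42.0, atol=1e-12)

    @pytest.mark.parametrize("aggregate", ["raw", "prefiltered"])
    def test_full_reduction_to_nlm(self, random_image, aggregate):
        # h=0, alpha=0, kappa2, tau -> inf: ONLM must equal NLM with kappa^2 = c
        img = random_image((14, 14), seed=9)
        c = 144.0
        params = ONLMParams(3, 1, 1.0, prefilter_radius=0, kappa2=np.inf,
                            tau=np.inf, alpha=0.0, c=c, aggregate=aggregate)
        ref = nlm_denoise(img, NLMParams(3, 1, 1.0, kappa=np.sqrt(c)))
        assert np.max(np.abs(onlm_denoise(img, params) - ref)) < 1e-12

    def test_matches_naive_oracle(self, random_image):
        img = random_image((16, 16), seed=10)
        kwargs = dict(search_radius=2, patch_radius=1, kernel_std=1.0,
                      prefilter_radius=1, prefilter_std=1.0, kappa2=30.0,
                      tau=2.0, alpha=1.0, c=100.0, aggregate="raw")
        expected = naive_onlm(img, **kwargs)
        assert np.max(np.abs(onlm_denoise(img, ONLMParams(**kwargs)) - expected)) < 1e-10

    def test_matches_naive_oracle_prefiltered_aggregation(self, random_image):
        img = random_image((12, 12), seed=11)
        kwargs = dict(search_radius=2, patch_radius=1, kernel_std=1.0,
                      prefilter_radius=2, prefilter_std=0.8, kappa2=25.0,
                      tau=1.5, alpha=0.5, c=50.0, aggregate="prefiltered")
        expected = naive_onlm(img, **kwargs)
        assert np.max(np.abs(onlm_denoise(img, ONLMParams(**kwargs)) - expected)) < 1e-10

    def test_denoise_agrees_with_weight_map(self, random_image):
        img = random_image((11, 11), seed=12)
        out = onlm_denoise(img, SMALL)
        pref = gaussian_prefilter(img, SMALL.prefilter_radius, SMALL.prefilter_std)
        s, r = SMALL.search_radius, SMALL.patch_radius
        q = np.pad(img, s + r, mode="symmetric")  # raw aggregation by default
        for i in [(0, 0), (5, 5), (10, 2)]:
            wm = onlm_weights(img, pref, i, SMALL)
            window = q[i[0] + r : i[0] + r + 2 * s + 1, i[1] + r : i[1] + r + 2 * s + 1]
            assert out[i] == pytest.approx(float((wm.weights * window).sum()), abs=1e-10)

    def test_output_is_convex_combination(self, random_image):
        img = random_image((20, 20), seed=13)
        out = onlm_denoise(img, SMALL)
        assert out.min() >= img.min() - 1e-10
        assert out.max() <= img.max() + 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_reduces_rmse_on_streaked_phantom(self, seed):
        from ctdenoise import default_phantom_spec, make_phantom

        truth = make_phantom(default_phantom_spec())
        noisy = corrupt(truth, NoiseSpec(sigma=20.0, streaks=5, seed=seed))
        out = onlm_denoise(noisy)
        assert compute_metrics(truth, out).rmse < compute_metrics(truth, noisy).rmse

    def test_edge_band_error_below_plain_nlm(self):
        # two-level step edge (0 | 200): mean absolute error within 2 px of
        # the edge, averaged over 10 noise draws, must favor ONLM
        truth = np.zeros((64, 64))
        truth[:, 32:] = 200.0
        band = np.zeros_like(truth, dtype=bool)
        band[:, 30:34] = True
        nlm_err, onlm_err = [], []
        for seed in range(10):
            noisy = corrupt(truth, NoiseSpec(sigma=20.0, streaks=0, seed=seed))
            nlm_err.append(np.abs(nlm_denoise(noisy) - truth)[band].mean())
            onlm_err.append(np.abs(onlm_denoise(noisy) - truth)[band].mean())
        assert np.mean(onlm_err) < np.mean(nlm_err)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            ONLMParams(aggregate="both")
        with pytest.raises(ValueError):
            ONLMParams(prefilter_std=0.0)
        with pytest.raises(ValueError):
            ONLMParams(alpha=-0.5)
        with pytest.raises(ValueError):
            ONLMParams(c=0.0)
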