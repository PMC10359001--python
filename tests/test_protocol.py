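"""The pixel-resampling Mahalanobis protocol, step by step and end to end."""

import numpy as np
import pytest
from scipy import stats

from canedisc.protocol import (
    ProtocolConfig,
    ProtocolError,
    SingularCovarianceError,
    between_difference,
    chisq_pvalue,
    combined_covariance,
    d2_statistic,
    qq_against_chisq,
    run_protocol,
    within_differences,
)


def flat_image(value, shape=(40, 40)):
    img = np.zeros((*shape, 3), np.uint8)
    img[...] = value
    return img, np.ones(shape, bool)


def noisy_image(mean, sd, shape, rng):
    img = np.clip(rng.normal(mean, sd, (*shape, 3)), 0, 255).astype(np.uint8)
    return img, np.ones(shape, bool)


class TestWithinDifferences:
    def test_constant_images_give_zero_differences(self):
        img_a, mask = flat_image(100)
        img_b, _ = flat_image(90)
        cfg = ProtocolConfig(n_pixels=50, n_resamples=10, attrs="R", seed=0)
        w = within_differences(img_a, mask, img_b, mask, cfg)
        assert w.shape == (10, 1)
        np.testing.assert_allclose(w, 0.0)

    def test_two_resamples_give_two_vectors(self):
        rng = np.random.default_rng(1)
        img_a, mask = noisy_image(100, 10, (30, 30), rng)
        img_b, _ = noisy_image(100, 10, (30, 30), rng)
        cfg = ProtocolConfig(n_pixels=100, n_resamples=2, attrs="RGB", seed=1)
        w = within_differences(img_a, mask, img_b, mask, cfg)
        assert w.shape == (2, 3)

    def test_within_sd_matches_binomial_oracle(self):
        """Two-valued image: bootstrap-mean differences have sd √2·255/(2√n)."""
        img = np.zeros((100, 100, 3), np.uint8)
        img[:50, :, 0] = 255
        mask = np.ones((100, 100), bool)
        cfg = ProtocolConfig(n_pixels=2500, n_resamples=100, attrs="R", seed=3)
        w = within_differences(img, mask, img, mask, cfg)
        expected = np.sqrt(2) * 255.0 / (2 * np.sqrt(2500))
        assert abs(w.std(ddof=1) - expected) / expected < 0.25

    def test_oversized_resample_rejected(self):
        img, mask = flat_image(100, (10, 10))
        cfg = ProtocolConfig(n_pixels=100, n_resamples=4, seed=0)
        with pytest.raises(ProtocolError):
            within_differences(img, mask, img, mask, cfg)


class TestBetweenDifference:
    def test_identical_images(self):
        img, mask = flat_image(120)
        np.testing.assert_allclose(
            between_difference(img, mask, img, mask, "RGB"), 0.0
        )

    def test_constant_offset(self):
        a, mask = flat_image(100)
        b, _ = flat_image(90)
        np.testing.assert_allclose(between_difference(a, mask, b, mask, "R"), [10.0])

    def test_hand_built_four_pixel_images(self):
        a = np.zeros((2, 2, 3), np.uint8)
        a[..., 0] = [[10, 20], [30, 40]]  # mean R 25
        b = np.zeros((2, 2, 3), np.uint8)
        b[..., 0] = [[0, 10], [10, 20]]  # mean R 10
        mask = np.ones((2, 2), bool)
        np.testing.assert_allclose(between_difference(a, mask, b, mask, "R"), [15.0])


class TestCovarianceAndD2:
    def test_p1_hand_variance(self):
        cov = combined_covariance(np.array([[-1.0], [1.0]]))
        np.testing.assert_allclose(cov, [[2.0]])

    def test_symmetric_psd(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(50, 3))
        cov = combined_covariance(w)
        np.testing.assert_allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)

    def test_pooled_with_between_adds_one_observation(self):
        w = np.array([[-1.0], [1.0]])
        pooled = combined_covariance(w, between=np.array([4.0]), mode="pooled-with-between")
        np.testing.assert_allclose(pooled, np.atleast_2d(np.var([-1, 1, 4], ddof=1)))

    def test_too_few_vectors_for_dimension(self):
        with pytest.raises(SingularCovarianceError, match="raise n_resamples"):
            combined_covariance(np.ones((3, 5)))

    def test_identical_within_vectors_lead_to_singularity_error(self):
        cov = combined_covariance(np.zeros((10, 1)))
        with pytest.raises(SingularCovarianceError):
            d2_statistic(np.array([1.0]), np.array([0.0]), cov)

    @pytest.mark.parametrize(
        "between,within_mean,cov,expected",
        [
            ([2.0, -1.0], [2.0, -1.0], np.eye(2), 0.0),
            ([3.0], [1.0], [[4.0]], 1.0),
            ([3.0, 4.0], [0.0, 0.0], np.eye(2), 25.0),
        ],
    )
    def test_quadratic_form_closed_forms(self, between, within_mean, cov, expected):
        d2 = d2_statistic(np.array(between), np.array(within_mean), np.array(cov))
        assert d2 == pytest.approx(expected)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=(60, 2))
        between = rng.normal(size=2)
        cov = combined_covariance(w)
        base = d2_statistic(between, w.mean(axis=0), cov)
        c = 7.3
        scaled = d2_statistic(
            c * between, c * w.mean(axis=0), combined_covariance(c * w)
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_swap_symmetry_of_quadratic_form(self):
        rng = np.random.default_rng(7)
        w = rng.normal(size=(60, 2))
        between = rng.normal(size=2)
        cov = combined_covariance(w)
        a = d2_statistic(between, w.mean(axis=0), cov)
        b = d2_statistic(-between, -w.mean(axis=0), cov)
        assert a == pytest.approx(b)

    def test_pinv_fallback_warns(self):
        cov = np.zeros((1, 1))
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            d2 = d2_statistic(np.array([1.0]), np.array([0.0]), cov, singular="pinv")
        assert d2 == 0.0


class TestChisqPvalue:
    def test_zero_statistic(self):
        assert chisq_pvalue(0.0, 1) == 1.0

    def test_p1_against_numeric_integration_oracle(self):
        # upper tail of chi2(1) by trapezoid on its density
        x = np.linspace(3.8415, 400.0, 400_000)
        pdf = x**-0.5 * np.exp(-x / 2) / (np.sqrt(2 * np.pi))
        oracle = np.trapezoid(pdf, x)
        assert chisq_pvalue(3.8415, 1) == pytest.approx(oracle, abs=1e-5)
        assert chisq_pvalue(3.8415, 1) == pytest.approx(0.05, abs=1e-3)

    def test_p2_closed_form(self):
        d2 = 2 * np.log(20.0)
        assert chisq_pvalue(d2, 2) == pytest.approx(np.exp(-d2 / 2), abs=1e-12)
        assert chisq_pvalue(d2, 2) == pytest.approx(0.05, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ProtocolError):
            chisq_pvalue(-1.0, 1)
        with pytest.raises(ProtocolError):
            chisq_pvalue(1.0, 0)


class TestRunProtocol:
    def test_image_against_its_own_copy_rarely_rejects(self):
        """Null behaviour: a leaf compared with an exact copy of itself."""
        rng = np.random.default_rng(8)
        img, mask = noisy_image(110, 12, (50, 50), rng)
        n = int(mask.sum()) - 1
        cfg = ProtocolConfig(n_pixels=n, n_resamples=100, attrs="R")
        big_p = 0
        runs = 100
        for i in range(runs):
            res = run_protocol(img, mask, img, mask, cfg, np.random.default_rng((8, i)))
            big_p += res.p_value > 0.01
        assert big_p >= 0.90 * runs

    def test_two_different_constants_raise_singularity(self):
        a, mask = flat_image(100)
        b, _ = flat_image(90)
        cfg = ProtocolConfig(n_pixels=50, n_resamples=20, attrs="R", seed=0)
        with pytest.raises(SingularCovarianceError):
            run_protocol(a, mask, b, mask, cfg)

    def test_same_clone_pairs_score_below_different_clone_pairs(self):
        """Median D² with a 3-pixel-SE clone shift exceeds the null median."""
        rng = np.random.default_rng(12)
        shape = (50, 50)
        sd = 12.0
        shift = 3 * np.sqrt(2) * sd / np.sqrt(shape[0] * shape[1])
        d2_same, d2_diff = [], []
        cfg = ProtocolConfig(n_pixels=shape[0] * shape[1] - 1, n_resamples=100, attrs="R")
        for i in range(60):
            r = np.random.default_rng((12, i))
            a, mask = noisy_image(110, sd, shape, r)
            b, _ = noisy_image(110, sd, shape, r)
            c, _ = noisy_image(110 + shift, sd, shape, r)
            d2_same.append(run_protocol(a, mask, b, mask, cfg, np.random.default_rng((13, i))).d2)
            d2_diff.append(run_protocol(a, mask, c, mask, cfg, np.random.default_rng((14, i))).d2)
        assert np.median(d2_same) < np.median(d2_diff)

    def test_rejection_rate_monotone_in_mean_shift(self):
        rng_shape = (40, 40)
        sd = 12.0
        se = np.sqrt(2) * sd / np.sqrt(rng_shape[0] * rng_shape[1])
        rates = []
        cfg = ProtocolConfig(
            n_pixels=rng_shape[0] * rng_shape[1] - 1, n_resamples=100, attrs="R"
        )
        for k, shift in enumerate((0.0, 3 * se, 8 * se)):
            rej = 0
            for i in range(50):
                r = np.random.default_rng((15, k, i))
                a, mask = noisy_image(110, sd, rng_shape, r)
                b, _ = noisy_image(110 + shift, sd, rng_shape, r)
                res = run_protocol(a, mask, b, mask, cfg, np.random.default_rng((16, k, i)))
                rej += res.p_value < 0.05
            rates.append(rej / 50)
        assert rates[0] <= rates[1] <= rates[2]

    def test_result_fields_consistent(self):
        rng = np.random.default_rng(17)
        a, mask = noisy_image(110, 10, (40, 40), rng)
        b, _ = noisy_image(112, 10, (40, 40), rng)
        cfg = ProtocolConfig(n_resamples=50, attrs="RGB", seed=4)
        res = run_protocol(a, mask, b, mask, cfg)
        assert res.df == 3
        assert res.within_cov.shape == (3, 3)
        assert res.n_within == 50  # 2 * floor(50/2)
        assert res.d2 >= 0.0 and 0.0 <= res.p_value <= 1.0
        assert res.p_value == pytest.approx(chisq_pvalue(res.d2, 3))

    def test_default_n_pixels_rule(self):
        cfg = ProtocolConfig()
        assert cfg.resolve_n_pixels([20000, 30000]) == 2000  # 10% of smaller
        assert cfg.resolve_n_pixels([4000, 5000]) == 500  # floor of 500
        assert cfg.resolve_n_pixels([400, 30000]) == 399  # capped at N-1


class TestQQ:
    def test_exact_chisq_sample_matches_theory(self):
        n = 2000
        probs = (np.arange(1, n + 1) - 0.5) / n
        vals = stats.chi2.ppf(probs, df=1)
        qq = qq_against_chisq(vals, 1)
        np.testing.assert_allclose(
            qq["empirical_quantile"], qq["theoretical_quantile"], atol=1e-8
        )

    def test_constant_values_flat(self):
        qq = qq_against_chisq([2.0] * 20, 1)
        assert (qq["empirical_quantile"] == 2.0).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ProtocolError):
            qq_against_chisq([1.0] * 5, 1)
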