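"""Statistical core: t-tests, effect sizes, correlations, OLS, allometry."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.special
from hypothesis import given
from hypothesis import strategies as st_

from organscale.errors import DegenerateTestError, DesignMatrixError
from organscale.scaling_models import (
    adjusted_r2,
    classify_strength,
    cohens_d_summary,
    fit_allometric,
    fit_linear_model,
    pearson_correlation,
    student_t_test,
)

finite_samples = st_.lists(
    st_.floats(min_value=-100, max_value=100, allow_nan=False),
    min_size=3,
    max_size=20,
)


def _ols_oracle(y, X):
    """Independent normal-equations solve with textbook SEs."""
    D = np.column_stack([np.ones(len(y)), X])
    XtX = D.T @ D
    beta = np.linalg.solve(XtX, D.T @ y)
    resid = y - D @ beta
    df = len(y) - D.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


class TestStudentTTest:
    def test_identical_samples_are_an_exact_null(self):
        res = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0
        assert res.p_value == 1.0
        assert res.cohens_d == 0.0
        assert res.direction == 0

    def test_hand_computed_example_with_independent_cdf(self):
        """a={1,2,3}, b={2,3,4}: pooled sd 1, t = -sqrt(3/2), df = 4."""
        res = student_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        t_expected = -1.0 / math.sqrt(2.0 / 3.0)
        assert res.t_stat == pytest.approx(t_expected, abs=1e-12)
        assert res.t_stat == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        # independent two-sided p from the regularized incomplete beta CDF
        p_oracle = 2.0 * scipy.special.stdtr(4, -abs(t_expected))
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.cohens_d == pytest.approx(-1.0)

    def test_power_at_large_n(self):
        rng = np.random.default_rng(99)
        a = rng.normal(35, 3, 500)
        b = rng.normal(30, 3, 500)
        assert student_t_test(a, b).p_value < 0.001

    def test_zero_pooled_variance_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            student_t_test([5.0, 5.0, 5.0], [5.0, 5.0])

    def test_welch_flag_changes_df(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0, 50.0]
        assert student_t_test(a, b).df == 5
        assert student_t_test(a, b, welch=True).df != 5

    @given(
        values=st_.lists(
            st_.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=4, max_size=24,
        ).filter(lambda v: len(v) % 2 == 0 and np.std(v) > 1e-6)
    )
    def test_t_equals_d_times_sqrt_half_n_for_equal_groups(self, values):
        n = len(values) // 2
        a, b = values[:n], values[n:]
        try:
            res = student_t_test(a, b)
        except DegenerateTestError:
            return
        assert res.t_stat == pytest.approx(
            res.cohens_d * math.sqrt(n / 2.0), rel=1e-9, abs=1e-9
        )

    def test_sample_d_equals_summary_d(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        res = student_t_test(a, b)
        d = cohens_d_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert res.cohens_d == d


class TestCohensDSummary:
    def test_equal_means_give_zero(self):
        assert cohens_d_summary(7.0, 1.0, 10, 7.0, 3.0, 20) == 0.0

    def test_hedges_correction_shrinks(self):
        d = cohens_d_summary(1.0, 1.0, 10, 0.0, 1.0, 10)
        g = cohens_d_summary(1.0, 1.0, 10, 0.0, 1.0, 10, hedges=True)
        assert abs(g) < abs(d)
        assert g == pytest.approx(d * (1 - 3 / (4 * 20 - 9)))

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(DegenerateTestError):
            cohens_d_summary(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestCorrelation:
    def test_exact_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        res = pearson_correlation(x, 3 * x + 2)
        assert res.r == pytest.approx(1.0)
        assert res.strength == "very strong"

    def test_hand_computed_r(self):
        res = pearson_correlation([1.0, 2, 3, 4], [1.0, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.strength == "strong"

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize(
        "abs_r, label",
        [
            (0.0, "negligible"),
            (0.058, "negligible"),
            (0.10, "weak"),  # lower bin edge belongs to the stronger label
            (0.21, "weak"),
            (0.26, "weak"),
            (0.40, "moderate"),
            (0.70, "strong"),
            (0.90, "very strong"),
            (1.0, "very strong"),
        ],
    )
    def test_strength_classification(self, abs_r, label):
        assert classify_strength(abs_r) == label

    def test_strength_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_strength(1.2)

    @given(
        seed=st_.integers(0, 1000),
        scale=st_.floats(min_value=0.01, max_value=50),
        shift=st_.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance_and_sign_flip(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r0 = pearson_correlation(x, y).r
        assert pearson_correlation(x, scale * y + shift).r == pytest.approx(r0, abs=1e-9)
        assert pearson_correlation(x, -scale * y).r == pytest.approx(-r0, abs=1e-9)


class TestLinearModel:
    def test_noise_free_line_fits_exactly(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        reg = fit_linear_model(2 + 3 * x, pd.DataFrame({"x": x}))
        assert reg["Intercept"].estimate == pytest.approx(2.0, abs=1e-10)
        assert reg["x"].estimate == pytest.approx(3.0, abs=1e-10)
        assert reg.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 8, 2
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        reg = fit_linear_model(y, pd.DataFrame(X, columns=["a", "b"]))
        beta, se = _ols_oracle(y, X)
        est = [reg["Intercept"].estimate, reg["a"].estimate, reg["b"].estimate]
        ses = [reg["Intercept"].se, reg["a"].se, reg["b"].se]
        assert np.allclose(est, beta, atol=1e-10)
        assert np.allclose(ses, se, atol=1e-10)

    def test_rank_deficient_design_is_rejected(self):
        x = np.arange(6.0)
        with pytest.raises(DesignMatrixError, match="collinear"):
            fit_linear_model(
                x, pd.DataFrame({"a": x, "b": 2 * x})
            )

    def test_too_small_sample_is_rejected(self):
        with pytest.raises(DesignMatrixError):
            fit_linear_model([1.0, 2.0], pd.DataFrame({"x": [1.0, 2.0]}))

    @given(seed=st_.integers(0, 500), n=st_.integers(6, 30))
    def test_adjusted_r2_identity_holds_for_every_fit(self, seed, n):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        y = X @ [1.0, -0.5] + rng.normal(size=n)
        reg = fit_linear_model(y, pd.DataFrame(X, columns=["a", "b"]))
        assert reg.adj_r2 == pytest.approx(
            adjusted_r2(reg.r2, reg.n, reg.k), abs=1e-12
        )
        assert all(
            c.ci_lower <= c.estimate <= c.ci_upper
            for c in reg.coefficients.values()
        )


class TestAllometricFit:
    def test_exact_power_law(self):
        x = np.array([1.0, 2.0, 3.5, 4.2, 7.7])
        fit = fit_allometric(x, 2.0 * x**0.75)
        assert fit.a == pytest.approx(2.0, rel=1e-10)
        assert fit.b == pytest.approx(0.75, abs=1e-10)
        assert fit.regression.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_isometric_case(self):
        x = np.array([1.0, 2.0, 3.5, 4.2, 7.7, 9.1])
        for c in (1.0, 2.5, 0.3):
            fit = fit_allometric(x, c * x)
            assert fit.b == pytest.approx(1.0, abs=1e-10)
            assert fit.isometry_t == 0.0
            assert fit.isometry_p == 1.0

    def test_isometry_statistic_is_wald_ratio(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(10, 40, 200)
        y = 3.0 * x**0.4 * np.exp(rng.normal(0, 0.1, 200))
        fit = fit_allometric(x, y)
        assert fit.isometry_t == (fit.b - 1.0) / fit.se_b
        assert fit.isometry_t < 0  # negative allometry

    def test_nonpositive_values_listed_not_dropped(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            fit_allometric([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])

    @given(
        kx=st_.floats(min_value=0.1, max_value=10),
        my=st_.floats(min_value=0.1, max_value=10),
    )
    def test_unit_change_invariance(self, kx, my):
        """x -> kx, y -> my leaves b (and se_b) alone; a -> m a k^-b."""
        rng = np.random.default_rng(8)
        x = rng.uniform(5, 50, 60)
        y = 2.0 * x**0.4 * np.exp(rng.normal(0, 0.2, 60))
        base = fit_allometric(x, y)
        scaled = fit_allometric(kx * x, my * y)
        assert scaled.b == pytest.approx(base.b, rel=1e-9)
        assert scaled.se_b == pytest.approx(base.se_b, rel=1e-9)
        assert scaled.a == pytest.approx(
            my * base.a * kx ** (-base.b), rel=1e-8
        )
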