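"""The homologous test: design construction, OLS, contrast, identities."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy import stats

from homtest import (
    InsufficientDataError,
    SingularDesignError,
    TimepointPairData,
    build_design,
    conditional_group_estimates,
    contrast_vector,
    fit_ols,
    homologous_test,
)
from conftest import random_pair


def make_pair(yp0, yc0, yp1, yc1):
    return TimepointPairData(0.0, 1.0, yp0, yc0, yp1, yc1)


finite_vec = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False), min_size=4, max_size=12
)


class TestBuildDesign:
    def test_row_structure(self):
        pair = make_pair([1.0, 2.0], [0, 0], [3.0, 4.0], [0, 0])
        with pytest.raises(InsufficientDataError):
            build_design(pair)  # n = 4 < 5
        pair = make_pair([1.0, 2.0, 5.0], [0, 0, 0], [3.0, 4.0], [0, 0])
        y, X = build_design(pair)
        expected = np.array(
            [[1, 0, 1, 0], [1, 0, 2, 0], [1, 0, 5, 0], [1, 1, 3, 3], [1, 1, 4, 4]],
            dtype=float,
        )
        assert np.array_equal(X, expected)
        assert X.shape == (5, 4)
        # interaction column vanishes on every group-0 row
        assert np.all(X[:3, 3] == 0)

    def test_group_zero_rows_first(self, rng):
        pair = random_pair(rng, n0=3, n1=4)
        _, X = build_design(pair)
        assert np.array_equal(X[:, 1], [0, 0, 0, 1, 1, 1, 1])


class TestFitOls:
    def test_exact_interpolation_recovers_coefficients(self, rng):
        pair = random_pair(rng, n0=4, n1=4)
        _, X = build_design(pair)
        beta = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_ols(X @ beta, X)
        assert fit.beta_hat == pytest.approx(beta, rel=1e-8)
        assert fit.sse == pytest.approx(0.0, abs=1e-9)

    def test_matches_statsmodels_ols(self, rng):
        """Independent oracle: statsmodels OLS on the same design."""
        for _ in range(5):
            pair = random_pair(rng, n0=5, n1=6, effect=0.7)
            y, X = build_design(pair)
            fit = fit_ols(y, X)
            ref = sm.OLS(y, X).fit()
            assert fit.beta_hat == pytest.approx(ref.params, rel=1e-8)
            assert fit.sse == pytest.approx(ref.ssr, rel=1e-8)
            assert fit.mse == pytest.approx(ref.mse_resid, rel=1e-8)
            assert fit.xtx_inv == pytest.approx(ref.normalized_cov_params, rel=1e-7)

    def test_normal_equations_agreement(self, rng):
        # same numbers as solving X'X b = X'y directly on well-conditioned data
        pair = random_pair(rng, n0=3, n1=3)
        y, X = build_design(pair)
        fit = fit_ols(y, X)
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.beta_hat == pytest.approx(beta_ne, rel=1e-8)

    def test_constant_covariate_is_singular_and_named(self):
        pair = make_pair([2.0, 2.0, 2.0], [1, 2, 3], [2.0, 2.0, 2.0], [2, 3, 4])
        y, X = build_design(pair)
        with pytest.raises(SingularDesignError) as err:
            fit_ols(y, X)
        assert err.value.column in {"y_prev", "group:y_prev"}


class TestContrastVector:
    def test_direct_substitution(self):
        pair = make_pair([2.0, 2.0, 2.0], [0, 0, 0], [5.0, 5.0], [0, 0])
        zc = contrast_vector(pair)
        assert np.array_equal(zc.z, [0, 1, 3, 5])

    def test_equal_covariate_means(self):
        pair = make_pair([1.0, 5.0], [0, 0], [2.0, 4.0], [0, 0])
        assert np.array_equal(contrast_vector(pair).z, [0, 1, 0, 3])

    def test_centered_covariates_reduce_to_effect_coefficient(self, rng):
        yp0 = rng.normal(size=6); yp0 -= yp0.mean()
        yp1 = rng.normal(size=6); yp1 -= yp1.mean()
        pair = make_pair(yp0, rng.normal(size=6), yp1, rng.normal(size=6))
        zc = contrast_vector(pair)
        assert zc.z == pytest.approx([0, 1, 0, 0], abs=1e-12)
        res = homologous_test(pair)
        y, X = build_design(pair)
        assert res.d_hat == pytest.approx(fit_ols(y, X).beta_hat[1], rel=1e-10)


class TestHomologousTest:
    def test_identical_groups_give_null_result(self):
        yc = np.array([1.0, 2.0, 3.0, 4.0])
        pair = make_pair([0.5, 1.0, 2.0, 3.5], yc, [0.2, 1.1, 2.2, 3.0], yc)
        res = homologous_test(pair)
        assert res.d_hat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_df_is_n_minus_4(self, rng):
        res = homologous_test(random_pair(rng, n0=4, n1=7))
        assert res.df == 7

    def test_p_value_from_central_t(self, rng):
        res = homologous_test(random_pair(rng, n0=5, n1=5))
        expected = 2 * stats.t.sf(abs(res.t_stat), res.df)
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_one_sided_alternatives_partition(self, rng):
        pair = random_pair(rng, n0=5, n1=5, effect=1.0)
        g = homologous_test(pair, alternative="greater")
        l = homologous_test(pair, alternative="less")
        assert g.p_value + l.p_value == pytest.approx(1.0, rel=1e-10)
        assert g.d_hat == l.d_hat

    @given(st.data())
    def test_mean_difference_identity(self, data):
        """The contrast estimate equals the raw difference of group means,
        for arbitrary (non-degenerate) data."""
        yp0 = np.array(data.draw(finite_vec))
        yp1 = np.array(data.draw(finite_vec))
        rng = np.random.default_rng(0)
        yc0 = yp0 + rng.normal(size=yp0.size)
        yc1 = 1.0 + yp1 + rng.normal(size=yp1.size)
        pair = make_pair(yp0, yc0, yp1, yc1)
        try:
            res = homologous_test(pair, with_group_estimates=False)
        except (SingularDesignError, InsufficientDataError):
            return
        expected = yc1.mean() - yc0.mean()
        assert res.d_hat == pytest.approx(expected, rel=1e-10, abs=1e-10)

    @given(st.data())
    def test_leverage_identity(self, data):
        """z (X'X)^-1 z' = 1/n0 + 1/n1 exactly: the contrast sits at each
        group's own covariate mean, where that group's leverage is 1/n_g."""
        yp0 = np.array(data.draw(finite_vec))
        yp1 = np.array(data.draw(finite_vec))
        rng = np.random.default_rng(1)
        pair = make_pair(yp0, rng.normal(size=yp0.size), yp1, rng.normal(size=yp1.size))
        try:
            y, X = build_design(pair)
            fit = fit_ols(y, X)
        except (SingularDesignError, InsufficientDataError):
            return
        z = contrast_vector(pair).z
        lev = float(z @ fit.xtx_inv @ z)
        assert lev == pytest.approx(1 / pair.n0 + 1 / pair.n1, rel=1e-8)

    def test_joint_fit_decouples_into_group_regressions(self, rng):
        """Interaction-model coefficients reproduce the two within-group
        simple regressions: (b0, b2) for group 0, (b0+b1, b2+b3) for group 1."""
        pair = random_pair(rng, n0=6, n1=8, effect=0.5)
        y, X = build_design(pair)
        beta = fit_ols(y, X).beta_hat
        s0, i0 = np.polyfit(pair.y_prev_0, pair.y_curr_0, 1)
        s1, i1 = np.polyfit(pair.y_prev_1, pair.y_curr_1, 1)
        assert beta[0] == pytest.approx(i0, rel=1e-8)
        assert beta[2] == pytest.approx(s0, rel=1e-8)
        assert beta[0] + beta[1] == pytest.approx(i1, rel=1e-8)
        assert beta[2] + beta[3] == pytest.approx(s1, rel=1e-8)


class TestConditionalGroupEstimates:
    def test_estimate_is_group_mean_regardless_of_slope(self, rng):
        pair = random_pair(rng, n0=5, n1=7, effect=2.0, rho_slope=3.0)
        est = conditional_group_estimates(pair)
        assert est[0].estimate == pytest.approx(pair.y_curr_0.mean(), rel=1e-12)
        assert est[1].estimate == pytest.approx(pair.y_curr_1.mean(), rel=1e-12)

    def test_perfect_line_gives_zero_mse_and_unit_rho(self):
        yp = np.array([1.0, 2.0, 3.0, 4.0])
        pair = make_pair(yp, 2 * yp + 1, yp, -yp + 5)
        est = conditional_group_estimates(pair)
        assert est[0].mse == pytest.approx(0.0, abs=1e-20)
        assert est[0].se == pytest.approx(0.0, abs=1e-10)
        assert est[0].rho == pytest.approx(1.0)
        assert est[1].rho == pytest.approx(-1.0)

    def test_mse_uses_n_minus_2_denominator(self, rng):
        pair = random_pair(rng, n0=6, n1=6)
        est = conditional_group_estimates(pair)
        slope, intercept = np.polyfit(pair.y_prev_0, pair.y_curr_0, 1)
        resid = pair.y_curr_0 - (intercept + slope * pair.y_prev_0)
        assert est[0].mse == pytest.approx(float(resid @ resid) / 4, rel=1e-8)
        assert est[0].se == pytest.approx(np.sqrt(est[0].mse / 6), rel=1e-12)

    def test_constant_covariate_flags_degenerate(self):
        pair = make_pair([1.0, 1.0, 1.0], [1, 2, 3], [0.0, 1.0, 2.0], [1, 2, 3])
        est = conditional_group_estimates(pair)
        assert est[0].degenerate and np.isnan(est[0].rho)
        assert not est[1].degenerate

    def test_variance_reduction_under_strong_correlation(self, rng):
        """With |rho| >= 0.9 the conditional SE beats s/sqrt(n) nearly always."""
        wins = 0
        total = 200
        for _ in range(total):
            n = 12
            yp = rng.normal(size=n)
            yc = yp + 0.3 * rng.normal(size=n)  # rho ~ 0.96
            pair = make_pair(yp, yc, rng.normal(size=n), rng.normal(size=n))
            est = conditional_group_estimates(pair)
            conventional = yc.std(ddof=1) / np.sqrt(n)
            if est[0].se < conventional:
                wins += 1
        assert wins / total >= 0.95
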