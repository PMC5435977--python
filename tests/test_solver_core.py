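"""Solver correctness: closed forms, optimality certificates, equivalences."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ipflasso as ipf
from ipflasso.core import (
    fit_weighted_lasso_path,
    lambda_max,
    rescale_design,
    soft_threshold,
    standardize_columns,
)
from ipflasso.objectives import BreslowIndex

from conftest import kkt_violation, proximal_weighted_lasso, random_instance

FAMILIES = ["gaussian", "binomial", "cox"]


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,gamma,expected",
        [(0.7, 0.2, 0.5), (-0.3, 0.5, 0.0), (1.5, 0.0, 1.5), (-2.0, 0.5, -1.5)],
    )
    def test_values(self, z, gamma, expected):
        assert soft_threshold(z, gamma) == pytest.approx(expected)

    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_shrinks_toward_zero_never_flips_sign(self, z, gamma):
        out = soft_threshold(z, gamma)
        assert abs(out) <= abs(z)
        assert out * z >= 0

    def test_rejects_negative_threshold(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


def _orthonormal_design(rng, n, p):
    """Centered columns with x_j^T x_k / n = delta_jk (so standardization
    leaves them unchanged up to scale 1)."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, p + 1)))
    Q = Q - Q.mean(axis=0)
    Q, _ = np.linalg.qr(Q)
    return Q[:, :p] * np.sqrt(n)


class TestLambdaMax:
    def test_gaussian_orthonormal_closed_form(self, rng):
        X = _orthonormal_design(rng, 50, 5)
        y = rng.standard_normal(50)
        out = ipf.Outcome.gaussian(y)
        lmax = lambda_max(X, out, np.ones(5), standardize=False)
        expected = np.max(np.abs(X.T @ (y - y.mean()))) / 50
        assert lmax == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_all_zero_solution_at_grid_top(self, family, rng):
        X, out = random_instance(family, 30, 12, rng)
        fit = fit_weighted_lasso_path(X, out, np.ones(12), nlambda=10)
        assert fit.df()[0] == 0

    def test_doubling_weights_halves_lambda_max(self, rng):
        """Verified against brute-force bisection for the smallest all-zero
        lambda on random 20 x 10 instances."""
        for family in FAMILIES:
            X, out = random_instance(family, 20, 10, rng)
            w = rng.uniform(0.5, 2.0, size=10)
            l1 = lambda_max(X, out, w)
            l2 = lambda_max(X, out, 2 * w)
            assert l2 == pytest.approx(l1 / 2, rel=1e-10)
            # bisection for the smallest lambda giving the empty model
            lo, hi = l1 * 0.5, l1 * 2
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                f = fit_weighted_lasso_path(X, out, w, grid=np.array([mid]))
                if f.df()[0] == 0:
                    hi = mid
                else:
                    lo = mid
            assert l1 == pytest.approx(hi, rel=1e-6)

    def test_degenerate_outcomes_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            lambda_max(X, ipf.Outcome.gaussian(np.ones(10)), np.ones(4))
        with pytest.raises(ValueError):
            lambda_max(X, ipf.Outcome.binomial(np.zeros(10)), np.ones(4))


class TestWeightedLassoPath:
    def test_unpenalized_limit_reaches_least_squares(self, rng):
        n, p = 18, 10
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        out = ipf.Outcome.gaussian(y)
        lmax = lambda_max(X, out, np.ones(p))
        grid = np.geomspace(lmax, lmax * 1e-8, 40)
        fit = fit_weighted_lasso_path(X, out, np.ones(p), grid=grid, tol=1e-10)
        Xc = np.column_stack([np.ones(n), X])
        ls = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef_[-1], ls[1:], atol=1e-6)
        np.testing.assert_allclose(fit.intercept_[-1], ls[0], atol=1e-6)

    def test_orthonormal_design_equals_soft_thresholding(self, rng):
        """On a centered orthonormal design (x_j^T x_j = n) the gaussian
        coordinate update decouples: beta_j = S(x_j^T y / n, lam)."""
        n, p = 50, 5
        X = _orthonormal_design(rng, n, p)
        y = rng.standard_normal(n)
        out = ipf.Outcome.gaussian(y)
        lmax = lambda_max(X, out, np.ones(p), standardize=False)
        grid = np.geomspace(lmax, 0.05 * lmax, 10)
        fit = fit_weighted_lasso_path(X, out, np.ones(p), grid=grid,
                                      standardize=False, tol=1e-12)
        yc = y - y.mean()
        for li, lam in enumerate(grid):
            expected = [soft_threshold(X[:, j] @ yc / n, lam) for j in range(p)]
            np.testing.assert_allclose(fit.coef_[li], expected, atol=1e-8)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_kkt_certificate_random_instances(self, family, rng):
        """Subgradient optimality at tolerance 1e-4 on 30 x 40 instances."""
        X, out = random_instance(family, 30, 40, rng)
        w = rng.choice([0.5, 1.0, 2.0], size=40)
        Xs, _ = standardize_columns(X)
        fit = fit_weighted_lasso_path(Xs, out, w, nlambda=20, standardize=False)
        for li in [0, 5, 10, 19]:
            beta, b0 = fit.coef_[li], fit.intercept_[li]
            assert kkt_violation(Xs, out, beta, b0, fit.lambdas[li], fit.penalty_weights) < 1e-4

    def test_loss_nonincreasing_along_path(self, rng):
        from ipflasso.objectives import loss

        for family in FAMILIES:
            X, out = random_instance(family, 25, 15, rng)
            Xs, _ = standardize_columns(X)
            fit = fit_weighted_lasso_path(Xs, out, np.ones(15), nlambda=25,
                                          standardize=False)
            losses = [
                loss(family, Xs, out, fit.coef_[li], fit.intercept_[li])
                for li in range(fit.n_lambdas)
            ]
            assert np.all(np.diff(losses) <= 1e-9)

    def test_zero_variance_column_excluded_with_warning(self, rng):
        X = rng.standard_normal((20, 5))
        X[:, 2] = 3.14
        out = ipf.Outcome.gaussian(rng.standard_normal(20))
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_weighted_lasso_path(X, out, np.ones(5), nlambda=10)
        assert np.all(fit.coef_[:, 2] == 0)


class TestIpfLasso:
    def test_uniform_pf_identical_to_standard_lasso(self, rng):
        X, out = random_instance("binomial", 30, 20, rng)
        blocks = ipf.BlockStructure.from_sizes([8, 12])
        f1 = ipf.fit_ipf_lasso(X, out, blocks, ipf.PenaltyFactors([1, 1]), nlambda=15)
        f2 = ipf.fit_standard_lasso(X, out, blocks=blocks, nlambda=15)
        np.testing.assert_array_equal(f1.coef_, f2.coef_)
        np.testing.assert_array_equal(f1.intercept_, f2.intercept_)

    def test_scalar_multiplied_pf_gives_identical_fit(self, rng):
        X, out = random_instance("gaussian", 25, 14, rng)
        blocks = ipf.BlockStructure.from_sizes([7, 7])
        f1 = ipf.fit_ipf_lasso(X, out, blocks, ipf.PenaltyFactors([1, 4]), nlambda=12)
        f2 = ipf.fit_ipf_lasso(X, out, blocks, ipf.PenaltyFactors([3, 12]), nlambda=12)
        np.testing.assert_array_equal(f1.coef_, f2.coef_)

    def test_rescale_design_values(self):
        X = np.full((4, 2), 2.0)
        blocks = ipf.BlockStructure.from_sizes([1, 1])
        Xr = rescale_design(X, blocks, ipf.PenaltyFactors([1, 2]))
        np.testing.assert_allclose(Xr[:, 0], 2.0)
        np.testing.assert_allclose(Xr[:, 1], 1.0)
        ones = rescale_design(X, blocks, ipf.PenaltyFactors([1, 1]))
        np.testing.assert_array_equal(ones, X)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_rescaling_route_equals_weighted_route(self, family, rng):
        """Dividing columns by their factors, fitting a uniform-penalty
        LASSO and dividing estimates back reproduces the weighted fit."""
        blocks = ipf.BlockStructure.from_sizes([8, 12])
        for _ in range(4):
            X, out = random_instance(family, 40, 20, rng)
            pf = ipf.PenaltyFactors([1.0, rng.choice([0.25, 0.5, 2.0, 4.0])])
            Xs, _ = standardize_columns(X)
            f1 = ipf.fit_ipf_lasso(Xs, out, blocks, pf, standardize=False,
                                   nlambda=15, lambda_min_ratio=0.05, tol=1e-9)
            Xr = rescale_design(Xs, blocks, pf)
            f2 = fit_weighted_lasso_path(Xr, out, np.ones(20), grid=f1.lambdas,
                                         standardize=False, tol=1e-9)
            back = f2.coef_ / pf.per_feature(blocks)
            assert np.abs(f1.coef_ - back).max() < 1e-6

    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_independent_proximal_oracle(self, family, rng):
        """Tiny instance vs a naive ISTA minimizer of the same objective."""
        n, p = 15, 8
        X, out = random_instance(family, n, p, rng)
        blocks = ipf.BlockStructure.from_sizes([4, 4])
        pf = ipf.PenaltyFactors([1.0, 4.0])
        Xs, _ = standardize_columns(X)
        pen = pf.per_feature(blocks)
        lmax = lambda_max(Xs, out, pen, standardize=False)
        lam = 0.3 * lmax
        fit = ipf.fit_ipf_lasso(Xs, out, blocks, pf, grid=np.array([lmax, lam]),
                                standardize=False, tol=1e-11)
        beta_o, b0_o = proximal_weighted_lasso(Xs, out, pen, lam)
        np.testing.assert_allclose(fit.coef_[1], beta_o, atol=1e-5)


class TestPredict:
    def test_null_binomial_model_predicts_constant_probability(self, rng):
        X, out = random_instance("binomial", 30, 6, rng)
        fit = ipf.fit_standard_lasso(X, out, nlambda=5)
        p0 = ipf.predict(fit, rng.standard_normal((7, 6)), 0)
        expected = 1 / (1 + np.exp(-fit.intercept_[0]))
        np.testing.assert_allclose(p0, expected)
        assert p0[0] == pytest.approx(out.y.mean(), abs=1e-6)

    def test_column_mismatch_raises(self, rng):
        X, out = random_instance("gaussian", 20, 6, rng)
        fit = ipf.fit_standard_lasso(X, out, nlambda=5)
        with pytest.raises(ValueError, match="columns"):
            ipf.predict(fit, np.zeros((3, 5)), 0)

    def test_breslow_baseline_matches_hand_computation(self):
        """6-subject toy, beta = 0: H0(t) = sum over event times of d / |risk set|."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        status = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        bindex = BreslowIndex(time, status)
        times, H = bindex.baseline_cumhaz(np.zeros(6))
        np.testing.assert_allclose(times, [1, 3, 4, 6])
        np.testing.assert_allclose(H, np.cumsum([1 / 6, 1 / 4, 1 / 3, 1 / 1]))

    def test_survival_curves_from_fit(self, rng):
        X, out = random_instance("cox", 25, 6, rng)
        fit = ipf.fit_standard_lasso(X, out, nlambda=8)
        S = ipf.predict_survival(fit, X, 4, [0.1, 0.5, 1.0])
        assert S.shape == (25, 3)
        assert np.all(np.diff(S, axis=1) <= 1e-12)  # nonincreasing in t
        assert np.all((S >= 0) & (S <= 1))
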