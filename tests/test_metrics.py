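"""Metric oracles: hand-counted toys, brute-force pair counting, IPCW."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ipflasso as ipf
from ipflasso.metrics import (
    BrierCurve,
    auc,
    binomial_deviance,
    brier_curve,
    cox_cvpl,
    default_eval_times,
    integrated_brier,
    misclassification_rate,
    mse,
    null_cox_loglik,
)
from ipflasso.objectives import BreslowIndex


class TestMisclassification:
    def test_perfect_and_inverted(self):
        y = np.array([1.0, 0, 1, 0])
        assert misclassification_rate(y, y) == 0.0
        assert misclassification_rate(1 - y, y) == 1.0

    def test_half_probability_classed_as_one(self):
        # (0.6 -> 1 == 1), (0.4 -> 0 != 1), (0.5 -> 1 != 0): 2 of 3 wrong
        assert misclassification_rate([0.6, 0.4, 0.5], [1, 1, 0]) == pytest.approx(2 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            misclassification_rate([], [])


def _brute_force_auc(score, y):
    """Count concordant pairs (ties half) over all case/control pairs."""
    pos = [s for s, t in zip(score, y) if t == 1]
    neg = [s for s, t in zip(score, y) if t == 0]
    tot = 0.0
    for a, b in itertools.product(pos, neg):
        tot += 1.0 if a > b else (0.5 if a == b else 0.0)
    return tot / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation_and_all_ties(self):
        assert auc([1, 2, 3, 9], [0, 0, 1, 1]) == 1.0
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_interleaved_example_vs_pair_counting(self):
        assert auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(5):
            y = rng.integers(0, 2, size=30).astype(float)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            score = rng.choice(np.arange(10) / 10, size=30)  # force ties
            assert auc(score, y) == pytest.approx(_brute_force_auc(score, y), abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=5.0))
    def test_monotone_transform_invariance(self, a):
        score = np.array([0.1, 0.4, 0.2, 0.9, 0.9, 0.3])
        y = np.array([0.0, 1, 0, 1, 0, 1])
        assert auc(np.exp(a * score), y) == pytest.approx(auc(score, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestCoxPartialLikelihood:
    def test_null_model_closed_form(self):
        """At beta = 0 the Breslow pll is -sum over events of log |risk set|."""
        time = np.array([2.0, 1.0, 3.0, 4.0, 2.5])
        status = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        # events at t=2 (risk {2,2.5,3,4}: 4), t=2.5 (3), t=3 (2)
        expected = -(np.log(4) + np.log(3) + np.log(2))
        assert null_cox_loglik(time, status) == pytest.approx(expected)

    def test_heldout_identical_to_training_gives_zero(self, rng):
        time = rng.exponential(1, 8) + 0.01
        status = np.ones(8)
        out = ipf.Outcome.cox(time, status)
        X = rng.standard_normal((8, 3))
        beta = np.array([0.5, -0.2, 0.1])
        assert cox_cvpl(beta, X, out, np.arange(8)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_enumeration_no_ties(self, rng):
        """8-subject toy: pll = sum_events [eta_i - log sum_{at risk} e^eta]."""
        time = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        status = np.array([1.0, 0, 1, 1, 0, 1, 0, 1])
        X = rng.standard_normal((8, 2))
        beta = np.array([0.7, -0.4])
        eta = X @ beta
        direct = sum(
            eta[i] - np.log(np.sum(np.exp(eta[time >= time[i]])))
            for i in range(8)
            if status[i] == 1
        )
        bindex = BreslowIndex(time, status)
        assert bindex.loglik(eta) == pytest.approx(direct, rel=1e-12)
        # Verweij-van Houwelingen difference on a real split
        out = ipf.Outcome.cox(time, status)
        train = np.array([0, 1, 2, 3, 4])
        tr = BreslowIndex(time[train], status[train])
        expected = bindex.loglik(eta) - tr.loglik(eta[train])
        assert cox_cvpl(beta, X, out, train) == pytest.approx(expected, rel=1e-12)


class TestBrier:
    def test_perfect_oracle_scores_zero(self):
        time = np.array([1.0, 2, 3, 4])
        status = np.ones(4)
        out = ipf.Outcome.cox(time, status)
        t_eval = np.array([0.5, 1.5, 2.5, 3.5])
        surv = (time[:, None] > t_eval[None, :]).astype(float)
        curve = brier_curve(surv, out, t_eval)
        np.testing.assert_allclose(curve.scores, 0.0)

    def test_no_censoring_reduces_to_squared_error(self, rng):
        time = rng.exponential(1, 40) + 0.01
        out = ipf.Outcome.cox(time, np.ones(40))
        t_eval = np.array([0.3, 0.8])
        surv = rng.random((40, 2))
        curve = brier_curve(surv, out, t_eval)
        for k, t in enumerate(t_eval):
            ind = (time > t).astype(float)
            assert curve.scores[k] == pytest.approx(np.mean((ind - surv[:, k]) ** 2))

    def test_hand_computed_ipcw_toy_with_censoring(self):
        """5 subjects, one censored at t=2; evaluate at t=2.5.

        Censoring KM: only censoring 'event' at t=2 with 4 at risk, so
        G(t) = 1 for t < 2 and 3/4 for t >= 2.  At t=2.5: subjects with
        events at 1 and 2.5... weights: event before t -> 1/G(T-);
        survivors -> 1/G(2.5); the censored subject -> 0.
        """
        time = np.array([1.0, 2.0, 2.5, 3.0, 4.0])
        status = np.array([1.0, 0.0, 1.0, 1.0, 1.0])
        out = ipf.Outcome.cox(time, status)
        surv = np.array([[0.4], [0.5], [0.6], [0.7], [0.8]])
        t = np.array([2.5])
        curve = brier_curve(surv, out, t)
        # G(1-) = 1; G(2.5) = 3/4; subject 3 (t=2.5, event): G(2.5-) = 3/4
        w = np.array([1.0, 0.0, 1 / (3 / 4), 1 / (3 / 4), 1 / (3 / 4)])
        ind = np.array([0.0, 0.0, 0.0, 1.0, 1.0])
        expected = np.sum(w * (ind - surv[:, 0]) ** 2) / 5
        assert curve.scores[0] == pytest.approx(expected, rel=1e-12)

    def test_weight_sum_equals_n_without_censoring_before_t(self, rng):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        status = np.array([1.0, 1.0, 1.0, 0.0, 1.0])  # censoring after t=2.5
        out = ipf.Outcome.cox(time, status)
        curve = brier_curve(np.full((5, 1), 0.5), out, np.array([2.5]))
        # all subjects weighted 1 (G == 1 up to 2.5): BS = mean squared error
        ind = (time > 2.5).astype(float)
        assert curve.scores[0] == pytest.approx(np.mean((ind - 0.5) ** 2))

    def test_cross_check_against_scikit_survival(self, rng):
        from sksurv.metrics import brier_score as sks_brier
        from sksurv.util import Surv

        time = rng.exponential(2, 60) + 0.01
        cens = rng.exponential(4, 60) + 0.01
        obs = np.minimum(time, cens)
        status = (time <= cens).astype(float)
        out = ipf.Outcome.cox(obs, status)
        t_eval = np.quantile(obs, [0.2, 0.4, 0.6])
        surv = np.clip(rng.random((60, 3)), 0.01, 0.99)
        curve = brier_curve(surv, out, t_eval)
        y = Surv.from_arrays(status.astype(bool), obs)
        _, expected = sks_brier(y, y, surv, t_eval)
        np.testing.assert_allclose(curve.scores, expected, atol=1e-10)


class TestIntegratedBrier:
    def test_constant_curve_integrates_to_itself(self):
        curve = BrierCurve(np.array([1.0, 2.0, 4.0]), np.full(3, 0.2), 4.0)
        # curve starts at BS(0)=0, so the initial segment is a ramp
        t = np.array([0, 1, 2, 4.0]); s = np.array([0, 0.2, 0.2, 0.2])
        assert integrated_brier(curve) == pytest.approx(np.trapezoid(s, t) / 4)

    def test_linear_curve(self):
        t = np.linspace(0.01, 5, 200)
        curve = BrierCurve(t, 0.2 * t / 5, 5.0)
        assert integrated_brier(curve) == pytest.approx(0.1, abs=1e-3)

    def test_km_null_model_matches_fine_grid_integration(self, rng):
        """IBS of the marginal KM survival prediction on exponential data,
        dense-grid numeric integration as the oracle."""
        n = 200
        time = rng.exponential(1, n) + 1e-4
        out = ipf.Outcome.cox(time, np.ones(n))
        # KM on uncensored data = empirical survival function
        ts = np.sort(time)
        km = 1.0 - np.searchsorted(ts, ts, side="right") / n
        horizon = float(np.quantile(time, 0.9))
        t_eval = default_eval_times(out, horizon)
        surv = np.tile(
            1.0 - np.searchsorted(ts, t_eval, side="right") / n, (n, 1)
        )
        curve = brier_curve(surv, out, t_eval)
        fine = np.linspace(1e-6, horizon, 5000)
        surv_f = np.tile(1.0 - np.searchsorted(ts, fine, side="right") / n, (n, 1))
        bs_f = np.mean(((time[:, None] > fine[None, :]) - surv_f) ** 2, axis=0)
        oracle = np.trapezoid(np.concatenate([[0], bs_f]), np.concatenate([[0], fine])) / horizon
        assert integrated_brier(curve) == pytest.approx(oracle, abs=1e-3)


def test_mse_and_deviance_basics():
    assert mse([1.0, 2.0], [0.0, 4.0]) == pytest.approx(2.5)
    assert binomial_deviance([0.5, 0.5], [1, 0]) == pytest.approx(-2 * np.log(0.5))
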