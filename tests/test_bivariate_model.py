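"""Unit and property tests for the bivariate odds-ratio model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvrs2 import (
    FULL_SPEC,
    REDUCED_SPEC,
    BivariateCoefficients,
    InputError,
    fit_bivariate_model,
    fit_bivariate_models,
    joint_cell_probs,
    neg_log_likelihood,
)
from cvrs2.bivariate_model import fit_logistic_models

from conftest import bisect_p11, draw_bivariate_outcomes, model_probs


class TestJointCellProbs:
    @pytest.mark.parametrize("p1,p2", [(0.5, 0.5), (0.6, 0.3), (0.05, 0.95)])
    def test_independence_at_psi_one(self, p1, p2):
        p11, p10, p01, p00 = joint_cell_probs(p1, p2, 1.0)
        assert p11 == pytest.approx(p1 * p2, abs=1e-12)
        assert p00 == pytest.approx((1 - p1) * (1 - p2), abs=1e-12)

    def test_matches_bisection_oracle(self):
        for p1, p2, psi in [(0.6, 0.3, 2.0), (0.2, 0.8, 0.3), (0.45, 0.55, 7.0)]:
            p11 = joint_cell_probs(p1, p2, psi)[0]
            assert p11 == pytest.approx(bisect_p11(p1, p2, psi), abs=1e-9)
        assert joint_cell_probs(0.6, 0.3, 2.0)[0] == pytest.approx(0.2135, abs=5e-4)

    def test_margins_and_odds_ratio_identity_on_grid(self):
        grid = np.arange(0.05, 0.96, 0.1)
        for psi in (0.1, 0.5, 1.0, 2.0, 10.0):
            p1, p2 = np.meshgrid(grid, grid)
            p11, p10, p01, p00 = joint_cell_probs(p1, p2, psi)
            for cell in (p11, p10, p01, p00):
                assert np.all(cell >= -1e-12) and np.all(cell <= 1 + 1e-12)
            np.testing.assert_allclose(p11 + p10, p1, atol=1e-10)
            np.testing.assert_allclose(p11 + p01, p2, atol=1e-10)
            np.testing.assert_allclose(p11 + p10 + p01 + p00, 1.0, atol=1e-10)
            np.testing.assert_allclose((p11 * p00) / (p10 * p01), psi, rtol=1e-9)

    def test_continuity_at_psi_one(self):
        for p1, p2 in [(0.3, 0.7), (0.5, 0.5), (0.9, 0.2)]:
            base = joint_cell_probs(p1, p2, 1.0)
            for psi in (1 - 1e-8, 1 + 1e-8):
                cells = joint_cell_probs(p1, p2, psi)
                assert max(abs(a - b) for a, b in zip(cells, base)) < 1e-6

    @pytest.mark.parametrize("bad", [(0.0, 0.5, 1.0), (0.5, 1.0, 1.0),
                                     (0.5, 0.5, -1.0), (np.nan, 0.5, 1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises((InputError, ValueError)):
            joint_cell_probs(*bad)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(p1=st.floats(0.02, 0.98), p2=st.floats(0.02, 0.98),
           log_psi=st.floats(-3.0, 3.0))
    def test_identity_property(self, p1, p2, log_psi):
        psi = float(np.exp(log_psi))
        p11, p10, p01, p00 = joint_cell_probs(p1, p2, psi)
        assert (p11 * p00) / (p10 * p01) == pytest.approx(psi, rel=1e-8)
        assert p11 + p10 == pytest.approx(p1, abs=1e-10)


class TestNegLogLikelihood:
    def test_zero_coefficients_give_uniform_cells(self, rng):
        n = 40
        t = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        y1, y2 = rng.integers(0, 2, (2, n))
        val = neg_log_likelihood(BivariateCoefficients(), t, x, y1, y2, FULL_SPEC)
        assert val == pytest.approx(n * np.log(4.0), rel=1e-12)

    def test_factorizes_at_psi_one(self, rng):
        n = 50
        t = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        y1, y2 = rng.integers(0, 2, (2, n))
        co = BivariateCoefficients(mu1=0.3, mu2=-0.6, lambda1=0.2, lambda2=-0.1,
                                   alpha1=0.5, alpha2=0.4, beta1=-0.7, beta2=0.9)
        joint = neg_log_likelihood(co, t, x, y1, y2, FULL_SPEC)

        def bern_nll(y, eta):
            return float(np.sum(np.logaddexp(0, eta) - y * eta))

        eta1 = co.mu1 + co.lambda1 * t + co.alpha1 * x + co.beta1 * t * x
        eta2 = co.mu2 + co.lambda2 * t + co.alpha2 * x + co.beta2 * t * x
        assert joint == pytest.approx(bern_nll(y1, eta1) + bern_nll(y2, eta2), rel=1e-10)

    def test_matches_hand_enumeration_on_toy_data(self):
        # eight patients, coefficients fixed; expected value computed by
        # enumerating each patient's cell probability with the bisection oracle
        t = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x = np.array([-1.0, 0.5, 1.5, -0.2, 0.8, -1.1, 0.3, 2.0])
        y1 = np.array([0, 1, 1, 0, 1, 0, 1, 1])
        y2 = np.array([1, 1, 0, 0, 1, 0, 0, 1])
        co = BivariateCoefficients(mu1=-0.4, mu2=0.2, lambda1=0.3, lambda2=-0.2,
                                   alpha1=0.6, alpha2=-0.5, beta1=1.1, beta2=0.7,
                                   log_psi=0.9)
        p1, p2 = model_probs(co, t, x)
        expected = 0.0
        for i in range(8):
            c11 = bisect_p11(p1[i], p2[i], np.exp(co.log_psi))
            cells = {(1, 1): c11, (1, 0): p1[i] - c11,
                     (0, 1): p2[i] - c11, (0, 0): 1 - p1[i] - p2[i] + c11}
            expected -= np.log(cells[(y1[i], y2[i])])
        got = neg_log_likelihood(co, t, x, y1, y2, FULL_SPEC)
        assert got == pytest.approx(expected, rel=1e-8)


def _simulate_from_model(rng, coeffs, n, psi=None):
    t = rng.integers(0, 2, n)
    x = rng.normal(size=n)
    p1, p2 = model_probs(coeffs, t, x)
    psi = coeffs.psi if psi is None else psi
    y1, y2 = draw_bivariate_outcomes(rng, p1, p2, psi)
    return t, x, y1, y2


class TestFitBivariateModel:
    def test_recovers_truth_within_three_se(self, rng):
        truth = BivariateCoefficients(mu1=-0.8, mu2=-0.3, beta1=0.9, beta2=-0.5,
                                      log_psi=0.8)
        t, x, y1, y2 = _simulate_from_model(rng, truth, 5000)
        fit = fit_bivariate_model(t, x, y1, y2, spec=REDUCED_SPEC)
        assert fit.converged
        assert fit.loglik <= 0.0
        for name, true_val in [("beta1", truth.beta1), ("beta2", truth.beta2),
                               ("log_psi", truth.log_psi)]:
            est = getattr(fit.coefficients, name)
            assert abs(est - true_val) < 3.0 * fit.se[name], name

    def test_fixed_psi_zero_reproduces_univariate_logistic(self, rng):
        n = 400
        t = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * t * x)))
        y1 = (rng.random(n) < p).astype(int)
        y2 = rng.integers(0, 2, n)        # independent of everything
        fit = fit_bivariate_model(t, x, y1, y2, spec=REDUCED_SPEC, fix_log_psi=0.0)
        theta, conv, _ = fit_logistic_models(t, x, y1, spec=REDUCED_SPEC)
        assert conv[0]
        assert fit.coefficients.mu1 == pytest.approx(theta[0, 0], abs=1e-4)
        assert fit.coefficients.beta1 == pytest.approx(theta[0, 1], abs=1e-4)

    def test_duplicated_data_same_estimate_double_loglik(self, rng):
        truth = BivariateCoefficients(mu1=-0.5, mu2=0.2, beta1=0.6, beta2=0.3,
                                      log_psi=0.5)
        t, x, y1, y2 = _simulate_from_model(rng, truth, 300)
        fit1 = fit_bivariate_model(t, x, y1, y2, spec=REDUCED_SPEC)
        fit2 = fit_bivariate_model(np.tile(t, 2), np.tile(x, 2),
                                   np.tile(y1, 2), np.tile(y2, 2), spec=REDUCED_SPEC)
        np.testing.assert_allclose(fit2.coefficients.pack(REDUCED_SPEC),
                                   fit1.coefficients.pack(REDUCED_SPEC), atol=2e-3)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-3)

    def test_order_and_outcome_swap_invariance(self, rng):
        truth = BivariateCoefficients(mu1=-0.6, mu2=0.1, beta1=0.7, beta2=-0.4,
                                      log_psi=0.6)
        t, x, y1, y2 = _simulate_from_model(rng, truth, 500)
        fit = fit_bivariate_model(t, x, y1, y2, spec=REDUCED_SPEC)
        perm = rng.permutation(t.size)
        fit_perm = fit_bivariate_model(t[perm], x[perm], y1[perm], y2[perm],
                                       spec=REDUCED_SPEC)
        np.testing.assert_allclose(fit_perm.coefficients.pack(REDUCED_SPEC),
                                   fit.coefficients.pack(REDUCED_SPEC), atol=1e-5)
        fit_swap = fit_bivariate_model(t, x, y2, y1, spec=REDUCED_SPEC)
        assert fit_swap.coefficients.mu1 == pytest.approx(fit.coefficients.mu2, abs=1e-5)
        assert fit_swap.coefficients.beta1 == pytest.approx(fit.coefficients.beta2, abs=1e-5)
        assert fit_swap.coefficients.log_psi == pytest.approx(fit.coefficients.log_psi, abs=1e-5)

    def test_input_errors(self, rng):
        with pytest.raises(InputError):
            fit_bivariate_model([], [], [], [])
        n = 20
        x = rng.normal(size=n)
        y = rng.integers(0, 2, n)
        with pytest.raises(InputError):
            fit_bivariate_model(np.ones(n), x, y, y)   # single arm

    def test_batch_agrees_with_reference_fit(self, rng):
        truth = BivariateCoefficients(mu1=-0.7, mu2=-0.2, beta1=0.8, beta2=0.5,
                                      log_psi=0.7)
        t, x, y1, y2 = _simulate_from_model(rng, truth, 1500)
        single = fit_bivariate_model(t, x, y1, y2, spec=REDUCED_SPEC)
        batch = fit_bivariate_models(t, x[:, None], y1, y2, spec=REDUCED_SPEC)
        assert batch.converged[0]
        got = np.concatenate([batch.theta1[0], batch.theta2[0], [batch.log_psi[0]]])
        np.testing.assert_allclose(got, single.coefficients.pack(REDUCED_SPEC),
                                   atol=2e-4)
        assert -batch.nll[0] == pytest.approx(single.loglik, abs=1e-6)


class TestParameterRecoveryBias:
    """Mean bias of the batched fitter over repeated simulated fits is
    within Monte-Carlo error of zero, for both model variants."""

    @pytest.mark.parametrize("spec,truth", [
        (REDUCED_SPEC, BivariateCoefficients(mu1=-0.6, mu2=-0.2, beta1=0.5,
                                             beta2=-0.4, log_psi=0.6)),
        (FULL_SPEC, BivariateCoefficients(mu1=-0.4, mu2=-0.1, lambda1=0.3,
                                          lambda2=-0.2, alpha1=0.2, alpha2=0.1,
                                          beta1=0.5, beta2=-0.3, log_psi=0.5)),
    ])
    def test_unbiased(self, spec, truth, rng):
        n_fits, n = 60, 800
        errs = []
        for _ in range(n_fits):
            t = rng.integers(0, 2, n)
            x = rng.normal(size=n)
            p1, p2 = model_probs(truth, t, x)
            # vectorized joint draw via the package-independent construction:
            # conditional P(y2=1|y1) derived from bisection-oracle cells
            from conftest import bisect_p11
            y1 = np.empty(n, int)
            y2 = np.empty(n, int)
            for i in range(n):
                c11 = bisect_p11(p1[i], p2[i], truth.psi)
                u = rng.random()
                if u < c11:
                    y1[i], y2[i] = 1, 1
                elif u < p1[i]:
                    y1[i], y2[i] = 1, 0
                elif u < p1[i] + p2[i] - c11:
                    y1[i], y2[i] = 0, 1
                else:
                    y1[i], y2[i] = 0, 0
            fit = fit_bivariate_models(t, x[:, None], y1, y2, spec=spec)
            if fit.converged[0]:
                est = np.concatenate([fit.theta1[0], fit.theta2[0], [fit.log_psi[0]]])
                errs.append(est - truth.pack(spec))
        errs = np.asarray(errs)
        assert errs.shape[0] >= 0.9 * n_fits
        bias = errs.mean(axis=0)
        se = errs.std(axis=0, ddof=1) / np.sqrt(errs.shape[0])
        assert np.all(np.abs(bias) < 4.0 * se + 0.02)
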