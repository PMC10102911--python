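"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from cvrs2 import BivariateCoefficients, TrialDataset
from cvrs2.bivariate_model import BivariateModelSpec


def bisect_p11(p1, p2, psi, tol=1e-12):
    """Independent Plackett-cell oracle: solve the odds-ratio identity
    (p11*p00)/(p10*p01) = psi by bisection on p11."""
    lo = max(0.0, p1 + p2 - 1.0) + 1e-14
    hi = min(p1, p2) - 1e-14

    def f(p11):
        return p11 * (1 - p1 - p2 + p11) - psi * (p1 - p11) * (p2 - p11)

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def draw_bivariate_outcomes(rng, p1, p2, psi):
    """Sample (y1, y2) from the joint cell distribution (via the bisection
    oracle, independent of the package's own cell solver)."""
    n = p1.size
    y1 = np.empty(n, dtype=int)
    y2 = np.empty(n, dtype=int)
    for i in range(n):
        c11 = bisect_p11(p1[i], p2[i], psi) if psi != 1.0 else p1[i] * p2[i]
        cells = np.array([c11, p1[i] - c11, p2[i] - c11, 1 - p1[i] - p2[i] + c11])
        pick = rng.choice(4, p=cells / cells.sum())
        y1[i] = 1 if pick in (0, 1) else 0
        y2[i] = 1 if pick in (0, 2) else 0
    return y1, y2


def model_probs(coeffs: BivariateCoefficients, t, x):
    """Marginal response probabilities under the bivariate model."""
    from scipy.special import expit

    eta1 = coeffs.mu1 + coeffs.lambda1 * t + coeffs.alpha1 * x + coeffs.beta1 * t * x
    eta2 = coeffs.mu2 + coeffs.lambda2 * t + coeffs.alpha2 * x + coeffs.beta2 * t * x
    return expit(eta1), expit(eta2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_dataset(rng):
    """Small null dataset: outcomes independent of covariates and arm."""
    n, p = 60, 4
    return TrialDataset(
        covariates=rng.normal(size=(n, p)),
        treatment=np.tile([0, 1], n // 2),
        y1=rng.integers(0, 2, n),
        y2=rng.integers(0, 2, n),
    )
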