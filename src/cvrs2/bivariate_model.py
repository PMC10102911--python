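"""Bivariate odds-ratio (Plackett) model for two correlated binary outcomes.

Two binary endpoints ``Y1`` and ``Y2`` are modelled jointly through their
marginal logistic regressions plus a constant (intercept-only) odds ratio
``psi`` linking them::

    logit P(Y1 = 1) = mu1 + lambda1*t + alpha1*x + beta1*t*x
    logit P(Y2 = 1) = mu2 + lambda2*t + alpha2*x + beta2*t*x
    log  psi        = log_psi                      (constant association)

``psi`` is the ratio of the odds of ``Y1 = 1`` when ``Y2 = 1`` to the odds
of ``Y1 = 1`` when ``Y2 = 0``; ``psi = 1`` if and only if the outcomes are
independent, in which case the joint likelihood factorizes into the two
univariate Bernoulli-logistic likelihoods.

The joint cell probabilities given the two margins and ``psi`` are the
Plackett solution: the root of the quadratic in ``p11`` implied by the
odds-ratio identity ``(p11*p00)/(p10*p01) = psi``.

Two fitting routes are provided:

* :func:`fit_bivariate_model` — one covariate, exact likelihood maximized
  with L-BFGS-B and an analytic gradient (the reference path).
* :func:`fit_bivariate_models` — the same likelihood fitted for many
  covariates at once with a damped Fisher-scoring iteration whose curvature
  is the empirical Fisher information; everything is vectorized across
  covariates, which is what makes the cross-validated scoring pipeline
  affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from ._exceptions import InputError

__all__ = [
    "BivariateModelSpec",
    "BivariateCoefficients",
    "BivariateFit",
    "BatchBivariateFit",
    "FULL_SPEC",
    "REDUCED_SPEC",
    "joint_cell_probs",
    "neg_log_likelihood",
    "fit_bivariate_model",
    "fit_bivariate_models",
    "fit_logistic_models",
]

CELL_FLOOR = 1e-12
LOG_PSI_BOUND = 10.0
_ETA_CLIP = 30.0


@dataclass(frozen=True)
class BivariateModelSpec:
    """Which fixed-effect terms enter the two marginal linear predictors.

    Intercepts and the treatment-by-covariate interactions are always
    present; the association ``log psi`` is always intercept-only.  The two
    variants in actual use are the full model (both main effects, used for
    observed trial data) and the reduced model (no main effects, matching
    the simulation's data-generating mechanism).
    """

    include_treatment_main: bool = True
    include_covariate_main: bool = True

    @property
    def n_margin_params(self) -> int:
        return 2 + int(self.include_treatment_main) + int(self.include_covariate_main)

    @property
    def n_params(self) -> int:
        return 2 * self.n_margin_params + 1

    @property
    def margin_terms(self) -> tuple[str, ...]:
        terms = ["intercept"]
        if self.include_treatment_main:
            terms.append("treatment")
        if self.include_covariate_main:
            terms.append("covariate")
        terms.append("interaction")
        return tuple(terms)


FULL_SPEC = BivariateModelSpec(True, True)
REDUCED_SPEC = BivariateModelSpec(False, False)


@dataclass
class BivariateCoefficients:
    """Coefficients on the logit scale; excluded terms are fixed at zero."""

    mu1: float = 0.0
    mu2: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    alpha1: float = 0.0
    alpha2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    log_psi: float = 0.0

    @property
    def psi(self) -> float:
        return float(np.exp(self.log_psi))

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in (
            "mu1", "mu2", "lambda1", "lambda2", "alpha1", "alpha2",
            "beta1", "beta2", "log_psi")}

    def pack(self, spec: BivariateModelSpec) -> np.ndarray:
        """Flatten to the free-parameter vector [theta1, theta2, log_psi]."""
        out = []
        for margin in (1, 2):
            out.append(getattr(self, f"mu{margin}"))
            if spec.include_treatment_main:
                out.append(getattr(self, f"lambda{margin}"))
            if spec.include_covariate_main:
                out.append(getattr(self, f"alpha{margin}"))
            out.append(getattr(self, f"beta{margin}"))
        out.append(self.log_psi)
        return np.asarray(out, dtype=float)

    @classmethod
    def unpack(cls, params: np.ndarray, spec: BivariateModelSpec) -> "BivariateCoefficients":
        params = np.asarray(params, dtype=float)
        if params.shape != (spec.n_params,):
            raise InputError(
                f"expected {spec.n_params} parameters for this model spec, got {params.shape}")
        out = cls()
        i = 0
        for margin in (1, 2):
            setattr(out, f"mu{margin}", float(params[i]))
            i += 1
            if spec.include_treatment_main:
                setattr(out, f"lambda{margin}", float(params[i]))
                i += 1
            if spec.include_covariate_main:
                setattr(out, f"alpha{margin}", float(params[i]))
                i += 1
            setattr(out, f"beta{margin}", float(params[i]))
            i += 1
        out.log_psi = float(params[i])
        return out


@dataclass
class BivariateFit:
    """Result of a single-covariate maximum-likelihood fit."""

    coefficients: BivariateCoefficients
    loglik: float
    converged: bool
    n_obs: int
    se: dict[str, float] | None = None


@dataclass
class BatchBivariateFit:
    """Per-covariate results of the vectorized fit (arrays of length P)."""

    theta1: np.ndarray          # (P, m) margin-1 coefficients
    theta2: np.ndarray          # (P, m) margin-2 coefficients
    log_psi: np.ndarray         # (P,)
    nll: np.ndarray             # (P,)
    converged: np.ndarray       # (P,) bool
    spec: BivariateModelSpec
    n_obs: int
    n_iter: int = 0

    @property
    def beta1(self) -> np.ndarray:
        return self.theta1[:, -1]

    @property
    def beta2(self) -> np.ndarray:
        return self.theta2[:, -1]


# ---------------------------------------------------------------------------
# Plackett cell probabilities
# ---------------------------------------------------------------------------

def _p11(p1, p2, psi):
    """Stable Plackett root.

    Written as 2*psi*p1*p2 / (S + sqrt(S^2 - 4*psi*(psi-1)*p1*p2)) which is
    the same root as (S - sqrt(...)) / (2*(psi-1)) but free of cancellation
    and continuous through psi = 1 (where it reduces to p1*p2).
    """
    S = 1.0 + (p1 + p2) * (psi - 1.0)
    disc = S * S - 4.0 * psi * (psi - 1.0) * p1 * p2
    disc = np.maximum(disc, 0.0)
    return 2.0 * psi * p1 * p2 / (S + np.sqrt(disc))


def joint_cell_probs(p1, p2, psi):
    """Joint cell probabilities (p11, p10, p01, p00) for the Plackett model.

    Parameters are the two marginal success probabilities and the odds
    ratio ``psi > 0``.  The cells satisfy the margin constraints and the
    odds-ratio identity exactly (to rounding).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2)) and np.all(np.isfinite(psi))):
        raise InputError("joint_cell_probs: inputs must be finite")
    if np.any(p1 <= 0) or np.any(p1 >= 1) or np.any(p2 <= 0) or np.any(p2 >= 1):
        raise InputError("joint_cell_probs: marginal probabilities must lie strictly in (0, 1)")
    if np.any(psi <= 0):
        raise InputError("joint_cell_probs: psi must be positive")
    S = 1.0 + (p1 + p2) * (psi - 1.0)
    disc = S * S - 4.0 * psi * (psi - 1.0) * p1 * p2
    if np.any(disc < -1e-8):
        raise FloatingPointError("joint_cell_probs: negative discriminant")
    p11 = _p11(p1, p2, psi)
    return p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11


# ---------------------------------------------------------------------------
# likelihood core (vectorized over patients x covariates)
# ---------------------------------------------------------------------------

def _expit(eta):
    out = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    special.expit(out, out=out)
    np.clip(out, 1e-12, 1.0 - 1e-12, out=out)
    return out


def build_design(t: np.ndarray, X: np.ndarray, spec: BivariateModelSpec) -> np.ndarray:
    """Stack the per-covariate marginal design matrices into (n, P, m)."""
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, P = X.shape
    tcol = np.broadcast_to(t[:, None], (n, P))
    cols = [np.ones((n, P))]
    if spec.include_treatment_main:
        cols.append(tcol)
    if spec.include_covariate_main:
        cols.append(X)
    cols.append(tcol * X)
    return np.stack(cols, axis=-1)


def _cell_scores(p1, p2, psi, y1c, y2c, want_grad):
    """Shared likelihood kernel: observed-cell probability ``q`` and, when
    requested, the per-patient scores (a, b, c) of the log-likelihood with
    respect to (eta1, eta2, log psi)."""
    S = 1.0 + (p1 + p2) * (psi - 1.0)
    disc = np.maximum(S * S - 4.0 * psi * (psi - 1.0) * p1 * p2, 1e-300)
    Droot = np.sqrt(disc)
    p11 = 2.0 * psi * p1 * p2 / (S + Droot)

    q = (y1c * y2c * p11
         + y1c * (1 - y2c) * (p1 - p11)
         + (1 - y1c) * y2c * (p2 - p11)
         + (1 - y1c) * (1 - y2c) * (1.0 - p1 - p2 + p11))
    q = np.maximum(q, CELL_FLOOR)
    if not want_grad:
        return q, None

    sgn11 = np.where(y1c == y2c, 1.0, -1.0)          # d q / d p11
    dq_dp1 = y1c * (1 - y2c) - (1 - y1c) * (1 - y2c)
    dq_dp2 = (1 - y1c) * y2c - (1 - y1c) * (1 - y2c)

    dp11_dp1 = 0.5 * (1.0 - (S - 2.0 * psi * p2) / Droot)
    dp11_dp2 = 0.5 * (1.0 - (S - 2.0 * psi * p1) / Droot)
    dpsi_den = 1.0 - p1 - p2 + 2.0 * p11 + psi * (p1 + p2 - 2.0 * p11)
    dp11_dpsi = (p1 - p11) * (p2 - p11) / np.maximum(dpsi_den, 1e-12)

    a = (dq_dp1 + sgn11 * dp11_dp1) * p1 * (1.0 - p1) / q
    b = (dq_dp2 + sgn11 * dp11_dp2) * p2 * (1.0 - p2) / q
    c = sgn11 * dp11_dpsi * psi / q
    return q, (a, b, c)


def _nll_core(theta1, theta2, lpsi, Dm, y1, y2, want_grad=False, want_fisher=False):
    """Negative log-likelihood per covariate; optionally gradient and
    empirical Fisher information.

    theta1, theta2: (P, m); lpsi: (P,); Dm: (n, P, m); y1, y2: (n,) in {0,1}.
    A fast path handles the reduced two-term design [1, t*x] without the
    stacked einsum contractions.
    """
    m = theta1.shape[1]
    fast = m == 2
    if fast:
        U = Dm[:, :, 1]
        eta1 = theta1[:, 0][None, :] + U * theta1[:, 1][None, :]
        eta2 = theta2[:, 0][None, :] + U * theta2[:, 1][None, :]
    else:
        eta1 = np.einsum("npm,pm->np", Dm, theta1)
        eta2 = np.einsum("npm,pm->np", Dm, theta2)
    p1 = _expit(eta1)
    p2 = _expit(eta2)
    psi = np.exp(np.clip(lpsi, -LOG_PSI_BOUND, LOG_PSI_BOUND))[None, :]
    y1c = y1[:, None]
    y2c = y2[:, None]
    q, scores = _cell_scores(p1, p2, psi, y1c, y2c, want_grad or want_fisher)
    nll = -np.sum(np.log(q), axis=0)
    if scores is None:
        return nll
    a, b, c = scores

    if fast:
        aU = a * U
        bU = b * U
        grad_nll = -np.stack([a.sum(0), aU.sum(0), b.sum(0), bU.sum(0),
                              c.sum(0)], axis=1)
    else:
        g1 = np.einsum("np,npm->pm", a, Dm)
        g2 = np.einsum("np,npm->pm", b, Dm)
        grad_nll = -np.concatenate([g1, g2, c.sum(0)[:, None]], axis=1)
    if not want_fisher:
        return nll, grad_nll

    P = theta1.shape[0]
    npar = 2 * m + 1
    F = np.empty((P, npar, npar))
    if fast:
        # empirical Fisher from products of the scores with 1, U, U^2
        def sym(u, v):
            return np.sum(u * v, axis=0)
        F[:, 0, 0] = sym(a, a)
        F[:, 0, 1] = F[:, 1, 0] = sym(a, aU)
        F[:, 1, 1] = sym(aU, aU)
        F[:, 0, 2] = F[:, 2, 0] = sym(a, b)
        F[:, 0, 3] = F[:, 3, 0] = sym(a, bU)
        F[:, 1, 2] = F[:, 2, 1] = sym(aU, b)
        F[:, 1, 3] = F[:, 3, 1] = sym(aU, bU)
        F[:, 2, 2] = sym(b, b)
        F[:, 2, 3] = F[:, 3, 2] = sym(b, bU)
        F[:, 3, 3] = sym(bU, bU)
        F[:, 0, 4] = F[:, 4, 0] = sym(a, c)
        F[:, 1, 4] = F[:, 4, 1] = sym(aU, c)
        F[:, 2, 4] = F[:, 4, 2] = sym(b, c)
        F[:, 3, 4] = F[:, 4, 3] = sym(bU, c)
        F[:, 4, 4] = sym(c, c)
        return nll, grad_nll, F
    F11 = np.einsum("np,npi,npj->pij", a * a, Dm, Dm)
    F12 = np.einsum("np,npi,npj->pij", a * b, Dm, Dm)
    F22 = np.einsum("np,npi,npj->pij", b * b, Dm, Dm)
    F1p = np.einsum("np,npi->pi", a * c, Dm)
    F2p = np.einsum("np,npi->pi", b * c, Dm)
    Fpp = np.sum(c * c, axis=0)
    F[:, :m, :m] = F11
    F[:, :m, m:2 * m] = F12
    F[:, m:2 * m, :m] = np.swapaxes(F12, 1, 2)
    F[:, m:2 * m, m:2 * m] = F22
    F[:, :m, -1] = F1p
    F[:, -1, :m] = F1p
    F[:, m:2 * m, -1] = F2p
    F[:, -1, m:2 * m] = F2p
    F[:, -1, -1] = Fpp
    return nll, grad_nll, F


def _split_params(params: np.ndarray, m: int):
    """(P, 2m+1) -> theta1 (P,m), theta2 (P,m), lpsi (P,)."""
    return params[:, :m], params[:, m:2 * m], params[:, -1]


# ---------------------------------------------------------------------------
# public likelihood
# ---------------------------------------------------------------------------

def neg_log_likelihood(coeffs: BivariateCoefficients, t, x, y1, y2,
                       spec: BivariateModelSpec = FULL_SPEC) -> float:
    """Exact negative log-likelihood of the bivariate odds-ratio model.

    Returns ``+inf`` (not an exception) if an observed outcome pattern has
    joint probability zero under the supplied coefficients.
    """
    t, x, y1, y2 = _validate_records(t, x, y1, y2, require_both_arms=False)
    Dm = build_design(t, x, spec)
    params = coeffs.pack(spec)[None, :]
    theta1, theta2, lpsi = _split_params(params, spec.n_margin_params)
    # detect exact-zero cells before flooring
    eta1 = Dm[:, 0, :] @ theta1[0]
    eta2 = Dm[:, 0, :] @ theta2[0]
    p1 = special.expit(np.clip(eta1, -700, 700))
    p2 = special.expit(np.clip(eta2, -700, 700))
    with np.errstate(all="ignore"):
        inner = np.clip(p1, 1e-300, 1 - 1e-16), np.clip(p2, 1e-300, 1 - 1e-16)
        p11 = _p11(inner[0], inner[1], np.exp(coeffs.log_psi))
        cell = (y1 * y2 * p11 + y1 * (1 - y2) * (inner[0] - p11)
                + (1 - y1) * y2 * (inner[1] - p11)
                + (1 - y1) * (1 - y2) * (1 - inner[0] - inner[1] + p11))
    if np.any(cell <= 0.0):
        return float("inf")
    nll = _nll_core(theta1, theta2, lpsi, Dm, y1, y2)
    return float(nll[0])


def _validate_records(t, x, y1, y2, require_both_arms=True):
    t = np.asarray(t, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    n = t.size
    if n == 0:
        raise InputError("empty data")
    if not (y1.size == n and y2.size == n and x.shape[0] == n):
        raise InputError("t, x, y1, y2 must have matching lengths")
    for name, arr in (("t", t), ("y1", y1), ("y2", y2)):
        if not np.all(np.isin(arr, (0.0, 1.0))):
            raise InputError(f"{name} must be binary 0/1")
    if require_both_arms and (t.min() == t.max()):
        raise InputError("data must contain both treatment arms")
    return t, x, y1, y2


# ---------------------------------------------------------------------------
# univariate logistic fits (starting values, CVRS scores, prefiltering)
# ---------------------------------------------------------------------------

def fit_logistic_models(t, X, y, spec: BivariateModelSpec = FULL_SPEC,
                        max_iter: int = 30, gtol: float = 1e-8):
    """Batched per-covariate univariate logistic ML fits (Newton/IRLS).

    Returns ``(theta, converged, beta_var)`` with ``theta`` of shape
    ``(P, m)`` (interaction coefficient last), a boolean convergence flag
    per covariate and the Wald variance of the interaction coefficient.
    """
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, P = X.shape
    Dm = build_design(t, X, spec)
    m = spec.n_margin_params
    theta = np.zeros((P, m))
    eye = np.eye(m)[None, :, :]

    fast = m == 2

    def eta_of(th, D):
        if fast:
            return th[:, 0][None, :] + D[:, :, 1] * th[:, 1][None, :]
        return np.einsum("npm,pm->np", D, th)

    def nll_of(th, D):
        eta = eta_of(th, D)
        # -loglik = sum log(1+exp(eta)) - y*eta
        return np.sum(np.logaddexp(0.0, eta) - y[:, None] * eta, axis=0)

    def grad_hess(th, D):
        p = _expit(eta_of(th, D))
        resid = y[:, None] - p
        w = np.maximum(p * (1.0 - p), 1e-10)
        if fast:
            U = D[:, :, 1]
            g = np.stack([resid.sum(0), (resid * U).sum(0)], axis=1)
            H = np.empty((th.shape[0], 2, 2))
            wU = w * U
            H[:, 0, 0] = w.sum(0)
            H[:, 0, 1] = H[:, 1, 0] = wU.sum(0)
            H[:, 1, 1] = (wU * U).sum(0)
            return g, H
        g = np.einsum("np,npm->pm", resid, D)
        H = np.einsum("np,npi,npj->pij", w, D, D)
        return g, H

    nll = nll_of(theta, Dm)
    converged = np.zeros(P, dtype=bool)
    gscale = gtol * max(1, n)
    for _ in range(max_iter):
        act = np.flatnonzero(~converged)
        if act.size == 0:
            break
        Da = Dm[:, act, :]
        g, H = grad_hess(theta[act], Da)
        done = np.max(np.abs(g), axis=1) < gscale
        converged[act[done]] = True
        if done.all():
            continue
        sub = ~done
        ridge = 1e-9 * np.trace(H[sub], axis1=1, axis2=2)[:, None, None]
        step = np.linalg.solve(H[sub] + ridge * eye, g[sub, :, None])[:, :, 0]
        rows = act[sub]
        alpha = np.ones(rows.size)
        accepted = np.zeros(rows.size, dtype=bool)
        Ds = Dm[:, rows, :]
        nll_cur = nll[rows].copy()
        th_cur = theta[rows].copy()
        for _ in range(12):
            trial = th_cur + (alpha * ~accepted)[:, None] * step
            nll_t = nll_of(trial, Ds)
            better = (nll_t <= nll_cur + 1e-10) & ~accepted
            th_cur[better] = trial[better]
            nll_cur[better] = nll_t[better]
            accepted |= better
            if accepted.all():
                break
            alpha[~accepted] *= 0.5
        theta[rows] = th_cur
        nll[rows] = nll_cur
    finite = np.all(np.isfinite(theta), axis=1) & (np.max(np.abs(theta), axis=1) < 100.0)
    converged = converged & finite
    beta_var = np.full(P, np.nan)
    _, H = grad_hess(theta, Dm)
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(H + 1e-12 * np.eye(m)[None, :, :])
            beta_var = cov[:, -1, -1]
        except np.linalg.LinAlgError:
            pass
    return theta, converged, beta_var


# ---------------------------------------------------------------------------
# batched bivariate fit (Fisher scoring)
# ---------------------------------------------------------------------------

def fit_bivariate_models(t, X, y1, y2, spec: BivariateModelSpec = REDUCED_SPEC,
                         max_iter: int = 150, gtol: float = 1e-6,
                         fix_log_psi: float | None = None) -> BatchBivariateFit:
    """Fit the single-covariate bivariate odds-ratio model for every column
    of ``X`` simultaneously.

    Starting values are the per-margin univariate logistic MLEs with
    ``log_psi = 0`` (the exact MLE of the factorized ``psi = 1`` model);
    iterations are damped Fisher-scoring steps using the empirical Fisher
    information as curvature.  ``log_psi`` is box-bounded to ±10; a
    covariate whose iteration fails, diverges, or ends on the bound is
    flagged not converged (callers then drop its contribution).
    """
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n, P = X.shape
    if n == 0:
        raise InputError("empty data")
    if t.min() == t.max():
        raise InputError("data must contain both treatment arms")
    m = spec.n_margin_params
    npar = 2 * m + 1
    Dm = build_design(t, X, spec)

    th1, ok1, _ = fit_logistic_models(t, X, y1, spec)
    th2, ok2, _ = fit_logistic_models(t, X, y2, spec)
    params = np.concatenate(
        [th1, th2, np.zeros((P, 1)) if fix_log_psi is None
         else np.full((P, 1), fix_log_psi)], axis=1)

    free = np.arange(npar) if fix_log_psi is None else np.arange(npar - 1)
    eye = np.eye(free.size)[None, :, :]
    gscale = gtol * max(1.0, float(n))

    theta1, theta2, lpsi = _split_params(params, m)
    nll = _nll_core(theta1, theta2, lpsi, Dm, y1, y2)
    converged = np.zeros(P, dtype=bool)
    stalled = np.zeros(P, dtype=bool)
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        act = np.flatnonzero(~(converged | stalled))
        if act.size == 0:
            break
        Da = Dm[:, act, :]
        t1, t2, lp = _split_params(params[act], m)
        _, grad, F = _nll_core(t1, t2, lp, Da, y1, y2,
                               want_grad=True, want_fisher=True)
        grad = np.nan_to_num(grad, nan=np.inf)
        done = np.max(np.abs(grad[:, free]), axis=1) < gscale
        converged[act[done]] = True
        if done.all():
            continue
        sub = ~done
        rows = act[sub]
        Ff = F[np.ix_(sub, free, free)]
        ridge = 1e-8 * (1.0 + np.trace(Ff, axis1=1, axis2=2))[:, None, None]
        with np.errstate(all="ignore"):
            try:
                step_f = np.linalg.solve(Ff + ridge * eye, -grad[sub][:, free, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step_f = np.linalg.solve(Ff + (ridge + 1e-4) * eye,
                                         -grad[sub][:, free, None])[:, :, 0]
        step = np.zeros((rows.size, npar))
        step[:, free] = np.nan_to_num(step_f)
        # cap absurd steps to keep the damped iteration stable
        norm = np.max(np.abs(step), axis=1, keepdims=True)
        step = np.where(norm > 20.0, step * (20.0 / norm), step)

        Ds = Dm[:, rows, :]
        par_cur = params[rows].copy()
        nll_cur = nll[rows].copy()
        alpha = np.ones(rows.size)
        accepted = np.zeros(rows.size, dtype=bool)
        for _ in range(12):
            trial = par_cur + (alpha * ~accepted)[:, None] * step
            trial[:, -1] = np.clip(trial[:, -1], -LOG_PSI_BOUND, LOG_PSI_BOUND)
            t1, t2, lp = _split_params(trial, m)
            nll_t = _nll_core(t1, t2, lp, Ds, y1, y2)
            better = (nll_t <= nll_cur + 1e-10) & ~accepted
            par_cur[better] = trial[better]
            nll_cur[better] = nll_t[better]
            accepted |= better
            if accepted.all():
                break
            alpha[~accepted] *= 0.5
        stalled[rows[~accepted]] = True       # no descent found: give up on row
        params[rows] = par_cur
        nll[rows] = nll_cur

    theta1, theta2, lpsi = _split_params(params, m)
    finite = np.all(np.isfinite(params), axis=1)
    at_bound = np.abs(lpsi) >= LOG_PSI_BOUND - 1e-9
    if fix_log_psi is not None:
        at_bound[:] = False
    converged = converged & finite & ~at_bound & ok1 & ok2
    return BatchBivariateFit(theta1=theta1.copy(), theta2=theta2.copy(),
                             log_psi=lpsi.copy(), nll=nll.copy(),
                             converged=converged, spec=spec, n_obs=n,
                             n_iter=n_iter)


# ---------------------------------------------------------------------------
# single-covariate reference fit
# ---------------------------------------------------------------------------

def fit_bivariate_model(t, x, y1, y2, spec: BivariateModelSpec = FULL_SPEC,
                        fix_log_psi: float | None = None) -> BivariateFit:
    """Maximum-likelihood fit of the single-covariate bivariate odds-ratio
    model by L-BFGS-B with an analytic gradient.

    ``fix_log_psi`` pins the association parameter (``0.0`` recovers the
    two independent univariate logistic fits exactly).  Non-convergence or
    an active ``log_psi`` bound is reported through ``converged=False``
    with best-effort coefficients.
    """
    t, x, y1, y2 = _validate_records(t, x, y1, y2)
    if x.ndim != 1:
        x = x.ravel()
    n = t.size
    m = spec.n_margin_params
    Dm = build_design(t, x, spec)

    th1, _, _ = fit_logistic_models(t, x, y1, spec)
    th2, _, _ = fit_logistic_models(t, x, y2, spec)
    start = np.concatenate([th1[0], th2[0],
                            [0.0 if fix_log_psi is None else fix_log_psi]])

    def fun(p):
        theta1, theta2, lpsi = _split_params(p[None, :], m)
        nll, grad = _nll_core(theta1, theta2, lpsi, Dm, y1, y2, want_grad=True)
        return nll[0], grad[0]

    bounds = [(None, None)] * (2 * m)
    if fix_log_psi is None:
        bounds.append((-LOG_PSI_BOUND, LOG_PSI_BOUND))
    else:
        bounds.append((fix_log_psi, fix_log_psi))
    res = optimize.minimize(fun, start, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    p_hat = res.x
    nll_val, grad = fun(p_hat)
    free = slice(0, 2 * m) if fix_log_psi is not None else slice(0, 2 * m + 1)
    at_bound = fix_log_psi is None and abs(p_hat[-1]) >= LOG_PSI_BOUND - 1e-6
    converged = bool(res.success) and np.max(np.abs(grad[free])) < 1e-4 * max(1, n) \
        and not at_bound and np.all(np.isfinite(p_hat))

    se = None
    if converged:
        se = _wald_se(fun, p_hat, spec, fix_log_psi)
    coeffs = BivariateCoefficients.unpack(p_hat, spec)
    return BivariateFit(coefficients=coeffs, loglik=float(-nll_val),
                        converged=converged, n_obs=int(n), se=se)


def _wald_se(fun, p_hat, spec, fix_log_psi):
    """Standard errors from a central-difference Hessian of the NLL."""
    npar = p_hat.size
    h = 1e-4 * np.maximum(1.0, np.abs(p_hat))
    if fix_log_psi is not None:
        h[-1] = 0.0
    H = np.zeros((npar, npar))
    for j in range(npar):
        if h[j] == 0.0:
            continue
        ej = np.zeros(npar); ej[j] = h[j]
        _, gp = fun(p_hat + ej)
        _, gm = fun(p_hat - ej)
        H[:, j] = (gp - gm) / (2.0 * h[j])
    H = 0.5 * (H + H.T)
    names = _param_names(spec)
    idx = [j for j in range(npar) if h[j] > 0.0]
    try:
        cov = np.linalg.inv(H[np.ix_(idx, idx)])
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if np.any(diag <= 0):
        return None
    out = {}
    for pos, j in enumerate(idx):
        out[names[j]] = float(np.sqrt(diag[pos]))
    return out


def _param_names(spec: BivariateModelSpec) -> list[str]:
    base = {"intercept": "mu", "treatment": "lambda", "covariate": "alpha",
            "interaction": "beta"}
    names = []
    for margin in (1, 2):
        names.extend(f"{base[t]}{margin}" for t in spec.margin_terms)
    names.append("log_psi")
    return names
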