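"""Hypothesis tests for the two-endpoint signature design.

The testing strategy splits the overall two-sided level ``alpha`` into a
trial-population comparison at ``alpha1`` (pooled two-proportion z-test,
all patients) and a sensitive-group comparison at ``alpha2`` (Fisher's
exact test restricted to the predicted sensitive cluster); the overall
result is positive if either rejects, controlling the overall type I error
at ``alpha1 + alpha2`` (defaults 0.04 + 0.01 = 0.05).

Because the sensitive group is found by cross-validation, the asymptotic
null of the treatment-by-sensitivity interaction is unreliable; the
permutation wrapper re-runs the entire scoring/clustering pipeline on
treatment-permuted data and reports

    p_perm = (1 + #{p* <= p0}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
import statsmodels.api as sm

from ._exceptions import InputError, PipelineError

__all__ = [
    "TestConfig",
    "TestResult",
    "PermutationResult",
    "trial_population_test",
    "sensitive_group_test",
    "interaction_test",
    "permutation_pvalue",
    "overall_decision",
]


@dataclass(frozen=True)
class TestConfig:
    """Significance-level split; overall level is alpha1 + alpha2."""

    __test__ = False        # not a pytest class despite the name

    alpha1: float = 0.04
    alpha2: float = 0.01

    @property
    def alpha(self) -> float:
        return self.alpha1 + self.alpha2


@dataclass
class TestResult:
    __test__ = False        # not a pytest class despite the name

    p_value: float
    reject: bool
    statistic: float
    test_name: str
    evaluable: bool = True


@dataclass
class PermutationResult:
    p0: float
    p_star: np.ndarray
    n_perm: int
    p_perm: float
    seed: int


def _check_binary(y, t):
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if y.size != t.size or y.size == 0:
        raise InputError("y and t must be nonempty and of equal length")
    if not (np.all(np.isin(y, (0.0, 1.0))) and np.all(np.isin(t, (0.0, 1.0)))):
        raise InputError("y and t must be binary 0/1")
    return y.astype(int), t.astype(int)


def trial_population_test(y, t, alpha1: float = 0.04) -> TestResult:
    """Two-sided pooled two-proportion z-test between arms (no continuity
    correction)."""
    y, t = _check_binary(y, t)
    n1 = int(np.sum(t == 1))
    n0 = int(np.sum(t == 0))
    if n0 == 0 or n1 == 0:
        raise InputError("both arms must be nonempty")
    x1 = int(np.sum(y[t == 1]))
    x0 = int(np.sum(y[t == 0]))
    p_pool = (x0 + x1) / (n0 + n1)
    var = p_pool * (1.0 - p_pool) * (1.0 / n0 + 1.0 / n1)
    diff = x1 / n1 - x0 / n0
    if var == 0.0:
        z = 0.0
        p = 1.0
    else:
        z = diff / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(p_value=float(p), reject=bool(p < alpha1),
                      statistic=float(z), test_name="trial_population_z")


def sensitive_group_test(y, t, membership, alpha2: float = 0.01) -> TestResult:
    """Two-sided Fisher's exact test between arms within the sensitive
    group.  An empty or single-arm sensitive group makes the test
    non-evaluable (reported as a non-rejection with p = NaN)."""
    y, t = _check_binary(y, t)
    membership = np.asarray(membership, dtype=bool).ravel()
    if membership.size != y.size:
        raise InputError("membership length must match y")
    ys = y[membership]
    ts = t[membership]
    if ys.size == 0 or ts.min() == ts.max():
        return TestResult(p_value=float("nan"), reject=False, statistic=float("nan"),
                          test_name="sensitive_group_fisher", evaluable=False)
    table = np.array([
        [np.sum((ts == 1) & (ys == 1)), np.sum((ts == 1) & (ys == 0))],
        [np.sum((ts == 0) & (ys == 1)), np.sum((ts == 0) & (ys == 0))],
    ])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(p_value=float(p), reject=bool(p < alpha2),
                      statistic=float(odds), test_name="sensitive_group_fisher")


def interaction_test(y, t, sensitivity) -> TestResult:
    """Wald test of the treatment-by-sensitivity interaction in the
    logistic model ``y ~ t + s + t:s``.  Separation or a failed fit is
    reported as non-evaluable."""
    y, t = _check_binary(y, t)
    s = np.asarray(sensitivity, dtype=float).ravel()
    if s.size != y.size:
        raise InputError("sensitivity length must match y")
    X = np.column_stack([np.ones_like(t, dtype=float), t, s, t * s])
    cells = {(int(a), int(b)) for a, b in zip(t, s)}
    if len(cells) < 4:
        return TestResult(float("nan"), False, float("nan"),
                          "interaction_wald", evaluable=False)
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        coef = float(res.params[3])
        se = float(res.bse[3])
        if not (np.isfinite(coef) and np.isfinite(se)) or se > 1e3 or se == 0.0:
            raise PipelineError("separation")
        z = coef / se
        p = 2.0 * stats.norm.sf(abs(z))
    except Exception:
        return TestResult(float("nan"), False, float("nan"),
                          "interaction_wald", evaluable=False)
    return TestResult(p_value=float(p), reject=bool(p < 0.05),
                      statistic=float(z), test_name="interaction_wald")


def permutation_pvalue(data, analysis, n_perm: int, seed: int) -> PermutationResult:
    """Permutation p-value for the treatment-sensitivity interaction.

    ``analysis(data, seed) -> p`` must run the complete cross-validated
    scoring, clustering and interaction-testing pipeline and return its
    interaction p-value.  For each permutation the treatment labels are
    randomly permuted across patients and the full pipeline re-run with a
    fresh derived seed (fresh fold plan included); non-evaluable permuted
    p-values count as 1 (conservative).
    """
    if n_perm < 1:
        raise InputError("n_perm must be at least 1")
    ss = np.random.SeedSequence(seed)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_perm + 1)]
    p0 = analysis(data, child_seeds[0])
    if not np.isfinite(p0):
        p0 = 1.0
    p_star = np.empty(n_perm)
    failures = 0
    for b in range(n_perm):
        permuted = _permute_treatment(data, perm_rng)
        try:
            p = analysis(permuted, child_seeds[b + 1])
        except Exception:
            failures += 1
            p = float("nan")
        p_star[b] = p if np.isfinite(p) else 1.0
    if failures > 0.1 * n_perm:
        raise PipelineError(
            f"analysis failed on {failures}/{n_perm} permutations")
    p_perm = (1.0 + int(np.sum(p_star <= p0))) / (1.0 + n_perm)
    return PermutationResult(p0=float(p0), p_star=p_star, n_perm=int(n_perm),
                             p_perm=float(p_perm), seed=int(seed))


def _permute_treatment(data, rng):
    import copy

    new = copy.copy(data)
    new.treatment = rng.permutation(data.treatment)
    return new


def overall_decision(tp_result: TestResult, sens_result: TestResult) -> bool:
    """Positive if either the trial-population or the sensitive-group test
    rejects at its own level."""
    return bool(tp_result.reject or sens_result.reject)
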