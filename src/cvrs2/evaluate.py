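"""Monte-Carlo operating characteristics of the design.

Each replicate simulates a trial, builds cross-validated bivariate risk
scores (reduced model, matching the simulated data-generating mechanism),
partitions them into k clusters, and applies the alpha-split tests:

* per outcome, the trial-population two-proportion test at ``alpha1``;
* per outcome and per assumed sensitive cluster c, Fisher's exact test at
  ``alpha2`` restricted to the patients assigned to cluster c;
* the overall decision is the per-replicate OR of the two rejections.

Aggregated over replicates this yields the empirical powers (trial
population, sensitive group, overall), the selection sensitivity and
specificity of each cluster against the simulation truth, and the mean
observed response rate among experimental-arm patients assigned to each
cluster.  A non-evaluable sensitive-group test (empty cluster or
single-arm cluster) counts as a non-rejection, keeping denominators fixed
at the replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InputError, PipelineError
from .bivariate_model import REDUCED_SPEC, BivariateModelSpec
from .inference import TestConfig, overall_decision, sensitive_group_test, trial_population_test
from .risk_scores import cluster_scores, compute_cvrs2_scores, make_folds, marginal_cvrs_assignment
from .simulate import ScenarioConfig, simulate_trial

__all__ = [
    "OperatingCharacteristics",
    "MarginalComparison",
    "selection_sens_spec",
    "overall_power_formula",
    "run_operating_characteristics",
    "run_marginal_comparison",
]


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo estimates; outcome axis first where present."""

    power_tp: np.ndarray                 # (2,)
    power_sens: np.ndarray               # (2, k)
    power_overall: np.ndarray            # (2, k)
    selection_sensitivity: np.ndarray    # (k,)
    selection_specificity: np.ndarray    # (k,)
    est_rate: np.ndarray                 # (2, k)
    n_reps: int
    k: int
    mc_se: dict[str, np.ndarray] = field(default_factory=dict)
    n_failures: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Tidy table mirroring the per-cluster layout of the design's
        operating-characteristics summaries."""
        rows = []
        for i in (0, 1):
            rows.append({"quantity": f"power_trial_population_y{i+1}",
                         "cluster": None, "value": float(self.power_tp[i]),
                         "mc_se": float(self.mc_se["power_tp"][i])})
        for name, arr, se in (("power_sensitive_group", self.power_sens, self.mc_se["power_sens"]),
                              ("power_overall", self.power_overall, self.mc_se["power_overall"]),
                              ("estimated_rate", self.est_rate, self.mc_se["est_rate"])):
            for i in (0, 1):
                for c in range(self.k):
                    rows.append({"quantity": f"{name}_y{i+1}", "cluster": c + 1,
                                 "value": float(arr[i, c]), "mc_se": float(se[i, c])})
        for name, arr, se in (("selection_sensitivity", self.selection_sensitivity,
                               self.mc_se["selection_sensitivity"]),
                              ("selection_specificity", self.selection_specificity,
                               self.mc_se["selection_specificity"])):
            for c in range(self.k):
                rows.append({"quantity": name, "cluster": c + 1,
                             "value": float(arr[c]), "mc_se": float(se[c])})
        return pd.DataFrame(rows)


@dataclass
class MarginalComparison:
    """Paired truth-agreement of CVRS2 (k = 4) vs marginal CVRS."""

    agreement_cvrs2: float
    agreement_marginal: float
    se_cvrs2: float
    se_marginal: float
    per_rep: pd.DataFrame
    n_reps: int


def selection_sens_spec(predicted, truth, assumed_cluster: int):
    """Selection sensitivity and specificity when ``assumed_cluster`` is
    taken as the sensitive group.

    sensitivity = P(predicted = c | truth = c);
    specificity = P(predicted != c | truth != c).  Undefined denominators
    yield NaN.
    """
    predicted = np.asarray(getattr(predicted, "label", predicted), dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.size != truth.size:
        raise InputError("predicted and truth labelings must have equal length")
    pos = truth == assumed_cluster
    neg = ~pos
    sens = float(np.mean(predicted[pos] == assumed_cluster)) if pos.any() else float("nan")
    spec = float(np.mean(predicted[neg] != assumed_cluster)) if neg.any() else float("nan")
    return sens, spec


def overall_power_formula(p_tp: float, p_sens: float) -> float:
    """Overall power when the two tests are independent:
    ``p_tp + (1 - p_tp) * p_sens``."""
    if not (0.0 <= p_tp <= 1.0 and 0.0 <= p_sens <= 1.0):
        raise InputError("powers must lie in [0, 1]")
    return p_tp + (1.0 - p_tp) * p_sens


def _replicate_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_single_replicate(config: ScenarioConfig, k: int, spec: BivariateModelSpec,
                         test_cfg: TestConfig, seed: int, r_folds: int = 10):
    """One simulate-score-cluster-test replicate; returns per-replicate
    rejection indicators, selection quality and cluster rates."""
    ss = np.random.SeedSequence(seed)
    s_sim, s_fold, s_km = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    data = simulate_trial(config, s_sim)
    folds = make_folds(data.n_patients, r_folds, s_fold)
    scores = compute_cvrs2_scores(data, spec, folds)
    assignment = cluster_scores(scores, k, s_km)

    reject_tp = np.zeros(2, dtype=bool)
    for i, y in enumerate((data.y1, data.y2)):
        reject_tp[i] = trial_population_test(y, data.treatment, test_cfg.alpha1).reject

    reject_sens = np.zeros((2, k), dtype=bool)
    est_rate = np.full((2, k), np.nan)
    treated = data.treatment == 1
    for c in range(1, k + 1):
        member = assignment.membership(c)
        for i, y in enumerate((data.y1, data.y2)):
            res = sensitive_group_test(y, data.treatment, member, test_cfg.alpha2)
            reject_sens[i, c - 1] = res.reject
            sel = treated & member
            if sel.any():
                est_rate[i, c - 1] = float(np.mean(y[sel]))
    reject_ov = reject_tp[:, None] | reject_sens

    sel_sens = np.full(k, np.nan)
    sel_spec = np.full(k, np.nan)
    if data.true_cluster is not None:
        for c in range(1, k + 1):
            sel_sens[c - 1], sel_spec[c - 1] = selection_sens_spec(
                assignment, data.true_cluster, c)
    return reject_tp, reject_sens, reject_ov, sel_sens, sel_spec, est_rate


def run_operating_characteristics(config: ScenarioConfig, k: int = 2,
                                  spec: BivariateModelSpec = REDUCED_SPEC,
                                  test_cfg: TestConfig = TestConfig(),
                                  n_reps: int = 100, seed: int = 0,
                                  r_folds: int = 10) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics over ``n_reps`` replicates.

    Replicate seeds derive deterministically from the master seed.
    Replicates whose pipeline fails are logged and excluded; more than 5%
    failures aborts the run.
    """
    if n_reps < 1:
        raise InputError("n_reps must be at least 1")
    seeds = _replicate_seeds(seed, n_reps)
    tp, sens, ov, ssens, sspec, rate = [], [], [], [], [], []
    failures = 0
    for s in seeds:
        try:
            rep = run_single_replicate(config, k, spec, test_cfg, s, r_folds)
        except PipelineError:
            failures += 1
            continue
        tp.append(rep[0]); sens.append(rep[1]); ov.append(rep[2])
        ssens.append(rep[3]); sspec.append(rep[4]); rate.append(rep[5])
    if failures > 0.05 * n_reps:
        raise PipelineError(f"{failures}/{n_reps} replicates failed")
    R = len(tp)
    tp = np.mean(tp, axis=0)
    sens = np.mean(sens, axis=0)
    ov = np.mean(ov, axis=0)
    ssens_arr = np.asarray(ssens)
    sspec_arr = np.asarray(sspec)
    rate_arr = np.asarray(rate)

    def _binom_se(p):
        return np.sqrt(np.asarray(p) * (1.0 - np.asarray(p)) / R) if R > 1 else np.zeros_like(np.asarray(p))

    def _mean_se(arr):
        with np.errstate(all="ignore"):
            m = np.nanmean(arr, axis=0)
            cnt = np.sum(np.isfinite(arr), axis=0)
            sd = np.nanstd(arr, axis=0, ddof=1) if R > 1 else np.zeros_like(m)
        se = np.where(cnt > 1, sd / np.sqrt(np.maximum(cnt, 1)), 0.0)
        return m, se

    ssens_m, ssens_se = _mean_se(ssens_arr)
    sspec_m, sspec_se = _mean_se(sspec_arr)
    rate_m, rate_se = _mean_se(rate_arr)
    mc_se = {
        "power_tp": _binom_se(tp),
        "power_sens": _binom_se(sens),
        "power_overall": _binom_se(ov),
        "selection_sensitivity": ssens_se,
        "selection_specificity": sspec_se,
        "est_rate": rate_se,
    }
    return OperatingCharacteristics(
        power_tp=tp, power_sens=sens, power_overall=ov,
        selection_sensitivity=ssens_m, selection_specificity=sspec_m,
        est_rate=rate_m, n_reps=R, k=k, mc_se=mc_se, n_failures=failures)


def run_marginal_comparison(config: ScenarioConfig,
                            spec: BivariateModelSpec = REDUCED_SPEC,
                            test_cfg: TestConfig = TestConfig(),
                            n_reps: int = 20, seed: int = 0,
                            r_folds: int = 10) -> MarginalComparison:
    """Paired comparison of CVRS2 (k = 4) against the marginal CVRS
    (single-outcome CVRS per outcome, memberships crossed into 4 groups)
    on identical simulated datasets."""
    seeds = _replicate_seeds(seed, n_reps)
    rows = []
    for s in seeds:
        ss = np.random.SeedSequence(s)
        s_sim, s_fold, s_km = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(3)]
        data = simulate_trial(config, s_sim)
        folds = make_folds(data.n_patients, r_folds, s_fold)
        scores = compute_cvrs2_scores(data, spec, folds)
        assign2 = cluster_scores(scores, 4, s_km)
        assignm = marginal_cvrs_assignment(data, spec, folds, s_km)
        truth = data.true_cluster
        rows.append({
            "seed": s,
            "agreement_cvrs2": float(np.mean(assign2.label == truth)),
            "agreement_marginal": float(np.mean(assignm.label == truth)),
        })
    df = pd.DataFrame(rows)
    R = len(df)
    return MarginalComparison(
        agreement_cvrs2=float(df["agreement_cvrs2"].mean()),
        agreement_marginal=float(df["agreement_marginal"].mean()),
        se_cvrs2=float(df["agreement_cvrs2"].std(ddof=1) / np.sqrt(R)) if R > 1 else 0.0,
        se_marginal=float(df["agreement_marginal"].std(ddof=1) / np.sqrt(R)) if R > 1 else 0.0,
        per_rep=df, n_reps=R)
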