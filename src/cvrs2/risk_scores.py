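"""Cross-validated risk scores and k-means subgroup assignment.

A patient's risk score is the sum of their baseline covariate values
weighted by the estimated treatment-by-covariate interaction coefficients,
each coefficient fitted on training folds that exclude the patient
(r-fold cross-validation, r = 10 by convention).  The single-outcome score
(CVRS) uses per-covariate univariate logistic fits; the two-outcome score
(CVRS2) uses per-covariate bivariate odds-ratio fits and yields the pair
``(RS1, RS2)``.

Within each test fold, k-means (k = 2 or 4) partitions the scores; raw
k-means labels are arbitrary, so each fold's clusters are mapped to
canonical labels from centroid geometry before memberships are pooled over
folds:

* k = 2 — cluster 2 ("sensitive") is the cluster whose centroid has the
  larger component sum;
* k = 4 — quadrants of the bivariate score: 1 = low/low, 2 = high on the
  outcome-2 score only, 3 = high on the outcome-1 score only, 4 = high/high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from ._exceptions import InputError, PipelineError
from .bivariate_model import (
    FULL_SPEC,
    BivariateModelSpec,
    fit_bivariate_models,
    fit_logistic_models,
)

__all__ = [
    "TrialDataset",
    "FoldPlan",
    "RiskScoreSet",
    "ClusterAssignment",
    "make_folds",
    "compute_cvrs2_scores",
    "compute_cvrs_scores",
    "kmeans_partition",
    "canonical_labels",
    "cluster_scores",
    "marginal_cvrs_assignment",
    "weighted_score",
]


@dataclass
class TrialDataset:
    """Patient-level trial data.

    ``covariates`` is the N x P baseline matrix, ``treatment`` the binary
    arm indicator (0 control, 1 experimental), ``y1``/``y2`` the binary
    outcomes (``y2`` optional for single-outcome use), ``true_cluster`` the
    simulation truth when available (labels in 1..k).
    """

    covariates: np.ndarray
    treatment: np.ndarray
    y1: np.ndarray
    y2: np.ndarray | None = None
    true_cluster: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self):
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim != 2:
            raise InputError("covariates must be a 2-d matrix (patients x covariates)")
        n = self.covariates.shape[0]
        self.treatment = _binary_vector(self.treatment, "treatment", n)
        self.y1 = _binary_vector(self.y1, "y1", n)
        if self.y2 is not None:
            self.y2 = _binary_vector(self.y2, "y2", n)
        if not np.all(np.isfinite(self.covariates)):
            bad = np.argwhere(~np.isfinite(self.covariates))[0]
            raise InputError(
                f"covariates contain a missing/non-finite value at row {bad[0]}, column {bad[1]}")
        if self.treatment.min() == self.treatment.max():
            raise InputError("both treatment arms must be represented")
        if self.true_cluster is not None:
            self.true_cluster = np.asarray(self.true_cluster, dtype=int).ravel()
            if self.true_cluster.size != n:
                raise InputError("true_cluster length must match the number of patients")
        if self.covariate_names is None:
            width = len(str(self.n_covariates))
            self.covariate_names = [f"x{j + 1:0{width}d}" for j in range(self.n_covariates)]
        elif len(self.covariate_names) != self.n_covariates:
            raise InputError("covariate_names length must match the number of covariates")

    @property
    def n_patients(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]


def _binary_vector(v, name, n):
    v = np.asarray(v, dtype=float).ravel()
    if v.size != n:
        raise InputError(f"{name} length {v.size} does not match {n} patients")
    if not np.all(np.isfinite(v)):
        row = int(np.flatnonzero(~np.isfinite(v))[0])
        raise InputError(f"{name} has a missing value at row {row}")
    if not np.all(np.isin(v, (0.0, 1.0))):
        row = int(np.flatnonzero(~np.isin(v, (0.0, 1.0)))[0])
        raise InputError(f"{name} must be binary 0/1; offending row {row}")
    return v.astype(int)


@dataclass
class FoldPlan:
    """Assignment of patients to r non-overlapping folds of near-equal size."""

    r: int
    assignment: np.ndarray      # (n,) fold index in 0..r-1
    seed: int

    @property
    def n(self) -> int:
        return self.assignment.size

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


@dataclass
class RiskScoreSet:
    """Per-patient cross-validated scores, d = 1 (CVRS) or 2 (CVRS2)."""

    scores: np.ndarray          # (n, d)
    fold_of: np.ndarray         # (n,)
    outcome_labels: tuple[int, ...]

    @property
    def d(self) -> int:
        return self.scores.shape[1]


@dataclass
class ClusterAssignment:
    """Canonical cluster label per patient, pooled over folds."""

    label: np.ndarray           # (n,) in 1..k
    k: int
    centroids_by_fold: dict[int, np.ndarray] = field(default_factory=dict)
    degenerate_folds: list[int] = field(default_factory=list)
    # folds where the k=4 quadrant pattern was not one-to-one and the
    # rank-order fallback labelled the centroids (a hint that the scores
    # support fewer than k clusters)
    fallback_folds: list[int] = field(default_factory=list)

    def membership(self, cluster: int) -> np.ndarray:
        return self.label == cluster


def make_folds(n: int, r: int, seed: int) -> FoldPlan:
    """Randomly divide n patients into r folds whose sizes differ by <= 1."""
    if r < 2:
        raise InputError("at least 2 folds are required")
    if n < 2 * r:
        raise InputError(f"n={n} too small for r={r} folds (need n >= 2r)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, r)):
        assignment[chunk] = fold
    return FoldPlan(r=r, assignment=assignment, seed=int(seed))


def _check_folds(data: TrialDataset, folds: FoldPlan):
    if folds.n != data.n_patients:
        raise InputError("fold plan size does not match the dataset")


def compute_cvrs2_scores(data: TrialDataset, spec: BivariateModelSpec,
                         folds: FoldPlan,
                         prefilter_alpha: float | None = None) -> RiskScoreSet:
    """Bivariate cross-validated risk scores.

    For each fold, every covariate's single-covariate bivariate odds-ratio
    model is fitted on the training folds; test patients are scored as
    ``(sum_j b1_j x_j, sum_j b2_j x_j)`` over the fitted interaction
    coefficients.  Covariates whose fit did not converge contribute zero.
    """
    _check_folds(data, folds)
    if data.y2 is None:
        raise InputError("CVRS2 scores require both outcomes (y2 missing)")
    n, P = data.covariates.shape
    scores = np.zeros((n, 2))
    for fold in range(folds.r):
        test = folds.assignment == fold
        train = ~test
        fit = fit_bivariate_models(data.treatment[train], data.covariates[train],
                                   data.y1[train], data.y2[train], spec=spec)
        keep = fit.converged
        if prefilter_alpha is not None:
            keep = keep & _prefilter_mask(data, train, spec, prefilter_alpha,
                                          outcomes=(1, 2))
        if not np.any(fit.converged):
            raise PipelineError(f"all covariate fits failed in fold {fold}")
        b1 = np.where(keep, fit.beta1, 0.0)
        b2 = np.where(keep, fit.beta2, 0.0)
        scores[test, 0] = data.covariates[test] @ b1
        scores[test, 1] = data.covariates[test] @ b2
    return RiskScoreSet(scores=scores, fold_of=folds.assignment.copy(),
                        outcome_labels=(1, 2))


def compute_cvrs_scores(data: TrialDataset, outcome: int,
                        spec: BivariateModelSpec, folds: FoldPlan,
                        prefilter_alpha: float | None = None) -> RiskScoreSet:
    """Single-outcome cross-validated risk scores (univariate logistic fits)."""
    _check_folds(data, folds)
    if outcome not in (1, 2):
        raise InputError("outcome must be 1 or 2")
    y = data.y1 if outcome == 1 else data.y2
    if y is None:
        raise InputError(f"outcome {outcome} is not present in the dataset")
    n, P = data.covariates.shape
    scores = np.zeros((n, 1))
    for fold in range(folds.r):
        test = folds.assignment == fold
        train = ~test
        theta, converged, _ = fit_logistic_models(
            data.treatment[train], data.covariates[train], y[train], spec=spec)
        keep = converged
        if prefilter_alpha is not None:
            keep = keep & _prefilter_mask(data, train, spec, prefilter_alpha,
                                          outcomes=(outcome,))
        if not np.any(converged):
            raise PipelineError(f"all covariate fits failed in fold {fold}")
        beta = np.where(keep, theta[:, -1], 0.0)
        scores[test, 0] = data.covariates[test] @ beta
    return RiskScoreSet(scores=scores, fold_of=folds.assignment.copy(),
                        outcome_labels=(outcome,))


def _prefilter_mask(data, train, spec, alpha, outcomes):
    """Keep covariates whose univariate interaction Wald p (training folds
    only) is below ``alpha`` for at least one requested outcome."""
    from scipy import stats

    keep = np.zeros(data.n_covariates, dtype=bool)
    for outcome in outcomes:
        y = data.y1 if outcome == 1 else data.y2
        theta, conv, beta_var = fit_logistic_models(
            data.treatment[train], data.covariates[train], y[train], spec=spec)
        with np.errstate(all="ignore"):
            z = theta[:, -1] / np.sqrt(beta_var)
            p = 2.0 * stats.norm.sf(np.abs(z))
        keep |= conv & np.isfinite(p) & (p < alpha)
    return keep


def kmeans_partition(points: np.ndarray, k: int, seed: int):
    """Best-of-10-restarts Lloyd k-means; returns (labels, centroids)."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    m = points.shape[0]
    if m < k:
        raise InputError(f"cannot form {k} clusters from {m} points")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2 ** 31),
                algorithm="lloyd")
    with warnings.catch_warnings():
        # duplicate points may collapse clusters; we flag that ourselves
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = km.fit_predict(points)
    return labels, km.cluster_centers_


def canonical_labels(centroids: np.ndarray, return_info: bool = False):
    """Map raw k-means cluster indices to canonical labels in 1..k.

    k = 2: the cluster with the larger centroid component-sum is the
    sensitive cluster (canonical 2).  k = 4 (bivariate scores): split each
    coordinate at the midpoint of the extreme centroids and read quadrants
    as 1 = low/low, 2 = high on dim 2 only, 3 = high on dim 1 only,
    4 = high/high; if that sign pattern is not one-to-one, fall back to
    ranking centroids by component-sum (ties between the middle two broken
    by the dim-2 coordinate).
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim == 1:
        centroids = centroids[:, None]
    k, d = centroids.shape
    if k == 2:
        sums = centroids.sum(axis=1)
        out = np.empty(2, dtype=int)
        order = np.argsort(sums, kind="stable")
        out[order[0]] = 1
        out[order[1]] = 2
        return (out, False) if return_info else out
    if k == 4:
        if d != 2:
            raise InputError("k=4 canonical labelling requires 2-d scores")
        mid = 0.5 * (centroids.min(axis=0) + centroids.max(axis=0))
        high = centroids > mid
        pattern = {(False, False): 1, (False, True): 2,
                   (True, False): 3, (True, True): 4}
        labels = np.array([pattern[tuple(row)] for row in high])
        if len(set(labels)) == 4:
            return (labels, False) if return_info else labels
        # fallback: rank by component sum, middle two ordered by dim 2
        sums = centroids.sum(axis=1)
        order = np.argsort(sums, kind="stable")
        out = np.empty(4, dtype=int)
        out[order[0]] = 1
        out[order[3]] = 4
        mid_pair = order[1:3]
        if centroids[mid_pair[0], 1] >= centroids[mid_pair[1], 1]:
            out[mid_pair[0]], out[mid_pair[1]] = 2, 3
        else:
            out[mid_pair[0]], out[mid_pair[1]] = 3, 2
        return (out, True) if return_info else out
    raise InputError("canonical labelling supports k in {2, 4} only")


def cluster_scores(scores: RiskScoreSet, k: int, seed: int) -> ClusterAssignment:
    """Per-fold k-means on the test-fold scores, canonical labels pooled
    into one assignment.

    The same derived seed drives k-means in every fold, so the pooled
    assignment does not depend on how folds are numbered.
    """
    n = scores.scores.shape[0]
    label = np.zeros(n, dtype=int)
    centroids_by_fold: dict[int, np.ndarray] = {}
    degenerate: list[int] = []
    fallback: list[int] = []
    for fold in np.unique(scores.fold_of):
        idx = np.flatnonzero(scores.fold_of == fold)
        pts = scores.scores[idx]
        if idx.size < k:
            raise InputError(
                f"fold {fold} has {idx.size} patients (< k={k}); use fewer folds")
        if np.unique(pts, axis=0).shape[0] < k:
            degenerate.append(int(fold))
        raw, centroids = kmeans_partition(pts, k, seed)
        mapping, used_fallback = canonical_labels(centroids, return_info=True)
        if used_fallback:
            fallback.append(int(fold))
        label[idx] = mapping[raw]
        ordered = np.empty_like(centroids)
        ordered[mapping - 1] = centroids
        centroids_by_fold[int(fold)] = ordered
    return ClusterAssignment(label=label, k=k,
                             centroids_by_fold=centroids_by_fold,
                             degenerate_folds=degenerate,
                             fallback_folds=fallback)


def marginal_cvrs_assignment(data: TrialDataset, spec: BivariateModelSpec,
                             folds: FoldPlan, seed: int) -> ClusterAssignment:
    """Four-group assignment from running the single-outcome CVRS (k = 2)
    on each outcome separately and crossing the memberships:
    (non, non) -> 1, (non, sens-for-2) -> 2, (sens-for-1, non) -> 3,
    (sens, sens) -> 4.
    """
    a1 = cluster_scores(compute_cvrs_scores(data, 1, spec, folds), 2, seed)
    a2 = cluster_scores(compute_cvrs_scores(data, 2, spec, folds), 2, seed)
    s1 = a1.label == 2
    s2 = a2.label == 2
    label = 1 + 2 * s1.astype(int) + s2.astype(int)
    return ClusterAssignment(label=label, k=4,
                             degenerate_folds=sorted(set(a1.degenerate_folds)
                                                     | set(a2.degenerate_folds)))


def weighted_score(scores: RiskScoreSet, w1: float, w2: float) -> RiskScoreSet:
    """Collapse a bivariate score to ``w1*RS1 + w2*RS2`` per patient."""
    if scores.d != 2:
        raise InputError("weighted_score requires a bivariate score set")
    if not (np.isfinite(w1) and np.isfinite(w2)):
        raise InputError("weights must be finite")
    combined = w1 * scores.scores[:, :1] + w2 * scores.scores[:, 1:]
    return RiskScoreSet(scores=combined, fold_of=scores.fold_of.copy(),
                        outcome_labels=scores.outcome_labels)
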