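"""Tests for cross-validated scoring, clustering and pooling."""

import itertools

import numpy as np
import pytest

from cvrs2 import (
    REDUCED_SPEC,
    InputError,
    TrialDataset,
    canonical_labels,
    cluster_scores,
    compute_cvrs2_scores,
    compute_cvrs_scores,
    kmeans_partition,
    make_folds,
    marginal_cvrs_assignment,
    scenario_preset,
    simulate_trial,
    weighted_score,
)
from cvrs2.risk_scores import RiskScoreSet


class TestMakeFolds:
    def test_sizes_and_partition(self):
        plan = make_folds(400, 10, seed=3)
        sizes = np.bincount(plan.assignment, minlength=10)
        assert np.all(sizes == 40)
        assert plan.assignment.size == 400

    def test_leave_one_out_limit_and_near_equal_sizes(self):
        sizes = np.bincount(make_folds(20, 10, seed=0).assignment)
        assert np.all(sizes == 2)
        sizes = np.bincount(make_folds(403, 10, seed=0).assignment)
        assert sizes.max() - sizes.min() <= 1

    def test_determinism_and_seed_sensitivity(self):
        a = make_folds(1000, 10, seed=5).assignment
        b = make_folds(1000, 10, seed=5).assignment
        c = make_folds(1000, 10, seed=6).assignment
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.array_equal(np.bincount(a), np.bincount(c))

    def test_too_few_patients(self):
        with pytest.raises(InputError):
            make_folds(15, 10, seed=0)


def _null_dataset(rng, n=80, p=5):
    # outcomes carry no signal; all interaction fits hover near zero
    return TrialDataset(covariates=rng.normal(size=(n, p)),
                        treatment=np.tile([0, 1], n // 2),
                        y1=rng.integers(0, 2, n),
                        y2=rng.integers(0, 2, n))


class TestScores:
    def test_cvrs_ignores_other_outcome(self, rng):
        data = _null_dataset(rng)
        folds = make_folds(data.n_patients, 4, seed=1)
        s_a = compute_cvrs_scores(data, 1, REDUCED_SPEC, folds)
        flipped = TrialDataset(covariates=data.covariates, treatment=data.treatment,
                               y1=data.y1, y2=1 - data.y2)
        s_b = compute_cvrs_scores(flipped, 1, REDUCED_SPEC, folds)
        np.testing.assert_array_equal(s_a.scores, s_b.scores)

    def test_scores_are_interaction_weighted_sums(self, rng):
        """Test-fold scores equal the dot product of held-out covariates
        with the training-fold interaction coefficients."""
        from cvrs2 import fit_bivariate_models

        data = _null_dataset(rng, n=60, p=2)
        folds = make_folds(60, 3, seed=2)
        scores = compute_cvrs2_scores(data, REDUCED_SPEC, folds)
        fold = 0
        test = folds.assignment == fold
        fit = fit_bivariate_models(data.treatment[~test], data.covariates[~test],
                                   data.y1[~test], data.y2[~test], spec=REDUCED_SPEC)
        b1 = np.where(fit.converged, fit.beta1, 0.0)
        b2 = np.where(fit.converged, fit.beta2, 0.0)
        for i in np.flatnonzero(test):
            assert scores.scores[i, 0] == pytest.approx(
                float(data.covariates[i] @ b1), abs=1e-10)
            assert scores.scores[i, 1] == pytest.approx(
                float(data.covariates[i] @ b2), abs=1e-10)

    def test_cross_validation_hygiene(self, rng):
        """Corrupting one patient's outcomes never changes that patient's
        own score (their fold is excluded from the fits that score them)."""
        data = _null_dataset(rng, n=60, p=3)
        folds = make_folds(60, 3, seed=7)
        base = compute_cvrs2_scores(data, REDUCED_SPEC, folds)
        victim = 11
        y1 = data.y1.copy()
        y2 = data.y2.copy()
        y1[victim] = 1 - y1[victim]
        y2[victim] = 1 - y2[victim]
        corrupted = TrialDataset(covariates=data.covariates, treatment=data.treatment,
                                 y1=y1, y2=y2)
        new = compute_cvrs2_scores(corrupted, REDUCED_SPEC, folds)
        np.testing.assert_allclose(new.scores[victim], base.scores[victim], atol=1e-12)
        # but other folds' scores do respond to the change
        assert not np.allclose(new.scores, base.scores)

    def test_weighted_score(self):
        scores = RiskScoreSet(scores=np.array([[2.0, 4.0], [1.0, -1.0]]),
                              fold_of=np.array([0, 0]), outcome_labels=(1, 2))
        assert weighted_score(scores, 0.5, 0.5).scores[0, 0] == pytest.approx(3.0)
        np.testing.assert_array_equal(weighted_score(scores, 1, 0).scores[:, 0],
                                      scores.scores[:, 0])
        assert np.all(weighted_score(scores, 0, 0).scores == 0)


class TestKMeansPartition:
    def test_separated_clouds(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (15, 2))])
        labels, centroids = kmeans_partition(pts, 2, seed=0)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_m(self, rng):
        pts = rng.normal(size=(5, 2))
        labels, centroids = kmeans_partition(pts, 5, seed=0)
        assert sorted(labels) == list(range(5))
        np.testing.assert_allclose(centroids[labels], pts, atol=1e-12)

    def test_matches_exhaustive_two_partition_search(self, rng):
        pts = rng.normal(size=(12, 2))
        labels, _ = kmeans_partition(pts, 2, seed=1)

        def wss(mask):
            out = 0.0
            for grp in (pts[mask], pts[~mask]):
                if len(grp):
                    out += np.sum((grp - grp.mean(axis=0)) ** 2)
            return out

        best = min(
            (wss(np.array(bits, dtype=bool)) for bits in
             itertools.product([0, 1], repeat=12) if 0 < sum(bits) < 12))
        got = wss(labels == labels[0])
        assert got == pytest.approx(best, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InputError):
            kmeans_partition(np.zeros((1, 2)), 2, seed=0)


class TestCanonicalLabels:
    def test_k2_sensitive_is_high_centroid(self):
        mapping = canonical_labels(np.array([[0.0, 0.0], [5.0, 5.0]]))
        assert list(mapping) == [1, 2]
        mapping = canonical_labels(np.array([[5.0, 5.0], [0.0, 0.0]]))
        assert list(mapping) == [2, 1]

    def test_k4_quadrants(self):
        cent = np.array([[0.0, 0.0], [0.0, 5.0], [5.0, 0.0], [5.0, 5.0]])
        assert list(canonical_labels(cent)) == [1, 2, 3, 4]

    def test_k4_permutation_invariance(self, rng):
        cent = np.array([[0.0, 0.0], [0.0, 5.0], [5.0, 0.0], [5.0, 5.0]])
        for perm in itertools.permutations(range(4)):
            mapped = canonical_labels(cent[list(perm)])
            for row, lab in zip(perm, mapped):
                assert lab == row + 1

    def test_k4_degenerate_falls_back_to_rank_order(self):
        cent = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        mapping = canonical_labels(cent)
        assert mapping[0] == 1 and mapping[3] == 4
        assert sorted(mapping) == [1, 2, 3, 4]

    def test_unsupported_k(self):
        with pytest.raises(InputError):
            canonical_labels(np.zeros((3, 2)))


class TestClusterScores:
    def test_scenario_one_agreement_with_truth(self):
        data = simulate_trial(scenario_preset("I", n_patients=400,
                                              sensitive_fraction=0.2), seed=31)
        folds = make_folds(400, 10, seed=32)
        scores = compute_cvrs2_scores(data, REDUCED_SPEC, folds)
        assign = cluster_scores(scores, 2, seed=33)
        agreement = np.mean(assign.label == data.true_cluster)
        assert agreement >= 0.99

    def test_fold_relabel_invariance(self, rng):
        data = _null_dataset(rng, n=60, p=3)
        folds = make_folds(60, 3, seed=9)
        scores = compute_cvrs2_scores(data, REDUCED_SPEC, folds)
        assign = cluster_scores(scores, 2, seed=4)
        relabel = np.array([2, 0, 1])[scores.fold_of]
        scrambled = RiskScoreSet(scores=scores.scores, fold_of=relabel,
                                 outcome_labels=(1, 2))
        assign2 = cluster_scores(scrambled, 2, seed=4)
        np.testing.assert_array_equal(assign.label, assign2.label)

    def test_identical_scores_are_degenerate_single_cluster(self):
        scores = RiskScoreSet(scores=np.zeros((30, 2)),
                              fold_of=np.repeat([0, 1, 2], 10),
                              outcome_labels=(1, 2))
        assign = cluster_scores(scores, 2, seed=0)
        assert len(np.unique(assign.label)) == 1
        assert assign.degenerate_folds == [0, 1, 2]

    def test_fold_smaller_than_k_rejected(self):
        scores = RiskScoreSet(scores=np.zeros((5, 2)),
                              fold_of=np.array([0, 0, 0, 0, 1]),
                              outcome_labels=(1, 2))
        with pytest.raises(InputError):
            cluster_scores(scores, 2, seed=0)


class TestMarginalCVRS:
    def test_disjoint_signatures_recover_four_clusters(self):
        cfg = scenario_preset("IIa", n_patients=600, n_overlap=0)
        data = simulate_trial(cfg, seed=55)
        folds = make_folds(600, 10, seed=56)
        assign = marginal_cvrs_assignment(data, REDUCED_SPEC, folds, seed=57)
        assert assign.k == 4
        agreement = np.mean(assign.label == data.true_cluster)
        assert agreement > 0.7

    def test_determinism(self, rng):
        data = _null_dataset(rng, n=60, p=3)
        folds = make_folds(60, 3, seed=8)
        a = marginal_cvrs_assignment(data, REDUCED_SPEC, folds, seed=5)
        b = marginal_cvrs_assignment(data, REDUCED_SPEC, folds, seed=5)
        np.testing.assert_array_equal(a.label, b.label)

    def test_null_data_rates_near_control(self, rng):
        # under pure noise every crossed group's response rate is ~ the
        # marginal rate; just check labels cover 1..4 plausibly
        data = _null_dataset(np.random.default_rng(0), n=200, p=10)
        folds = make_folds(200, 5, seed=1)
        assign = marginal_cvrs_assignment(data, REDUCED_SPEC, folds, seed=2)
        assert set(np.unique(assign.label)) <= {1, 2, 3, 4}
        overall = data.y1.mean()
        for c in range(1, 5):
            member = assign.label == c
            if member.sum() >= 20:
                assert abs(data.y1[member].mean() - overall) < 0.25
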