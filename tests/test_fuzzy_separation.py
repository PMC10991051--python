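"""Fuzzy c-means clustering, condition matching and CI-overlap screening."""

import numpy as np
import pandas as pd
import pytest

from affectval.fuzzy_separation import (
    FeatureMatrix,
    FuzzyPartition,
    ZeroVarianceError,
    affiliation_separability,
    build_feature_matrix,
    fuzzy_cmeans,
    match_and_correspondence,
)
from affectval.rating_model import (
    ContinuousSeries,
    PostRating,
    RatingBundle,
    StimulusMeta,
)


def constant_bundle(valence, arousal, dominance, sid="s1", condition="neutral"):
    """One stimulus; one participant per element of the value vectors."""
    manifest = [StimulusMeta(sid, condition, 40)]
    continuous, post = [], []
    for i, (v, a, d) in enumerate(zip(valence, arousal, dominance)):
        pid = f"P{i}"
        continuous.append(ContinuousSeries(pid, sid, "valence", np.full(41, float(v))))
        continuous.append(ContinuousSeries(pid, sid, "arousal", np.full(41, float(a))))
        post.append(PostRating(pid, sid, float(d), 50.0, "joy", "interest", 3, 1))
    return RatingBundle(manifest, continuous, post)


class TestFeatureMatrix:
    def test_hand_z_scores_population_sd(self):
        fm = build_feature_matrix(
            constant_bundle([10, 20, 30], [20, 40, 60], [30, 50, 70]))
        expected = np.array([-1.22474487, 0.0, 1.22474487])
        for col in range(3):
            assert np.allclose(fm.X[:, col], expected)

    def test_columns_standardized(self, small_bundle):
        fm = build_feature_matrix(small_bundle)
        assert np.allclose(fm.X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(fm.X.std(axis=0), 1.0, atol=1e-9)

    def test_row_count_matches_design(self, small_bundle):
        fm = build_feature_matrix(small_bundle)
        assert len(fm) == len(small_bundle.post)

    def test_identical_rows_rejected(self):
        with pytest.raises(ZeroVarianceError):
            build_feature_matrix(
                constant_bundle([50, 50, 50], [50, 50, 50], [50, 50, 50]))


def two_blobs(n_per=4, sep=20.0, rng=None):
    rng = rng or np.random.default_rng(0)
    a = rng.normal(0.0, 0.5, size=(n_per, 2))
    b = rng.normal(sep, 0.5, size=(n_per, 2))
    return np.vstack([a, b])


class TestFuzzyCMeans:
    def test_membership_rows_sum_to_one(self, rng):
        X = rng.normal(size=(40, 3))
        part = fuzzy_cmeans(X, k=3, stream=rng)
        assert np.allclose(part.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert part.memberships.min() >= 0.0
        assert part.memberships.max() <= 1.0

    def test_far_separated_blobs_near_hard(self, rng):
        X = two_blobs(sep=50.0)
        part = fuzzy_cmeans(X, k=2, stream=rng)
        own = np.max(part.memberships, axis=1)
        assert (own > 0.99).all()

    def test_point_at_center_gets_membership_one(self, rng):
        # duplicated points force the converged centers onto the points
        X = np.array([[0.0, 0.0]] * 3 + [[10.0, 10.0]] * 3)
        part = fuzzy_cmeans(X, k=2, stream=rng)
        assert np.allclose(np.max(part.memberships, axis=1), 1.0)

    def test_objective_decreases_on_random_data(self):
        # the implementation asserts monotonicity internally every iteration
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            fuzzy_cmeans(rng.normal(size=(30, 3)), k=3, stream=rng)

    def test_feature_permutation_equivariance(self):
        X = two_blobs()
        perm = [1, 0]
        p1 = fuzzy_cmeans(X, k=2, stream=np.random.default_rng(5))
        p2 = fuzzy_cmeans(X[:, perm], k=2, stream=np.random.default_rng(5))
        assert np.allclose(p1.memberships, p2.memberships, atol=1e-9)
        assert np.allclose(p1.centers[:, perm], p2.centers, atol=1e-9)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            fuzzy_cmeans(np.zeros((2, 3)), k=3, stream=rng)

    def test_fuzzifier_must_exceed_one(self, rng):
        with pytest.raises(ValueError):
            fuzzy_cmeans(np.zeros((5, 3)), k=2, m=1.0, stream=rng)

    def test_agrees_with_fixed_point_oracle(self):
        """On tiny well-separated instances the converged memberships match
        an independently coded fixed-point iteration within 1e-6."""
        rng = np.random.default_rng(77)
        for _ in range(5):
            X = np.vstack([rng.normal(0, 0.3, (4, 2)),
                           rng.normal(8, 0.3, (4, 2))])
            part = fuzzy_cmeans(X, k=2, m=2.0, tol=1e-10, restarts=3,
                                stream=rng)
            u_oracle, c_oracle = _fcm_oracle(X, k=2, m=2.0)
            # align oracle clusters to implementation clusters by centers
            order = [int(np.argmin(np.sum((c_oracle - c) ** 2, axis=1)))
                     for c in part.centers]
            assert sorted(order) == [0, 1]
            assert np.allclose(part.memberships, u_oracle[:, order], atol=1e-6)


def _fcm_oracle(X, k, m, iters=500):
    """Brute-force fixed-point iteration with plain loops (independent of the
    vectorized implementation); init centers on the first/last points."""
    n, d = X.shape
    centers = np.array([X[0], X[-1]], dtype=float)
    u = np.zeros((n, k))
    for _ in range(iters):
        for i in range(n):
            dists = [sum((X[i, j] - centers[c, j]) ** 2 for j in range(d))
                     for c in range(k)]
            if min(dists) == 0.0:
                u[i] = 0.0
                u[i][int(np.argmin(dists))] = 1.0
                continue
            for c in range(k):
                u[i, c] = 1.0 / sum((dists[c] / dists[cc]) ** (1.0 / (m - 1.0))
                                    for cc in range(k))
        for c in range(k):
            w = u[:, c] ** m
            centers[c] = (w[:, None] * X).sum(axis=0) / w.sum()
    return u, centers


def make_fm(conditions, sid_per_row=None):
    n = len(conditions)
    ids = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "stimulus_id": sid_per_row or [f"s{i}" for i in range(n)],
        "condition": conditions,
    })
    return FeatureMatrix(ids=ids, X=np.zeros((n, 3)))


def one_hot(labels, k=3):
    u = np.zeros((len(labels), k))
    u[np.arange(len(labels)), labels] = 1.0
    return u


class TestMatching:
    def test_perfect_separation_is_100(self):
        conds = ["negative"] * 3 + ["neutral"] * 3 + ["positive"] * 3
        part = FuzzyPartition(one_hot([0] * 3 + [1] * 3 + [2] * 3),
                              np.zeros((3, 3)), 0.0, 1, True)
        out = match_and_correspondence(part, make_fm(conds))
        assert out.correspondence == 100.0

    def test_one_of_ten_misassigned_is_90(self):
        conds = ["negative"] * 4 + ["neutral"] * 3 + ["positive"] * 3
        labels = [0, 0, 0, 1, 1, 1, 1, 2, 2, 2]  # first cluster loses one row
        part = FuzzyPartition(one_hot(labels), np.zeros((3, 3)), 0.0, 1, True)
        out = match_and_correspondence(part, make_fm(conds))
        assert out.correspondence == pytest.approx(90.0)

    def test_invariant_under_cluster_relabeling(self):
        conds = ["negative"] * 4 + ["neutral"] * 3 + ["positive"] * 3
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2])
        u = one_hot(labels)
        perm = np.array([2, 0, 1])
        u_relab = u[:, np.argsort(perm)]
        a = match_and_correspondence(
            FuzzyPartition(u, np.zeros((3, 3)), 0.0, 1, True), make_fm(conds))
        b = match_and_correspondence(
            FuzzyPartition(u_relab, np.zeros((3, 3)), 0.0, 1, True), make_fm(conds))
        assert a.correspondence == b.correspondence

    def test_k_condition_mismatch_rejected(self):
        part = FuzzyPartition(one_hot([0, 1, 1], k=2), np.zeros((2, 3)), 0.0, 1, True)
        with pytest.raises(ValueError):
            match_and_correspondence(
                part, make_fm(["negative", "neutral", "positive"]))


class TestSeparability:
    def _screen(self, memberships, conds, sids, rng):
        n = len(conds)
        ids = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "stimulus_id": sids,
            "condition": conds})
        fm = FeatureMatrix(ids=ids, X=np.zeros((n, 3)))
        part = FuzzyPartition(memberships, np.zeros((3, 3)), 0.0, 1, True,
                              cluster_to_condition={0: "negative", 1: "neutral",
                                                    2: "positive"})
        bundle = RatingBundle([StimulusMeta(s, c, 40) for s, c in
                               dict(zip(sids, conds)).items()], [], [])
        bundle.config.n_boot = 1000
        return affiliation_separability(part, fm, bundle, stream=rng)

    def test_unanimous_membership_never_screened(self, rng):
        conds = ["negative"] * 5
        u = one_hot([0] * 5)
        df = self._screen(u, conds, ["s1"] * 5, rng)
        assert df.empty  # no misassigned participant, nothing to screen

    def test_overlapping_probabilities_flagged(self, rng):
        # true-cluster ~0.50, competing cluster ~0.45, with jitter wide
        # enough that some participants misassign and the CIs overlap
        jitter = np.linspace(-0.12, 0.12, 13)
        true_p = 0.50 + jitter
        off_p = 0.45 - jitter
        rest = 1.0 - true_p - off_p
        u = np.column_stack([true_p, off_p, rest])
        df = self._screen(u, ["negative"] * 13, ["s1"] * 13, rng)
        assert not df.empty
        assert df["flagged"].all()

    def test_clear_majority_not_flagged(self, rng):
        u = np.column_stack([np.full(13, 0.95), np.full(13, 0.03),
                             np.full(13, 0.02)])
        u[0] = [0.10, 0.85, 0.05]  # single misassignment, but CIs far apart
        df = self._screen(u, ["negative"] * 13, ["s1"] * 13, rng)
        assert not df.empty
        assert not df["flagged"].any()

    def test_single_rater_warns_degenerate(self, rng):
        u = np.array([[0.2, 0.7, 0.1]])
        with pytest.warns(UserWarning, match="single rater"):
            df = self._screen(u, ["negative"], ["s1"], rng)
        assert len(df) == 3
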