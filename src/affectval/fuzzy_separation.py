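"""Fuzzy c-means separability diagnostics in valence–arousal–dominance space.

Each rated (participant, stimulus) pair contributes one z-scored feature
triplet (trimmed valence mean, trimmed arousal mean, dominance).  Soft
clustering with the Bezdek fuzzy c-means objective

    J = sum_i sum_k  u_ik^m * ||x_k - v_i||^2,     sum_i u_ik = 1,

yields per-point membership probabilities.  Clusters are matched to the three
stimulus conditions by majority vote (with an exhaustive-bijection fallback),
giving a correspondence rate; stimuli that are misassigned for at least one
participant are then screened with bootstrapped membership-probability CIs:
if an off-cluster CI reaches up to the true cluster's lower CI bound, the
stimulus is flagged as poorly separated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .continuous_summary import BootSummary, bootstrap_mean_ci, participant_stimulus_means
from .rating_model import RatingBundle

__all__ = [
    "FeatureMatrix",
    "FuzzyPartition",
    "MissingFeatureError",
    "ZeroVarianceError",
    "UnresolvedMatchingError",
    "build_feature_matrix",
    "fuzzy_cmeans",
    "match_and_correspondence",
    "affiliation_separability",
]


class MissingFeatureError(ValueError):
    """A rated (participant, stimulus) pair lacks one of the three features."""


class ZeroVarianceError(ValueError):
    """A feature column is constant and cannot be z-scored."""


class UnresolvedMatchingError(ValueError):
    """Cluster-to-condition matching is ambiguous (tied majorities and tied
    bijections); reported rather than broken silently."""


@dataclass
class FeatureMatrix:
    """Rows of (participant, stimulus, condition) with a 3-D feature triplet."""

    ids: pd.DataFrame  # columns participant_id, stimulus_id, condition
    X: np.ndarray  # (n, 3), z-scored when standardized
    feature_names: tuple[str, ...] = ("valence", "arousal", "dominance")
    standardized: bool = True

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class FuzzyPartition:
    memberships: np.ndarray  # (n, k), rows sum to 1
    centers: np.ndarray  # (k, n_features)
    objective: float
    n_iter: int
    converged: bool
    cluster_to_condition: dict[int, str] | None = None
    correspondence: float | None = None  # percent of rows correctly mapped

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def build_feature_matrix(bundle: RatingBundle) -> FeatureMatrix:
    """One z-scored row per rated (participant, stimulus).

    Standardization uses the population SD pooled over all rows per column.
    """
    frames = {}
    for scale in ("valence", "arousal", "dominance"):
        pm = participant_stimulus_means(bundle, scale)
        frames[scale] = pm.set_index(["participant_id", "stimulus_id"])
    base = frames["valence"].rename(columns={"value": "valence"})
    base["arousal"] = frames["arousal"]["value"]
    base["dominance"] = frames["dominance"]["value"]
    missing = base.index[base[["arousal", "dominance"]].isna().any(axis=1)]
    if len(missing):
        raise MissingFeatureError(
            "missing arousal/dominance for: "
            + ", ".join(map(str, missing.tolist()[:10])))
    base = base.reset_index().sort_values(
        ["participant_id", "stimulus_id"], ignore_index=True)
    X = base[["valence", "arousal", "dominance"]].to_numpy(dtype=float)
    sd = X.std(axis=0)  # population convention
    if np.any(sd == 0):
        bad = [n for n, s in zip(("valence", "arousal", "dominance"), sd) if s == 0]
        raise ZeroVarianceError(f"constant feature column(s): {bad}")
    X = (X - X.mean(axis=0)) / sd
    ids = base[["participant_id", "stimulus_id", "condition"]]
    return FeatureMatrix(ids=ids, X=X)


# ---------------------------------------------------------------------------
# fuzzy c-means


def _update_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)) with the
    zero-distance convention: a point coinciding with a center gets
    membership 1 there."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    zero_rows = np.isinf(inv).any(axis=1)
    if zero_rows.any():
        u[zero_rows] = 0.0
        u[zero_rows, np.argmin(d2[zero_rows], axis=1)] = 1.0
    return u


def fuzzy_cmeans(
    X: FeatureMatrix | np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    restarts: int = 5,
    stream: np.random.Generator | None = None,
) -> FuzzyPartition:
    """Fuzzy c-means with random-membership initialization and restarts.

    Alternates the center and membership updates of the weighted-least-squares
    objective; the objective is asserted non-increasing every iteration.
    Convergence: ``max |u_new - u| < tol``.  The restart with the lowest final
    objective wins.
    """
    data = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n = data.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    if m <= 1.0:
        raise ValueError("fuzzifier m must exceed 1")
    if stream is None:
        stream = np.random.default_rng()

    best: FuzzyPartition | None = None
    for _ in range(restarts):
        u = stream.random((n, k))
        u /= u.sum(axis=1, keepdims=True)
        prev_obj = np.inf
        converged = False
        for it in range(1, max_iter + 1):
            um = u ** m
            centers = (um.T @ data) / um.sum(axis=0)[:, None]
            d2 = cdist(data, centers, metric="sqeuclidean")
            u_new = _update_memberships(d2, m)
            obj = float(((u_new ** m) * d2).sum())
            if obj > prev_obj + 1e-9 * max(1.0, abs(prev_obj)):
                raise AssertionError(
                    f"fuzzy c-means objective increased: {prev_obj} -> {obj}")
            delta = float(np.max(np.abs(u_new - u)))
            u = u_new
            prev_obj = obj
            if delta < tol:
                converged = True
                break
        cand = FuzzyPartition(memberships=u, centers=centers,
                              objective=prev_obj, n_iter=it, converged=converged)
        if best is None or cand.objective < best.objective:
            best = cand
    return best


def match_and_correspondence(
    partition: FuzzyPartition, X: FeatureMatrix
) -> FuzzyPartition:
    """Map clusters to conditions and score the agreement.

    Hard labels are argmax memberships.  Each cluster maps to the majority
    condition of its members; if that map is not a bijection (or a cluster's
    majority is tied), the bijection maximizing total agreement over all k!
    assignments is used instead.  ``correspondence`` is the percentage of rows
    whose mapped condition equals the a-priori condition.
    """
    conditions = sorted(X.ids["condition"].unique())
    k = partition.memberships.shape[1]
    if k != len(conditions):
        raise ValueError(
            f"k={k} clusters but {len(conditions)} conditions present")
    hard = partition.hard_labels
    true = X.ids["condition"].to_numpy()

    majority: dict[int, str] = {}
    tied = False
    for c in range(k):
        members = true[hard == c]
        if members.size == 0:
            tied = True
            break
        vals, counts = np.unique(members, return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        if len(winners) > 1:
            tied = True
            break
        majority[c] = str(winners[0])

    if not tied and len(set(majority.values())) == k:
        mapping = majority
    else:
        # exhaustive best-agreement bijection over the k! assignments
        scores = []
        for perm in itertools.permutations(conditions):
            mapped = np.array([perm[c] for c in hard])
            scores.append((int((mapped == true).sum()), perm))
        best_score = max(s for s, _ in scores)
        winners_ = [perm for s, perm in scores if s == best_score]
        if len(winners_) > 1:
            raise UnresolvedMatchingError(
                "tied majority within a cluster and tied best bijections; "
                f"candidates: {winners_}")
        mapping = dict(enumerate(winners_[0]))

    mapped = np.array([mapping[c] for c in hard])
    corr = 100.0 * float((mapped == true).mean())
    return FuzzyPartition(
        memberships=partition.memberships,
        centers=partition.centers,
        objective=partition.objective,
        n_iter=partition.n_iter,
        converged=partition.converged,
        cluster_to_condition=mapping,
        correspondence=corr,
    )


# ---------------------------------------------------------------------------
# CI-overlap separability screen


def affiliation_separability(
    partition: FuzzyPartition,
    X: FeatureMatrix,
    bundle: RatingBundle,
    n_boot: int | None = None,
    ci_level: float | None = None,
    stream: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Membership-probability screen for stimuli misassigned at least once.

    For every stimulus with >= 1 misassigned participant rating, bootstrap
    (across that stimulus's raters) the mean membership probability for each
    cluster.  The lower CI bound of the true cluster's probability acts as a
    threshold: if any other cluster's upper CI bound reaches it, the stimulus
    is flagged as less clearly differentiated from neighbouring clusters.

    Returns a tidy frame with one row per (stimulus, cluster) and a
    stimulus-level ``flagged`` column.
    """
    if partition.cluster_to_condition is None:
        raise ValueError("partition must be matched to conditions first")
    cfg = bundle.config
    n_boot = cfg.n_boot if n_boot is None else n_boot
    ci_level = cfg.ci_level if ci_level is None else ci_level
    if stream is None:
        stream = np.random.default_rng()

    cond_to_cluster = {v: c for c, v in partition.cluster_to_condition.items()}
    hard = partition.hard_labels
    mapping = partition.cluster_to_condition
    mapped = np.array([mapping[c] for c in hard])
    true = X.ids["condition"].to_numpy()
    mis_by_stim = pd.Series(mapped != true).groupby(
        X.ids["stimulus_id"].to_numpy()).any()

    k = partition.memberships.shape[1]
    rows = []
    for sid in mis_by_stim.index[mis_by_stim]:
        mask = (X.ids["stimulus_id"] == sid).to_numpy()
        condition = str(true[mask][0])
        true_cluster = cond_to_cluster[condition]
        n_raters = int(mask.sum())
        if n_raters == 1:
            warnings.warn(
                f"stimulus {sid!r} has a single rater; separability computed "
                "on point values (degenerate CI)", UserWarning, stacklevel=2)
        summaries: dict[int, BootSummary] = {}
        for c in range(k):
            vals = partition.memberships[mask, c]
            summaries[c] = bootstrap_mean_ci(vals, n_boot, ci_level, stream)
        threshold = summaries[true_cluster].ci_low
        flagged = any(
            summaries[c].ci_high >= threshold for c in range(k) if c != true_cluster
        )
        for c in range(k):
            s = summaries[c]
            rows.append({
                "stimulus_id": sid,
                "condition": condition,
                "cluster": c,
                "cluster_condition": mapping[c],
                "is_true_cluster": c == true_cluster,
                "n_raters": n_raters,
                "prob_mean": s.mean,
                "prob_ci_low": s.ci_low,
                "prob_ci_high": s.ci_high,
                "flagged": flagged,
            })
    columns = ["stimulus_id", "condition", "cluster", "cluster_condition",
               "is_true_cluster", "n_raters", "prob_mean", "prob_ci_low",
               "prob_ci_high", "flagged"]
    return pd.DataFrame(rows, columns=columns)
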