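"""Polarity scores and choice frequencies for the discrete emotion ratings.

Participants pick one of six basic emotions and one Geneva Emotion Wheel (GEW)
category (with a 1–6 intensity) after each stimulus.  Each category carries a
polarity; per participant and stimulus this yields

* ``pos_basic`` / ``neg_basic``: 0/1 indicators of the basic-emotion polarity
  (they sum to 1 — the choice is forced and the polarity map is exhaustive);
* ``pos_gew`` / ``neg_gew``: the GEW intensity if the chosen category has that
  polarity, else 0 (intensity-weighted polarity scores on [0, 6]);
* ``gew_strength``: the intensity regardless of polarity.

Per stimulus the scores are bootstrapped across participants; per condition
the grand average over stimuli is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .continuous_summary import bootstrap_mean_ci
from .rating_model import BASIC_EMOTIONS, GEW_EMOTIONS, RatingBundle

__all__ = ["PolarityMap", "polarity_scores", "normalized_frequencies",
           "participant_scores"]

SCORE_COLUMNS = ("neg_basic", "pos_basic", "neg_gew", "pos_gew", "gew_strength")


@dataclass(frozen=True)
class PolarityMap:
    """Which categories count as positive vs. negative in each system."""

    gew_positive: frozenset = frozenset(
        {"interest", "joy", "pleasure", "satisfaction", "amusement",
         "compassion", "pride", "relief"})
    gew_negative: frozenset = frozenset(
        {"fear", "disgust", "hatred", "anger", "disappointment", "sadness",
         "contempt", "shame", "guilt", "regret"})
    basic_positive: frozenset = frozenset({"joy", "surprise"})
    basic_negative: frozenset = frozenset({"sadness", "fear", "disgust", "anger"})

    def __post_init__(self) -> None:
        if self.gew_positive & self.gew_negative:
            raise ValueError("GEW polarity sets overlap")
        if self.basic_positive & self.basic_negative:
            raise ValueError("basic polarity sets overlap")
        if self.gew_positive | self.gew_negative != set(GEW_EMOTIONS):
            raise ValueError("GEW polarity sets must cover the GEW categories")
        if self.basic_positive | self.basic_negative != set(BASIC_EMOTIONS):
            raise ValueError("basic polarity sets must cover the basic emotions")


def participant_scores(
    bundle: RatingBundle, pmap: PolarityMap | None = None
) -> pd.DataFrame:
    """Per (participant, stimulus) raw polarity scores (tidy frame)."""
    pmap = pmap or PolarityMap()
    cond = bundle.condition_of()
    rows = []
    for p in bundle.post:
        pos_b = 1.0 if p.basic_emotion in pmap.basic_positive else 0.0
        gew_pos = p.gew_emotion in pmap.gew_positive
        rows.append({
            "participant_id": p.participant_id,
            "stimulus_id": p.stimulus_id,
            "condition": cond[p.stimulus_id],
            "neg_basic": 1.0 - pos_b,
            "pos_basic": pos_b,
            "neg_gew": 0.0 if gew_pos else float(p.gew_intensity),
            "pos_gew": float(p.gew_intensity) if gew_pos else 0.0,
            "gew_strength": float(p.gew_intensity),
        })
    return pd.DataFrame(rows)


def polarity_scores(
    bundle: RatingBundle,
    stream: np.random.Generator,
    pmap: PolarityMap | None = None,
    n_boot: int | None = None,
    ci_level: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrapped per-stimulus polarity scores plus condition averages.

    Returns ``(stimulus_rows, condition_rows)``; the stimulus frame has one
    row per stimulus x score with mean and CI, the condition frame the
    unweighted grand average of its stimuli's means.
    """
    cfg = bundle.config
    n_boot = cfg.n_boot if n_boot is None else n_boot
    ci_level = cfg.ci_level if ci_level is None else ci_level
    raw = participant_scores(bundle, pmap)
    if raw.empty:
        raise ValueError("no post-presentation ratings")
    rows = []
    for (sid, condition), grp in raw.groupby(["stimulus_id", "condition"], sort=True):
        for score in SCORE_COLUMNS:
            s = bootstrap_mean_ci(grp[score].to_numpy(), n_boot, ci_level, stream)
            rows.append({"stimulus_id": sid, "condition": condition,
                         "score": score, "n_raters": len(grp),
                         "mean": s.mean, "ci_low": s.ci_low, "ci_high": s.ci_high})
    stim_df = pd.DataFrame(rows)
    cond_df = (
        stim_df.groupby(["condition", "score"], sort=True)["mean"]
        .mean().rename("grand_mean").reset_index()
    )
    return stim_df, cond_df


def normalized_frequencies(
    bundle: RatingBundle, system: str, mode: str = "proportion"
) -> pd.DataFrame:
    """Per-stimulus choice frequencies normalized to [0, 1].

    ``system`` is ``"basic"`` or ``"gew"``.  With ``mode="proportion"``
    (default) counts are divided by the number of raters, so frequencies sum
    to 1 per stimulus; ``mode="max"`` divides by the most frequent category's
    count instead (radar-chart style scaling, maximum exactly 1).
    """
    if system == "basic":
        categories, attr = BASIC_EMOTIONS, "basic_emotion"
    elif system == "gew":
        categories, attr = GEW_EMOTIONS, "gew_emotion"
    else:
        raise ValueError(f"unknown system {system!r}")
    post = bundle.post_frame()
    if post.empty:
        raise ValueError("no post-presentation ratings")
    counts = (
        post.groupby(["stimulus_id", attr], sort=True).size().unstack(fill_value=0)
        .reindex(columns=list(categories), fill_value=0)
    )
    if mode == "proportion":
        freq = counts.div(counts.sum(axis=1), axis=0)
    elif mode == "max":
        freq = counts.div(counts.max(axis=1), axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    freq.columns.name = None
    return freq.reset_index()
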