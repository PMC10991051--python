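"""Monte-Carlo subtractive pairwise discrimination against the neutral set.

Every emotional (negative or positive) stimulus is paired with every neutral
stimulus.  For each pair and affective scale, ratings are drawn with
replacement from the two stimuli's rating pools, the neutral draw is
subtracted from the emotional draw, and the fraction of draws contradicting
the hypothesized ordering is the pair's violation rate:

* valence: negative < neutral < positive;
* arousal and dominance: emotional > neutral.

Ties count as violations by default (failure to separate is failure to
discriminate); a strict-inequality mode is available.  Pairs whose violation
rate exceeds the threshold (default 20%) are flagged, and stimuli are ranked
by how many flagged pairs they participate in — the top of the ranking are
candidates for removal when a maximally distinct subset is wanted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .continuous_summary import participant_stimulus_means, trim_adaptation
from .rating_model import RatingBundle, StimulusMeta

__all__ = [
    "EMOTIONAL_ABOVE", "EMOTIONAL_BELOW",
    "assumed_direction", "enumerate_pairs", "violation_rate",
    "pair_comparisons", "flag_and_rank",
]

EMOTIONAL_ABOVE = "emotional_above_neutral"
EMOTIONAL_BELOW = "emotional_below_neutral"

MCS_SCALES = ("valence", "arousal", "dominance")


def assumed_direction(scale: str, emotional_condition: str) -> str:
    """Hypothesized ordering of an emotional stimulus vs. a neutral one."""
    if emotional_condition not in ("negative", "positive"):
        raise ValueError(f"{emotional_condition!r} is not an emotional condition")
    if scale == "valence":
        return EMOTIONAL_BELOW if emotional_condition == "negative" else EMOTIONAL_ABOVE
    if scale in ("arousal", "dominance"):
        return EMOTIONAL_ABOVE
    raise ValueError(f"unknown scale {scale!r}")


def enumerate_pairs(manifest: list[StimulusMeta]) -> pd.DataFrame:
    """Cartesian product of emotional x neutral stimuli with subset labels."""
    neutral = [m.stimulus_id for m in manifest if m.condition == "neutral"]
    if not neutral:
        raise ValueError("no neutral stimuli: nothing to compare against")
    rows = [
        {"emotional_id": m.stimulus_id, "neutral_id": nid,
         "subset": f"{m.condition}-neutral",
         "emotional_condition": m.condition}
        for m in manifest if m.condition in ("negative", "positive")
        for nid in neutral
    ]
    return pd.DataFrame(
        rows, columns=["emotional_id", "neutral_id", "subset",
                       "emotional_condition"])


def violation_rate(
    emotional_values,
    neutral_values,
    direction: str,
    n_draws: int,
    stream: np.random.Generator,
    ties_violate: bool = True,
) -> float:
    """Fraction of subtractive Monte-Carlo draws contradicting ``direction``.

    Draws ``n_draws`` values with replacement independently from each pool and
    forms ``neutral - emotional``; for :data:`EMOTIONAL_ABOVE` a non-negative
    difference is a violation, for :data:`EMOTIONAL_BELOW` a non-positive one
    (strict comparisons if ``ties_violate`` is False).
    """
    e = np.asarray(emotional_values, dtype=float)
    nv = np.asarray(neutral_values, dtype=float)
    if e.size == 0 or nv.size == 0:
        raise ValueError("empty rating pool")
    e_draw = e[stream.integers(0, e.size, n_draws)]
    n_draw = nv[stream.integers(0, nv.size, n_draws)]
    diff = n_draw - e_draw
    if direction == EMOTIONAL_ABOVE:
        viol = diff >= 0 if ties_violate else diff > 0
    elif direction == EMOTIONAL_BELOW:
        viol = diff <= 0 if ties_violate else diff < 0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(viol.mean())


def _pools(bundle: RatingBundle, scale: str, mode: str) -> dict[str, np.ndarray]:
    """Rating pool per stimulus for one scale.

    ``participant_means`` (default): per-participant trimmed series means
    (valence/arousal) or post ratings (dominance).  ``timepoints``: the raw
    trimmed per-second samples pooled over participants (continuous scales
    only).
    """
    if mode == "participant_means" or scale == "dominance":
        pm = participant_stimulus_means(bundle, scale)
        return {sid: grp["value"].to_numpy()
                for sid, grp in pm.groupby("stimulus_id")}
    if mode == "timepoints":
        trim = bundle.config.trim_seconds
        pools: dict[str, list[np.ndarray]] = {}
        for s in bundle.continuous:
            if s.scale == scale:
                pools.setdefault(s.stimulus_id, []).append(
                    trim_adaptation(s, trim).values)
        return {sid: np.concatenate(parts) for sid, parts in pools.items()}
    raise ValueError(f"unknown sampling mode {mode!r}")


def pair_comparisons(
    bundle: RatingBundle,
    stream: np.random.Generator,
    n_draws: int | None = None,
    threshold: float | None = None,
    mode: str = "participant_means",
    ties_violate: bool = True,
) -> pd.DataFrame:
    """Violation rate for every emotional-neutral pair on every scale."""
    cfg = bundle.config
    n_draws = cfg.mcs_draws if n_draws is None else n_draws
    threshold = cfg.mcs_threshold if threshold is None else threshold
    pairs = enumerate_pairs(bundle.manifest)
    rows = []
    for scale in MCS_SCALES:
        pools = _pools(bundle, scale, mode)
        for pair in pairs.itertuples():
            direction = assumed_direction(scale, pair.emotional_condition)
            rate = violation_rate(pools[pair.emotional_id],
                                  pools[pair.neutral_id],
                                  direction, n_draws, stream, ties_violate)
            rows.append({
                "emotional_id": pair.emotional_id,
                "neutral_id": pair.neutral_id,
                "subset": pair.subset,
                "scale": scale,
                "assumed_direction": direction,
                "violation_rate": rate,
                "n_draws": n_draws,
                "flagged": rate > threshold,
            })
    return pd.DataFrame(rows)


def flag_and_rank(
    comparisons: pd.DataFrame, threshold: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scale flagged fraction and per-stimulus removal ranking.

    A stimulus is ranked by the number of flagged pairs it participates in
    (primary key) and its maximum violation rate (tie-break), descending; the
    head of the ranking lists the removal candidates.
    """
    if comparisons.empty:
        raise ValueError("no comparisons to summarise")
    df = comparisons.copy()
    df["flagged"] = df["violation_rate"] > threshold
    summary = (
        df.groupby("scale", sort=True)
        .agg(n_pairs=("flagged", "size"), n_flagged=("flagged", "sum"),
             flagged_fraction=("flagged", "mean"))
        .reset_index()
    )
    long = pd.concat([
        df.rename(columns={"emotional_id": "stimulus_id"})[
            ["scale", "stimulus_id", "violation_rate", "flagged"]],
        df.rename(columns={"neutral_id": "stimulus_id"})[
            ["scale", "stimulus_id", "violation_rate", "flagged"]],
    ])
    ranking = (
        long.groupby(["scale", "stimulus_id"], sort=True)
        .agg(n_flagged_pairs=("flagged", "sum"),
             max_violation_rate=("violation_rate", "max"))
        .reset_index()
    )
    ranking = ranking[ranking["n_flagged_pairs"] > 0].sort_values(
        ["scale", "n_flagged_pairs", "max_violation_rate"],
        ascending=[True, False, False], ignore_index=True)
    return summary, ranking
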