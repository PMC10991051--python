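"""Adaptation trimming and bootstrapped summaries of continuous ratings.

During roughly the first 30 s of a stimulus, listeners orient themselves and
start moving the slider away from its midpoint start; that adaptation phase is
removed before any per-stimulus summary.  All confidence intervals are plain
percentile bootstrap intervals across participants: resample the participants
with replacement, recompute the mean, take the empirical 2.5th/97.5th
percentiles (at the default 95% level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rating_model import ContinuousSeries, RatingBundle, SCALES

__all__ = [
    "BootSummary",
    "TooShortError",
    "UndefinedCorrelationError",
    "trim_adaptation",
    "bootstrap_mean_ci",
    "timepoint_summary",
    "stimulus_summary",
    "participant_stimulus_means",
    "rating_correlation",
    "position_correlation",
    "familiarity_correlations",
]


class TooShortError(ValueError):
    """Series shorter than (or equal to) the trimming window."""


class UndefinedCorrelationError(ValueError):
    """Correlation requested on a zero-variance input."""


@dataclass(frozen=True)
class BootSummary:
    """Mean with a percentile-bootstrap confidence interval."""

    mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float


def trim_adaptation(series: ContinuousSeries, trim_seconds: int) -> ContinuousSeries:
    """Drop samples with t < trim_seconds (an index slice at 1 Hz)."""
    if len(series.values) <= trim_seconds:
        raise TooShortError(
            f"series ({series.participant_id}, {series.stimulus_id}, "
            f"{series.scale}) has {len(series.values)} samples, cannot trim "
            f"{trim_seconds} s")
    return ContinuousSeries(series.participant_id, series.stimulus_id,
                            series.scale, series.values[trim_seconds:])


def bootstrap_mean_ci(
    values,
    n_boot: int,
    ci_level: float,
    stream: np.random.Generator,
) -> BootSummary:
    """Percentile bootstrap CI of the mean of ``values``.

    The point estimate is the plain arithmetic mean; only the interval is
    resampled (size-n draws with replacement).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("bootstrap_mean_ci: empty input")
    mean = float(values.mean())
    if n == 1:
        return BootSummary(mean, mean, mean, n_boot, ci_level)
    idx = stream.integers(0, n, size=(n_boot, n))
    boot_means = values[idx].mean(axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(boot_means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootSummary(mean, float(lo), float(hi), n_boot, ci_level)


# ---------------------------------------------------------------------------
# per-second summaries


def timepoint_summary(
    bundle: RatingBundle,
    scale: str,
    stimulus_id: str,
    stream: np.random.Generator,
    n_boot: int | None = None,
) -> pd.DataFrame:
    """Bootstrapped mean across participants at every second.

    Seconds past the end of some participants' series use the raters still
    available (their count is reported in ``n``); no trimming is applied, so
    the adaptation phase is visible in the output.
    """
    cfg = bundle.config
    n_boot = cfg.n_boot if n_boot is None else n_boot
    series = bundle.series(scale, stimulus_id)
    if not series:
        raise ValueError(f"no raters for stimulus {stimulus_id!r} on {scale}")
    if len(series) < 2:
        raise ValueError(
            f"timepoint summary needs >= 2 raters for {stimulus_id!r} on {scale}")
    lengths = np.array([len(s.values) for s in series])
    t_max = int(lengths.max())
    mat = np.full((len(series), t_max), np.nan)
    for i, s in enumerate(series):
        mat[i, : len(s.values)] = s.values

    rows = []
    # available-rater set only shrinks at length boundaries; one vectorized
    # bootstrap per block keeps the cost independent of stimulus duration
    boundaries = np.unique(np.concatenate([[0], lengths, [t_max]]))
    alpha = 1.0 - cfg.ci_level
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        if start >= t_max:
            break
        avail = np.where(lengths > start)[0]
        block = mat[np.ix_(avail, np.arange(start, stop))]
        n = len(avail)
        means = block.mean(axis=0)
        if n > 1:
            # chunked to bound the (chunk, n, T) intermediate's memory
            boot_parts = []
            remaining = n_boot
            while remaining > 0:
                chunk = min(remaining, 500)
                idx = stream.integers(0, n, size=(chunk, n))
                boot_parts.append(block[idx].mean(axis=1))
                remaining -= chunk
            boot = np.concatenate(boot_parts, axis=0)  # (n_boot, T)
            lo, hi = np.percentile(boot, qs, axis=0)
        else:
            lo = hi = means
        for j, t in enumerate(range(start, stop)):
            rows.append({"t_s": t, "n": n, "mean": means[j],
                         "ci_low": lo[j], "ci_high": hi[j]})
    df = pd.DataFrame(rows)
    df.insert(0, "scale", scale)
    df.insert(0, "stimulus_id", stimulus_id)
    return df


# ---------------------------------------------------------------------------
# per-stimulus summaries


def participant_stimulus_means(bundle: RatingBundle, scale: str) -> pd.DataFrame:
    """Trimmed per-participant series means (valence/arousal) or post values
    (dominance/familiarity) as a tidy frame.

    Columns: participant_id, stimulus_id, condition, value.
    """
    cond = bundle.condition_of()
    rows = []
    if scale in SCALES:
        trim = bundle.config.trim_seconds
        for s in bundle.continuous:
            if s.scale != scale:
                continue
            trimmed = trim_adaptation(s, trim)
            rows.append((s.participant_id, s.stimulus_id,
                         cond[s.stimulus_id], float(trimmed.values.mean())))
    elif scale in ("dominance", "familiarity"):
        for p in bundle.post:
            v = getattr(p, scale)
            if not np.isnan(v):
                rows.append((p.participant_id, p.stimulus_id,
                             cond[p.stimulus_id], float(v)))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return pd.DataFrame(rows, columns=["participant_id", "stimulus_id",
                                       "condition", "value"])


def stimulus_summary(
    bundle: RatingBundle,
    stream: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrapped grand mean and within-series-SD summary per stimulus.

    For valence and arousal the unit of observation is the participant's mean
    over the trimmed series (average within participant first, then bootstrap
    across participants); ``sd_*`` columns summarise the per-participant SD of
    the series over time, a consistency measure.  Dominance comes from the
    post-presentation rating, so no over-time SD exists for it.

    Returns ``(stimulus_rows, condition_rows)``; the per-condition grand
    average is the unweighted mean of its stimuli's grand means.
    """
    cfg = bundle.config
    trim = cfg.trim_seconds
    cond = bundle.condition_of()
    rows = []
    for scale in ("valence", "arousal", "dominance"):
        pm = participant_stimulus_means(bundle, scale)
        sds: dict[str, list[float]] = {}
        if scale in SCALES:
            for s in bundle.continuous:
                if s.scale != scale:
                    continue
                trimmed = trim_adaptation(s, trim)
                sds.setdefault(s.stimulus_id, []).append(
                    float(np.std(trimmed.values, ddof=1)))
        for sid, grp in pm.groupby("stimulus_id", sort=True):
            grand = bootstrap_mean_ci(grp["value"].to_numpy(),
                                      cfg.n_boot, cfg.ci_level, stream)
            row = {
                "stimulus_id": sid,
                "condition": cond[sid],
                "scale": scale,
                "n_raters": len(grp),
                "mean": grand.mean,
                "ci_low": grand.ci_low,
                "ci_high": grand.ci_high,
            }
            if scale in SCALES:
                sd = bootstrap_mean_ci(np.asarray(sds[sid]),
                                       cfg.n_boot, cfg.ci_level, stream)
                row.update(sd_mean=sd.mean, sd_ci_low=sd.ci_low,
                           sd_ci_high=sd.ci_high)
            else:
                row.update(sd_mean=np.nan, sd_ci_low=np.nan, sd_ci_high=np.nan)
            rows.append(row)
    stim_df = pd.DataFrame(rows)
    cond_df = (
        stim_df.groupby(["condition", "scale"], sort=True)["mean"]
        .mean()
        .rename("grand_mean")
        .reset_index()
    )
    return stim_df, cond_df


# ---------------------------------------------------------------------------
# correlations


def rating_correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs >= 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def position_correlation(bundle: RatingBundle, scale: str) -> tuple[float, float]:
    """Does the serial position within a session shift the continuous rating?

    Pools (session_position, trimmed series mean) pairs over all participants
    and stimuli for one scale and reports the Pearson correlation.
    """
    pm = participant_stimulus_means(bundle, scale)
    pos = {(p.participant_id, p.stimulus_id): p.session_position
           for p in bundle.post}
    x = [pos[(r.participant_id, r.stimulus_id)] for r in pm.itertuples()]
    return rating_correlation(x, pm["value"].to_numpy(), "pearson")


def familiarity_correlations(bundle: RatingBundle) -> pd.DataFrame:
    """Per condition and scale: Pearson correlation of the affective rating
    with the stimulus familiarity rating (a potential moderator)."""
    fam = participant_stimulus_means(bundle, "familiarity")
    fam_idx = fam.set_index(["participant_id", "stimulus_id"])["value"]
    rows = []
    for scale in ("valence", "arousal", "dominance"):
        pm = participant_stimulus_means(bundle, scale)
        pm = pm.set_index(["participant_id", "stimulus_id"])
        for condition, grp in pm.groupby("condition", sort=True):
            joined = grp.join(fam_idx.rename("familiarity"), how="inner")
            try:
                r, p = rating_correlation(joined["familiarity"],
                                          joined["value"], "pearson")
            except UndefinedCorrelationError:
                r, p = np.nan, np.nan
            rows.append({"scale": scale, "condition": condition,
                         "n": len(joined), "r": r, "p_value": p})
    return pd.DataFrame(rows)
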