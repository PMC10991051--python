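"""Within-subjects inference: rmANOVA, bootstrap contrasts, interrater screen.

The unit of analysis is the participant x condition table in which each cell
is a participant's mean over their rated stimuli of that condition.  The
one-way repeated-measures ANOVA uses the classical decomposition

    SS_total = SS_subjects + SS_effect + SS_error,
    F = (SS_effect / (k-1)) / (SS_error / ((k-1)(n-1))),

with partial eta squared SS_effect / (SS_effect + SS_error) and no sphericity
correction.  Post-hoc contrasts take participant-wise differences per
condition pair and bootstrap the mean; the percentile levels are Bonferroni
adjusted (alpha / m over the m pairwise contrasts), and a contrast is
significant when its CI excludes zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RmAnovaResult", "ContrastResult", "InterraterResult",
    "IncompleteDesignError", "DegenerateFitError",
    "rm_anova", "bootstrap_contrasts", "interrater_screen",
    "condition_table",
]


class IncompleteDesignError(ValueError):
    """Participant x condition table with missing cells."""


class DegenerateFitError(ValueError):
    """SS_error = 0: the F ratio is not finite.

    Carries the sums of squares so callers can report the degenerate fit.
    """

    def __init__(self, msg: str, ss_effect: float, ss_error: float):
        super().__init__(msg)
        self.ss_effect = ss_effect
        self.ss_error = ss_error
        self.F = np.inf if ss_effect > 0 else np.nan


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df_effect: int
    df_error: int
    p_value: float
    partial_eta_sq: float
    n_participants: int
    k_conditions: int
    ss_effect: float
    ss_error: float
    ss_subjects: float


@dataclass(frozen=True)
class ContrastResult:
    condition_a: str
    condition_b: str
    mean_diff: float
    ci_low: float
    ci_high: float
    n_contrasts_corrected_for: int
    significant: bool


@dataclass(frozen=True)
class InterraterResult:
    spearman_rho: float | None
    p_value: float | None
    exact_agreement_fraction: float
    keep: np.ndarray  # boolean per stimulus
    mean_ratings: np.ndarray


def _as_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        if table.isna().any().any():
            missing = [(str(i), str(c)) for i, c in
                       zip(*np.where(table.isna().to_numpy()))]
            raise IncompleteDesignError(f"missing cells at {missing[:5]}")
        return table.to_numpy(dtype=float), [str(c) for c in table.columns]
    arr = np.asarray(table, dtype=float)
    if np.isnan(arr).any():
        raise IncompleteDesignError("missing cells in condition table")
    return arr, [str(j) for j in range(arr.shape[1])]


def rm_anova(table: pd.DataFrame | np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a participants x conditions table."""
    data, _ = _as_matrix(table)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    grand = data.mean()
    ss_effect = n * float(((data.mean(axis=0) - grand) ** 2).sum())
    ss_subjects = k * float(((data.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_error = ss_total - ss_effect - ss_subjects
    ss_error = max(ss_error, 0.0)  # guard tiny negative rounding
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    if ss_error == 0.0:
        raise DegenerateFitError(
            f"SS_error = 0 (SS_effect = {ss_effect:g}); F is "
            + ("infinite" if ss_effect > 0 else "undefined"),
            ss_effect, ss_error)
    F = (ss_effect / df_effect) / (ss_error / df_error)
    p = float(stats.f.sf(F, df_effect, df_error))
    return RmAnovaResult(
        F=float(F), df_effect=df_effect, df_error=df_error, p_value=p,
        partial_eta_sq=ss_effect / (ss_effect + ss_error),
        n_participants=n, k_conditions=k,
        ss_effect=ss_effect, ss_error=ss_error, ss_subjects=ss_subjects)


def bootstrap_contrasts(
    table: pd.DataFrame,
    n_boot: int,
    ci_level: float,
    stream: np.random.Generator,
    bonferroni: bool = True,
) -> list[ContrastResult]:
    """Bootstrap percentile CIs of all pairwise participant-wise differences.

    With ``bonferroni=True`` (default) the per-contrast interval level is
    ``1 - alpha/m`` for m contrasts; otherwise plain ``ci_level`` percentiles
    are used.
    """
    data, names = _as_matrix(table)
    n, k = data.shape
    if n < 2:
        raise ValueError("need at least 2 participants for contrasts")
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    alpha = 1.0 - ci_level
    level_alpha = alpha / m if bonferroni else alpha
    qs = [100 * level_alpha / 2, 100 * (1 - level_alpha / 2)]
    out = []
    for a, b in pairs:
        diffs = data[:, a] - data[:, b]
        idx = stream.integers(0, n, size=(n_boot, n))
        boot = diffs[idx].mean(axis=1)
        lo, hi = np.percentile(boot, qs)
        out.append(ContrastResult(
            condition_a=names[a], condition_b=names[b],
            mean_diff=float(diffs.mean()), ci_low=float(lo), ci_high=float(hi),
            n_contrasts_corrected_for=m if bonferroni else 1,
            significant=not (lo <= 0.0 <= hi)))
    return out


def condition_table(values: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy (participant_id, condition, value) frame into the
    participants x conditions matrix of condition means used by the ANOVA."""
    return values.pivot_table(index="participant_id", columns="condition",
                              values="value", aggfunc="mean")


def interrater_screen(
    rater_a, rater_b, cutoff: float = 6.0
) -> InterraterResult:
    """Preselection screen from two raters' suitability ratings (0–10 scale).

    Reports the Spearman rank correlation between raters, the fraction of
    stimuli rated identically, and a keep/exclude decision per stimulus
    (excluded when the two-rater mean falls below ``cutoff``).  With a
    zero-variance rater the correlation is undefined and returned as ``None``
    (with a warning); agreement and screening are still computed.
    """
    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if a.size != b.size:
        raise ValueError("rater vectors must have equal length")
    if a.size < 3:
        raise ValueError("screen needs >= 3 stimuli")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance in a rater: Spearman rho undefined",
                      UserWarning, stacklevel=2)
        rho, p = None, None
    else:
        res = stats.spearmanr(a, b)
        rho, p = float(res.statistic), float(res.pvalue)
    means = (a + b) / 2.0
    return InterraterResult(
        spearman_rho=rho, p_value=p,
        exact_agreement_fraction=float((a == b).mean()),
        keep=means >= cutoff, mean_ratings=means)
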