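"""Pipeline orchestration: run every analysis stage and assemble the report.

The report answers, per stimulus and per condition, the three validation
questions — differentiation (cluster separability, pairwise discrimination),
salience/strength (rating levels, GEW intensity) and generalizability across
participants (bootstrap CIs, consistency SDs) — and records enough metadata
to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import spawn_streams
from .config import AnalysisConfig
from .continuous_summary import (
    familiarity_correlations,
    participant_stimulus_means,
    position_correlation,
    stimulus_summary,
    timepoint_summary,
)
from .discrete_scores import normalized_frequencies, participant_scores, polarity_scores
from .fuzzy_separation import (
    affiliation_separability,
    build_feature_matrix,
    fuzzy_cmeans,
    match_and_correspondence,
)
from .inferential import (
    DegenerateFitError,
    bootstrap_contrasts,
    condition_table,
    rm_anova,
)
from .mcs_discrimination import flag_and_rank, pair_comparisons
from .rating_model import RatingBundle, validate_bundle

logger = logging.getLogger("affectval")

__all__ = ["ValidationReport", "run_pipeline"]


@dataclass
class ValidationReport:
    stimulus_rows: pd.DataFrame
    condition_rows: pd.DataFrame
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    correspondence: float
    separability: pd.DataFrame
    mcs_summary: pd.DataFrame
    removal_candidates: pd.DataFrame
    correlations: pd.DataFrame
    run_metadata: dict


# analysed with the rmANOVA + contrasts, per the validation design
_ANOVA_QUANTITIES = (
    "valence", "arousal", "dominance", "familiarity",
    "neg_basic", "pos_basic", "neg_gew", "pos_gew", "gew_strength",
    "sd_valence", "sd_arousal",
)


def _participant_condition_values(bundle: RatingBundle, quantity: str) -> pd.DataFrame:
    """Tidy (participant_id, condition, value) frame for one quantity."""
    if quantity in ("valence", "arousal", "dominance", "familiarity"):
        return participant_stimulus_means(bundle, quantity)[
            ["participant_id", "condition", "value"]]
    if quantity.startswith("sd_"):
        scale = quantity[3:]
        from .continuous_summary import trim_adaptation
        cond = bundle.condition_of()
        rows = [
            (s.participant_id, cond[s.stimulus_id],
             float(np.std(trim_adaptation(s, bundle.config.trim_seconds).values,
                          ddof=1)))
            for s in bundle.continuous if s.scale == scale
        ]
        return pd.DataFrame(rows, columns=["participant_id", "condition", "value"])
    raw = participant_scores(bundle)
    return raw[["participant_id", "condition", quantity]].rename(
        columns={quantity: "value"})


def run_pipeline(
    bundle: RatingBundle,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    with_timepoints: bool = False,
) -> ValidationReport:
    """Execute all stages in order and (optionally) write the tables.

    Stage order: continuous summaries -> fuzzy clustering -> Monte-Carlo
    discrimination -> discrete scores -> inference.  ``seed`` overrides the
    bundle config's master seed; each stage gets an independent spawned
    stream.  ``with_timepoints`` additionally writes the (large) per-second
    summary table.
    """
    validate_bundle(bundle)
    cfg = bundle.config
    master_seed = cfg.rng_seed if seed is None else seed
    streams = spawn_streams(master_seed)

    # -- continuous summaries ----------------------------------------------
    stim_df, cond_df = stimulus_summary(bundle, streams["continuous"])
    logger.info("stimulus summary: %d stimuli x scale rows", len(stim_df))

    tp_frames = []
    if with_timepoints:
        for m in bundle.manifest:
            for scale in ("valence", "arousal"):
                tp_frames.append(timepoint_summary(
                    bundle, scale, m.stimulus_id, streams["continuous"]))

    corr_rows = []
    for scale in ("valence", "arousal"):
        r, p = position_correlation(bundle, scale)
        corr_rows.append({"analysis": "session_position", "scale": scale,
                          "condition": "all", "r": r, "p_value": p})
    fam = familiarity_correlations(bundle)
    for row in fam.itertuples():
        corr_rows.append({"analysis": "familiarity", "scale": row.scale,
                          "condition": row.condition, "r": row.r,
                          "p_value": row.p_value})
    correlations = pd.DataFrame(corr_rows)

    # -- fuzzy clustering ----------------------------------------------------
    fm = build_feature_matrix(bundle)
    partition = fuzzy_cmeans(
        fm, k=cfg.fcm_clusters, m=cfg.fcm_fuzzifier, tol=cfg.fcm_tol,
        max_iter=cfg.fcm_max_iter, restarts=cfg.fcm_restarts,
        stream=streams["fuzzy"])
    partition = match_and_correspondence(partition, fm)
    logger.info("cluster-condition correspondence: %.2f%%",
                partition.correspondence)
    separability = affiliation_separability(
        partition, fm, bundle, stream=streams["fuzzy"])

    clusters = fm.ids.copy()
    for c in range(partition.memberships.shape[1]):
        clusters[f"p_cluster{c}_{partition.cluster_to_condition[c]}"] = (
            partition.memberships[:, c])
    clusters["hard_condition"] = [
        partition.cluster_to_condition[c] for c in partition.hard_labels]

    # -- Monte-Carlo discrimination -----------------------------------------
    comparisons = pair_comparisons(bundle, streams["mcs"])
    mcs_summary, removal = flag_and_rank(comparisons, cfg.mcs_threshold)
    for row in mcs_summary.itertuples():
        logger.info("MCS %s: %.1f%% of %d pairs above threshold",
                    row.scale, 100 * row.flagged_fraction, row.n_pairs)

    # -- discrete scores -----------------------------------------------------
    scores_df, scores_cond = polarity_scores(bundle, streams["discrete"])
    freq_basic = normalized_frequencies(bundle, "basic")
    freq_gew = normalized_frequencies(bundle, "gew")

    # -- inference ------------------------------------------------------------
    anova_rows, contrast_rows = [], []
    for quantity in _ANOVA_QUANTITIES:
        values = _participant_condition_values(bundle, quantity)
        table = condition_table(values)
        try:
            res = rm_anova(table)
            anova_rows.append({
                "quantity": quantity, "F": res.F, "df_effect": res.df_effect,
                "df_error": res.df_error, "p_value": res.p_value,
                "partial_eta_sq": res.partial_eta_sq,
                "n_participants": res.n_participants})
            logger.info("rmANOVA %s: F(%d,%d) = %.2f, p = %.3g", quantity,
                        res.df_effect, res.df_error, res.F, res.p_value)
        except DegenerateFitError as err:
            anova_rows.append({
                "quantity": quantity, "F": err.F, "df_effect": np.nan,
                "df_error": np.nan, "p_value": np.nan,
                "partial_eta_sq": np.nan, "n_participants": len(table)})
        for c in bootstrap_contrasts(table, cfg.n_boot, cfg.ci_level,
                                     streams["inferential"]):
            contrast_rows.append({"quantity": quantity, **dataclasses.asdict(c)})
    anova = pd.DataFrame(anova_rows)
    contrasts = pd.DataFrame(contrast_rows)

    # -- assemble stimulus verdict rows ---------------------------------------
    flagged_sep = set(separability.loc[separability["flagged"], "stimulus_id"])
    mcs_long = pd.concat([
        comparisons.rename(columns={"emotional_id": "stimulus_id"})[
            ["scale", "stimulus_id", "violation_rate", "flagged"]],
        comparisons.rename(columns={"neutral_id": "stimulus_id"})[
            ["scale", "stimulus_id", "violation_rate", "flagged"]],
    ])
    mcs_per_stim = (
        mcs_long.groupby("stimulus_id")
        .agg(mcs_flagged_pairs=("flagged", "sum"),
             mcs_max_violation=("violation_rate", "max"))
    )
    verdicts = []
    for m in bundle.manifest:
        row = {"stimulus_id": m.stimulus_id, "condition": m.condition,
               "duration_s": m.duration_s,
               "separability_flagged": m.stimulus_id in flagged_sep}
        sub = stim_df[stim_df["stimulus_id"] == m.stimulus_id]
        for r in sub.itertuples():
            row[f"{r.scale}_mean"] = r.mean
            row[f"{r.scale}_ci_low"] = r.ci_low
            row[f"{r.scale}_ci_high"] = r.ci_high
            if r.scale in ("valence", "arousal"):
                row[f"{r.scale}_sd_mean"] = r.sd_mean
        if m.stimulus_id in mcs_per_stim.index:
            row["mcs_flagged_pairs"] = int(
                mcs_per_stim.loc[m.stimulus_id, "mcs_flagged_pairs"])
            row["mcs_max_violation"] = float(
                mcs_per_stim.loc[m.stimulus_id, "mcs_max_violation"])
        else:
            row["mcs_flagged_pairs"] = 0
            row["mcs_max_violation"] = np.nan
        verdicts.append(row)
    stimulus_rows = pd.DataFrame(verdicts)

    metadata = {
        "affectval_version": __version__,
        "master_seed": int(master_seed),
        "config": dataclasses.asdict(cfg),
        "n_participants": len({p.participant_id for p in bundle.post}),
        "n_stimuli": len(bundle.manifest),
        "correspondence_percent": partition.correspondence,
    }
    report = ValidationReport(
        stimulus_rows=stimulus_rows, condition_rows=cond_df, anova=anova,
        contrasts=contrasts, correspondence=partition.correspondence,
        separability=separability, mcs_summary=mcs_summary,
        removal_candidates=removal, correlations=correlations,
        run_metadata=metadata)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stim_df.to_csv(out / "stimulus_summary.csv", index=False)
        cond_df.to_csv(out / "condition_summary.csv", index=False)
        if tp_frames:
            pd.concat(tp_frames, ignore_index=True).to_csv(
                out / "timepoint_summary.csv", index=False)
        correlations.to_csv(out / "correlations.csv", index=False)
        clusters.to_csv(out / "clusters.csv", index=False)
        separability.to_csv(out / "separability.csv", index=False)
        comparisons.to_csv(out / "mcs_pairs.csv", index=False)
        removal.to_csv(out / "removal_candidates.csv", index=False)
        scores_df.to_csv(out / "discrete_scores.csv", index=False)
        scores_cond.to_csv(out / "discrete_scores_condition.csv", index=False)
        freq_basic.to_csv(out / "frequencies_basic.csv", index=False)
        freq_gew.to_csv(out / "frequencies_gew.csv", index=False)
        anova.to_csv(out / "anova.csv", index=False)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        stimulus_rows.to_csv(out / "stimulus_verdicts.csv", index=False)
        (out / "report.json").write_text(json.dumps({
            "metadata": metadata,
            "stimuli": stimulus_rows.to_dict(orient="records"),
            "conditions": cond_df.to_dict(orient="records"),
            "anova": anova.to_dict(orient="records"),
            "mcs_summary": mcs_summary.to_dict(orient="records"),
        }, indent=2, allow_nan=True, default=float) + "\n")
    return report
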