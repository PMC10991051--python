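"""Trimming, bootstrap summaries and correlations of the continuous ratings."""

import itertools

import numpy as np
import pandas as pd
import pytest

from affectval.continuous_summary import (
    TooShortError,
    UndefinedCorrelationError,
    bootstrap_mean_ci,
    participant_stimulus_means,
    position_correlation,
    rating_correlation,
    stimulus_summary,
    timepoint_summary,
    trim_adaptation,
)
from affectval.rating_model import ContinuousSeries
from affectval.synthetic_cohort import simulate_cohort

from conftest import small_spec


def series(values, pid="P1", sid="s1", scale="valence"):
    return ContinuousSeries(pid, sid, scale, np.asarray(values, dtype=float))


class TestTrim:
    def test_slices_at_30_seconds(self):
        s = series(np.arange(151))
        out = trim_adaptation(s, 30)
        assert len(out.values) == 121
        assert out.values[0] == 30  # first retained sample is t = 30 s

    def test_trim_zero_is_identity(self):
        s = series([1, 2, 3])
        assert np.array_equal(trim_adaptation(s, 0).values, s.values)

    def test_too_short_series_rejected(self):
        with pytest.raises(TooShortError):
            trim_adaptation(series(np.arange(20)), 30)


class TestBootstrapMeanCI:
    def test_constant_vector_degenerate_interval(self, rng):
        s = bootstrap_mean_ci([7, 7, 7], 200, 0.95, rng)
        assert (s.mean, s.ci_low, s.ci_high) == (7, 7, 7)

    def test_two_point_pool_matches_enumeration(self, rng):
        """Resamples of {0, 10} are 4 equally likely pairs with means
        {0, 5, 5, 10}; the bootstrap distribution must reproduce that."""
        values = np.array([0.0, 10.0])
        n_boot = 40000
        exact = sorted(np.mean(p) for p in itertools.product(values, repeat=2))
        assert exact == [0.0, 5.0, 5.0, 10.0]
        s = bootstrap_mean_ci(values, n_boot, 0.95, rng)
        assert s.mean == 5.0
        assert s.ci_low in (0.0, 5.0, 10.0)
        assert s.ci_high in (0.0, 5.0, 10.0)

    def test_point_estimate_invariant_to_n_boot(self, rng):
        values = np.linspace(3, 9, 11)
        means = {bootstrap_mean_ci(values, nb, 0.9, rng).mean
                 for nb in (10, 100, 1000)}
        assert len(means) == 1

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_mean_ci([], 10, 0.95, rng)


class TestTimepointSummary:
    def test_identical_series_zero_width(self, rng):
        from affectval.rating_model import RatingBundle, StimulusMeta
        base = np.linspace(50, 80, 40)
        bundle = RatingBundle(
            manifest=[StimulusMeta("s1", "positive", 39)],
            continuous=[series(base, pid=f"P{i}") for i in range(3)],
            post=[])
        df = timepoint_summary(bundle, "valence", "s1", rng, n_boot=200)
        assert np.allclose(df["mean"], base)
        assert np.allclose(df["ci_low"], df["ci_high"])

    def test_two_constant_raters_average(self, rng):
        from affectval.rating_model import RatingBundle, StimulusMeta, PostRating
        bundle = RatingBundle(
            manifest=[StimulusMeta("s1", "neutral", 9)],
            continuous=[series(np.full(10, 40.0), pid="P1"),
                        series(np.full(10, 60.0), pid="P2")],
            post=[],
        )
        df = timepoint_summary(bundle, "valence", "s1", rng, n_boot=100)
        assert np.allclose(df["mean"], 50.0)
        assert (df["n"] == 2).all()

    def test_ragged_ends_report_available_raters(self, rng):
        from affectval.rating_model import RatingBundle, StimulusMeta
        bundle = RatingBundle(
            manifest=[StimulusMeta("s1", "neutral", 19)],
            continuous=[series(np.full(20, 40.0), pid="P1"),
                        series(np.full(10, 60.0), pid="P2")],
            post=[])
        df = timepoint_summary(bundle, "valence", "s1", rng, n_boot=100)
        assert (df.loc[df["t_s"] < 10, "n"] == 2).all()
        assert (df.loc[df["t_s"] >= 10, "n"] == 1).all()
        assert np.allclose(df.loc[df["t_s"] >= 10, "mean"], 40.0)

    def test_per_second_means_track_generator_drift(self, rng):
        """With no participant/stimulus effects the population mean path is
        the closed-form drift; the bootstrap CI should cover it at >= 90% of
        seconds."""
        bundle = simulate_cohort(small_spec(
            n_participants=14, participant_sd=0.0, stimulus_sd=0.0,
            noise_sd=3.0, rng_seed=8))
        targets = {"negative": 20.0, "neutral": 50.0, "positive": 80.0}
        covered = total = 0
        for m in bundle.manifest:
            df = timepoint_summary(bundle, "valence", m.stimulus_id, rng,
                                   n_boot=400)
            t = df["t_s"].to_numpy()
            drift = 50 + (targets[m.condition] - 50) * (1 - np.exp(-t / 10.0))
            covered += int(((df["ci_low"] <= drift) & (drift <= df["ci_high"])).sum())
            total += len(df)
        assert covered / total >= 0.90


class TestStimulusSummary:
    def test_noise_free_grand_means_hit_targets(self, rng):
        bundle = simulate_cohort(small_spec(
            noise_sd=0.0, participant_sd=0.0, stimulus_sd=0.0,
            dominance_noise_sd=0.0, duration_mean=400, duration_sd=1,
            duration_min=395, duration_max=405))
        bundle.config.n_boot = 200
        stim_df, cond_df = stimulus_summary(bundle, rng)
        # after full drift (~400 s series, tau 10) the trimmed mean is within
        # a fraction of a unit of the target
        val = stim_df[stim_df["scale"] == "valence"].set_index("stimulus_id")
        for sid, row in val.iterrows():
            target = {"negative": 20, "neutral": 50, "positive": 80}[row["condition"]]
            assert row["mean"] == pytest.approx(target, abs=1.0)

    def test_condition_average_is_unweighted_mean_of_stimuli(self, small_bundle, rng):
        stim_df, cond_df = stimulus_summary(small_bundle, rng)
        for row in cond_df.itertuples():
            sub = stim_df[(stim_df["condition"] == row.condition)
                          & (stim_df["scale"] == row.scale)]
            assert row.grand_mean == pytest.approx(sub["mean"].mean())

    def test_condition_ordering_recovered(self, small_bundle, rng):
        _, cond_df = stimulus_summary(small_bundle, rng)
        val = cond_df[cond_df["scale"] == "valence"].set_index("condition")["grand_mean"]
        assert val["negative"] < val["neutral"] < val["positive"]

    def test_trimmed_samples_only(self, rng):
        """The pre-trim samples must not leak into per-participant means."""
        from affectval.rating_model import RatingBundle, StimulusMeta
        poisoned = np.concatenate([np.full(30, 100.0), np.full(20, 10.0)])
        bundle = RatingBundle(
            manifest=[StimulusMeta("s1", "neutral", 49)],
            continuous=[series(poisoned, pid="P1"),
                        series(poisoned, pid="P1", scale="arousal")],
            post=[])
        pm = participant_stimulus_means(bundle, "valence")
        assert pm["value"].iloc[0] == 10.0


class TestCorrelations:
    def test_perfect_linear_pearson(self):
        x = np.arange(10.0)
        r, p = rating_correlation(x, 2 * x + 1, "pearson")
        assert r == pytest.approx(1.0)

    def test_spearman_hand_example(self):
        # ranks d = (-2, 1, 1): rho = 1 - 6*6 / (3*8) = -0.5
        r, _ = rating_correlation([1, 2, 3], [3, 1, 2], "spearman")
        assert r == pytest.approx(-0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            rating_correlation([1, 1, 1], [1, 2, 3], "pearson")

    def test_position_correlation_runs_on_cohort(self, small_bundle):
        r, p = position_correlation(small_bundle, "valence")
        assert -1.0 <= r <= 1.0 and 0.0 <= p <= 1.0
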