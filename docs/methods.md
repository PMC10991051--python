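# Methods

`affectval` implements a validation analysis for sets of affect-inducing
stimuli that are rated continuously while being experienced.  The canonical
use case is an auditory stimulus set with three intended conditions
(negative, neutral, positive): participants move a slider (0–100, sampled at
1 Hz, starting at the midpoint 50) to report valence during a first
presentation and arousal during a second, and afterwards rate dominance and
familiarity (0–100 sliders), pick a basic emotion (joy, anger, disgust, fear,
sadness, surprise) and a Geneva Emotion Wheel (GEW) category with a 6-point
intensity.  The pipeline quantifies three properties of the stimulus set:

* **differentiation** — do the conditions separate in rating space?
* **salience / strength** — are the induced responses strong enough?
* **generalizability** — do they hold up across participants?

## Adaptation trimming

Continuous series begin with an orientation phase in which listeners learn
the context and barely move the slider from its midpoint start.  The first
`trim_seconds` (default 30 s) are therefore removed before any per-stimulus
summary.  Because the time axis is 0-based seconds, trimming is an index
slice: `values[trim_seconds:]` keeps exactly the samples at t ≥ 30 s.
Per-second time-course summaries are *not* trimmed, so the adaptation phase
remains visible there.

## Bootstrapped summaries

All intervals are plain percentile bootstrap CIs (default `n_boot = 5000`
resamples, level 0.95): resample the units with replacement, recompute the
mean, report the empirical α/2 and 1−α/2 quantiles.  The point estimate is
always the plain mean, so it is invariant to `n_boot`.  BCa or studentized
intervals were deliberately not used; the diagnostic conventions here are
built on raw percentile intervals throughout, and mixing interval types would
make the CI-overlap rules inconsistent.

For per-stimulus summaries the unit is the participant: series are first
averaged within participant over the trimmed time course, then bootstrapped
across participants.  Within-series standard deviations (a consistency
measure — how much a rating wanders over a stimulus's time course) are
summarized the same way.  Per-condition grand averages are unweighted means
of the condition's per-stimulus grand means.  Per-second summaries resample
participants jointly per stimulus; at ragged series ends the raters still
available are used and their count reported.

Calibration: for normal samples of n = 26 the percentile interval at
`n_boot = 5000` achieves ~93–94% empirical coverage at nominal 95% — the
well-known small-sample undercoverage of the percentile method.  The
acceptance suite pins this to the 93–96% band.

## Fuzzy c-means separability

Each rated (participant, stimulus) pair contributes one feature triplet
(trimmed valence mean, trimmed arousal mean, dominance), z-scored per column
with the population SD pooled over all rows.  Soft clustering minimizes the
Bezdek objective

J = Σᵢ Σₖ uᵢₖᵐ ‖xₖ − vᵢ‖²,  Σᵢ uᵢₖ = 1,

with fuzzifier m = 2, Euclidean distances, random-membership initialization,
`fcm_restarts = 5` restarts keeping the lowest objective, and convergence
when the largest membership change falls below `fcm_tol = 1e-5` (cap
`fcm_max_iter = 300`).  The alternating updates guarantee a non-increasing
objective, which the implementation asserts on every iteration.  A data point
coinciding with a center receives membership exactly 1 there.  k is fixed to
the number of conditions (3) by design; no model selection over k is done.

Clusters map to conditions by the majority condition of their hard-assigned
members; if the majority map is not a bijection (or a majority is tied), the
bijection over all k! assignments maximizing total agreement is used, and a
remaining tie raises an explicit error.  The *correspondence* is the
percentage of rating points whose mapped cluster condition equals the a
priori condition — computed over per-participant points, not over stimuli.

Stimuli misassigned for at least one participant are screened further: for
each such stimulus the mean membership probability per cluster is
bootstrapped across its raters.  The lower CI bound of the true cluster's
probability is the threshold; if any competing cluster's upper CI bound
reaches it, the stimulus is flagged as poorly differentiated from its
neighbouring clusters.

## Monte-Carlo subtractive pair comparison

Every emotional stimulus is paired with every neutral stimulus (for 11/11/15
stimuli per condition: 330 pairs, 165 negative–neutral + 165
positive–neutral).  Per pair and scale, `mcs_draws = 5000` ratings are drawn
with replacement from each stimulus's pool, the emotional draw is subtracted
from the neutral draw, and the fraction of draws contradicting the
hypothesized ordering (valence: negative < neutral < positive; arousal and
dominance: emotional > neutral) is the violation rate.  As draws grow this
converges to the exact cross-product probability over the empirical pools,
which the tests exploit as an exhaustive oracle.

Two choices were genuinely open:

* **Sampling pools.**  Default pools are per-participant trimmed series
  means (valence, arousal) and per-participant post ratings (dominance),
  ignoring the within-subject pairing; a `timepoints` mode pools raw trimmed
  per-second samples instead (for the continuous scales).
* **Ties.**  A zero difference counts as a violation by default — failure to
  separate two stimuli is failure to discriminate them; a strict-inequality
  mode is available.

Pairs with violation rate above `mcs_threshold = 0.20` are flagged; stimuli
are ranked by their number of flagged pairs (max violation rate as
tie-break), and the head of the ranking lists removal candidates for users
who need a maximally distinct subset.

## Discrete-emotion polarity scores

GEW categories split into 8 positive (interest, joy, pleasure, satisfaction,
amusement, compassion, pride, relief) and 10 negative (fear, disgust, hatred,
anger, disappointment, sadness, contempt, shame, guilt, regret); basic
emotions into positive {joy, surprise} and negative {sadness, fear, disgust,
anger}.  Basic scores are 0/1 polarity indicators (summing to 1 per rating —
the choice is forced and the neutral option is absent by design); GEW scores
are intensity-weighted (the chosen category's intensity counts toward its
polarity, 0 toward the other), so pos_gew + neg_gew equals the raw intensity.
Choice frequencies are normalized per stimulus as proportions of raters
(summing to 1); a max-count mode (peak exactly 1) is offered for radar-style
displays.

## Inference

Condition-level tests use one-way repeated-measures ANOVA on the
participant × condition table of condition means (each participant's mean
over their rated stimuli of that condition; with 26 participants and 3
conditions this yields df (2, 50)).  The classical decomposition SS_total =
SS_subjects + SS_effect + SS_error gives F and partial η² =
SS_effect/(SS_effect + SS_error); no sphericity correction is applied.
SS_error = 0 raises a degenerate-fit error carrying the infinite/undefined F
rather than returning a number.

Post-hoc contrasts bootstrap participant-wise condition differences;
"Bonferroni-corrected" is implemented as correction on the percentile
*levels* (per-contrast level 1 − α/m for m pairwise contrasts), with a switch
for uncorrected 2.5/97.5 percentiles.  A contrast is significant when its CI
excludes zero.

The preselection interrater screen takes two raters' 0–10 suitability
ratings: Spearman ρ between raters, exact-agreement fraction, and exclusion
of stimuli whose two-rater mean falls below the cutoff (default 6).  With a
zero-variance rater, ρ is undefined and returned as `None` with a warning
while agreement and screening still run.

## Loudness normalization

Stimulus audio is equalized to a common average level (default −20 dBFS) so
loudness does not confound conditions.  Levels are RMS re full scale, pooled
over all channels; normalization is a single broadband gain
10^((target − current)/20).  If the gain pushes peaks past full scale, a
warning is emitted and samples are clamped — the exact-level guarantee holds
only in the clip-free case.  16-bit PCM WAV is the canonical on-disk format
(integers read as full-scale-relative reals).  Perceptual loudness (LUFS)
and per-channel normalization are out of scope.  Duration summaries use the
sample SD (n − 1); a single stimulus reports SD = NaN.

## Synthetic cohort generator

The generator produces bundles with the statistical structure the analyses
assume, making the whole pipeline testable without any recordings.  Slider
model per (participant, stimulus, scale): mean path
50 + (target − 50)(1 − exp(−t/τ)) with τ = 10 s (drift essentially complete
by ~30 s, matching the trimming window), plus AR(1) noise (lag-1 coefficient
0.8, innovation SD 3) started at zero so t = 0 is exactly 50, clipped to
[0, 100] after noise addition (the slider is physically bounded).  Targets
are condition means (defaults: valence 20/50/80; arousal 65/30/55; dominance
70/35/60 for negative/neutral/positive) plus per-stimulus jitter (SD 5) and
per-participant random offsets (SD 5).  Sessions assign each participant
⌈fraction_rated × N⌉ stimuli (default half), split across conditions by
largest remainder; each stimulus is presented twice — valence pass first,
arousal pass second — with the seam fixed so at least one other presentation
separates the two presentations of any stimulus.  Post ratings draw the
emotion categories from condition-specific categorical distributions
(negative → anger/contempt/disgust-dominant; neutral → interest-dominant;
positive → amusement-dominant), intensity from a rounded clipped normal
(means 4.5/2.0/4.5), familiarity from a clipped normal (means 25/55/45).
Stimulus durations are clipped normals with mean 148.8 s, SD 64.12, range
59–393 s.  Everything is reproducible from a single seed.

The default sample sizes mirror the validation design the package targets:
26 participants and 11/11/15 stimuli per condition.  No quantitative noise
or drift parameters exist for the real instrument, so those defaults were
chosen once for plausibility (visible drift over tens of seconds; smooth,
strongly autocorrelated slider noise; between-participant spread comparable
to between-stimulus spread).

What the generator does **not** emulate: semantic/prosodic stimulus content;
non-stationary affect dynamics within a stimulus (the latent target is
constant, so real time-varying episodes are absent); slider inertia or
discrete movement bursts; correlations between the affective dimensions
beyond what condition targets induce; rater fatigue or order effects
(session position is generated but has no effect on ratings, which makes it
a true null for the position-correlation analysis).  Passing tests on
synthetic cohorts therefore demonstrate correctness of the statistical
machinery under the assumed data model, not validity of any particular real
stimulus set.

For the type-I-error calibration of the rmANOVA, the null cohorts use
identical condition targets *and* no stimulus-level target jitter: with only
a couple of stimuli per condition, shared stimulus jitter would act as a
genuine condition effect and the rejection rate would not be a type-I error.

## Numerical choices and degenerate inputs

* Bootstrap of an n = 1 sample returns a degenerate CI equal to the mean
  (with a warning in the separability screen).
* Percentile computation uses linear interpolation of order statistics.
* Fuzzy c-means breaks exact-zero distances with a one-hot membership; ties
  in cluster matching raise rather than resolve silently.
* Correlations on zero-variance inputs raise (`rating_correlation`) or
  return `None` with a warning where partial results are still meaningful
  (interrater screen).
* Master seed → per-stage child streams via `numpy` `SeedSequence.spawn`, so
  changing one stage's resampling effort cannot perturb another stage's
  draws; two runs with the same inputs and seed produce byte-identical
  reports.

## Problem sizes used in the test and acceptance suites

Unit fixtures use 6-participant cohorts with 2 stimuli per condition and
~45 s stimuli; recovery and calibration checks use full-size cohorts (26
participants, 11/11/15 stimuli, natural durations), 1000-replicate
calibration loops on 10-participant cohorts with ~40 s stimuli, and the
configured defaults (5000 bootstrap resamples and Monte-Carlo draws)
wherever a calibration property depends on them.  These sizes were chosen so
every statistical property is exercised at full resampling resolution while
simulation-bound loops stay small.

## Known limitations

* The rmANOVA applies no sphericity correction; with k = 3 and clearly
  non-spherical data its p-values are anti-conservative.
* The percentile bootstrap undercovers at small n (see calibration above);
  users needing exact coverage should increase n or switch methods.
* The MCS default ignores the within-subject pairing by design (the
  procedure is a property of the stimulus pool, not a hypothesis test), so
  its violation rates are descriptive, not inferential.
* Cluster correspondence depends on the z-scoring scope (pooled population
  SD); per-scale or per-participant standardization would change results.
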