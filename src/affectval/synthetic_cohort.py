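"""Synthetic rating-cohort generator.

Emulates the statistical structure that the downstream analyses assume, so the
whole pipeline is testable without any real recordings:

* 1 Hz slider series on a 0–100 scale starting at the midpoint (50), drifting
  with an exponential approach (time constant ``adaptation_tau``) toward a
  condition-dependent target during an initial adaptation phase, plus AR(1)
  noise, clipped to the physical slider range;
* per-stimulus target jitter and per-participant random offsets (random
  effects) on each affective dimension;
* a session design in which each participant rates a condition-balanced subset
  of the stimuli in random order, every stimulus presented twice — valence on
  the first presentation, arousal on the second, with at least one other
  stimulus between the two presentations;
* condition-dependent categorical emotion choices (basic emotions and the
  Geneva Emotion Wheel) with a 6-point intensity, plus dominance and
  familiarity sliders.

Everything is reproducible from ``rng_seed``.  Within a participant, the
bundle's ``continuous`` entries appear in presentation order (the whole
valence pass, then the whole arousal pass), so the session structure can be
reconstructed from the bundle itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .config import AnalysisConfig
from .rating_model import (
    BASIC_EMOTIONS,
    CONDITIONS,
    GEW_EMOTIONS,
    ContinuousSeries,
    PostRating,
    RatingBundle,
    StimulusMeta,
)

__all__ = ["CohortSpec", "DesignError", "ParameterError",
           "simulate_series", "simulate_cohort"]


class ParameterError(ValueError):
    """A generator parameter outside its admissible range."""


class DesignError(ValueError):
    """A session design that cannot be realised (e.g. empty condition)."""


def _default_targets() -> dict[str, tuple[float, float, float]]:
    # (valence, arousal, dominance): valence ordered negative < neutral <
    # positive; arousal and dominance higher for emotional than neutral
    # stimuli, highest for the negative condition.
    return {
        "negative": (20.0, 65.0, 70.0),
        "neutral": (50.0, 30.0, 35.0),
        "positive": (80.0, 55.0, 60.0),
    }


def _default_basic_probs() -> dict[str, dict[str, float]]:
    return {
        "negative": {"anger": 0.35, "fear": 0.25, "sadness": 0.2,
                     "disgust": 0.15, "surprise": 0.04, "joy": 0.01},
        "neutral": {"joy": 0.45, "surprise": 0.45, "sadness": 0.04,
                    "fear": 0.02, "disgust": 0.02, "anger": 0.02},
        "positive": {"joy": 0.75, "surprise": 0.2, "anger": 0.02,
                     "sadness": 0.01, "fear": 0.01, "disgust": 0.01},
    }


def _default_gew_probs() -> dict[str, dict[str, float]]:
    return {
        "negative": {"anger": 0.25, "contempt": 0.15, "disgust": 0.14,
                     "fear": 0.12, "disappointment": 0.1, "sadness": 0.1,
                     "shame": 0.05, "compassion": 0.05, "hatred": 0.02,
                     "guilt": 0.01, "regret": 0.01},
        "neutral": {"interest": 0.6, "satisfaction": 0.15, "relief": 0.08,
                    "pleasure": 0.07, "joy": 0.05, "amusement": 0.05},
        "positive": {"amusement": 0.55, "joy": 0.2, "pleasure": 0.1,
                     "interest": 0.08, "satisfaction": 0.07},
    }


@dataclass
class CohortSpec:
    """Parameters of the simulated rating study.

    Defaults mirror the validated stimulus-set design: 26 participants, 11
    negative / 15 neutral / 11 positive stimuli, each participant rating half
    of the set balanced across conditions, stimulus durations averaging
    ~149 s (SD 64, range 59–393 s), and the slider model described in the
    module docstring.
    """

    n_participants: int = 26
    stimuli_per_condition: dict[str, int] = field(
        default_factory=lambda: {"negative": 11, "neutral": 15, "positive": 11})
    condition_targets: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_targets)
    stimulus_sd: float = 5.0
    participant_sd: float = 5.0
    adaptation_tau: float = 10.0
    noise_sd: float = 3.0
    noise_ar1: float = 0.8
    basic_probs: dict[str, dict[str, float]] = field(default_factory=_default_basic_probs)
    gew_probs: dict[str, dict[str, float]] = field(default_factory=_default_gew_probs)
    intensity_means: dict[str, float] = field(
        default_factory=lambda: {"negative": 4.5, "neutral": 2.0, "positive": 4.5})
    intensity_sd: float = 1.0
    familiarity_means: dict[str, float] = field(
        default_factory=lambda: {"negative": 25.0, "neutral": 55.0, "positive": 45.0})
    familiarity_sd: float = 15.0
    dominance_noise_sd: float = 5.0
    duration_mean: float = 148.8
    duration_sd: float = 64.12
    duration_min: float = 59.0
    duration_max: float = 393.0
    fraction_rated: float = 0.5
    rng_seed: int = 2023

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be positive")
        if not 0.0 < self.fraction_rated <= 1.0:
            raise ParameterError("fraction_rated must lie in (0, 1]")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ParameterError("noise_ar1 must lie in [0, 1)")
        if self.adaptation_tau <= 0:
            raise ParameterError("adaptation_tau must be positive")
        for name in ("stimulus_sd", "participant_sd", "noise_sd",
                     "intensity_sd", "familiarity_sd", "dominance_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for cond, n in self.stimuli_per_condition.items():
            if cond not in CONDITIONS:
                raise ParameterError(f"unknown condition {cond!r}")
            if n < 1:
                raise ParameterError(f"stimuli_per_condition[{cond!r}] must be >= 1")
        for cond, triple in self.condition_targets.items():
            if any(not (0.0 <= v <= 100.0) for v in triple):
                raise ParameterError(
                    f"condition_targets[{cond!r}] must lie in [0, 100]")
        for label, probs, cats in (("basic_probs", self.basic_probs, BASIC_EMOTIONS),
                                   ("gew_probs", self.gew_probs, GEW_EMOTIONS)):
            for cond, dist in probs.items():
                if abs(sum(dist.values()) - 1.0) > 1e-9:
                    raise ParameterError(
                        f"{label}[{cond!r}] must sum to 1 within 1e-9")
                unknown = set(dist) - set(cats)
                if unknown:
                    raise ParameterError(
                        f"{label}[{cond!r}] has unknown categories {sorted(unknown)}")
        for cond, mu in self.intensity_means.items():
            if not 1.0 <= mu <= 6.0:
                raise ParameterError(f"intensity_means[{cond!r}] must lie in [1, 6]")


def simulate_series(
    target: float,
    duration: float,
    spec: CohortSpec,
    stream: np.random.Generator,
) -> np.ndarray:
    """One slider trace: midpoint start, exponential approach, AR(1) noise.

    The mean path is ``50 + (target - 50) * (1 - exp(-t / tau))``; the noise is
    an AR(1) process with lag-1 coefficient ``noise_ar1`` and innovation SD
    ``noise_sd`` started at zero, so the t = 0 sample is exactly 50.  Values
    are clipped to the physical slider range [0, 100] after noise addition.
    """
    if not np.isfinite(target):
        raise ParameterError("target must be finite")
    if not 0.0 <= target <= 100.0:
        raise ParameterError(f"target {target} outside [0, 100]")
    if duration < 1:
        raise ParameterError("duration must be >= 1 s")
    n = int(math.floor(duration)) + 1  # samples at t = 0..floor(duration)
    t = np.arange(n, dtype=float)
    mean = 50.0 + (target - 50.0) * (1.0 - np.exp(-t / spec.adaptation_tau))
    if spec.noise_sd > 0:
        innov = stream.normal(0.0, spec.noise_sd, size=n)
        innov[0] = 0.0
        noise = lfilter([1.0], [1.0, -spec.noise_ar1], innov)
    else:
        noise = 0.0
    return np.clip(mean + noise, 0.0, 100.0)


def _allocate_per_condition(
    counts: dict[str, int], fraction: float
) -> dict[str, int]:
    """Largest-remainder allocation of ``ceil(fraction * total)`` rated
    stimuli across conditions, ties broken in mapping order."""
    total_target = math.ceil(fraction * sum(counts.values()))
    exact = {c: fraction * n for c, n in counts.items()}
    alloc = {c: math.floor(v) for c, v in exact.items()}
    for c in counts:
        if alloc[c] < 1:
            raise DesignError(
                f"fraction_rated={fraction} leaves condition {c!r} with no "
                "rated stimulus")
    remaining = total_target - sum(alloc.values())
    order = sorted(counts, key=lambda c: exact[c] - alloc[c], reverse=True)
    for c in order[:remaining]:
        if alloc[c] < counts[c]:
            alloc[c] += 1
    return alloc


def simulate_cohort(spec: CohortSpec) -> RatingBundle:
    """Generate a complete, validation-clean :class:`RatingBundle`."""
    rng = np.random.default_rng(spec.rng_seed)

    # --- manifest: per-stimulus durations and latent targets ---------------
    manifest: list[StimulusMeta] = []
    stim_targets: dict[str, np.ndarray] = {}
    for cond in spec.stimuli_per_condition:  # mapping order is the design order
        n_stim = spec.stimuli_per_condition[cond]
        base = np.asarray(spec.condition_targets[cond], dtype=float)
        for i in range(n_stim):
            sid = f"{cond}_{i + 1:02d}"
            dur = float(np.clip(rng.normal(spec.duration_mean, spec.duration_sd),
                                spec.duration_min, spec.duration_max))
            dur = float(round(dur))
            manifest.append(StimulusMeta(sid, cond, dur))
            stim_targets[sid] = np.clip(
                base + rng.normal(0.0, spec.stimulus_sd, size=3), 0.0, 100.0)

    by_condition = {c: [m for m in manifest if m.condition == c]
                    for c in spec.stimuli_per_condition}
    alloc = _allocate_per_condition(
        {c: len(v) for c, v in by_condition.items()}, spec.fraction_rated)

    # per-participant random offsets on (valence, arousal, dominance)
    offsets = rng.normal(0.0, spec.participant_sd, size=(spec.n_participants, 3))

    continuous: list[ContinuousSeries] = []
    post: list[PostRating] = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        chosen: list[StimulusMeta] = []
        for cond in spec.stimuli_per_condition:
            pool = by_condition[cond]
            idx = rng.choice(len(pool), size=alloc[cond], replace=False)
            chosen.extend(pool[i] for i in sorted(idx))
        if len(chosen) < 2:
            raise DesignError(
                "each participant must rate >= 2 stimuli so that the two "
                "presentations of a stimulus can be separated")

        # first pass rates valence, second pass arousal; permuting each pass
        # independently and fixing the seam guarantees >= 1 other stimulus
        # between the two presentations of any stimulus.
        first = list(rng.permutation(len(chosen)))
        second = list(rng.permutation(len(chosen)))
        if second[0] == first[-1]:
            second[0], second[1] = second[1], second[0]
        position = {chosen[j].stimulus_id: rank + 1
                    for rank, j in enumerate(first)}

        for j in first:
            m = chosen[j]
            tgt = float(np.clip(stim_targets[m.stimulus_id][0] + offsets[p, 0],
                                0.0, 100.0))
            continuous.append(ContinuousSeries(
                pid, m.stimulus_id, "valence",
                simulate_series(tgt, m.duration_s, spec, rng)))
        for j in second:
            m = chosen[j]
            tgt = float(np.clip(stim_targets[m.stimulus_id][1] + offsets[p, 1],
                                0.0, 100.0))
            continuous.append(ContinuousSeries(
                pid, m.stimulus_id, "arousal",
                simulate_series(tgt, m.duration_s, spec, rng)))

        for m in chosen:
            cond = m.condition
            dom = float(np.clip(
                stim_targets[m.stimulus_id][2] + offsets[p, 2]
                + rng.normal(0.0, spec.dominance_noise_sd), 0.0, 100.0))
            fam = float(np.clip(
                rng.normal(spec.familiarity_means[cond], spec.familiarity_sd),
                0.0, 100.0))
            bprobs = spec.basic_probs[cond]
            basic = str(rng.choice(list(bprobs), p=list(bprobs.values())))
            gprobs = spec.gew_probs[cond]
            gew = str(rng.choice(list(gprobs), p=list(gprobs.values())))
            intensity = int(np.clip(
                round(rng.normal(spec.intensity_means[cond], spec.intensity_sd)),
                1, 6))
            post.append(PostRating(pid, m.stimulus_id, dom, fam, basic, gew,
                                   intensity, position[m.stimulus_id]))

    return RatingBundle(manifest, continuous, post,
                        AnalysisConfig(rng_seed=spec.rng_seed))
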