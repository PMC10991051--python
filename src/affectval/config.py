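"""Analysis configuration shared by every pipeline stage.

All resampling sizes, trimming windows and clustering hyperparameters live in a
single :class:`AnalysisConfig` so that a run can be reproduced from one file.
The file representation is YAML or JSON (chosen by extension) and round-trips
losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Parameters governing a validation run.

    Attributes
    ----------
    trim_seconds:
        Length of the initial orientation/adaptation phase (seconds) removed
        from every continuous series before summarising.
    n_boot:
        Bootstrap iterations for every percentile confidence interval.
    ci_level:
        Confidence level of the percentile bootstrap intervals.
    mcs_draws:
        Monte-Carlo draws per stimulus pair in the subtractive comparison.
    mcs_threshold:
        Violation-rate threshold above which a pair is flagged as poorly
        discriminated.
    fcm_clusters:
        Number of fuzzy c-means clusters (one per stimulus condition).
    fcm_fuzzifier:
        Fuzzifier exponent m (> 1) of the c-means objective.
    fcm_tol / fcm_max_iter / fcm_restarts:
        Convergence tolerance on the membership change, iteration cap, and
        number of random restarts (lowest objective kept).
    rng_seed:
        Master seed; per-stage generators are spawned from it.
    target_dbfs:
        RMS loudness-normalization target in dB relative to full scale.
    """

    trim_seconds: int = 30
    n_boot: int = 5000
    ci_level: float = 0.95
    mcs_draws: int = 5000
    mcs_threshold: float = 0.20
    fcm_clusters: int = 3
    fcm_fuzzifier: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    fcm_restarts: int = 5
    rng_seed: int = 2023
    target_dbfs: float = -20.0

    def __post_init__(self) -> None:
        if self.trim_seconds < 0:
            raise ValueError("trim_seconds must be non-negative")
        if self.n_boot < 1 or self.mcs_draws < 1:
            raise ValueError("n_boot and mcs_draws must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if not 0.0 < self.mcs_threshold < 1.0:
            raise ValueError("mcs_threshold must lie in (0, 1)")
        if self.fcm_clusters < 1:
            raise ValueError("fcm_clusters must be positive")
        if self.fcm_fuzzifier <= 1.0:
            raise ValueError("fcm_fuzzifier must exceed 1")
        if self.fcm_tol <= 0 or self.fcm_max_iter < 1 or self.fcm_restarts < 1:
            raise ValueError("fcm_tol, fcm_max_iter and fcm_restarts must be positive")

    # -- file representation -------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "AnalysisConfig":
        """Build a config from a (possibly partial) mapping; missing keys
        take their defaults, unknown keys are rejected."""
        mapping = dict(mapping or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_mapping(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
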