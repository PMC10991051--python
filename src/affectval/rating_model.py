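"""Domain types, table readers/writers and structural validation.

The pipeline's single input is a :class:`RatingBundle`: a stimulus manifest,
continuous 1 Hz slider series (valence and arousal on a 0–100 scale), one
post-presentation rating record per (participant, stimulus), and an
:class:`~affectval.config.AnalysisConfig`.

Canonical interchange is long (tidy) CSV with a header row; TSV is accepted by
sniffing the delimiter.  The time axis is 0-based seconds: ``values[k]`` is the
sample at t = k s, so trimming the adaptation phase is an index slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "CONDITIONS",
    "SCALES",
    "BASIC_EMOTIONS",
    "GEW_EMOTIONS",
    "StimulusMeta",
    "ContinuousSeries",
    "PostRating",
    "RatingBundle",
    "ValidationError",
    "SchemaError",
    "RangeError",
    "SamplingError",
    "ReferentialError",
    "load_bundle",
    "write_bundle",
    "validate_bundle",
]

CONDITIONS = ("negative", "neutral", "positive")
SCALES = ("valence", "arousal")
BASIC_EMOTIONS = ("joy", "anger", "disgust", "fear", "sadness", "surprise")
#: Geneva Emotion Wheel categories (neutral removed: the instrument is a
#: forced choice; a neutral experience is expressed through low intensity).
GEW_EMOTIONS = (
    "interest", "joy", "pleasure", "satisfaction", "amusement", "compassion",
    "pride", "relief", "fear", "disgust", "hatred", "anger", "disappointment",
    "sadness", "contempt", "shame", "guilt", "regret",
)


class ValidationError(ValueError):
    """Base class for structural problems in rating data."""


class SchemaError(ValidationError):
    """Unknown label / malformed column."""


class RangeError(ValidationError):
    """A value outside its documented bounds."""


class SamplingError(ValidationError):
    """Continuous series whose time stamps are not contiguous 1 Hz samples."""


class ReferentialError(ValidationError):
    """A record referencing a stimulus absent from the manifest."""


@dataclass(frozen=True)
class StimulusMeta:
    stimulus_id: str
    condition: str
    duration_s: float
    audio_path: str | None = None


@dataclass
class ContinuousSeries:
    """One participant's 1 Hz slider trace for one stimulus and scale."""

    participant_id: str
    stimulus_id: str
    scale: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContinuousSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.stimulus_id == other.stimulus_id
            and self.scale == other.scale
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class PostRating:
    participant_id: str
    stimulus_id: str
    dominance: float  # NaN when absent
    familiarity: float  # NaN when absent
    basic_emotion: str
    gew_emotion: str
    gew_intensity: int
    session_position: int


@dataclass
class RatingBundle:
    manifest: list[StimulusMeta]
    continuous: list[ContinuousSeries]
    post: list[PostRating]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def meta(self, stimulus_id: str) -> StimulusMeta:
        for m in self.manifest:
            if m.stimulus_id == stimulus_id:
                return m
        raise KeyError(stimulus_id)

    def condition_of(self) -> dict[str, str]:
        return {m.stimulus_id: m.condition for m in self.manifest}

    def series(self, scale: str, stimulus_id: str) -> list[ContinuousSeries]:
        return [
            s for s in self.continuous
            if s.scale == scale and s.stimulus_id == stimulus_id
        ]

    def continuous_frame(self) -> pd.DataFrame:
        """Long-format view of all continuous series."""
        parts = []
        for s in self.continuous:
            parts.append(pd.DataFrame({
                "participant_id": s.participant_id,
                "stimulus_id": s.stimulus_id,
                "scale": s.scale,
                "t_s": np.arange(len(s.values)),
                "value": s.values,
            }))
        return pd.concat(parts, ignore_index=True)

    def post_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.post])

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.manifest])

    def __eq__(self, other: object) -> bool:
        # content equality: record order (e.g. presentation order vs. the
        # loader's sorted order) is not part of a bundle's identity
        if not isinstance(other, RatingBundle):
            return NotImplemented
        key_s = lambda s: (s.participant_id, s.stimulus_id, s.scale)
        key_p = lambda p: (p.participant_id, p.stimulus_id)
        return (
            sorted(self.manifest, key=lambda m: m.stimulus_id)
            == sorted(other.manifest, key=lambda m: m.stimulus_id)
            and sorted(self.continuous, key=key_s) == sorted(other.continuous, key=key_s)
            and sorted(self.post, key=key_p) == sorted(other.post, key=key_p)
            and self.config == other.config
        )


# ---------------------------------------------------------------------------
# loading / writing


def _read_table(path: str | Path) -> pd.DataFrame:
    # sniff comma vs tab from the header; round_trip parsing keeps the
    # write->read cycle lossless for float64
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns {missing}")


def load_bundle(
    manifest_file: str | Path,
    continuous_file: str | Path,
    post_file: str | Path,
    config_file: str | Path | None = None,
) -> RatingBundle:
    """Read the three canonical tables (+ optional config) and validate."""
    mdf = _read_table(manifest_file)
    _require_columns(mdf, ("stimulus_id", "condition", "duration_s"), "manifest")
    manifest = []
    for _, row in mdf.iterrows():
        audio = row.get("audio_path") if "audio_path" in mdf.columns else None
        manifest.append(StimulusMeta(
            stimulus_id=str(row["stimulus_id"]),
            condition=str(row["condition"]),
            duration_s=float(row["duration_s"]),
            audio_path=audio if isinstance(audio, str) and audio else None,
        ))

    cdf = _read_table(continuous_file)
    _require_columns(cdf, ("participant_id", "stimulus_id", "scale", "t_s", "value"), "continuous")
    continuous = []
    for (pid, sid, scale), grp in cdf.groupby(
        ["participant_id", "stimulus_id", "scale"], sort=True
    ):
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy()
        if len(t) == 0 or t[0] != 0 or not np.array_equal(t, np.arange(len(t))):
            raise SamplingError(
                f"series ({pid}, {sid}, {scale}): seconds not contiguous from 0"
            )
        continuous.append(ContinuousSeries(str(pid), str(sid), str(scale),
                                           grp["value"].to_numpy(dtype=float)))

    pdf = _read_table(post_file)
    _require_columns(
        pdf,
        ("participant_id", "stimulus_id", "dominance", "familiarity",
         "basic_emotion", "gew_emotion", "gew_intensity", "session_position"),
        "post",
    )
    post = []
    for _, row in pdf.iterrows():
        post.append(PostRating(
            participant_id=str(row["participant_id"]),
            stimulus_id=str(row["stimulus_id"]),
            dominance=float(row["dominance"]) if pd.notna(row["dominance"]) else float("nan"),
            familiarity=float(row["familiarity"]) if pd.notna(row["familiarity"]) else float("nan"),
            basic_emotion=str(row["basic_emotion"]),
            gew_emotion=str(row["gew_emotion"]),
            gew_intensity=int(row["gew_intensity"]),
            session_position=int(row["session_position"]),
        ))

    config = AnalysisConfig.from_file(config_file) if config_file else AnalysisConfig()
    bundle = RatingBundle(manifest, continuous, post, config)
    validate_bundle(bundle)
    return bundle


def write_bundle(bundle: RatingBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical tables + config; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": out / "manifest.csv",
        "continuous": out / "continuous.csv",
        "post": out / "post.csv",
        "config": out / "config.yaml",
    }
    # %.17g keeps the text form lossless for float64
    bundle.manifest_frame().to_csv(paths["manifest"], index=False, float_format="%.17g")
    bundle.continuous_frame().to_csv(paths["continuous"], index=False, float_format="%.17g")
    bundle.post_frame().to_csv(paths["post"], index=False, float_format="%.17g")
    bundle.config.to_file(paths["config"])
    return paths


# ---------------------------------------------------------------------------
# validation


def validate_bundle(bundle: RatingBundle) -> None:
    """Check every structural invariant; raise the matching error subclass."""
    ids = [m.stimulus_id for m in bundle.manifest]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate stimulus_id in manifest: {dupes}")
    known = set(ids)
    durations = {}
    for m in bundle.manifest:
        if m.condition not in CONDITIONS:
            raise SchemaError(
                f"stimulus {m.stimulus_id}: unknown condition {m.condition!r}"
            )
        if not m.duration_s >= 1:
            raise RangeError(f"stimulus {m.stimulus_id}: duration must be >= 1 s")
        durations[m.stimulus_id] = m.duration_s

    seen_series: set[tuple[str, str, str]] = set()
    for s in bundle.continuous:
        if s.stimulus_id not in known:
            raise ReferentialError(
                f"continuous series references unknown stimulus {s.stimulus_id!r}"
            )
        if s.scale not in SCALES:
            raise SchemaError(f"unknown scale {s.scale!r}")
        v = s.values
        if v.size == 0:
            raise SamplingError(
                f"series ({s.participant_id}, {s.stimulus_id}, {s.scale}) is empty"
            )
        if np.any(~np.isfinite(v)) or v.min() < 0 or v.max() > 100:
            raise RangeError(
                f"series ({s.participant_id}, {s.stimulus_id}, {s.scale}): "
                "values must lie in [0, 100]"
            )
        if len(v) > durations[s.stimulus_id] + 1:
            raise SamplingError(
                f"series ({s.participant_id}, {s.stimulus_id}, {s.scale}): "
                f"length {len(v)} exceeds duration {durations[s.stimulus_id]} + 1"
            )
        key = (s.participant_id, s.stimulus_id, s.scale)
        if key in seen_series:
            raise SchemaError(f"duplicate continuous series {key}")
        seen_series.add(key)

    seen_post: set[tuple[str, str]] = set()
    for p in bundle.post:
        if p.stimulus_id not in known:
            raise ReferentialError(
                f"post rating references unknown stimulus {p.stimulus_id!r}"
            )
        for name, val in (("dominance", p.dominance), ("familiarity", p.familiarity)):
            if not math.isnan(val) and not 0 <= val <= 100:
                raise RangeError(
                    f"post ({p.participant_id}, {p.stimulus_id}): "
                    f"{name} {val} outside [0, 100]"
                )
        if p.basic_emotion not in BASIC_EMOTIONS:
            raise SchemaError(
                f"post ({p.participant_id}, {p.stimulus_id}): "
                f"unknown basic emotion {p.basic_emotion!r}"
            )
        if p.gew_emotion not in GEW_EMOTIONS:
            raise SchemaError(
                f"post ({p.participant_id}, {p.stimulus_id}): "
                f"unknown GEW emotion {p.gew_emotion!r}"
            )
        if p.gew_intensity not in range(1, 7):
            raise RangeError(
                f"post ({p.participant_id}, {p.stimulus_id}): "
                f"gew_intensity {p.gew_intensity} outside 1..6"
            )
        if p.session_position < 1:
            raise RangeError(
                f"post ({p.participant_id}, {p.stimulus_id}): "
                "session_position must be >= 1"
            )
        key2 = (p.participant_id, p.stimulus_id)
        if key2 in seen_post:
            raise SchemaError(f"duplicate post rating {key2}")
        seen_post.add(key2)

    # design completeness: both scales + a post record per rated stimulus
    rated: dict[tuple[str, str], set[str]] = {}
    for s in bundle.continuous:
        rated.setdefault((s.participant_id, s.stimulus_id), set()).add(s.scale)
    for (pid, sid), scales in rated.items():
        if scales != set(SCALES):
            raise SchemaError(
                f"participant {pid}, stimulus {sid}: needs both a valence and "
                f"an arousal series (got {sorted(scales)})"
            )
        if (pid, sid) not in seen_post:
            raise SchemaError(
                f"participant {pid}, stimulus {sid}: continuous ratings "
                "without a post-presentation record"
            )
    for key2 in seen_post:
        if key2 not in rated:
            raise SchemaError(
                f"post rating {key2} without continuous series"
            )
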