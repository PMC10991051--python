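"""RMS loudness measurement and normalization in dBFS, plus duration stats.

Stimulus audio is normalized to a common average level so that loudness does
not confound the affective comparison between conditions.  Levels are measured
as RMS relative to digital full scale (0 dBFS = RMS 1.0) pooled over all
channels, and normalization applies a single broadband gain.

16-bit PCM WAV is the canonical on-disk form; integer samples are read as
full-scale-relative reals (int16 / 32768).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "SilentClipError",
    "ClippingWarning",
    "measure_dbfs",
    "normalize_dbfs",
    "duration_summary",
    "read_wav",
    "write_wav",
]


class SilentClipError(ValueError):
    """RMS is zero: the level in dBFS is undefined."""


class ClippingWarning(UserWarning):
    """Gain pushed samples past full scale; they were clamped to [-1, 1]."""


@dataclass
class AudioClip:
    """PCM audio with samples on [-1, 1] (full scale = 1).

    ``samples`` has shape (n,) for mono or (n, channels) otherwise.
    """

    samples: np.ndarray
    rate: int
    channels: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("AudioClip needs at least one sample")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        inferred = 1 if self.samples.ndim == 1 else self.samples.shape[1]
        if inferred != self.channels:
            raise ValueError(
                f"channels={self.channels} inconsistent with sample shape "
                f"{self.samples.shape}")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.rate


def measure_dbfs(clip: AudioClip) -> float:
    """RMS level in dB relative to full scale, pooled over all channels."""
    rms = float(np.sqrt(np.mean(np.square(clip.samples))))
    if rms == 0.0:
        raise SilentClipError("silent clip: RMS level is undefined")
    return 20.0 * np.log10(rms)


def normalize_dbfs(clip: AudioClip, target: float) -> AudioClip:
    """Scale the clip so its RMS level equals ``target`` dBFS.

    A single gain factor ``10**((target - current) / 20)`` is applied.  If the
    gain pushes any sample past full scale, a :class:`ClippingWarning` is
    emitted and the samples are clamped to [-1, 1]; in that case the achieved
    level falls short of the target.
    """
    current = measure_dbfs(clip)
    gain = 10.0 ** ((target - current) / 20.0)
    scaled = clip.samples * gain
    peak = float(np.max(np.abs(scaled)))
    if peak > 1.0:
        warnings.warn(
            f"normalization to {target:+.1f} dBFS clips {np.mean(np.abs(scaled) > 1.0):.1%} "
            f"of samples (peak {peak:.3f}); clamping to full scale",
            ClippingWarning,
            stacklevel=2,
        )
        scaled = np.clip(scaled, -1.0, 1.0)
    return AudioClip(scaled, clip.rate, clip.channels)


def duration_summary(manifest) -> dict[str, float]:
    """Descriptive statistics of manifest durations.

    Uses the sample standard deviation (n - 1); a single stimulus therefore
    yields ``sd = nan``.  ``total_minutes`` is the summed playing time.
    """
    durations = np.asarray([m.duration_s for m in manifest], dtype=float)
    if durations.size == 0:
        raise ValueError("empty manifest")
    sd = float(np.std(durations, ddof=1)) if durations.size > 1 else float("nan")
    return {
        "count": int(durations.size),
        "mean_s": float(durations.mean()),
        "sd_s": sd,
        "min_s": float(durations.min()),
        "max_s": float(durations.max()),
        "total_minutes": float(durations.sum() / 60.0),
    }


# ---------------------------------------------------------------------------
# WAV I/O (PCM 16-bit canonical)


def read_wav(path: str | Path) -> AudioClip:
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:  # float WAV already full-scale-relative
        samples = data.astype(float)
    channels = 1 if samples.ndim == 1 else samples.shape[1]
    return AudioClip(samples, int(rate), channels)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    data = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.rate, np.round(data * 32767.0).astype(np.int16))
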