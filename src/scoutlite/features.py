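"""Automatically extracted stimulus features.

Low-level visual (brightness), auditory (RMS loudness), speech (binary
indicator from force-aligned transcripts) and lexical (z-scored dictionary
norms) predictors, plus the generic change-point indicator used for shot
changes and the 3 Hz bin-average downsampler applied to dense streams
before storage.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stimio import FeatureStream, LexicalNorms, TranscriptWord, ValidationError

__all__ = [
    "FrameSequence",
    "AudioSignal",
    "extract_brightness",
    "extract_rms",
    "speech_indicator",
    "lexical_feature",
    "log10_word_frequency",
    "text_length",
    "indicator_from_changepoints",
    "downsample_dense",
    "DENSE_INGEST_RATE_HZ",
    "BRIGHTNESS_DIVISOR",
]

DENSE_INGEST_RATE_HZ = 3.0
"""Default rate dense streams are downsampled to on ingestion."""

BRIGHTNESS_DIVISOR = 255.0
"""Maximum value in 8-bit RGB space; brightness is normalized by it."""


@dataclass
class FrameSequence:
    """Video frames as H x W x 3 integer arrays sampled at ``rate`` Hz."""

    frames: Sequence[np.ndarray]
    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValidationError("frame rate must be > 0")
        shapes = {np.asarray(f).shape for f in self.frames}
        if len(shapes) > 1:
            raise ValidationError("all frames must share one shape")


@dataclass
class AudioSignal:
    """A mono audio signal with samples in [-1, 1]."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValidationError("sample rate must be > 0")


def extract_brightness(frames: FrameSequence) -> FeatureStream:
    """Average luminosity per frame: mean over pixels of the RGB max, / 255.

    Returns a dense stream in [0, 1] at the frame rate.
    """
    if len(frames.frames) == 0:
        raise ValidationError("frame sequence must be non-empty")
    values = np.empty(len(frames.frames))
    for i, frame in enumerate(frames.frames):
        arr = np.asarray(frame)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValidationError("frames must be H x W x 3")
        if arr.min() < 0 or arr.max() > BRIGHTNESS_DIVISOR:
            raise ValidationError("channel values must lie in [0, 255]")
        values[i] = arr.max(axis=2).mean() / BRIGHTNESS_DIVISOR
    return FeatureStream(name="brightness", kind="dense", values=values, sampling_rate=frames.rate)


def extract_rms(audio: AudioSignal, frame_length: int, hop: int) -> FeatureStream:
    """Windowed root-mean-square energy ('loudness') of an audio signal.

    Windows start at multiples of ``hop`` samples; the output is dense at
    ``audio.rate / hop`` Hz.
    """
    if frame_length < 1 or hop < 1:
        raise ValidationError("frame_length and hop must be >= 1")
    n = len(audio.samples)
    if frame_length > n:
        raise ValidationError("frame_length exceeds signal length")
    n_frames = 1 + (n - frame_length) // hop
    starts = np.arange(n_frames) * hop
    idx = starts[:, None] + np.arange(frame_length)[None, :]
    values = np.sqrt(np.mean(audio.samples[idx] ** 2, axis=1))
    return FeatureStream(name="rms", kind="dense", values=values, sampling_rate=audio.rate / hop)


def speech_indicator(
    words: Sequence[TranscriptWord], rate: float, duration: float
) -> FeatureStream:
    """Binary speech-presence stream from word onset/offset intervals.

    Sample t is 1 iff t falls inside some half-open word interval
    [onset, onset + duration).
    """
    if rate <= 0:
        raise ValidationError("rate must be > 0")
    for w in words:
        if w.onset + w.duration > duration + 1e-9:
            raise ValidationError(f"word {w.text!r} extends beyond stream duration")
    t = np.arange(int(round(duration * rate))) / rate
    values = np.zeros(len(t))
    for w in words:
        values[(t >= w.onset) & (t < w.onset + w.duration)] = 1.0
    return FeatureStream(name="speech", kind="dense", values=values, sampling_rate=rate)


_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def _normalize_word(text: str) -> str:
    return text.lower().translate(_PUNCT_TABLE)


def lexical_feature(
    words: Sequence[TranscriptWord], norms: LexicalNorms, name: str | None = None
) -> FeatureStream:
    """Sparse per-word regressor of z-scored dictionary norms.

    Values are ``(lookup - mean) / sd`` with moments taken from the
    dictionary itself; out-of-vocabulary words get 0, which after the
    rescaling amounts to imputing the dictionary-mean value.
    """
    onsets = np.array([w.onset for w in words], dtype=float)
    durations = np.array([w.duration for w in words], dtype=float)
    values = np.zeros(len(words))
    for i, w in enumerate(words):
        v = norms.lookup(_normalize_word(w.text))
        if v is not None:
            values[i] = (v - norms.mean) / norms.sd
    return FeatureStream(
        name=name or norms.name, kind="sparse",
        onsets=onsets, durations=durations, values=values,
    )


def log10_word_frequency(count: int) -> float:
    """Base-10 log of a word's corpus occurrence count (Log10WF)."""
    if count < 1:
        raise ValidationError("occurrence count must be >= 1")
    return float(np.log10(count))


def text_length(word: str) -> int:
    """Number of characters in a word's transcription."""
    return len(word)


def indicator_from_changepoints(
    times: Sequence[float], rate: float, duration: float, name: str = "shot_change"
) -> FeatureStream:
    """Binary stream that is 1 at the grid sample containing each change point.

    Models shot-change style annotations: the transition time gets a 1, all
    other samples 0.
    """
    if rate <= 0:
        raise ValidationError("rate must be > 0")
    n = int(round(duration * rate))
    values = np.zeros(n)
    for t in times:
        if not 0 <= t < duration:
            raise ValidationError(f"changepoint {t} outside [0, {duration})")
        values[int(t * rate)] = 1.0
    return FeatureStream(name=name, kind="dense", values=values, sampling_rate=rate)


def downsample_dense(
    stream: FeatureStream, target_rate: float = DENSE_INGEST_RATE_HZ
) -> FeatureStream:
    """Bin-average a dense stream down to ``target_rate`` Hz.

    Averaging (rather than decimation) is anti-aliasing and preserves the
    time-average of the input.  Streams already at or below the target rate
    are returned unchanged; incomplete trailing bins are dropped.
    """
    if target_rate <= 0:
        raise ValidationError("target_rate must be > 0")
    if stream.kind != "dense":
        raise ValidationError("downsample_dense requires a dense stream")
    if stream.sampling_rate <= target_rate:
        return stream
    n_in = len(stream.values)
    n_out = int(np.floor(n_in * target_rate / stream.sampling_rate))
    t = np.arange(n_in) / stream.sampling_rate
    bins = np.floor(t * target_rate).astype(int)
    keep = bins < n_out
    sums = np.bincount(bins[keep], weights=stream.values[keep], minlength=n_out)
    counts = np.bincount(bins[keep], minlength=n_out)
    return FeatureStream(
        name=stream.name, kind="dense", values=sums / counts, sampling_rate=target_rate
    )
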