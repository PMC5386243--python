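"""Waveform and annotation I/O for word-segmented speech.

All downstream processing runs at a working rate of 16 kHz. Audio is kept
on its original amplitude scale: the feature coder is invariant to global
gain, so no normalization is applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

WORKING_RATE = 16000

ANNOTATION_COLUMNS = ["audio_file", "start_s", "end_s", "word", "speaker"]


@dataclass(frozen=True)
class AudioSegment:
    """A word token's waveform with its lexome and speaker labels.

    ``samples`` is a 1-D float array (dimensionless amplitude); ``rate`` is
    in samples/second. ``word`` and ``speaker`` may be empty for raw file
    reads that have not been cut into labelled tokens yet.
    """

    samples: np.ndarray
    rate: int
    word: str = ""
    speaker: str = ""
    token_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("AudioSegment requires a nonempty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSegment samples must all be finite")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class AnnotationRecord:
    """One word-boundary row: where in which file a token lies."""

    audio_file: str
    start_s: float
    end_s: float
    word: str
    speaker: str

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"annotation requires 0 <= start < end, got [{self.start_s}, {self.end_s})"
            )
        if not self.word or any(ch.isspace() for ch in self.word) or "_" in self.word:
            raise ValueError(
                f"word label {self.word!r} must be nonempty without whitespace or underscore"
            )


def read_wav(path: str | Path) -> AudioSegment:
    """Read a mono WAV file; integer PCM is scaled to [-1, 1].

    Multi-channel files are rejected outright rather than mixed down:
    dialogue corpora carry per-speaker segments and a silent mixdown would
    corrupt the features.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"WAV file not found: {path}")
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels; "
            "multi-channel input is rejected (no mixdown)"
        )
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioSegment(samples=samples, rate=int(rate))


def write_wav(path: str | Path, segment: AudioSegment, subtype: str = "float") -> None:
    """Write a segment as mono WAV (``"float"`` 32-bit or ``"pcm16"``)."""
    if subtype == "float":
        wavfile.write(path, segment.rate, segment.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(segment.samples, -1.0, 1.0)
        wavfile.write(path, segment.rate, np.round(clipped * 32767.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")


def resample_to_16k(segment: AudioSegment) -> AudioSegment:
    """Resample to the 16 kHz working rate (polyphase, anti-aliased).

    A segment already at 16 kHz is returned unchanged (bitwise identity).
    """
    if segment.rate == WORKING_RATE:
        return segment
    g = math.gcd(WORKING_RATE, segment.rate)
    up, down = WORKING_RATE // g, segment.rate // g
    resampled = resample_poly(segment.samples, up, down)
    return replace(segment, samples=resampled, rate=WORKING_RATE)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a word-level annotation TSV.

    Required columns: audio_file, start_s, end_s, word, speaker. Rows are
    returned in file order; a malformed row raises an error naming it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            start_s, end_s = float(row.start_s), float(row.end_s)
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 1}: non-numeric time: {exc}") from None
        try:
            records.append(
                AnnotationRecord(
                    audio_file=row.audio_file,
                    start_s=start_s,
                    end_s=end_s,
                    word=row.word,
                    speaker=row.speaker,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from None
    return records


def write_annotations(path: str | Path, records: list[AnnotationRecord]) -> None:
    pd.DataFrame([vars(r) for r in records], columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def cut_tokens(
    audio: AudioSegment, annotations: list[AnnotationRecord]
) -> list[AudioSegment]:
    """Cut labelled word tokens out of a longer recording.

    Times map to sample indices as half-open intervals
    [floor(start*rate), floor(end*rate)): deterministic, and adjacent
    annotations never share a sample.
    """
    segments = []
    n = audio.samples.size
    for i, ann in enumerate(annotations):
        lo = math.floor(ann.start_s * audio.rate)
        hi = math.floor(ann.end_s * audio.rate)
        if hi > n:
            raise ValueError(
                f"annotation {i + 1} [{ann.start_s}, {ann.end_s}) s extends beyond "
                f"the audio ({n / audio.rate:.3f} s)"
            )
        segments.append(
            AudioSegment(
                samples=audio.samples[lo:hi],
                rate=audio.rate,
                word=ann.word,
                speaker=ann.speaker,
                token_id=f"{ann.audio_file}:{i + 1}",
            )
        )
    return segments
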