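"""Seeded synthetic multi-speaker word-token corpus.

The generator emulates the structure the model assumes in a word-segmented
spontaneous-speech corpus, without attempting intelligible speech:

* a fixed vocabulary of word types, each realised as a fixed template of
  1-4 amplitude bursts of resonance-filtered noise (2-3 type-specific
  spectral resonances per burst, standing in for formant structure);
* speakers differing by a fixed spectral tilt (dB/octave), a global gain,
  and a small vocal-tract-like frequency scaling of all resonances;
* token-level jitter of burst durations and amplitudes, and an optional
  reduction process that drops a token's final burst (emulating reduced
  conversational forms);
* silent inter-burst gaps longer than the 62.5 ms chunking window, so
  bursts map one-to-one onto envelope-minimum chunks.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfilt

from .audio_io import AudioSegment, AnnotationRecord, write_wav, write_annotations
from .events import TokenRecord, write_events
from .fbs import encode_word_ids

WORKING_RATE = 16000


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    ``gap_ms`` must exceed the 62.5 ms chunking window so each burst maps
    to its own chunk. ``jitter`` is the relative (log-scale) sd of both
    token burst duration and amplitude. ``tilt_sd`` is the across-speaker
    sd of spectral tilt in dB/octave. ``reduction_p`` is the probability
    that a token drops its final burst (a reduced form).
    """

    vocab_size: int = 20
    speakers: int = 4
    tokens_per_type_per_speaker: int = 15
    rate: int = WORKING_RATE
    burst_ms: float = 100.0
    gap_ms: float = 120.0
    jitter: float = 0.15
    tilt_sd: float = 3.0
    reduction_p: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_ms <= 62.5:
            raise ValueError("gap_ms must exceed the 62.5 ms chunking window")
        if min(self.vocab_size, self.speakers, self.tokens_per_type_per_speaker) < 1:
            raise ValueError("all corpus counts must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")
        if not (0 <= self.reduction_p <= 1):
            raise ValueError("reduction_p must be a probability")


@dataclass(frozen=True)
class _BurstTemplate:
    centers_hz: np.ndarray  # 2-3 resonance centres
    bandwidths_hz: np.ndarray
    gains: np.ndarray


@dataclass(frozen=True)
class _WordTemplate:
    label: str
    bursts: tuple[_BurstTemplate, ...]


@dataclass(frozen=True)
class _Speaker:
    label: str
    tilt_db_per_octave: float
    gain: float
    freq_scale: float


def _make_templates(config: GeneratorConfig, rng: np.random.Generator) -> list[_WordTemplate]:
    templates = []
    for v in range(config.vocab_size):
        n_bursts = int(rng.integers(1, 5))
        bursts = []
        for _ in range(n_bursts):
            n_res = int(rng.integers(2, 4))
            centers = np.exp(rng.uniform(np.log(300.0), np.log(6000.0), size=n_res))
            bursts.append(
                _BurstTemplate(
                    centers_hz=centers,
                    bandwidths_hz=rng.uniform(200.0, 500.0, size=n_res),
                    gains=rng.uniform(0.5, 1.0, size=n_res),
                )
            )
        templates.append(_WordTemplate(label=f"word{v:02d}", bursts=tuple(bursts)))
    return templates


def _make_speakers(config: GeneratorConfig, rng: np.random.Generator) -> list[_Speaker]:
    return [
        _Speaker(
            label=f"spk{s}",
            tilt_db_per_octave=float(rng.normal(0.0, config.tilt_sd)),
            gain=float(np.exp(rng.normal(0.0, 0.3))),
            freq_scale=float(np.exp(rng.normal(0.0, 0.05))),
        )
        for s in range(config.speakers)
    ]


def _apply_tilt(samples: np.ndarray, tilt_db_per_octave: float, rate: int) -> np.ndarray:
    """Reshape a burst's spectrum by tilt dB/octave relative to 1 kHz."""
    spectrum = np.fft.rfft(samples)
    freqs = np.fft.rfftfreq(samples.size, d=1.0 / rate)
    octaves = np.log2(np.maximum(freqs, 50.0) / 1000.0)
    spectrum *= 10.0 ** (tilt_db_per_octave * octaves / 20.0)
    return np.fft.irfft(spectrum, n=samples.size)


def _synth_burst(
    template: _BurstTemplate,
    speaker: _Speaker,
    n_samples: int,
    amplitude: float,
    rate: int,
    rng: np.random.Generator,
) -> np.ndarray:
    noise = rng.standard_normal(n_samples)
    out = np.zeros(n_samples)
    nyq = rate / 2
    for c, bw, g in zip(template.centers_hz, template.bandwidths_hz, template.gains):
        c = c * speaker.freq_scale
        lo = max(c - bw / 2, 50.0)
        hi = min(c + bw / 2, nyq - 100.0)
        if hi <= lo:
            continue
        sos = butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
        out += g * sosfilt(sos, noise)
    out = _apply_tilt(out, speaker.tilt_db_per_octave, rate)
    out *= np.hanning(n_samples)
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= amplitude * speaker.gain / peak
    return out


def _synth_token(
    template: _WordTemplate,
    speaker: _Speaker,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    bursts = list(template.bursts)
    if len(bursts) > 1 and rng.random() < config.reduction_p:
        bursts = bursts[:-1]  # reduced form: final burst dropped
    gap = np.zeros(int(round(config.gap_ms / 1000.0 * config.rate)))
    pieces = []
    for i, burst in enumerate(bursts):
        dur_ms = config.burst_ms * np.exp(rng.normal(0.0, config.jitter))
        amp = np.exp(rng.normal(0.0, config.jitter))
        n = max(int(round(dur_ms / 1000.0 * config.rate)), 160)
        if i > 0:
            pieces.append(gap)
        pieces.append(_synth_burst(burst, speaker, n, amp, config.rate, rng))
    return np.concatenate(pieces)


def make_burst_train(
    n_bursts: int,
    seed: int = 0,
    burst_ms: float = 100.0,
    gap_ms: float = 120.0,
    rate: int = WORKING_RATE,
) -> AudioSegment:
    """One standalone token of noise bursts separated by silent gaps.

    Useful for exercising the chunker: with gaps longer than the 62.5 ms
    rolling window, each burst becomes one chunk.
    """
    rng = np.random.default_rng(seed)
    template = _BurstTemplate(
        centers_hz=np.array([500.0, 1500.0, 3000.0]),
        bandwidths_hz=np.array([300.0, 400.0, 500.0]),
        gains=np.array([1.0, 0.8, 0.6]),
    )
    speaker = _Speaker(label="ref", tilt_db_per_octave=0.0, gain=1.0, freq_scale=1.0)
    n = max(int(round(burst_ms / 1000.0 * rate)), 160)
    gap = np.zeros(int(round(gap_ms / 1000.0 * rate)))
    pieces = []
    for i in range(n_bursts):
        if i > 0:
            pieces.append(gap)
        pieces.append(_synth_burst(template, speaker, n, 1.0, rate, rng))
    return AudioSegment(
        samples=np.concatenate(pieces), rate=rate, word="burst-train",
        speaker="ref", token_id=f"burst-train-{n_bursts}",
    )


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[AudioSegment], list[AnnotationRecord]]:
    """Generate the labelled token corpus.

    Produces vocab_size * speakers * tokens_per_type_per_speaker word
    tokens, each its own segment, with matching annotation records (one
    per token, covering the whole token file). Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    templates = _make_templates(config, rng)
    speakers = _make_speakers(config, rng)
    segments: list[AudioSegment] = []
    annotations: list[AnnotationRecord] = []
    for speaker in speakers:
        for template in templates:
            for k in range(config.tokens_per_type_per_speaker):
                token_id = f"{speaker.label}-{template.label}-{k:03d}"
                samples = _synth_token(template, speaker, config, rng)
                segments.append(
                    AudioSegment(
                        samples=samples,
                        rate=config.rate,
                        word=template.label,
                        speaker=speaker.label,
                        token_id=token_id,
                    )
                )
                annotations.append(
                    AnnotationRecord(
                        audio_file=f"{token_id}.wav",
                        start_s=0.0,
                        end_s=samples.size / config.rate,
                        word=template.label,
                        speaker=speaker.label,
                    )
                )
    return segments, annotations


def encode_corpus(segments: list[AudioSegment]) -> list[TokenRecord]:
    """Run the FBS coder over every token of a corpus."""
    return [
        TokenRecord(
            token_id=seg.token_id,
            word=seg.word,
            speaker=seg.speaker,
            cues=encode_word_ids(seg),
        )
        for seg in segments
    ]


def generate_event_stream(
    config: GeneratorConfig, shuffle_seed: int | None = None
) -> list[TokenRecord]:
    """Generate, encode and shuffle the corpus into one training order.

    The shuffle emulates tokens appearing interleaved across speakers in
    running dialogue; ``shuffle_seed`` defaults to the corpus seed.
    """
    segments, _ = generate_corpus(config)
    tokens = encode_corpus(segments)
    rng = np.random.default_rng(config.seed if shuffle_seed is None else shuffle_seed)
    order = rng.permutation(len(tokens))
    return [tokens[i] for i in order]


def write_corpus(
    out_dir: str | Path, config: GeneratorConfig, shuffle_seed: int | None = None
) -> dict:
    """Materialise a corpus on disk: WAVs, annotations TSV, events TSV."""
    out_dir = Path(out_dir)
    wav_dir = out_dir / "wav"
    wav_dir.mkdir(parents=True, exist_ok=True)
    segments, annotations = generate_corpus(config)
    for seg in segments:
        write_wav(wav_dir / f"{seg.token_id}.wav", seg)
    write_annotations(out_dir / "annotations.tsv", annotations)
    tokens = encode_corpus(segments)
    rng = np.random.default_rng(config.seed if shuffle_seed is None else shuffle_seed)
    order = rng.permutation(len(tokens))
    write_events(out_dir / "events.tsv", [tokens[i] for i in order])
    return {"n_tokens": len(segments), "wav_dir": str(wav_dir)}
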