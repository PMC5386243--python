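"""By-word Frequency Band Summary (FBS) coding of speech.

A word token's waveform is turned into a small set of discrete cues in four
stages:

1. the Hilbert amplitude envelope is computed and smoothed with a Daniell
   (moving-average) kernel;
2. the signal is partitioned into chunks at envelope minima, detected with
   a rolling 1000-sample (62.5 ms at 16 kHz) window;
3. each chunk is analysed into a 21-band mel power matrix (5 ms frames,
   64 spectral bands over 0-8000 Hz) and discretized to s=5 intensity
   levels by min-max scaling of log power;
4. each of the 21 band rows is summarised by its first, median, minimum,
   maximum and last level, yielding one FBS feature per band per chunk.

FBS features are robust to speech rate and require no speaker
normalization; downstream, a feature is just an opaque identifier string
such as ``band1start1median2min1max4end2part1``.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .audio_io import AudioSegment, WORKING_RATE

#: smoothing kernel dimension m; the moving average spans 2m+1 samples
KERNEL_DIM = 800
#: rolling-minimum window for chunk boundary detection, in samples
CHUNK_WINDOW = 1000
#: analysis frame length: 5 ms at 16 kHz
FRAME_LEN = 80
#: FFT length per frame; bins 1..64 cover 0-8000 Hz in 125 Hz steps
N_FFT = 128
N_SPECTRAL_BANDS = 64
N_MEL_BANDS = 21
#: number of discrete intensity levels s
N_LEVELS = 5
#: relative floor applied to power before taking logs
LOG_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class Envelope:
    """Smoothed Hilbert amplitude envelope of a signal."""

    values: np.ndarray
    kernel_dim: int = KERNEL_DIM

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.size == 0:
            raise ValueError("envelope must be nonempty")
        if np.any(values < 0):
            raise ValueError("envelope values must be nonnegative")


@dataclass(frozen=True)
class ChunkSpan:
    """Half-open sample span [start, end) of one chunk; part is 1-based."""

    start: int
    end: int
    part: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid chunk span [{self.start}, {self.end})")
        if self.part < 1:
            raise ValueError("chunk part numbering starts at 1")


@dataclass(frozen=True)
class SpectralMatrix:
    """21 x n_frames mel-band power matrix (linear power) for one chunk."""

    M: np.ndarray
    band_edges_hz: np.ndarray
    frame_len: int = FRAME_LEN

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=np.float64)
        object.__setattr__(self, "M", M)
        if M.ndim != 2 or M.shape[0] != N_MEL_BANDS:
            raise ValueError(f"spectral matrix must have {N_MEL_BANDS} rows")
        if np.any(M < 0):
            raise ValueError("band powers must be nonnegative")


@dataclass(frozen=True)
class DiscretizedSpectrum:
    """Integer intensity matrix with entries in {1..s}."""

    Ms: np.ndarray
    s: int = N_LEVELS

    def __post_init__(self) -> None:
        Ms = np.asarray(self.Ms, dtype=np.int64)
        object.__setattr__(self, "Ms", Ms)
        if Ms.size and (Ms.min() < 1 or Ms.max() > self.s):
            raise ValueError(f"discretized entries must lie in 1..{self.s}")


def _fmt(v: float) -> str:
    """Render a summary value: integers without decimals, else e.g. '2.5'."""
    return format(float(v), "g")


@dataclass(frozen=True)
class FBSFeature:
    """One Frequency Band Summary: a discrete cue for the learner.

    ``band`` indexes the mel band (1-21), ``part`` the chunk; the five
    summaries are discretized intensity levels (the median of an
    even-length row may be a half-integer).
    """

    band: int
    start: float
    median: float
    min: float
    max: float
    end: float
    part: int
    id: str = field(init=False)

    def __post_init__(self) -> None:
        if not (self.min <= self.start <= self.max):
            raise ValueError("first value must lie between min and max")
        if not (self.min <= self.end <= self.max):
            raise ValueError("last value must lie between min and max")
        if not (self.min <= self.median <= self.max):
            raise ValueError("median must lie between min and max")
        object.__setattr__(
            self,
            "id",
            f"band{self.band}start{_fmt(self.start)}median{_fmt(self.median)}"
            f"min{_fmt(self.min)}max{_fmt(self.max)}end{_fmt(self.end)}part{self.part}",
        )


def compute_envelope(segment: AudioSegment, kernel_dim: int = KERNEL_DIM) -> Envelope:
    """Smoothed Hilbert amplitude envelope.

    The modulus of the analytic signal is smoothed with a Daniell kernel of
    dimension ``kernel_dim``, i.e. a moving average over 2*kernel_dim+1
    samples (edges are zero-padded).
    """
    if segment.rate != WORKING_RATE:
        raise ValueError(f"envelope expects {WORKING_RATE} Hz audio, got {segment.rate}")
    magnitude = np.abs(hilbert(segment.samples))
    size = 2 * kernel_dim + 1
    smoothed = uniform_filter1d(magnitude, size=size, mode="constant", cval=0.0)
    # numerical noise can push an all-but-zero average fractionally negative
    np.maximum(smoothed, 0.0, out=smoothed)
    return Envelope(values=smoothed, kernel_dim=kernel_dim)


def find_chunks(envelope: Envelope, window: int = CHUNK_WINDOW) -> list[ChunkSpan]:
    """Partition a signal at envelope minima found by a rolling window.

    A boundary is placed at every index i where the first position
    attaining the minimum of the ``window``-sample window
    [i - window//2, i + window//2) is i itself (evaluated only where the
    full window fits). Requiring the *first* minimum to sit at the centre
    makes every position independently testable and keeps flat stretches
    from cascading into boundary runs: a silent gap yields exactly one
    boundary (at the onset of its envelope minimum), a constant or
    monotone envelope yields none. A boundary sample starts the next
    chunk. A signal shorter than the window is one chunk.
    """
    env = envelope.values
    n = env.size
    half = window // 2
    spans: list[int] = []
    if n > window:
        windows = np.lib.stride_tricks.sliding_window_view(env, window)
        first_min = windows.argmin(axis=1)  # argmin returns the first minimum
        # centre i corresponds to the window starting at i - half
        centers = np.arange(half, n - (window - half) + 1)
        spans = [int(i) for i in centers[first_min[centers - half] == half] if 0 < i < n]
    bounds = [0, *spans, n]
    return [
        ChunkSpan(start=lo, end=hi, part=p)
        for p, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1)
        if hi > lo
    ]


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_band_edges_hz(
    n_bands: int = N_MEL_BANDS, f_max: float = WORKING_RATE / 2
) -> np.ndarray:
    """Edges (Hz) of ``n_bands`` equal-width mel bands over [0, f_max]."""
    return np.asarray(_mel_to_hz(np.linspace(0.0, _hz_to_mel(f_max), n_bands + 1)))


def _mel_pooling_matrix() -> np.ndarray:
    """21 x 64 matrix pooling spectral-band power into mel bands.

    Spectral band k (1-based) covers [(k-1)*125, k*125) Hz; its power is
    split across mel bands proportionally to overlap on the mel axis, so
    every mel band receives power and pooling is linear (a global gain on
    the signal scales all band powers equally).
    """
    hz_edges = np.arange(N_SPECTRAL_BANDS + 1) * (WORKING_RATE / 2 / N_SPECTRAL_BANDS)
    mel_spec = np.asarray(_hz_to_mel(hz_edges))
    mel_edges = np.linspace(0.0, float(_hz_to_mel(WORKING_RATE / 2)), N_MEL_BANDS + 1)
    P = np.zeros((N_MEL_BANDS, N_SPECTRAL_BANDS))
    for k in range(N_SPECTRAL_BANDS):
        lo, hi = mel_spec[k], mel_spec[k + 1]
        overlap_lo = np.maximum(mel_edges[:-1], lo)
        overlap_hi = np.minimum(mel_edges[1:], hi)
        P[:, k] = np.maximum(overlap_hi - overlap_lo, 0.0) / (hi - lo)
    return P


_MEL_POOL = _mel_pooling_matrix()


def spectral_matrix(chunk: np.ndarray, rate: int = WORKING_RATE) -> SpectralMatrix:
    """Mel-band power matrix of one chunk.

    The chunk is cut into non-overlapping 5 ms frames (80 samples;
    n_frames = floor(len/80)); each frame is zero-padded to 128 samples
    and its 64 positive-frequency power-spectrum bands (0-8000 Hz, DC
    dropped) are pooled into 21 equal-width mel bands.
    """
    chunk = np.asarray(chunk, dtype=np.float64)
    if rate != WORKING_RATE:
        raise ValueError(f"spectral analysis expects {WORKING_RATE} Hz audio")
    n_frames = chunk.size // FRAME_LEN
    if n_frames < 1:
        raise ValueError(
            f"chunk of {chunk.size} samples is shorter than one {FRAME_LEN}-sample frame"
        )
    frames = chunk[: n_frames * FRAME_LEN].reshape(n_frames, FRAME_LEN)
    spectrum = np.fft.rfft(frames, n=N_FFT, axis=1)
    power = np.abs(spectrum[:, 1 : N_SPECTRAL_BANDS + 1]) ** 2  # frames x 64
    M = _MEL_POOL @ power.T  # 21 x n_frames
    return SpectralMatrix(M=M, band_edges_hz=mel_band_edges_hz())


def discretize(
    matrix: SpectralMatrix, s: int = N_LEVELS, log_floor_rel: float = LOG_FLOOR_REL
) -> DiscretizedSpectrum:
    """Min-max discretization of log band power to levels {1..s}.

    Levels are ceil(s * (logM - min) / |min - max|); the value 0 produced
    at the matrix minimum is clamped to 1 so the level range is {1..s} and
    the maximum maps exactly to s. Power is floored at ``log_floor_rel``
    times the matrix maximum before the log, so exact zeros are defined and
    a global gain on the signal cancels. A constant matrix (the scaling is
    undefined) maps everything to level 1.
    """
    M = matrix.M
    peak = M.max()
    if peak <= 0:
        warnings.warn("all-zero spectral matrix; discretizing to the lowest level")
        return DiscretizedSpectrum(Ms=np.ones(M.shape, dtype=np.int64), s=s)
    logM = np.log(np.maximum(M, log_floor_rel * peak))
    lo, hi = logM.min(), logM.max()
    if hi == lo:
        warnings.warn("constant log-power matrix; discretizing to the lowest level")
        return DiscretizedSpectrum(Ms=np.ones(M.shape, dtype=np.int64), s=s)
    Ms = np.ceil(s * (logM - lo) / (hi - lo)).astype(np.int64)
    np.clip(Ms, 1, s, out=Ms)
    return DiscretizedSpectrum(Ms=Ms, s=s)


def summarize_band(row: np.ndarray, band: int, part: int) -> FBSFeature:
    """Summarise one discretized band row as an FBS feature.

    The summary records the row's first, median (standard sample median;
    even-length rows may yield half-integers), minimum, maximum and last
    intensity level, tagged with the band number and chunk index.
    """
    row = np.asarray(row)
    if row.size == 0:
        raise ValueError("cannot summarise an empty band row")
    return FBSFeature(
        band=band,
        start=float(row[0]),
        median=float(np.median(row)),
        min=float(row.min()),
        max=float(row.max()),
        end=float(row[-1]),
        part=part,
    )


def _merge_short_chunks(spans: list[ChunkSpan], min_len: int = FRAME_LEN) -> list[ChunkSpan]:
    """Merge chunks shorter than one frame into the preceding chunk
    (the following one if the first chunk is short)."""
    merged: list[tuple[int, int]] = []
    for span in spans:
        if merged and (span.end - span.start < min_len or merged[-1][1] - merged[-1][0] < min_len):
            merged[-1] = (merged[-1][0], span.end)
        else:
            merged.append((span.start, span.end))
    return [ChunkSpan(start=lo, end=hi, part=p) for p, (lo, hi) in enumerate(merged, start=1)]


def encode_word(
    segment: AudioSegment,
    s: int = N_LEVELS,
    window: int = CHUNK_WINDOW,
    kernel_dim: int = KERNEL_DIM,
) -> set[FBSFeature]:
    """Run the full FBS pipeline on a word token.

    Returns 21 features per chunk (features carry their chunk index, so a
    word with N chunks always yields exactly 21*N features).
    """
    envelope = compute_envelope(segment, kernel_dim=kernel_dim)
    spans = _merge_short_chunks(find_chunks(envelope, window=window))
    features: set[FBSFeature] = set()
    for span in spans:
        matrix = spectral_matrix(segment.samples[span.start : span.end])
        levels = discretize(matrix, s=s)
        for band in range(N_MEL_BANDS):
            features.add(summarize_band(levels.Ms[band], band=band + 1, part=span.part))
    return features


def encode_word_ids(segment: AudioSegment, **kwargs) -> set[str]:
    """Feature identifiers of a token (the learner's cue set)."""
    return {f.id for f in encode_word(segment, **kwargs)}


_NUM = r"(\d+(?:\.\d+)?)"
_ID_RE = re.compile(
    rf"band(\d+)start{_NUM}median{_NUM}min{_NUM}max{_NUM}end{_NUM}part(\d+)$"
)
_TOKENS = ("band", "start", "median", "min", "max", "end", "part")


def parse_feature(identifier: str) -> FBSFeature:
    """Parse a canonical FBS identifier back into its fields.

    ``parse_feature(f.id)`` reproduces ``f`` for any valid feature; a
    malformed identifier raises an error naming the first violated token.
    """
    m = _ID_RE.match(identifier)
    if m is None:
        pos = 0
        for tok in _TOKENS:
            if not identifier.startswith(tok, pos):
                raise ValueError(
                    f"malformed FBS identifier {identifier!r}: expected {tok!r} "
                    f"at position {pos}"
                )
            pos += len(tok)
            num = re.match(r"\d+" if tok in ("band", "part") else _NUM, identifier[pos:])
            if num is None:
                raise ValueError(
                    f"malformed FBS identifier {identifier!r}: expected a number "
                    f"after {tok!r}"
                )
            pos += num.end()
        raise ValueError(f"malformed FBS identifier {identifier!r}: trailing text")
    band, start, median, vmin, vmax, end, part = m.groups()
    return FBSFeature(
        band=int(band),
        start=float(start),
        median=float(median),
        min=float(vmin),
        max=float(vmax),
        end=float(end),
        part=int(part),
    )
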