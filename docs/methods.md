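# Methods

This note records the model as implemented, the numerical choices made
where the procedure left room, what the synthetic corpus does and does not
emulate, and the known limitations.

## Audio conventions

Audio is mono WAV (16-bit PCM or IEEE float); integer PCM is scaled to
[-1, 1] on read. Everything downstream runs at 16 kHz; other rates are
resampled with `scipy.signal.resample_poly` (polyphase, anti-aliased).
Multi-channel input is rejected rather than mixed down: in dialogue
corpora the channels carry different speakers, and a silent mixdown would
corrupt the token's spectrum. No amplitude normalization is applied at any
point — the coder is exactly invariant to global gain (see below), so
corpus recordings at different volumes need no preprocessing.

Word boundaries map to samples as half-open intervals
`[floor(start*rate), floor(end*rate))`: deterministic, and adjacent
annotations never share a sample. Whether the source corpora treat end
times as inclusive is unknowable from the annotations alone; half-open is
this package's convention.

## FBS coding

**Envelope.** The amplitude envelope is `|hilbert(x)|` smoothed with a
Daniell kernel of dimension 800, implemented as a moving average over
2·800+1 = 1601 samples (the standard time-series convention for a Daniell
kernel of dimension m), zero-padded at the edges. The kernel dimension and
the factor-of-two convention are arguments of `compute_envelope`.

**Chunking.** A chunk boundary is placed at index i when the *first*
position attaining the minimum of the 1000-sample window centred on i
(`[i-500, i+500)`, evaluated only where the window fits) is i itself —
the rolling "is the middle the smallest value" test. Requiring the first
minimum keeps ties well behaved: a silent stretch produces exactly one
boundary (at the onset of its envelope minimum) instead of a cascade, a
constant or monotone envelope produces none, and every position is
independently testable, which is how the test suite's brute-force oracle
checks the implementation. The boundary sample starts the next chunk.
Chunks shorter than one 5 ms frame are merged into the preceding chunk
(the following one if the first is short), since spectral analysis needs
at least one frame.

**Spectral analysis.** Each chunk is cut into non-overlapping 5 ms frames
(80 samples; a trailing partial frame is dropped, so n_frames =
floor(len/80)). A frame is zero-padded to 128 samples and transformed
with a rectangular window; the 64 positive-frequency power bands cover
0–8000 Hz in 125 Hz steps (the DC bin is dropped). Band powers are pooled
into 21 equal-width mel bands spanning mel(0)–mel(8000)
(mel = 2595·log10(1+f/700)). Because the lowest mel bands are narrower
than 125 Hz, whole-bin assignment would leave them empty; instead each
125 Hz band's power is split across mel bands proportionally to its
overlap on the mel axis. This pooling is linear in power, so a global
gain g scales every entry of **M** by g², which the discretizer then
cancels. Window choice and FFT length are the least-surprising
realizations of "5 ms frames, 64 bands"; they are module constants, not
claims about the original coder.

**Discretization.** Levels are `ceil(s·(logM − min)/(max − min))` with
s = 5. The matrix minimum yields ceil(0) = 0, which is clamped to 1 so the
level range is {1..5} and the maximum maps exactly to 5, matching the
worked identifier whose values start at 1. Powers are floored at 1e-12 of
the matrix maximum before the log (a *relative* floor, preserving gain
invariance); a constant matrix, for which the scaling is undefined, maps
to all-1 with a warning.

**Summaries.** Per band row: first, median, min, max, last level plus
band and chunk number, rendered as
`band{b}start{a}median{m}min{lo}max{hi}end{z}part{p}`. The median is the
standard sample median, so even-length rows can produce half-integers
(`median2.5`), rendered without trailing zeros. Identifiers round-trip
through `parse_feature` exactly.

## Learning and decision measures

The learner is plain Rescorla–Wagner with a single global learning rate
η = α·β = 0.001 and asymptote λ = 1.0. All weight changes within an event
are computed from pre-event weights; duplicate cues collapse to a set;
outcomes never yet encountered receive no decrement; events with empty
cue sets are skipped. Storage is sparse (per-cue dict of outcome
weights): a pair never co-seen with an active cue is simply absent and
contributes exactly 0. The single-pair closed form λ(1−(1−η)^t) and a
dense brute-force reference implementation serve as independent oracles
in the tests.

Activation of an outcome is the sum of afferent weights from the active
cues (unknown cues contribute nothing); the best candidate is the argmax,
with exact ties broken toward the lexicographically smallest label so
runs are reproducible across platforms. The L1-norm sums absolute
activations over all known outcomes.

Pruning removes exactly floor(fraction·stored) connections of smallest
magnitude; ties at the cutoff are resolved by removing earlier-registered
pairs first. Registries and parameters survive pruning, and the input
network is never mutated.

Models persist as a directory: Matrix Market coordinate file at 17
significant digits (lossless for float64), cue/outcome label sidecars in
registry order, and a JSON parameter header. Identical event streams
produce byte-identical model files.

## Evaluation procedures

*Held-out accuracy* trains on the corpus minus the stimulus sample
(corpus order preserved) and scores the stimuli; accuracy denominators
always count the full test set. *Stimulus sampling* draws uniformly
without replacement among tokens whose word type occurs at least 11 times
in the corpus, so held-out types almost surely retain training tokens.
*Leave-one-speaker-out* builds one fold per speaker and evaluates only
in-vocabulary tokens — those whose type occurs at least once in the
training fold — reporting per-fold, pooled (micro) and macro-averaged
accuracy; pooled is the headline number. *Accommodation* splits the
held-out speaker's tokens 50/50 (seeded) into an adaptation half added to
training and an evaluation half, and reports the accuracy delta together
with the speaker's count of novel FBS features (features no other speaker
produces); with adaptation fraction 0 the delta is exactly 0 by
construction. *Feature distribution* groups features by their corpus
frequency (frequency of frequencies, no further binning) and fits the
log–log least-squares slope.

## The synthetic corpus

The generator emulates the *structure* the model assumes in a
word-segmented spontaneous-speech corpus: word types realized as 1–4
noise bursts with 2–3 type-specific band-pass resonances (a stand-in for
formant structure); speakers differing by spectral tilt
(sd 3 dB/octave), overall gain, and a ±5%-scale vocal-tract-like
frequency shift of all resonances; per-token log-normal jitter of burst
duration and amplitude (sd 0.15 around a 100 ms burst mean); and a
reduction process dropping a token's final burst with p = 0.1, emulating
reduced conversational forms. Bursts are separated by 120 ms silent
gaps — comfortably longer than the 62.5 ms chunking window — so bursts
map one-to-one onto chunks. The default corpus is 20 word types ×
4 speakers × 15 tokens each (1200 tokens), shuffled into a single
training order.

Chosen where unstated: burst duration (syllable-scale), jitter and tilt
magnitudes (within the range of natural token variability and voice-
quality differences), and the resonance range 300–6000 Hz. These were
fixed once as plausible speech-like values.

What the generator does **not** emulate: continuous coarticulated speech,
pitch and voicing, within-word envelope structure beyond bursts, channel
noise, or any lexical-frequency skew (all types are equally frequent).
Consequently, passing the end-to-end tests shows that the pipeline
learns burst-resonance word classes under speaker variation — it does not
certify accuracy levels on real conversational speech, where
identification accuracy is known to be far lower.

## Problem sizes and runtime

The test suite and the reproduction script run at desk scale: the default
1200-token corpus (~10 s to synthesize and encode), 50 random event
streams for the oracle comparison, 10⁴ events for the closed-form
trajectory. Training itself is linear in events × active cues × touched
outcomes and takes well under a second at these sizes.

## Known limitations

- The exact spectral pipeline of the original coder (frame window, power
  scaling, mel pooling) is underdetermined; identifiers produced by this
  package are internally consistent but need not match another
  implementation's bit-for-bit on real audio.
- Per-cue saliences, continuous-outcome (Widrow–Hoff) variants, and
  equilibrium solutions of the learning rule are out of scope, as are
  semantic vector spaces: lexomes stay opaque identifiers.
- Activations are unbounded in principle; they merely tend to fall in
  [-1, 1] and nothing enforces that.
- `sample_stimuli` mirrors the stimulus-selection procedure but the
  package makes no attempt to model human response data.
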