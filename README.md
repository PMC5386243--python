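# widelearn

Auditory word recognition without phonemes. `widelearn` implements a
"wide learning" model of spoken word identification: the speech signal of
a word token is coded into a small set of **discrete acoustic cues** —
Frequency Band Summary (FBS) features — and those cues feed a two-layer
network, trained with the **Rescorla–Wagner** error-driven learning rule,
whose output units are *lexomes* (opaque word identifiers, pointers into
semantic space). There is no phone or syllable layer anywhere: the model
goes straight from cochlear-style spectral summaries to words.

The package is for researchers in computational cognitive science and
psycholinguistics who want to train, probe, and evaluate this model —
on their own word-segmented speech corpora (WAV + annotation TSV) or on
the built-in synthetic multi-speaker corpus generator.

## The model

**FBS coding.** A word token (resampled to 16 kHz) is partitioned into
chunks at minima of its smoothed Hilbert amplitude envelope (Daniell
kernel of dimension 800; minima found with a rolling 1000-sample, 62.5 ms
window). Each chunk is analysed in non-overlapping 5 ms frames into 64
spectral bands (0–8000 Hz), pooled into 21 equal-width mel bands, giving a
time×frequency power matrix **M**. Intensities are discretized by

    Ms = ceil( s · (log M − min) / |min − max| ),   s = 5,

and each of the 21 band rows is summarised by its first, median, minimum,
maximum and last level, e.g. `band1start1median2min1max4end2part1`. A word
with *N* chunks thus contributes *N*×21 discrete cues. The code is
invariant to global amplitude and tolerant of speech-rate and speaker
variation.

**Wide learning.** For each learning event *t* (the token's cue set C_t,
its lexome as outcome), every weight w_ij from an active cue c_i changes by

    Δw_ij = η · (λ · 1[o_j present] − Σ_{m: c_m ∈ C_t} w_mj)

with λ = 1.0 and η = α·β = 0.001, for every outcome seen so far; weights
of inactive cues, and of never-co-seen pairs, are untouched. Decision
measures: the **activation** a(O_j) of an outcome is the sum of afferent
weights from the stimulus's active cues; the argmax outcome is the model's
best candidate; the **L1-norm** Σ_j |a(O_j)| measures overall support for
lexicality. After training, the weight matrix can be pruned by magnitude
with essentially no accuracy cost.

**Evaluation procedures.** Held-out identification accuracy with stimulus
sampling restricted to types occurring ≥ 11 times, leave-one-speaker-out
cross-validation over in-vocabulary tokens, speaker-accommodation deltas
(accuracy with vs. without a held-out speaker's audio in training, against
their count of novel FBS features), pruning–accuracy curves, and the
grouped feature-frequency power-law diagnostic.

## Worked example

Generate a small synthetic corpus (8 word types, 2 speakers, 10 tokens
per type per speaker), train, and evaluate:

```sh
widelearn simulate --out demo --vocab-size 8 --speakers 2 \
    --tokens-per-type-per-speaker 10 --seed 7
# wrote 160 tokens to demo
widelearn train --events demo/events.tsv --out demo/model
# trained on 160 events: 1247 cues, 8 outcomes -> demo/model
widelearn evaluate --model demo/model --events demo/events.tsv --report demo/report.json
# accuracy 0.881 on 160 tokens
widelearn prune-curve --model demo/model --events demo/events.tsv \
    --fractions 0,0.9 --out demo/curve.json
# fraction 0.00: accuracy 0.881
# fraction 0.90: accuracy 0.863
```

The simulated corpus yields 1247 distinct FBS cues for 8 lexomes; the
trained network identifies 88.1% of the tokens (chance is 12.5%), and
removing the 90% smallest-magnitude connections moves accuracy by less
than 2 points — the signature behaviour of the wide network: knowledge
concentrates in a sparse subset of strong cue→lexome connections.
`demo/events.tsv` shows the cue code itself: one row per token, FBS
identifiers joined by `_`.

The same pipeline runs on real recordings via
`widelearn encode --wav FILE --annotations TSV --out events.tsv`, where
the TSV lists `audio_file`, `start_s`, `end_s`, `word`, `speaker` per
token, and `widelearn loso --events events.tsv --out loso.json` for the
speaker cross-validation.

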