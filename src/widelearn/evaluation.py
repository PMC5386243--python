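"""Evaluation procedures for the wide learning model.

Covers held-out identification accuracy, stimulus sampling with a
type-frequency floor, leave-one-speaker-out cross-validation, speaker
accommodation deltas, pruning-accuracy curves and the grouped FBS
feature-frequency diagnostic (the power-law check).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .events import TokenRecord
from .network import LearningEvent, WeightMatrix, train, DEFAULT_ETA, DEFAULT_LAMBDA

logger = logging.getLogger(__name__)

MIN_TYPE_COUNT = 11


@dataclass(frozen=True)
class EvalReport:
    """Identification results for one test set.

    ``per_token`` holds, per token, the predicted lexome, whether it was
    correct, its activation, and the stimulus L1-norm (lexicality).
    """

    n_tokens: int
    n_correct: int
    per_token: list[dict] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_tokens

    def to_dict(self) -> dict:
        return {
            "n_tokens": self.n_tokens,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "per_token": self.per_token,
        }


def tokens_to_events(tokens: Iterable[TokenRecord]) -> list[LearningEvent]:
    return [
        LearningEvent(cues=t.cues, outcomes=frozenset({t.word}), order_index=i + 1)
        for i, t in enumerate(tokens)
    ]


def evaluate(weights: WeightMatrix, test: Sequence[TokenRecord]) -> EvalReport:
    """Identify each test token and report accuracy plus per-token measures."""
    if not test:
        raise ValueError("cannot evaluate on an empty test set")
    if not weights.known_outcomes:
        raise ValueError("cannot evaluate an untrained model (no known outcomes)")
    per_token = []
    n_correct = 0
    for t in test:
        av = weights.activate(t.cues)
        predicted = av.best
        correct = predicted == t.word
        n_correct += correct
        per_token.append(
            {
                "token_id": t.token_id,
                "word": t.word,
                "predicted": predicted,
                "correct": bool(correct),
                "activation": av.activations[predicted],
                "l1": av.l1,
            }
        )
    return EvalReport(n_tokens=len(test), n_correct=n_correct, per_token=per_token)


def sample_stimuli(
    corpus: Sequence[TokenRecord],
    n: int,
    min_type_count: int = MIN_TYPE_COUNT,
    seed: int = 0,
) -> list[TokenRecord]:
    """Sample n stimulus tokens uniformly without replacement.

    Only tokens whose word type occurs at least ``min_type_count`` times in
    the corpus are eligible; the floor makes it statistically likely that
    some tokens of every sampled type remain in the training data.
    """
    if not corpus:
        raise ValueError("cannot sample from an empty corpus")
    type_counts = Counter(t.word for t in corpus)
    eligible = [i for i, t in enumerate(corpus) if type_counts[t.word] >= min_type_count]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} tokens belong to types with >= {min_type_count} "
            f"tokens; cannot sample {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n, replace=False)
    return [corpus[eligible[i]] for i in sorted(chosen)]


def holdout_eval(
    corpus: Sequence[TokenRecord],
    stimuli: Sequence[TokenRecord],
    lam: float = DEFAULT_LAMBDA,
    eta: float = DEFAULT_ETA,
) -> EvalReport:
    """Train on the corpus minus the stimuli (corpus order preserved) and
    evaluate on the stimuli."""
    if not stimuli:
        raise ValueError("empty holdout set")
    held = {t.token_id for t in stimuli}
    training = [t for t in corpus if t.token_id not in held]
    trained_types = {t.word for t in training}
    oov = {t.word for t in stimuli} - trained_types
    if oov:
        warnings.warn(
            f"{len(oov)} word type(s) are entirely held out and cannot be recognised: "
            f"{sorted(oov)[:5]}..."
        )
    weights = train(tokens_to_events(training), lam=lam, eta=eta)
    return evaluate(weights, stimuli)


def loso_crossval(
    corpus: Sequence[TokenRecord],
    lam: float = DEFAULT_LAMBDA,
    eta: float = DEFAULT_ETA,
) -> dict[str, EvalReport]:
    """Leave-one-speaker-out cross-validation.

    One fold per speaker: train on every other speaker's tokens in corpus
    order, evaluate on the held-out speaker's in-vocabulary tokens (those
    whose word type occurs at least once in the training fold).
    """
    speakers = sorted({t.speaker for t in corpus})
    if len(speakers) < 2:
        raise ValueError("leave-one-speaker-out requires at least 2 speakers")
    reports: dict[str, EvalReport] = {}
    for speaker in speakers:
        training = [t for t in corpus if t.speaker != speaker]
        trained_types = {t.word for t in training}
        test = [t for t in corpus if t.speaker == speaker and t.word in trained_types]
        if not test:
            logger.warning("speaker %s has no in-vocabulary tokens; fold skipped", speaker)
            continue
        weights = train(tokens_to_events(training), lam=lam, eta=eta)
        reports[speaker] = evaluate(weights, test)
    return reports


def pooled_accuracy(reports: dict[str, EvalReport]) -> float:
    """Micro-averaged accuracy over folds (all tokens pooled)."""
    n = sum(r.n_tokens for r in reports.values())
    return sum(r.n_correct for r in reports.values()) / n


def macro_accuracy(reports: dict[str, EvalReport]) -> float:
    """Per-fold accuracies averaged with equal fold weight."""
    return float(np.mean([r.accuracy for r in reports.values()]))


def accommodation(
    corpus: Sequence[TokenRecord],
    speaker: str,
    lam: float = DEFAULT_LAMBDA,
    eta: float = DEFAULT_ETA,
    seed: int = 0,
    adaptation_fraction: float = 0.5,
) -> tuple[float, int]:
    """Speaker accommodation: the accuracy gain from hearing a speaker.

    The held-out speaker's tokens are split (seeded) into an adaptation
    half and an evaluation half. Accuracy on the evaluation half is
    compared between a model trained without any of the speaker's tokens
    and one whose training additionally includes the adaptation half (in
    corpus order). Returns ``(accuracy_with - accuracy_without,
    novel_feature_count)``, where the count is the number of FBS features
    occurring in the speaker's speech but in no other speaker's. With
    ``adaptation_fraction=0`` the two models are identical and the delta is
    exactly 0.
    """
    own = [t for t in corpus if t.speaker == speaker]
    others = [t for t in corpus if t.speaker != speaker]
    if len(own) < 2:
        raise ValueError(f"speaker {speaker!r} needs at least 2 tokens in the corpus")
    rng = np.random.default_rng(seed)
    n_adapt = int(round(adaptation_fraction * len(own)))
    adapt_idx = set(rng.choice(len(own), size=n_adapt, replace=False).tolist())
    adapt_ids = {own[i].token_id for i in adapt_idx}
    eval_set = [t for t in own if t.token_id not in adapt_ids]
    if not eval_set:
        raise ValueError("adaptation fraction leaves no evaluation tokens")

    without = train(tokens_to_events(others), lam=lam, eta=eta)
    with_training = [
        t for t in corpus if t.speaker != speaker or t.token_id in adapt_ids
    ]
    with_ = train(tokens_to_events(with_training), lam=lam, eta=eta)

    acc_without = evaluate(without, eval_set).accuracy
    acc_with = evaluate(with_, eval_set).accuracy

    own_features = set().union(*(t.cues for t in own))
    other_features = set().union(*(t.cues for t in others)) if others else set()
    novel = len(own_features - other_features)
    return acc_with - acc_without, novel


def pruning_curve(
    weights: WeightMatrix,
    test: Sequence[TokenRecord],
    fractions: Sequence[float],
) -> list[tuple[float, float]]:
    """Identification accuracy of pruned copies of the network.

    The input network is left unmodified; fraction 0 reproduces the
    unpruned accuracy exactly.
    """
    if list(fractions) != sorted(fractions):
        raise ValueError("pruning fractions must be sorted ascending")
    return [(f, evaluate(weights.prune(f), test).accuracy) for f in fractions]


def feature_distribution(
    tokens: Sequence[TokenRecord],
) -> tuple[list[tuple[int, int]], float]:
    """Grouped FBS feature-frequency distribution and its log-log slope.

    Counts how often each feature occurs across tokens, groups features by
    that frequency (frequency-of-frequencies, no further binning), and fits
    log(number of features) on log(frequency) by least squares. A clearly
    negative slope is the power-law signature of the feature inventory.
    """
    freq = Counter()
    for t in tokens:
        freq.update(t.cues)
    grouped = Counter(freq.values())
    if len(grouped) < 2:
        raise ValueError(
            "feature-frequency distribution is degenerate (a single frequency "
            "value); a log-log slope is undefined"
        )
    table = sorted(grouped.items())
    x = np.log([f for f, _ in table])
    y = np.log([c for _, c in table])
    slope = float(np.polyfit(x, y, 1)[0])
    return table, slope
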