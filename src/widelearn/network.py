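"""Wide two-layer Rescorla-Wagner learning over discrete cues and outcomes.

The network is a sparse k x n matrix of association weights from cues
(FBS features) to outcomes (lexomes, opaque word identifiers). Learning is
incremental and error driven: for each learning event, every active cue's
weight to a present outcome moves toward the asymptote λ, and its weight
to a known-but-absent outcome moves toward 0, each step scaled by the
learning rate η = α·β and by the summed prediction of all active cues.
Pairs of cues and outcomes that have never co-occurred in training carry
no stored connection and contribute exactly zero.

Decision measures: the activation of an outcome for a stimulus cue set is
the sum of afferent weights from the active cues; the L1-norm of the
activation vector measures overall support for lexicality; the outcome
with the highest activation is the model's best candidate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

#: asymptote of learning for a present outcome
DEFAULT_LAMBDA = 1.0
#: learning rate α_i * β_j, one global constant for all connections
DEFAULT_ETA = 0.001


@dataclass(frozen=True)
class LearningEvent:
    """One training token: its active cue set and its outcome set."""

    cues: frozenset[str]
    outcomes: frozenset[str]
    order_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cues", frozenset(self.cues))
        object.__setattr__(self, "outcomes", frozenset(self.outcomes))
        if not self.outcomes:
            raise ValueError("a learning event requires at least one outcome")


@dataclass(frozen=True)
class ActivationVector:
    """Per-outcome activations for one stimulus, with the derived measures."""

    activations: dict[str, float]
    l1: float
    best: str | None


@dataclass
class WeightMatrix:
    """Sparse cue-outcome association weights plus label registries.

    Weights are stored per cue as ``{outcome: weight}``; a pair that was
    never touched by learning is absent and has weight exactly 0. The
    registries record every cue and outcome ever encountered, in first-seen
    order (which also serves as the deterministic tie-break order for
    pruning).
    """

    lam: float = DEFAULT_LAMBDA
    eta: float = DEFAULT_ETA
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    known_cues: dict[str, int] = field(default_factory=dict)
    known_outcomes: dict[str, int] = field(default_factory=dict)

    # -- registry bookkeeping -------------------------------------------------

    def _register(self, cues: Iterable[str], outcomes: Iterable[str]) -> None:
        for c in cues:
            if c not in self.known_cues:
                self.known_cues[c] = len(self.known_cues)
                self.weights[c] = {}
        for o in outcomes:
            if o not in self.known_outcomes:
                self.known_outcomes[o] = len(self.known_outcomes)

    def weight(self, cue: str, outcome: str) -> float:
        return self.weights.get(cue, {}).get(outcome, 0.0)

    @property
    def n_connections(self) -> int:
        """Number of stored (touched) cue-outcome connections."""
        return sum(len(row) for row in self.weights.values())

    # -- learning -------------------------------------------------------------

    def update(self, event: LearningEvent) -> None:
        """Apply one Rescorla-Wagner learning event in place.

        All weight changes are computed from the pre-event weights
        (synchronous within the event). Inactive cues are untouched; known
        outcomes absent from the event are decremented only through active
        cues; outcomes never yet seen receive no update. An event with an
        empty cue set is skipped.
        """
        if not event.cues:
            return
        self._register(event.cues, event.outcomes)
        cues = sorted(event.cues)
        # summed prediction of the active cues for every outcome they touch
        pred: dict[str, float] = {}
        for c in cues:
            for o, w in self.weights[c].items():
                pred[o] = pred.get(o, 0.0) + w
        # outcomes with zero prediction and absent from the event would get
        # Δ = η(0-0) = 0, so only predicted or present outcomes need work
        targets = set(pred)
        targets.update(event.outcomes)
        deltas = {
            o: self.eta * ((self.lam if o in event.outcomes else 0.0) - pred.get(o, 0.0))
            for o in targets
        }
        for c in cues:
            row = self.weights[c]
            for o, d in deltas.items():
                row[o] = row.get(o, 0.0) + d

    # -- decision measures ----------------------------------------------------

    def activate(self, stim_cues: Iterable[str]) -> ActivationVector:
        """Activations of all known outcomes for a stimulus cue set.

        Unknown cues are ignored (they have no afferent weights); outcomes
        never co-seen with any active cue get activation 0.
        """
        acts = dict.fromkeys(self.known_outcomes, 0.0)
        for c in set(stim_cues):
            for o, w in self.weights.get(c, {}).items():
                acts[o] += w
        l1 = float(sum(abs(a) for a in acts.values()))
        best = None
        if acts:
            peak = max(acts.values())
            best = min(o for o, a in acts.items() if a == peak)
        return ActivationVector(activations=acts, l1=l1, best=best)

    def predict(self, stim_cues: Iterable[str]) -> str:
        """Best candidate: argmax activation, ties to the lexicographically
        smallest outcome label."""
        if not self.known_outcomes:
            raise ValueError("cannot predict with no known outcomes")
        best = self.activate(stim_cues).best
        assert best is not None
        return best

    # -- pruning --------------------------------------------------------------

    def prune(self, fraction: float) -> "WeightMatrix":
        """Copy of the network with the smallest-magnitude connections removed.

        Exactly ``floor(fraction * n_connections)`` stored connections are
        dropped, smallest |w| first; ties at the cutoff magnitude are
        resolved by removing earliest-registered pairs first. Registries
        and parameters are unchanged.
        """
        if not (0 <= fraction < 1):
            raise ValueError(f"prune fraction must be in [0, 1), got {fraction}")
        pairs = [
            (c, o, w)
            for c in self.known_cues
            for o, w in self.weights[c].items()
        ]
        n_drop = int(fraction * len(pairs))
        # stable sort: among equal magnitudes, earlier (cue-reg, insertion) first
        order = sorted(range(len(pairs)), key=lambda i: abs(pairs[i][2]))
        drop = set(order[:n_drop])
        kept: dict[str, dict[str, float]] = {c: {} for c in self.known_cues}
        for i, (c, o, w) in enumerate(pairs):
            if i not in drop:
                kept[c][o] = w
        return WeightMatrix(
            lam=self.lam,
            eta=self.eta,
            weights=kept,
            known_cues=dict(self.known_cues),
            known_outcomes=dict(self.known_outcomes),
        )


def update(weights: WeightMatrix, event: LearningEvent) -> WeightMatrix:
    """Functional wrapper over :meth:`WeightMatrix.update` (in place)."""
    weights.update(event)
    return weights


def train(
    events: Iterable[LearningEvent],
    lam: float = DEFAULT_LAMBDA,
    eta: float = DEFAULT_ETA,
) -> WeightMatrix:
    """Fold the update rule over an ordered event stream.

    Training is order sensitive and deterministic: the same stream always
    produces the identical network.
    """
    weights = WeightMatrix(lam=lam, eta=eta)
    for event in events:
        weights.update(event)
    return weights


def l1_norm(av: ActivationVector) -> float:
    return av.l1


def closed_form_single_pair(t: int, eta: float = DEFAULT_ETA, lam: float = DEFAULT_LAMBDA) -> float:
    """Analytic weight after t events of one cue and one outcome always
    co-present: λ(1 - (1 - η)^t)."""
    if t < 0:
        raise ValueError("event count must be nonnegative")
    return lam * (1.0 - (1.0 - eta) ** t)


# -- persistence ---------------------------------------------------------------
#
# A saved model is a directory: weights.mtx (Matrix Market coordinate,
# full float64 precision), cues.txt and outcomes.txt (one label per line,
# registry order), params.json (λ, η).


def save_weights(weights: WeightMatrix, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows, cols, vals = [], [], []
    for c, ci in weights.known_cues.items():
        for o, w in weights.weights[c].items():
            rows.append(ci)
            cols.append(weights.known_outcomes[o])
            vals.append(w)
    mat = sp.coo_matrix(
        (vals, (rows, cols)),
        shape=(len(weights.known_cues), len(weights.known_outcomes)),
    )
    mmwrite(path / "weights.mtx", mat, precision=16)
    (path / "cues.txt").write_text("".join(f"{c}\n" for c in weights.known_cues), "utf-8")
    (path / "outcomes.txt").write_text(
        "".join(f"{o}\n" for o in weights.known_outcomes), "utf-8"
    )
    (path / "params.json").write_text(
        json.dumps({"lambda": weights.lam, "eta": weights.eta}), "utf-8"
    )


def load_weights(path: str | Path) -> WeightMatrix:
    path = Path(path)
    for name in ("weights.mtx", "cues.txt", "outcomes.txt", "params.json"):
        if not (path / name).exists():
            raise FileNotFoundError(f"model directory {path} is missing {name}")
    params = json.loads((path / "params.json").read_text("utf-8"))
    cues = (path / "cues.txt").read_text("utf-8").splitlines()
    outcomes = (path / "outcomes.txt").read_text("utf-8").splitlines()
    mat = sp.coo_matrix(mmread(path / "weights.mtx"))
    if mat.shape != (len(cues), len(outcomes)):
        raise ValueError(
            f"weight matrix shape {mat.shape} does not match label registries "
            f"({len(cues)} cues, {len(outcomes)} outcomes)"
        )
    weights = WeightMatrix(lam=params["lambda"], eta=params["eta"])
    weights._register(cues, outcomes)
    for r, c, v in zip(mat.row, mat.col, mat.data):
        weights.weights[cues[r]][outcomes[c]] = float(v)
    return weights


def as_dense(weights: WeightMatrix) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense k x n array view with row (cue) and column (outcome) labels."""
    cues = list(weights.known_cues)
    outcomes = list(weights.known_outcomes)
    W = np.zeros((len(cues), len(outcomes)))
    for c, ci in weights.known_cues.items():
        for o, w in weights.weights[c].items():
            W[ci, weights.known_outcomes[o]] = w
    return W, cues, outcomes
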