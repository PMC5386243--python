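import numpy as np
import pytest

from widelearn.network import (
    LearningEvent,
    WeightMatrix,
    as_dense,
    closed_form_single_pair,
    load_weights,
    save_weights,
    train,
)


def ev(cues, outcomes, t=1):
    return LearningEvent(cues=frozenset(cues), outcomes=frozenset(outcomes), order_index=t)


class DenseRW:
    """Brute-force dense Rescorla-Wagner reference.

    Maintains an explicit k x n array and applies the four-condition rule
    literally, outcome by outcome, from pre-event weights.
    """

    def __init__(self, lam=1.0, eta=0.001):
        self.lam, self.eta = lam, eta
        self.cues: list[str] = []
        self.outcomes: list[str] = []
        self.W = np.zeros((0, 0))

    def update(self, cues, outcomes):
        if not cues:
            return
        for c in sorted(cues):
            if c not in self.cues:
                self.cues.append(c)
                self.W = np.vstack([self.W, np.zeros((1, self.W.shape[1]))])
        for o in sorted(outcomes):
            if o not in self.outcomes:
                self.outcomes.append(o)
                self.W = np.hstack([self.W, np.zeros((self.W.shape[0], 1))])
        active = np.array([c in cues for c in self.cues])
        present = np.array([o in outcomes for o in self.outcomes])
        pred = self.W[active].sum(axis=0)
        delta = np.where(present, self.eta * (self.lam - pred), self.eta * (0.0 - pred))
        W_new = self.W.copy()
        W_new[active] += delta
        self.W = W_new

    def weight(self, c, o):
        if c not in self.cues or o not in self.outcomes:
            return 0.0
        return self.W[self.cues.index(c), self.outcomes.index(o)]


class TestUpdate:
    def test_first_event_moves_weight_by_eta_lambda(self):
        w = train([ev({"c"}, {"o"})])
        assert w.weight("c", "o") == 0.001

    def test_inactive_cue_weights_untouched(self):
        w = train([ev({"c1"}, {"o"}), ev({"c2"}, {"o"})])
        before = dict(w.weights["c1"])
        w.update(ev({"c2"}, {"o"}, t=3))
        assert w.weights["c1"] == before

    def test_known_absent_outcome_is_decremented(self):
        w = train([ev({"c"}, {"o"})])
        assert w.weight("c", "o") == 0.001
        w.update(ev({"c"}, {"o2"}, t=2))
        # condition 3: Δ = η(0 - 0.001) = -1e-6
        assert w.weight("c", "o") == pytest.approx(0.000999, abs=1e-15)

    def test_two_active_cues_share_the_summed_prediction(self):
        stream = [ev({"a", "b"}, {"o"}), ev({"a", "b"}, {"o"}, t=2)]
        w = train(stream)
        expected = 0.001 + 0.001 * (1 - 0.002)
        assert w.weight("a", "o") == pytest.approx(expected, abs=1e-15)
        assert w.weight("b", "o") == pytest.approx(expected, abs=1e-15)

    def test_never_coseen_pairs_remain_absent(self):
        w = train([ev({"c1"}, {"o1"}), ev({"c2"}, {"o2"}, t=2)])
        # c1 was inactive when o2 appeared: no stored connection, weight 0
        assert "o2" not in w.weights["c1"]
        assert w.weight("c1", "o2") == 0.0

    def test_empty_cue_event_is_skipped(self):
        w = train([ev({"c"}, {"o"})])
        before = as_dense(w)
        w.update(LearningEvent(cues=frozenset(), outcomes=frozenset({"o"}), order_index=2))
        after = as_dense(w)
        assert np.array_equal(before[0], after[0]) and before[1:] == after[1:]

    def test_event_requires_an_outcome(self):
        with pytest.raises(ValueError):
            ev({"c"}, set())


class TestTrain:
    def test_single_pair_matches_closed_form_at_every_step(self):
        w = WeightMatrix()
        event = ev({"c"}, {"o"})
        for t in range(1, 10_001):
            w.update(event)
            if t <= 100 or t % 997 == 0 or t == 10_000:
                assert abs(w.weight("c", "o") - closed_form_single_pair(t)) < 1e-12

    def test_single_pair_weight_is_bounded_and_increasing(self):
        w = WeightMatrix()
        prev = 0.0
        for t in range(200):
            w.update(ev({"c"}, {"o"}))
            cur = w.weight("c", "o")
            assert prev < cur <= 1.0
            prev = cur

    def test_empty_stream_gives_empty_network(self):
        w = train([])
        assert not w.known_cues and not w.known_outcomes and w.n_connections == 0

    def test_order_sensitivity(self):
        # o1 is decremented at the second event only if it was seen first
        e1, e2 = ev({"a"}, {"o1"}), ev({"a"}, {"o2"})
        w12 = train([e1, e2])
        w21 = train([e2, e1])
        assert w12.weight("a", "o1") != w21.weight("a", "o1")
        assert w12.weight("a", "o1") == pytest.approx(0.000999, abs=1e-15)
        assert w21.weight("a", "o1") == pytest.approx(0.001, abs=1e-15)

    def test_matches_dense_reference_on_random_streams(self, rng):
        for _ in range(50):
            n_cues = int(rng.integers(2, 21))
            n_out = int(rng.integers(1, 11))
            n_events = int(rng.integers(1, 201))
            cue_pool = [f"c{i}" for i in range(n_cues)]
            out_pool = [f"o{i}" for i in range(n_out)]
            sparse = WeightMatrix()
            dense = DenseRW()
            for t in range(n_events):
                size = int(rng.integers(1, min(6, n_cues + 1)))
                cues = set(rng.choice(cue_pool, size=size, replace=False))
                outs = {str(rng.choice(out_pool))}
                sparse.update(ev(cues, outs, t=t + 1))
                dense.update(cues, outs)
            for c in cue_pool:
                for o in out_pool:
                    assert abs(sparse.weight(c, o) - dense.weight(c, o)) < 1e-10


class TestActivation:
    def test_disjoint_stimulus_gives_zero_vector(self):
        w = train([ev({"c"}, {"o"})])
        av = w.activate({"x", "y"})
        assert av.l1 == 0.0
        assert av.activations == {"o": 0.0}

    def test_activation_is_sum_of_afferent_weights(self):
        w = WeightMatrix()
        w._register(["c1", "c2"], ["o"])
        w.weights["c1"]["o"] = 0.2
        w.weights["c2"]["o"] = 0.3
        assert w.activate({"c1", "c2"}).activations["o"] == pytest.approx(0.5)

    def test_unknown_cue_changes_nothing(self):
        w = train([ev({"c1", "c2"}, {"o"})])
        assert w.activate({"c1", "c2"}).activations == w.activate(
            {"c1", "c2", "zzz"}
        ).activations

    def test_l1_sums_absolute_activations(self):
        w = WeightMatrix()
        w._register(["c"], ["p", "q"])
        w.weights["c"]["p"] = 0.5
        w.weights["c"]["q"] = -0.25
        assert w.activate({"c"}).l1 == pytest.approx(0.75)

    def test_l1_is_linear_in_weights(self):
        w = train([ev({"a", "b"}, {"o1"}), ev({"a"}, {"o2"}, t=2)])
        l1 = w.activate({"a", "b"}).l1
        for c in w.weights:
            for o in w.weights[c]:
                w.weights[c][o] *= 2
        assert w.activate({"a", "b"}).l1 == pytest.approx(2 * l1)


class TestPredict:
    def test_single_outcome_always_wins(self):
        w = train([ev({"c"}, {"o"})])
        assert w.predict({"zzz"}) == "o"

    def test_argmax_outcome_selected(self):
        w = WeightMatrix()
        w._register(["c"], ["a", "b", "x"])
        w.weights["c"] = {"a": 0.1, "b": 0.4, "x": 0.2}
        assert w.predict({"c"}) == "b"

    def test_exact_tie_breaks_lexicographically(self):
        w = WeightMatrix()
        w._register(["c"], ["b", "a"])
        w.weights["c"] = {"b": 0.4, "a": 0.4}
        assert w.predict({"c"}) == "a"

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            WeightMatrix().predict({"c"})


class TestPrune:
    @staticmethod
    def handmade():
        w = WeightMatrix()
        w._register([f"c{i}" for i in range(10)], ["o"])
        for i in range(10):
            w.weights[f"c{i}"]["o"] = (i + 1) / 10 * (-1) ** i
        return w

    def test_fraction_zero_is_identity(self):
        w = self.handmade()
        assert as_dense(w.prune(0.0))[0].tolist() == as_dense(w)[0].tolist()

    def test_half_keeps_the_five_largest_magnitudes(self):
        pruned = self.handmade().prune(0.5)
        kept = {c for c in pruned.weights if pruned.weights[c]}
        assert kept == {f"c{i}" for i in range(5, 10)}
        assert pruned.n_connections == 5

    def test_registries_survive_pruning(self):
        pruned = self.handmade().prune(0.9)
        assert len(pruned.known_cues) == 10
        assert pruned.n_connections == 1

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_fraction_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            self.handmade().prune(bad)


class TestPersistence:
    def test_round_trip_preserves_activations(self, tmp_path, rng):
        stream = [
            ev(set(rng.choice([f"c{i}" for i in range(8)], size=3, replace=False)),
               {f"o{int(rng.integers(3))}"}, t=t)
            for t in range(40)
        ]
        w = train(stream)
        save_weights(w, tmp_path / "model")
        w2 = load_weights(tmp_path / "model")
        stim = {"c0", "c3", "c5"}
        assert w.activate(stim).activations == w2.activate(stim).activations
        assert w2.lam == w.lam and w2.eta == w.eta

    def test_empty_network_round_trips(self, tmp_path):
        save_weights(train([]), tmp_path / "m")
        w = load_weights(tmp_path / "m")
        assert not w.known_cues and not w.known_outcomes

    def test_identical_streams_give_bitwise_identical_files(self, tmp_path):
        stream = [ev({"a", "b"}, {"o1"}), ev({"b"}, {"o2"}, t=2)]
        save_weights(train(list(stream)), tmp_path / "m1")
        save_weights(train(list(stream)), tmp_path / "m2")
        for name in ("weights.mtx", "cues.txt", "outcomes.txt", "params.json"):
            assert (tmp_path / "m1" / name).read_bytes() == (
                tmp_path / "m2" / name
            ).read_bytes()

    def test_shape_registry_mismatch_rejected(self, tmp_path):
        w = train([ev({"a"}, {"o"})])
        save_weights(w, tmp_path / "m")
        # drop a registered outcome label: the stored weight now refers to
        # an unknown column
        (tmp_path / "m" / "outcomes.txt").write_text("")
        with pytest.raises((ValueError, Exception)):
            load_weights(tmp_path / "m")

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_weights(tmp_path / "nope")


class TestClosedForm:
    def test_zero_events_zero_weight(self):
        assert closed_form_single_pair(0) == 0.0

    def test_one_event(self):
        assert closed_form_single_pair(1) == pytest.approx(0.001)

    def test_monotone_and_bounded_by_lambda(self):
        vals = [closed_form_single_pair(t) for t in range(0, 5000, 50)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0
        assert closed_form_single_pair(10_000_000) == pytest.approx(1.0)
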