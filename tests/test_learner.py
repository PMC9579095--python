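import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edlsim import (
    EventStream,
    LearnerConfig,
    LearningEvent,
    WeightMatrix,
    activation,
    stream_from_table,
    train,
    update_deltas,
)
from edlsim.paradigms import outcome_competition_paradigm

LABELS = ["a", "b", "c", "d"]
events_st = st.builds(
    LearningEvent,
    cues=st.sets(st.sampled_from(LABELS), min_size=1, max_size=3),
    outcomes=st.sets(st.sampled_from(LABELS), max_size=2),
)
streams_st = st.builds(EventStream, st.lists(events_st, min_size=1, max_size=20))


class TestActivation:
    def test_sum_over_present_cues(self):
        w = WeightMatrix.from_dict({("light", "food"): 0.4, ("tone", "food"): 0.2})
        assert activation(w, {"light", "tone"}, "food") == pytest.approx(0.6)

    def test_empty_cue_set_activates_nothing(self):
        w = WeightMatrix.from_dict({("light", "food"): 0.4})
        assert activation(w, set(), "food") == 0.0

    def test_unknown_labels_contribute_zero(self):
        w = WeightMatrix()
        assert activation(w, {"light"}, "food") == 0.0


class TestUpdateDeltas:
    def test_present_pair_from_zero_state(self):
        w = WeightMatrix()
        d = update_deltas(w, LearningEvent({"light"}, {"food"}), LearnerConfig(), {"food"})
        assert d == {("light", "food"): pytest.approx(0.01)}

    def test_absent_outcome_decrement(self):
        w = WeightMatrix.from_dict({("light", "food"): 1.0})
        d = update_deltas(w, LearningEvent({"light"}, set()), LearnerConfig(), {"food"})
        assert d[("light", "food")] == pytest.approx(-0.01)

    def test_absent_cue_changes_nothing(self):
        w = WeightMatrix.from_dict({("tone", "food"): 0.5})
        d = update_deltas(w, LearningEvent({"light"}, {"food"}), LearnerConfig(), {"food"})
        assert all(cue != "tone" for cue, _ in d)

    def test_rescorla_wagner_salience_scaling(self):
        cfg = LearnerConfig(
            rule="rescorla_wagner", alpha={"light": 0.5}, beta_present=0.2, beta_absent=0.1
        )
        d = update_deltas(WeightMatrix(), LearningEvent({"light"}, {"food"}), cfg, {"food"})
        assert d[("light", "food")] == pytest.approx(0.5 * 0.2 * 1.0)

    def test_outcome_missing_from_universe_is_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            update_deltas(WeightMatrix(), LearningEvent({"a"}, {"x"}), LearnerConfig(), set())

    def test_disable_outcome_competition_drops_absent_outcomes(self):
        w = WeightMatrix.from_dict({("light", "food"): 0.5, ("light", "water"): 0.5})
        cfg = LearnerConfig(disable_outcome_competition=True)
        d = update_deltas(w, LearningEvent({"light"}, {"food"}), cfg, {"food", "water"})
        assert ("light", "water") not in d

    def test_disable_cue_competition_uses_single_weight_error(self):
        w = WeightMatrix.from_dict({("light", "food"): 0.2, ("tone", "food"): 0.7})
        cfg = LearnerConfig(disable_cue_competition=True)
        d = update_deltas(w, LearningEvent({"light", "tone"}, {"food"}), cfg, {"food"})
        assert d[("light", "food")] == pytest.approx(0.01 * (1 - 0.2))
        assert d[("tone", "food")] == pytest.approx(0.01 * (1 - 0.7))


class TestTrain:
    def test_single_pair_trajectory_matches_closed_form(self):
        stream = EventStream([LearningEvent({"A"}, {"X"})] * 1000)
        _, hist = train(stream, LearnerConfig(eta=0.01), track=[("A", "X")])
        n = np.arange(1, 1001)
        assert np.allclose(hist.series("A", "X"), 1 - 0.99**n, rtol=0, atol=1e-12)

    def test_outcome_competition_learns_conditional_probabilities(self):
        stream = stream_from_table(
            outcome_competition_paradigm(), mode="sampled", n_trials=30000, seed=2
        )
        w, _ = train(stream, LearnerConfig(eta=0.01))
        assert w.get("light", "food") == pytest.approx(2 / 3, abs=0.05)
        assert w.get("light", "water") == pytest.approx(1 / 3, abs=0.05)

    def test_empty_stream_returns_initial_state(self):
        init = WeightMatrix.from_dict({("a", "x"): 0.3})
        w, hist = train(EventStream(), initial=init)
        assert w.get("a", "x") == 0.3
        assert len(hist) == 0

    def test_initial_weights_are_a_pretrained_starting_point(self):
        init = WeightMatrix.from_dict({("light", "food"): 1.0})
        stream = EventStream([LearningEvent({"light", "tone"}, {"food"})] * 100)
        w, _ = train(stream, initial=init)
        # the light already fully predicts food, so the tone stays blocked
        assert abs(w.get("tone", "food")) < 1e-12

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(streams_st)
    def test_absent_cues_never_change_weight(self, stream):
        """Case 1 exactness: a trial leaves every absent cue's row untouched."""
        w, hist = train(stream, LearnerConfig(eta=0.05), track="all")
        vals = hist.values
        for t, ev in enumerate(stream):
            prev = vals[t - 1] if t > 0 else np.zeros(vals.shape[1])
            for k, (cue, _) in enumerate(hist.pairs):
                if cue not in ev.cues:
                    assert vals[t, k] == prev[k]

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(streams_st)
    def test_rescorla_wagner_reduction_is_bit_identical(self, stream):
        """With alpha=1, beta1=beta2=eta, lambda=1 the RW variant is the delta rule."""
        w1, _ = train(stream, LearnerConfig(rule="delta", eta=0.02))
        w2, _ = train(
            stream,
            LearnerConfig(rule="rescorla_wagner", eta=0.02, beta_present=0.02, beta_absent=0.02),
        )
        assert np.array_equal(w1.values, w2.values)

    def test_within_trial_enumeration_order_is_irrelevant(self):
        """Synchronous updating: cue/outcome listing order cannot change weights."""
        s1 = EventStream([LearningEvent(["a", "b", "c"], ["x", "y"])] * 20)
        s2 = EventStream([LearningEvent(["c", "a", "b"], ["y", "x"])] * 20)
        w1, _ = train(s1)
        w2, _ = train(s2)
        assert w1.cues == w2.cues and w1.outcomes == w2.outcomes
        assert np.array_equal(w1.values, w2.values)

    def test_without_outcome_competition_weights_rise_monotonically_to_limit(self):
        stream = EventStream([LearningEvent({"light"}, {"food", "water"})] * 2000)
        cfg = LearnerConfig(disable_outcome_competition=True)
        w, hist = train(stream, cfg, track="all")
        for pair in hist.pairs:
            traj = hist.series(*pair)
            assert np.all(np.diff(traj) >= 0)
            assert traj[-1] <= 1.0 + 1e-12
        assert w.get("light", "food") == pytest.approx(1.0, abs=1e-6)
        assert w.get("light", "water") == pytest.approx(1.0, abs=1e-6)

    def test_growing_universe_defers_absent_outcome_updates(self):
        trials = [LearningEvent({"light"}, {"food"})] * 10 + [
            LearningEvent({"light"}, {"water"})
        ]
        stream = EventStream(trials)
        init = WeightMatrix.from_dict({("light", "water"): 0.5})
        _, hist_fixed = train(stream, initial=init, track=[("light", "water")])
        _, hist_grown = train(
            stream, initial=init, track=[("light", "water")], growing_universe=True
        )
        # fixed universe decrements light->water from trial 1; the growing
        # universe leaves it untouched until water is first observed
        assert np.all(hist_grown.values[:10] == 0.5)
        assert np.all(np.diff(hist_fixed.values[:10, 0]) < 0)
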