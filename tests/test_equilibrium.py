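import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edlsim import (
    EventStream,
    FrequencyTable,
    LearningEvent,
    activation,
    moments_from_stream,
    residual,
    solve_equilibrium,
)
from edlsim.paradigms import (
    dog_rabbit_paradigm,
    negative_patterning_paradigm,
    outcome_competition_paradigm,
)


def brute_force_least_squares(table: FrequencyTable, lambda_max: float = 1.0):
    """Independent oracle: weighted least squares on the explicit design matrix.

    Builds one row per trial type (presence indicators scaled by the
    square root of the type's probability) and solves with
    numpy.lstsq, returning the minimum-norm weights and the summed
    squared residual — no moment matrices involved.
    """
    cues = table.cue_labels()
    outcomes = table.outcome_labels()
    p = table.probabilities
    X = np.zeros((len(table.rows), len(cues)))
    Y = np.zeros((len(table.rows), len(outcomes)))
    for r, (ev, _) in enumerate(table.rows):
        w = np.sqrt(p[r])
        for c in ev.cues:
            X[r, cues.index(c)] = w
        for o in ev.outcomes:
            Y[r, outcomes.index(o)] = w * lambda_max
    V, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    rss = float(((X @ V - Y) ** 2).sum())
    return cues, outcomes, V, rss


class TestMoments:
    def test_single_cue_two_outcomes(self):
        m = moments_from_stream(outcome_competition_paradigm())
        assert np.allclose(m.cue_cooccurrence, [[1.0]])
        food, water = m.outcomes.index("food"), m.outcomes.index("water")
        assert m.cue_outcome[0, food] == pytest.approx(2 / 3)
        assert m.cue_outcome[0, water] == pytest.approx(1 / 3)

    def test_always_copresent_cues(self):
        s = EventStream([LearningEvent({"A", "B"}, {"X"})])
        m = moments_from_stream(s)
        assert np.allclose(m.cue_cooccurrence, [[1, 1], [1, 1]])

    def test_order_invariance(self):
        evs = [
            LearningEvent({"a"}, {"x"}),
            LearningEvent({"b"}, {"y"}),
            LearningEvent({"a", "b"}, {"x"}),
        ]
        m1 = moments_from_stream(EventStream(evs))
        m2 = moments_from_stream(EventStream(evs[::-1]))
        assert np.allclose(m1.cue_cooccurrence, m2.cue_cooccurrence)
        assert np.allclose(m1.cue_outcome, m2.cue_outcome)

    def test_empty_stream_is_an_error(self):
        with pytest.raises(ValueError, match="no trials"):
            moments_from_stream(EventStream())

    def test_cooccurrence_is_symmetric_psd_with_probability_diagonal(self, fixture_designs):
        for tab in fixture_designs.values():
            m = moments_from_stream(tab)
            C = m.cue_cooccurrence
            assert np.allclose(C, C.T)
            assert np.all(np.linalg.eigvalsh(C) > -1e-12)
            p = tab.probabilities
            for i, c in enumerate(m.cues):
                occ = sum(pr for (ev, _), pr in zip(tab.rows, p) if c in ev.cues)
                assert C[i, i] == pytest.approx(occ)


class TestSolveEquilibrium:
    def test_conditional_probability_design(self):
        V = solve_equilibrium(moments_from_stream(outcome_competition_paradigm()))
        assert V.get("light", "food") == pytest.approx(2 / 3)
        assert V.get("light", "water") == pytest.approx(1 / 3)

    def test_perfectly_predictive_single_cue(self):
        s = EventStream([LearningEvent({"bell"}, {"food"})])
        V = solve_equilibrium(moments_from_stream(s))
        assert V.get("bell", "food") == pytest.approx(1.0)

    def test_dog_rabbit_design_is_exactly_solvable(self):
        tab = dog_rabbit_paradigm(1)
        m = moments_from_stream(tab)
        V = solve_equilibrium(m)
        assert residual(m, V) == pytest.approx(0.0, abs=1e-12)
        for ev, _ in tab.rows:
            (label,) = ev.outcomes
            other = "rabbit" if label == "dog" else "dog"
            assert activation(V, ev.cues, label) == pytest.approx(1.0, abs=1e-9)
            assert activation(V, ev.cues, other) == pytest.approx(0.0, abs=1e-9)

    def test_matches_explicit_least_squares_oracle(self, fixture_designs):
        for name, tab in fixture_designs.items():
            m = moments_from_stream(tab)
            V = solve_equilibrium(m)
            cues, outcomes, V_ref, rss_ref = brute_force_least_squares(tab)
            got = np.array([[V.get(c, o) for o in outcomes] for c in cues])
            assert np.allclose(got, V_ref, atol=1e-9), name
            assert residual(m, V) == pytest.approx(rss_ref, abs=1e-9), name

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(
        freqs=st.lists(st.integers(min_value=1, max_value=9), min_size=2, max_size=4)
    )
    def test_shared_single_cue_weights_equal_conditional_probabilities(self, freqs):
        """With one constant cue, equilibrium weights are outcome probabilities."""
        rows = [({"ctx"}, {f"o{k}"}, f) for k, f in enumerate(freqs)]
        tab = FrequencyTable.from_rows(rows)
        V = solve_equilibrium(moments_from_stream(tab))
        total = sum(freqs)
        for k, f in enumerate(freqs):
            assert V.get("ctx", f"o{k}") == pytest.approx(f / total)


class TestResidual:
    def test_zero_for_exactly_fittable_design(self):
        tab = FrequencyTable.from_rows([({"a"}, {"x"}, 1), ({"b"}, {"y"}, 2)])
        m = moments_from_stream(tab)
        assert residual(m, solve_equilibrium(m)) == pytest.approx(0.0, abs=1e-12)

    def test_negative_patterning_elemental_is_inconsistent(self):
        m = moments_from_stream(negative_patterning_paradigm("elemental"))
        r = residual(m, solve_equilibrium(m))
        _, _, _, rss_ref = brute_force_least_squares(
            negative_patterning_paradigm("elemental")
        )
        assert r > 0.1
        assert r == pytest.approx(rss_ref, abs=1e-12)

    def test_configural_cue_restores_exact_fit(self):
        for coding in ("configural", "mixed"):
            m = moments_from_stream(negative_patterning_paradigm(coding))
            assert residual(m, solve_equilibrium(m)) == pytest.approx(0.0, abs=1e-12)

    def test_residual_of_suboptimal_weights_exceeds_optimum(self):
        m = moments_from_stream(outcome_competition_paradigm())
        best = residual(m, solve_equilibrium(m))
        from edlsim import WeightMatrix

        worse = residual(m, WeightMatrix.from_dict({("light", "food"): 1.0}))
        assert worse > best
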