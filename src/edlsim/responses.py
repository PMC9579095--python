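"""From learned weights to behavioral predictions.

A trained weight matrix is related to behavior in two steps: first the
activation of every outcome given a test cue set (the activation
matrix), then an order-preserving transformation of activations into
choice probabilities (Luce's ratio rule over non-negative activations,
a logistic transform, or a hard threshold) or a reaction-time proxy
(the negated activation, or log of the inverse activation).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import LearningEvent
from .learner import WeightMatrix, activation

__all__ = [
    "cue_set_label",
    "activation_matrix",
    "choice_probabilities",
    "reaction_time",
    "choice_accuracy",
]


def cue_set_label(cues: Iterable[str]) -> str:
    """Canonical row label for a test cue set: sorted, comma-joined."""
    return ",".join(sorted(set(cues)))


def activation_matrix(
    weights: WeightMatrix,
    test_cue_sets: Sequence[Iterable[str]],
    outcome_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Outcome activations for each test cue set.

    Rows are labeled by the (sorted) cue sets, columns by outcome; the
    entry is the summed weight from the set's cues to the outcome.
    ``outcome_universe`` defaults to the outcomes of the weight matrix.
    """
    sets = [frozenset(s) for s in test_cue_sets]
    if not sets:
        raise ValueError("need at least one test cue set")
    outcomes = tuple(outcome_universe) if outcome_universe is not None else weights.outcomes
    data = np.array(
        [[activation(weights, s, o) for o in outcomes] for s in sets]
    )
    return pd.DataFrame(data, index=[cue_set_label(s) for s in sets], columns=list(outcomes))


def _logistic(x: np.ndarray, slope: float, midpoint: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-slope * (x - midpoint)))


def choice_probabilities(
    activations,
    rule: str = "luce",
    *,
    threshold: float = 0.5,
    slope: float = 1.0,
    midpoint: float = 0.0,
):
    """Map an activation vector over outcomes to choice probabilities.

    All rules preserve the order of the activations.

    * ``"luce"``: negative activations are clipped to zero, then each
      outcome's probability is its share of the summed activation.  If
      everything clips to zero there is no evidence for any outcome and
      the uniform distribution is returned.
    * ``"logistic"``: elementwise logistic transform (``slope``,
      ``midpoint``), then normalization.
    * ``"threshold"``: indicator of activation >= ``threshold``, then
      normalization (uniform over the ties); uniform if nothing
      reaches the threshold.

    Accepts a sequence or :class:`pandas.Series`; returns the same kind.
    """
    is_series = isinstance(activations, pd.Series)
    a = np.asarray(activations, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("activations must be a non-empty 1-D vector")
    if rule == "luce":
        clipped = np.clip(a, 0.0, None)
        total = clipped.sum()
        p = clipped / total if total > 0 else np.full(a.size, 1.0 / a.size)
    elif rule == "logistic":
        g = _logistic(a, slope, midpoint)
        p = g / g.sum()
    elif rule == "threshold":
        ind = (a >= threshold).astype(float)
        total = ind.sum()
        p = ind / total if total > 0 else np.full(a.size, 1.0 / a.size)
    else:
        raise ValueError(f"unknown choice rule {rule!r}")
    if is_series:
        return pd.Series(p, index=activations.index)
    return p


def reaction_time(activation_value: float, transform: str = "log_inverse") -> float:
    """Reaction-time proxy for a single outcome activation.

    ``"negated"`` returns the negative activation (usable directly for
    small designs); ``"log_inverse"`` returns log(1/activation), which
    removes the skew for larger designs but requires a strictly
    positive activation.
    """
    if transform == "negated":
        return float(-activation_value)
    if transform == "log_inverse":
        if activation_value <= 0:
            raise ValueError(
                "log_inverse requires activation > 0; clip or floor activations "
                "before the transform, or use transform='negated'"
            )
        return float(np.log(1.0 / activation_value))
    raise ValueError(f"unknown transform {transform!r}")


def choice_accuracy(
    weights: WeightMatrix,
    test_events: Sequence[LearningEvent],
    outcome_universe: Iterable[str] | None = None,
    rule: str = "luce",
    rng: np.random.Generator | None = None,
    expected: bool = True,
) -> float:
    """Proportion of correct choices over test events with a single true outcome.

    For each event the choice distribution over the outcome universe is
    computed from the activations of its cue set.  With
    ``expected=True`` (default) the mean probability assigned to the
    correct outcome is returned; with ``expected=False`` one choice per
    event is sampled with ``rng`` and the hit rate returned.
    """
    if not test_events:
        raise ValueError("need at least one test event")
    outcomes = tuple(outcome_universe) if outcome_universe is not None else weights.outcomes
    if expected is False and rng is None:
        rng = np.random.default_rng()
    hits = 0.0
    for ev in test_events:
        if len(ev.outcomes) != 1:
            raise ValueError(f"test event must have exactly one outcome: {ev}")
        (truth,) = ev.outcomes
        acts = np.array([activation(weights, ev.cues, o) for o in outcomes])
        p = choice_probabilities(acts, rule=rule)
        j = outcomes.index(truth)
        if expected:
            hits += p[j]
        else:
            hits += float(rng.choice(len(outcomes), p=p) == j)
    return hits / len(test_events)
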