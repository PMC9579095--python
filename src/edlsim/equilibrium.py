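"""Direct computation of the network's convergence point.

Under a fixed trial distribution, incremental delta-rule learning
fluctuates around (or asymptotes toward) the least-squares solution of
the training design: the weight matrix minimizing the expected squared
difference between the target activations (lambda for a present
outcome, 0 otherwise) and the actual summed activations.  That solution
satisfies the normal equations

    C V = B

where C is the cue co-occurrence matrix (expected products of cue
presence indicators over the trial distribution) and B the cue-outcome
moment matrix (expected products of cue indicators with the outcome
targets) — the equilibrium equations of Danks.  Solving them directly
gives the endpoint of learning without simulating it, and serves as an
independent oracle for the incremental learner.

When cues are perfectly correlated the system is singular and the
equilibrium is not unique; the minimum-norm solution is returned, which
is the limit a zero-initialized incremental learner approaches (its
iterates never leave the row space of the design).
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np

from .events import EventStream, FrequencyTable
from .learner import WeightMatrix

__all__ = ["DesignMoments", "moments_from_stream", "solve_equilibrium", "residual"]


@dataclass
class DesignMoments:
    """Second moments of a training design over its trial distribution.

    cue_cooccurrence
        Symmetric PSD matrix with entry (i, k) the probability that
        cues i and k are both present on a trial; the diagonal holds
        each cue's occurrence probability.
    cue_outcome
        Entry (i, j) is the expectation of cue i's presence indicator
        times outcome j's target (lambda if present, else 0).
    target_second_moment
        Entry j is the expectation of the squared target of outcome j
        (lambda^2 times its occurrence probability); needed to evaluate
        the residual from moments alone.
    """

    cues: tuple[str, ...]
    outcomes: tuple[str, ...]
    cue_cooccurrence: np.ndarray
    cue_outcome: np.ndarray
    target_second_moment: np.ndarray
    lambda_max: float = 1.0

    def __post_init__(self):
        n, m = len(self.cues), len(self.outcomes)
        self.cue_cooccurrence = np.asarray(self.cue_cooccurrence, dtype=float)
        self.cue_outcome = np.asarray(self.cue_outcome, dtype=float)
        self.target_second_moment = np.asarray(self.target_second_moment, dtype=float)
        if self.cue_cooccurrence.shape != (n, n):
            raise ValueError("cue_cooccurrence shape mismatch")
        if self.cue_outcome.shape != (n, m):
            raise ValueError("cue_outcome shape mismatch")
        if self.target_second_moment.shape != (m,):
            raise ValueError("target_second_moment shape mismatch")
        if not np.allclose(self.cue_cooccurrence, self.cue_cooccurrence.T):
            raise ValueError("cue_cooccurrence must be symmetric")


def moments_from_stream(
    source: EventStream | FrequencyTable,
    outcome_universe: Iterable[str] | None = None,
    lambda_max: float = 1.0,
) -> DesignMoments:
    """Empirical design moments from a stream or frequency table.

    Trials are weighted by their relative frequency, so the result is
    invariant to trial order.  ``outcome_universe`` may declare extra
    outcomes beyond those observed.
    """
    if isinstance(source, FrequencyTable):
        events, probs = source.events, source.probabilities
    elif isinstance(source, EventStream):
        if len(source) == 0:
            raise ValueError("no trials: cannot compute moments of an empty stream")
        events = source.trials
        probs = np.full(len(events), 1.0 / len(events))
    else:
        raise TypeError(f"expected EventStream or FrequencyTable, got {type(source).__name__}")

    cues = tuple(sorted(set().union(*(e.cues for e in events))))
    outcomes = set().union(*(e.outcomes for e in events))
    if outcome_universe is not None:
        outcomes |= set(outcome_universe)
    outcomes = tuple(sorted(outcomes))

    ci = {c: i for i, c in enumerate(cues)}
    oi = {o: j for j, o in enumerate(outcomes)}
    C = np.zeros((len(cues), len(cues)))
    B = np.zeros((len(cues), len(outcomes)))
    q = np.zeros(len(outcomes))
    for ev, p in zip(events, probs):
        x = np.zeros(len(cues))
        for c in ev.cues:
            x[ci[c]] = 1.0
        y = np.zeros(len(outcomes))
        for o in ev.outcomes:
            y[oi[o]] = lambda_max
        C += p * np.outer(x, x)
        B += p * np.outer(x, y)
        q += p * y**2
    return DesignMoments(cues, outcomes, C, B, q, lambda_max)


def solve_equilibrium(moments: DesignMoments) -> WeightMatrix:
    """The least-squares convergence point of the design.

    Solves the normal equations C V = B; when C is singular (perfectly
    correlated or redundant cues) the minimum-norm solution is
    returned, which is deterministic and matches the limit of a
    zero-initialized incremental learner.
    """
    V = np.linalg.pinv(moments.cue_cooccurrence) @ moments.cue_outcome
    return WeightMatrix(moments.cues, moments.outcomes, V)


def residual(moments: DesignMoments, weights: WeightMatrix) -> float:
    """Frequency-weighted expected squared prediction error of a weight matrix.

    Expands E[ sum_j (target_j - act_j)^2 ] over the trial
    distribution in terms of the design moments.  Zero exactly when the
    design is exactly fittable (every trial type's targets are
    reproduced); strictly positive for linearly non-separable designs
    such as elementally coded negative patterning.
    """
    V = weights.reindexed(moments.cues, moments.outcomes).values
    C, B, q = moments.cue_cooccurrence, moments.cue_outcome, moments.target_second_moment
    total = 0.0
    for j in range(len(moments.outcomes)):
        v = V[:, j]
        total += q[j] - 2.0 * B[:, j] @ v + v @ C @ v
    # exact fits can land a hair below zero in floating point
    return float(max(total, 0.0))
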