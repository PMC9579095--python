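"""The learning engine: activations and incremental delta-rule updates.

The model is a fully connected two-layer feed-forward network with
discrete cue units, discrete outcome units and a linear identity
activation: the activation of an outcome is simply the sum of the
weights from all currently present cues.  Weights are updated online,
trial by trial, in proportion to the prediction error between a target
activation (lambda for a present outcome, 0 for an absent one) and the
actual activation.

Two rule variants are provided.  The plain delta rule (Widrow-Hoff) has
a single learning rate eta.  The Rescorla-Wagner variant adds per-cue
saliences alpha_i and separate rates beta_present / beta_absent for
positive and negative evidence; with all alphas 1, both betas equal to
eta and lambda = 1 it reduces exactly to the delta rule.

Two ablations isolate the competitive mechanisms:

* ``disable_outcome_competition`` skips the updating of absent
  outcomes, so weights only grow toward the activation ceiling;
* ``disable_cue_competition`` replaces the summed activation by the
  single weight in the error term, so each weight independently
  approaches the conditional probability of its outcome given its cue.

All within-trial deltas are computed from the pre-update weights and
applied at once (synchronous update), so enumeration order inside a
trial cannot influence the result.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventStream, LearningEvent

__all__ = [
    "WeightMatrix",
    "LearnerConfig",
    "WeightHistory",
    "activation",
    "update_deltas",
    "train",
]


class WeightMatrix:
    """Real-valued association weights indexed by (cue label, outcome label).

    Lookup of any pair not present in the matrix yields 0 — an unseen
    association carries no weight.  The label sets are exactly the cues
    and outcomes declared or observed.
    """

    def __init__(
        self,
        cues: Iterable[str] = (),
        outcomes: Iterable[str] = (),
        values: np.ndarray | None = None,
    ):
        self._cues = tuple(cues)
        self._outcomes = tuple(outcomes)
        if len(set(self._cues)) != len(self._cues):
            raise ValueError("duplicate cue labels")
        if len(set(self._outcomes)) != len(self._outcomes):
            raise ValueError("duplicate outcome labels")
        shape = (len(self._cues), len(self._outcomes))
        if values is None:
            values = np.zeros(shape)
        values = np.asarray(values, dtype=float)
        if values.shape != shape:
            raise ValueError(f"values shape {values.shape} does not match labels {shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("weights must be finite")
        self._values = values
        self._cue_index = {c: i for i, c in enumerate(self._cues)}
        self._outcome_index = {o: j for j, o in enumerate(self._outcomes)}

    @classmethod
    def from_dict(cls, weights: Mapping[tuple[str, str], float]) -> "WeightMatrix":
        cues = sorted({c for c, _ in weights})
        outcomes = sorted({o for _, o in weights})
        m = cls(cues, outcomes)
        for (c, o), w in weights.items():
            m._values[m._cue_index[c], m._outcome_index[o]] = w
        return m

    @property
    def cues(self) -> tuple[str, ...]:
        return self._cues

    @property
    def outcomes(self) -> tuple[str, ...]:
        return self._outcomes

    @property
    def values(self) -> np.ndarray:
        """The underlying (n_cues, n_outcomes) array (not a copy)."""
        return self._values

    def get(self, cue: str, outcome: str) -> float:
        i = self._cue_index.get(cue)
        j = self._outcome_index.get(outcome)
        if i is None or j is None:
            return 0.0
        return float(self._values[i, j])

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.get(*key)

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self._cues, self._outcomes, self._values.copy())

    def reindexed(self, cues: Iterable[str], outcomes: Iterable[str]) -> "WeightMatrix":
        """A new matrix over the given label sets, filling unknowns with 0."""
        cues = tuple(cues)
        outcomes = tuple(outcomes)
        out = WeightMatrix(cues, outcomes)
        for i, c in enumerate(cues):
            for j, o in enumerate(outcomes):
                out._values[i, j] = self.get(c, o)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._values.copy(), index=list(self._cues), columns=list(self._outcomes))

    def to_dict(self) -> dict[tuple[str, str], float]:
        return {
            (c, o): float(self._values[i, j])
            for i, c in enumerate(self._cues)
            for j, o in enumerate(self._outcomes)
        }

    def __repr__(self) -> str:
        return f"WeightMatrix({len(self._cues)} cues x {len(self._outcomes)} outcomes)"


@dataclass(frozen=True)
class LearnerConfig:
    """Parameters of the learning rule.

    rule
        ``"delta"`` (single rate eta) or ``"rescorla_wagner"``
        (per-cue salience ``alpha`` times ``beta_present`` /
        ``beta_absent``).
    eta
        Learning rate of the delta rule, default 0.01.
    lambda_max
        Target activation of a present outcome, default 1.0; acts only
        as a scale.
    alpha
        Mapping cue label -> salience in (0, 1]; unlisted cues get 1.
        Used by the Rescorla-Wagner rule only.
    beta_present, beta_absent
        Rates for present-outcome and absent-outcome updates
        (Rescorla-Wagner); both default to eta.
    disable_outcome_competition
        Skip the updating of absent outcomes entirely.
    disable_cue_competition
        Use the single weight instead of the summed activation in the
        error term, letting each weight independently approach its
        limit.
    """

    rule: str = "delta"
    eta: float = 0.01
    lambda_max: float = 1.0
    alpha: Mapping[str, float] = field(default_factory=dict)
    beta_present: float | None = None
    beta_absent: float | None = None
    disable_outcome_competition: bool = False
    disable_cue_competition: bool = False

    def __post_init__(self):
        if self.rule not in ("delta", "rescorla_wagner"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if not (self.eta > 0):
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if not (self.lambda_max > 0):
            raise ValueError(f"lambda_max must be > 0, got {self.lambda_max}")
        for k, v in dict(self.alpha).items():
            if not (0 < v <= 1):
                raise ValueError(f"alpha[{k!r}] must be in (0, 1], got {v}")
        for name in ("beta_present", "beta_absent"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")

    def rates_for(self, cues: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        """Per-cue update rates (present-outcome, absent-outcome)."""
        cues = list(cues)
        if self.rule == "delta":
            r = np.full(len(cues), self.eta)
            return r, r.copy()
        alpha = np.array([dict(self.alpha).get(c, 1.0) for c in cues])
        b1 = self.beta_present if self.beta_present is not None else self.eta
        b2 = self.beta_absent if self.beta_absent is not None else self.eta
        return alpha * b1, alpha * b2


class WeightHistory:
    """Per-trial weight trajectories for a tracked set of (cue, outcome) pairs.

    One record per tracked pair per trial, taken after the trial's
    update was applied.  Trial indices are 0-based.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]], values: np.ndarray | None = None):
        self.pairs = tuple(tuple(p) for p in pairs)
        if values is None:
            values = np.zeros((0, len(self.pairs)))
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.pairs):
            raise ValueError("values must be (n_trials, n_pairs)")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def series(self, cue: str, outcome: str) -> np.ndarray:
        """The trajectory of one tracked pair, one value per trial."""
        try:
            k = self.pairs.index((cue, outcome))
        except ValueError:
            raise KeyError(f"pair ({cue!r}, {outcome!r}) was not tracked") from None
        return self.values[:, k].copy()

    @property
    def records(self) -> list[tuple[int, str, str, float]]:
        """Flat (trial, cue, outcome, weight) records in trial order."""
        return [
            (t, c, o, float(self.values[t, k]))
            for t in range(self.n_trials)
            for k, (c, o) in enumerate(self.pairs)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns trial, cue, outcome, weight."""
        recs = self.records
        return pd.DataFrame(recs, columns=["trial", "cue", "outcome", "weight"])


def activation(weights: WeightMatrix, cues: Iterable[str], outcome: str) -> float:
    """Summed weight from the present cues to one outcome.

    The network's activation function is the identity, so the
    activation of an outcome is just the net input: the sum of the
    weights from every present cue.  Unknown labels contribute 0; an
    empty cue set activates nothing.
    """
    return float(sum(weights.get(c, outcome) for c in sorted(set(cues))))


def _trial_deltas(
    values: np.ndarray,
    cue_idx: np.ndarray,
    present: np.ndarray,
    rate_present: np.ndarray,
    rate_absent: np.ndarray,
    lam: float,
    disable_outcome_competition: bool,
    disable_cue_competition: bool,
    active_outcomes: np.ndarray | None = None,
) -> np.ndarray:
    """Delta-rule weight changes for one trial, from the pre-update state.

    Returns an array of shape (len(cue_idx), n_outcomes): the change for
    every (present cue, tracked outcome) pair.  ``present`` is the
    boolean mask of present outcomes; ``active_outcomes`` optionally
    restricts absent-outcome updates (growing-universe mode).
    """
    target = lam * present.astype(float)
    if disable_cue_competition:
        err = target[np.newaxis, :] - values[cue_idx, :]
    else:
        act = values[cue_idx, :].sum(axis=0)
        err = np.broadcast_to(target - act, (len(cue_idx), values.shape[1])).copy()
    rate = np.where(present[np.newaxis, :], rate_present[:, np.newaxis], rate_absent[:, np.newaxis])
    deltas = rate * err
    if disable_outcome_competition:
        deltas[:, ~present] = 0.0
    elif active_outcomes is not None:
        deltas[:, ~active_outcomes & ~present] = 0.0
    return deltas


def update_deltas(
    weights: WeightMatrix,
    event: LearningEvent,
    config: LearnerConfig,
    outcome_universe: Iterable[str],
) -> dict[tuple[str, str], float]:
    """Weight changes the learning rule prescribes for one trial.

    The three cases: a cue absent from the trial changes no weight (its
    pairs are simply omitted from the returned map); a present cue and
    present outcome move the weight by rate * (lambda - activation); a
    present cue and absent outcome (anywhere in ``outcome_universe``)
    move it by rate * (0 - activation).  All activations are taken from
    the supplied pre-update weights.
    """
    universe = sorted(set(outcome_universe))
    missing = event.outcomes - set(universe)
    if missing:
        raise ValueError(f"outcome universe is missing event outcomes: {sorted(missing)}")
    cues = sorted(event.cues)
    if not cues:
        return {}
    m = weights.reindexed(cues, universe)
    cue_idx = np.arange(len(cues))
    present = np.array([o in event.outcomes for o in universe], dtype=bool)
    rp, ra = config.rates_for(cues)
    deltas = _trial_deltas(
        m.values,
        cue_idx,
        present,
        rp,
        ra,
        config.lambda_max,
        config.disable_outcome_competition,
        config.disable_cue_competition,
    )
    out: dict[tuple[str, str], float] = {}
    for i, c in enumerate(cues):
        for j, o in enumerate(universe):
            if config.disable_outcome_competition and not present[j]:
                continue
            out[(c, o)] = float(deltas[i, j])
    return out


def train(
    stream: EventStream,
    config: LearnerConfig | None = None,
    initial: WeightMatrix | None = None,
    track: str | Iterable[tuple[str, str]] | None = None,
    extra_outcomes: Iterable[str] = (),
    growing_universe: bool = False,
) -> tuple[WeightMatrix, WeightHistory]:
    """Train the network on a stream, trial by trial, in stream order.

    The outcome universe is fixed before training to every outcome
    appearing anywhere in the stream plus ``extra_outcomes`` (plus the
    outcomes of ``initial``), so absent-outcome updates apply from the
    first trial even to outcomes that have not yet occurred.  Setting
    ``growing_universe=True`` switches to the alternative in which an
    outcome only participates in absent-outcome updates once it has
    been observed; this makes results depend on trial order in ways the
    fixed universe does not.

    ``track`` selects (cue, outcome) pairs to snapshot after every
    trial: ``None`` records nothing, ``"all"`` records every pair, or
    pass an explicit iterable of pairs.  Training is deterministic
    given (stream, config, initial).
    """
    config = config or LearnerConfig()
    cues = sorted(
        set().union(*(e.cues for e in stream), set(initial.cues if initial else ()))
    ) if len(stream) or initial else []
    outcomes = sorted(
        set().union(
            *(e.outcomes for e in stream),
            set(extra_outcomes),
            set(initial.outcomes if initial else ()),
        )
    ) if len(stream) or initial or extra_outcomes else []

    if track is None:
        pairs: tuple[tuple[str, str], ...] = ()
    elif track == "all":
        pairs = tuple((c, o) for c in cues for o in outcomes)
    else:
        pairs = tuple(tuple(p) for p in track)

    base = WeightMatrix(cues, outcomes)
    if initial is not None:
        base = initial.reindexed(cues, outcomes)
    V = base.values

    cue_index = {c: i for i, c in enumerate(cues)}
    outcome_index = {o: j for j, o in enumerate(outcomes)}
    pair_idx = [
        (cue_index.get(c), outcome_index.get(o)) for c, o in pairs
    ]
    for (c, o), (i, j) in zip(pairs, pair_idx):
        if i is None or j is None:
            raise ValueError(f"tracked pair ({c!r}, {o!r}) not in the training universe")

    hist = np.zeros((len(stream), len(pairs))) if track is not None else None

    lam = config.lambda_max
    seen = np.zeros(len(outcomes), dtype=bool) if growing_universe else None

    # Pre-resolve per-trial index structures once; the trial loop then
    # only does small dense array arithmetic.
    prepared = []
    for ev in stream:
        ci = np.array(sorted(cue_index[c] for c in ev.cues), dtype=int)
        present = np.zeros(len(outcomes), dtype=bool)
        for o in ev.outcomes:
            present[outcome_index[o]] = True
        sorted_cues = sorted(ev.cues)
        rp, ra = config.rates_for(sorted_cues)
        prepared.append((ci, present, rp, ra))

    for t, (ci, present, rp, ra) in enumerate(prepared):
        if seen is not None:
            seen |= present
        if len(ci):
            deltas = _trial_deltas(
                V,
                ci,
                present,
                rp,
                ra,
                lam,
                config.disable_outcome_competition,
                config.disable_cue_competition,
                active_outcomes=seen,
            )
            V[ci, :] += deltas
        if hist is not None:
            for k, (i, j) in enumerate(pair_idx):
                hist[t, k] = V[i, j]

    final = WeightMatrix(cues, outcomes, V)
    history = WeightHistory(pairs, hist if hist is not None else np.zeros((0, 0)))
    return final, history
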