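"""Event-level data model and event-stream construction.

Learning in a two-layer error-driven network is driven by *learning
events*: one trial pairs a set of discrete cues (the stimuli present
before the prediction is tested) with a set of discrete outcomes (what
actually followed, possibly nothing).  Everything the learner ever sees
is an ordered stream of such events, so the order of a stream is
semantically meaningful.

This module defines the event types plus the standard transformations
used to construct training designs: replicating/sampling a frequency
table into a stream, exchanging cues and outcomes (the object-first vs
label-first manipulation), inserting a constant background cue,
expanding elemental cue sets with configural compound cues, and turning
a symbol sequence into associative-chain events via a shift register.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LABEL_SEPARATOR",
    "COMPOUND_JOINER",
    "LearningEvent",
    "EventStream",
    "FrequencyTable",
    "stream_from_table",
    "swap_cues_outcomes",
    "add_constant_cue",
    "expand_configural",
    "chain_events",
]

#: Reserved separator used to join labels within one cell of an event
#: table file; therefore forbidden inside any label.
LABEL_SEPARATOR = "_"

#: Joiner for configural compound cue labels ("Light+Tone"); forbidden
#: inside *atomic* labels so compounds are always recognizable.
COMPOUND_JOINER = "+"


def check_label(label: str, *, allow_compound: bool = True) -> str:
    """Validate a cue/outcome label; returns it unchanged.

    Labels must be non-empty strings without the reserved file
    separator ``"_"``; atomic labels additionally may not contain the
    compound joiner ``"+"``.
    """
    if not isinstance(label, str) or not label:
        raise ValueError(f"labels must be non-empty strings, got {label!r}")
    if LABEL_SEPARATOR in label:
        raise ValueError(
            f"label {label!r} contains the reserved separator {LABEL_SEPARATOR!r}"
        )
    if not allow_compound and COMPOUND_JOINER in label:
        raise ValueError(
            f"atomic label {label!r} contains the compound joiner {COMPOUND_JOINER!r}"
        )
    return label


@dataclass(frozen=True)
class LearningEvent:
    """One trial: a set of cues followed by a set of outcomes.

    An empty outcome set means "nothing followed" and still drives
    learning (weights from the present cues to every tracked outcome
    are decremented).
    """

    cues: frozenset[str]
    outcomes: frozenset[str] = frozenset()

    def __init__(self, cues: Iterable[str], outcomes: Iterable[str] = ()) -> None:
        cue_set = frozenset(check_label(c) for c in cues)
        outcome_set = frozenset(check_label(o) for o in outcomes)
        object.__setattr__(self, "cues", cue_set)
        object.__setattr__(self, "outcomes", outcome_set)

    def swapped(self) -> "LearningEvent":
        """Exchange the roles of cues and outcomes."""
        return LearningEvent(self.outcomes, self.cues)

    def __repr__(self) -> str:  # stable, sorted representation
        c = ",".join(sorted(self.cues))
        o = ",".join(sorted(self.outcomes))
        return f"LearningEvent({{{c}}} -> {{{o}}})"


@dataclass
class EventStream:
    """An ordered, finite sequence of learning events.

    Iteration order is the training order.  ``metadata`` records
    provenance (generator name, seed, phase boundaries) and never
    affects learning.
    """

    trials: tuple[LearningEvent, ...]
    metadata: dict = field(default_factory=dict)

    def __init__(self, trials: Iterable[LearningEvent] = (), metadata: dict | None = None):
        self.trials = tuple(trials)
        self.metadata = dict(metadata or {})

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def cue_labels(self) -> tuple[str, ...]:
        """All cue labels occurring anywhere in the stream, sorted."""
        return tuple(sorted(set().union(*(e.cues for e in self.trials)) if self.trials else set()))

    def outcome_labels(self) -> tuple[str, ...]:
        """All outcome labels occurring anywhere in the stream, sorted."""
        return tuple(sorted(set().union(*(e.outcomes for e in self.trials)) if self.trials else set()))

    def map_events(self, fn) -> "EventStream":
        return EventStream((fn(e) for e in self.trials), metadata=dict(self.metadata))


@dataclass
class FrequencyTable:
    """A training design as weighted trial types.

    Each row is a trial type (a :class:`LearningEvent`) with a positive
    frequency — an integer count for exact replication or a positive
    rate for i.i.d. sampling.
    """

    rows: tuple[tuple[LearningEvent, float], ...]

    def __init__(self, rows: Iterable[tuple[LearningEvent, float]]):
        rows = tuple((ev, float(f)) for ev, f in rows)
        if not rows:
            raise ValueError("a frequency table needs at least one row")
        for ev, f in rows:
            if not (f > 0):
                raise ValueError(f"frequencies must be positive, got {f} for {ev}")
        self.rows = rows

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[Iterable[str], Iterable[str], float]]
    ) -> "FrequencyTable":
        """Build from ``(cues, outcomes, frequency)`` triples."""
        return cls([(LearningEvent(c, o), f) for c, o, f in rows])

    @property
    def events(self) -> tuple[LearningEvent, ...]:
        return tuple(ev for ev, _ in self.rows)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, f in self.rows], dtype=float)

    @property
    def probabilities(self) -> np.ndarray:
        f = self.frequencies
        return f / f.sum()

    def cue_labels(self) -> tuple[str, ...]:
        return tuple(sorted(set().union(*(e.cues for e in self.events))))

    def outcome_labels(self) -> tuple[str, ...]:
        return tuple(sorted(set().union(*(e.outcomes for e in self.events))))

    def map_events(self, fn) -> "FrequencyTable":
        return FrequencyTable([(fn(ev), f) for ev, f in self.rows])

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def stream_from_table(
    table: FrequencyTable,
    mode: str = "exact",
    n_trials: int | None = None,
    order: str = "random",
    seed: int | None = None,
) -> EventStream:
    """Materialize a frequency table into a training stream.

    ``mode="exact"`` replicates every row exactly in proportion to its
    (integer) frequency; ``n_trials``, if given, must be a multiple of
    the total frequency and scales the whole multiset.  With
    ``mode="sampled"``, ``n_trials`` events are drawn i.i.d. with row
    probabilities proportional to the frequencies.  ``order="random"``
    shuffles with the seed; ``order="as_given"`` keeps row order.
    Identical arguments (including the seed) yield identical streams.
    """
    if mode not in ("exact", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    if order not in ("random", "as_given"):
        raise ValueError(f"unknown order {order!r}")
    if n_trials is not None and n_trials <= 0:
        raise ValueError(f"n_trials must be positive, got {n_trials}")

    rng = np.random.default_rng(seed)
    events = table.events

    if mode == "exact":
        freqs = table.frequencies
        if not np.allclose(freqs, np.round(freqs)):
            raise ValueError("exact mode requires integer frequencies")
        counts = np.round(freqs).astype(int)
        total = int(counts.sum())
        if n_trials is None:
            reps = 1
        else:
            if n_trials % total != 0:
                raise ValueError(
                    f"n_trials={n_trials} is not a multiple of the total frequency {total}"
                )
            reps = n_trials // total
        trials = [ev for ev, c in zip(events, counts) for _ in range(c * reps)]
        if order == "random":
            perm = rng.permutation(len(trials))
            trials = [trials[i] for i in perm]
    else:
        if n_trials is None:
            raise ValueError("sampled mode requires n_trials")
        idx = rng.choice(len(events), size=n_trials, p=table.probabilities)
        if order == "as_given":
            idx = np.sort(idx)
        trials = [events[i] for i in idx]

    return EventStream(
        trials,
        metadata={"generator": "stream_from_table", "mode": mode, "order": order, "seed": seed},
    )


def _dispatch(source, fn):
    """Apply an event transform to a stream or a frequency table."""
    if isinstance(source, (EventStream, FrequencyTable)):
        return source.map_events(fn)
    raise TypeError(f"expected EventStream or FrequencyTable, got {type(source).__name__}")


def swap_cues_outcomes(source):
    """Exchange cue and outcome sets in every event.

    Swapping turns an object-first design (features predict labels,
    features compete as cues) into a label-first design (labels predict
    features, features compete as outcomes) — the asymmetry
    manipulation.  Applying it twice restores the input.
    """
    return _dispatch(source, LearningEvent.swapped)


def add_constant_cue(source, label: str = "ctx"):
    """Add a constant background cue to every event's cue set.

    The constant (context) cue stands for undiscriminated properties of
    the environment present on every trial; it plays the role of the
    intercept in a regression and guarantees no two cue sets are
    disjoint.  Idempotent under set semantics.
    """
    check_label(label)
    outcome_collision = False
    if isinstance(source, EventStream):
        outcome_collision = label in set(source.outcome_labels())
    elif isinstance(source, FrequencyTable):
        outcome_collision = label in set(source.outcome_labels())
    if outcome_collision:
        warnings.warn(
            f"constant-cue label {label!r} is also used as an outcome label",
            UserWarning,
            stacklevel=2,
        )
    return _dispatch(source, lambda e: LearningEvent(e.cues | {label}, e.outcomes))


def expand_configural(source, max_order: int = 2, max_new_cues: int = 256):
    """Add configural compound cues for cue subsets of size 2..max_order.

    A compound cue represents the conjunction of its members as a unit
    of its own — the representation needed to solve designs such as
    negative patterning that are not linearly separable over elemental
    cues.  Compound labels are the member labels sorted and joined by
    ``"+"``; existing compounds are left alone (the operation is
    idempotent at fixed ``max_order``).  More than ``max_new_cues``
    generated compounds in one event raises an error: enumerating all
    subsets is combinatorially explosive.
    """
    if max_order < 2:
        raise ValueError(f"max_order must be >= 2, got {max_order}")

    def expand(event: LearningEvent) -> LearningEvent:
        atoms = sorted(c for c in event.cues if COMPOUND_JOINER not in c)
        new: set[str] = set()
        for k in range(2, min(max_order, len(atoms)) + 1):
            for combo in itertools.combinations(atoms, k):
                new.add(COMPOUND_JOINER.join(combo))
                if len(new) > max_new_cues:
                    raise ValueError(
                        f"configural expansion would add more than {max_new_cues} "
                        f"compound cues to one event ({len(atoms)} atomic cues, "
                        f"max_order={max_order}); raise max_new_cues explicitly "
                        "if this is intended"
                    )
        return LearningEvent(event.cues | new, event.outcomes)

    return _dispatch(source, expand)


def chain_events(
    sequence: Sequence, memory: int = 1, tag_lags: bool = True
) -> EventStream:
    """Turn a symbol sequence into associative-chain learning events.

    Each element of the sequence becomes the outcome of one event whose
    cues are the preceding ``memory`` elements (a shift register): at
    position p the cues are the symbols at p-1 .. p-memory, as far as
    the sequence reaches back.  With ``tag_lags=True`` (default) cues
    are tagged by their lag (``"lag1:0"``), so the same symbol at
    different distances is a distinct cue; untagged cues collapse the
    register into an unordered recency set.
    """
    if memory < 1:
        raise ValueError(f"memory must be >= 1, got {memory}")
    symbols = [str(s) for s in sequence]
    for s in symbols:
        check_label(s, allow_compound=False)
    trials = []
    for p in range(1, len(symbols)):
        k = min(memory, p)
        if tag_lags:
            cues = {f"lag{lag}:{symbols[p - lag]}" for lag in range(1, k + 1)}
        else:
            cues = {symbols[p - lag] for lag in range(1, k + 1)}
        trials.append(LearningEvent(cues, {symbols[p]}))
    return EventStream(
        trials, metadata={"generator": "chain_events", "memory": memory, "tag_lags": tag_lags}
    )
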