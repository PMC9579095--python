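"""Ready-made training designs for the classic learning phenomena.

Each generator returns a :class:`~edlsim.events.FrequencyTable` (a
declarative design) or an :class:`~edlsim.events.EventStream` (when the
phase order itself is the manipulation), reproducible bit-exactly from
its arguments and seed.

The default exemplar frequencies are engineering choices: they satisfy
every ordinal constraint the designs impose (e.g. small dogs more
frequent than barking dogs; large rabbits rare) but are not canonical
values, and the qualitative results are invariant to any frequency
assignment consistent with those constraints.
"""

from __future__ import annotations

import numpy as np

from .events import EventStream, FrequencyTable, stream_from_table, swap_cues_outcomes

__all__ = [
    "blocking_paradigm",
    "light_tone_paradigm",
    "outcome_competition_paradigm",
    "dog_rabbit_paradigm",
    "negative_patterning_paradigm",
    "cyclic_sequence",
    "permutation_sequence",
    "xor_sequence",
    "PARADIGMS",
]


def blocking_paradigm(
    regimen: str = "pretrained",
    n_single: int = 300,
    n_compound: int = 300,
    seed: int | None = None,
) -> EventStream:
    """Kamin's blocking design: light -> food and {light, tone} -> food.

    regimen
        ``"pretrained"`` trains the light alone first, then the
        compound: after enough pretraining the light fully predicts
        food and the redundant tone is blocked.  ``"compound_first"``
        reverses the phases: the tone keeps whatever weight it earned
        while only the light is trained.  ``"randomized"`` shuffles the
        union of both phases with the seed.

    The default of 300 single-cue trials makes the light's weight
    exceed 0.95 at the default learning rate 0.01 (closed form
    1 - 0.99^300), which is enough pretraining to block the tone.
    """
    if n_single <= 0 or n_compound <= 0:
        raise ValueError("trial counts must be positive")
    from .events import LearningEvent

    single = [LearningEvent({"light"}, {"food"})] * n_single
    compound = [LearningEvent({"light", "tone"}, {"food"})] * n_compound
    if regimen == "pretrained":
        trials = single + compound
    elif regimen == "compound_first":
        trials = compound + single
    elif regimen == "randomized":
        trials = single + compound
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(trials))
        trials = [trials[i] for i in perm]
    else:
        raise ValueError(f"unknown regimen {regimen!r}")
    return EventStream(
        trials,
        metadata={
            "generator": "blocking_paradigm",
            "regimen": regimen,
            "n_single": n_single,
            "n_compound": n_compound,
            "seed": seed,
            "phase_boundary": None if regimen == "randomized" else (n_single if regimen == "pretrained" else n_compound),
        },
    )


def light_tone_paradigm(variant: str = "independent") -> FrequencyTable:
    """Cue competition beyond frequency: a light paired with two tones.

    ``"independent"``: the light appears with a loud tone (frequent) or
    a soft tone (rare) before food.  Both tones compete with the light
    in exactly the same way, so at equilibrium they end up with the
    same weight despite their different frequencies.

    ``"interacting"``: every cue also appears in a pair with every
    other cue, so all cues interact with all others and all frequency
    effects cancel — every cue converges to the same weight.
    """
    if variant == "independent":
        return FrequencyTable.from_rows(
            [
                ({"light", "loud"}, {"food"}, 2),
                ({"light", "soft"}, {"food"}, 1),
            ]
        )
    if variant == "interacting":
        return FrequencyTable.from_rows(
            [
                ({"light", "loud"}, {"food"}, 3),
                ({"light", "soft"}, {"food"}, 2),
                ({"loud", "soft"}, {"food"}, 1),
            ]
        )
    raise ValueError(f"unknown variant {variant!r}")


def outcome_competition_paradigm() -> FrequencyTable:
    """One cue, two outcomes: light predicts food 2/3 and water 1/3 of the time.

    With absent-outcome updating the weights converge to these
    conditional probabilities; with it disabled both weights climb to
    the activation ceiling.
    """
    return FrequencyTable.from_rows(
        [
            ({"light"}, {"food"}, 2),
            ({"light"}, {"water"}, 1),
        ]
    )


_DOG_RABBIT_1 = (
    (frozenset({"big", "tail-wagging"}), "dog"),
    (frozenset({"small", "tail-wagging"}), "dog"),
    (frozenset({"small", "barking"}), "dog"),
    (frozenset({"small", "hopping"}), "rabbit"),
)
_DOG_RABBIT_1_FREQ = (2.0, 2.0, 1.0, 3.0)

_DOG_RABBIT_2 = (
    (frozenset({"big", "tail-wagging"}), "dog"),
    (frozenset({"small", "barking"}), "dog"),
    (frozenset({"small", "hopping"}), "rabbit"),
    (frozenset({"big", "hopping"}), "rabbit"),
)
_DOG_RABBIT_2_FREQ = (4.0, 1.0, 4.0, 1.0)


def dog_rabbit_paradigm(
    example: int = 1,
    order: str = "object_first",
    frequencies: tuple[float, ...] | None = None,
) -> FrequencyTable:
    """Species discrimination with interacting cue and outcome competition.

    Example 1: big and small tail-wagging dogs, small barking dogs and
    small hopping rabbits; small dogs are more frequent than barking
    dogs.  Example 2 adds the cross-over that makes the asymmetry
    dramatic: dogs are mostly big and rabbits mostly small, but a few
    small (barking) dogs and big (hopping) rabbits exist.

    ``order="object_first"`` presents animal features as cues and the
    species label as outcome (features compete as cues);
    ``order="label_first"`` swaps the two (features compete as
    outcomes, weights approach conditional feature probabilities).

    ``frequencies`` overrides the default exemplar frequencies (one
    positive number per exemplar type, in the order documented above).
    """
    if example == 1:
        types, default = _DOG_RABBIT_1, _DOG_RABBIT_1_FREQ
    elif example == 2:
        types, default = _DOG_RABBIT_2, _DOG_RABBIT_2_FREQ
    else:
        raise ValueError(f"example must be 1 or 2, got {example}")
    freqs = default if frequencies is None else tuple(float(f) for f in frequencies)
    if len(freqs) != len(types):
        raise ValueError(f"need {len(types)} frequencies, got {len(freqs)}")
    if any(f <= 0 for f in freqs):
        raise ValueError("frequencies must be positive")
    table = FrequencyTable.from_rows(
        [(cues, {label}, f) for (cues, label), f in zip(types, freqs)]
    )
    if order == "object_first":
        return table
    if order == "label_first":
        return swap_cues_outcomes(table)
    raise ValueError(f"unknown order {order!r}")


def negative_patterning_paradigm(coding: str = "elemental") -> FrequencyTable:
    """Negative patterning: tone -> food, light -> food, compound -> water.

    The compound trial's cue set depends on the coding:

    * ``"elemental"``: {Tone, Light} — the design is linearly
      inseparable and the two outcomes cannot be discriminated;
    * ``"configural"``: {Tone+Light} only — perfectly separable but
      with no generalization to the elements;
    * ``"mixed"``: {Tone, Light, Tone+Light} — separable with
      generalization through the shared elements.
    """
    if coding == "elemental":
        compound = {"Tone", "Light"}
    elif coding == "configural":
        compound = {"Light+Tone"}
    elif coding == "mixed":
        compound = {"Tone", "Light", "Light+Tone"}
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return FrequencyTable.from_rows(
        [
            ({"Tone"}, {"food"}, 1),
            ({"Light"}, {"food"}, 1),
            (compound, {"water"}, 1),
        ]
    )


def cyclic_sequence(length: int, n_symbols: int = 4) -> list[int]:
    """A deterministic-successor sequence: the repeating cycle 0..n-1.

    Every element fully determines its successor, so an associative
    chain learner with any memory reaches perfect prediction.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    return [i % n_symbols for i in range(length)]


def permutation_sequence(n_blocks: int, n_symbols: int = 4, seed: int | None = None) -> list[int]:
    """Concatenated random permutations of 0..n-1 (low statistical complexity).

    Within each block every symbol occurs once, so later elements of a
    block are increasingly predictable from the preceding ones.
    """
    rng = np.random.default_rng(seed)
    out: list[int] = []
    for _ in range(n_blocks):
        out.extend(int(x) for x in rng.permutation(n_symbols))
    return out


def xor_sequence(n_triplets: int, seed: int | None = None) -> list[int]:
    """Triplets [a, b, a XOR b] with a, b drawn i.i.d. uniform from {0, 1}.

    The third element of each triplet is a higher-order (XOR) function
    of the preceding two — not linearly separable over lag-tagged
    elemental cues, so a two-layer chain learner stays at chance on it.
    """
    rng = np.random.default_rng(seed)
    out: list[int] = []
    for _ in range(n_triplets):
        a, b = int(rng.integers(0, 2)), int(rng.integers(0, 2))
        out.extend([a, b, a ^ b])
    return out


#: Registry used by the CLI ``paradigm`` subcommand.
PARADIGMS = {
    "blocking": blocking_paradigm,
    "light_tone": light_tone_paradigm,
    "outcome_competition": outcome_competition_paradigm,
    "dog_rabbit": dog_rabbit_paradigm,
    "negative_patterning": negative_patterning_paradigm,
}
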