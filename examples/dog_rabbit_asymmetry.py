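"""Cue-outcome asymmetry in a species-discrimination task.

Learners see big or small, tail-wagging, barking or hopping animals.
Object-first training (features as cues, species label as outcome) lets
the features compete as cues and produces perfectly discriminative
choices; label-first training (the swapped design) makes the features
compete as outcomes, so the weights mirror conditional feature
probabilities and certainty is lost.
"""

from edlsim import (
    activation_matrix,
    choice_probabilities,
    dog_rabbit_paradigm,
    moments_from_stream,
    solve_equilibrium,
)

for example in (1, 2):
    table = dog_rabbit_paradigm(example, order="object_first")
    V = solve_equilibrium(moments_from_stream(table))
    tests = [{"small", "barking"}, {"big", "tail-wagging"}] if example == 2 else [
        {"small", "barking"}
    ]
    print(f"dog-rabbit example {example}, object-first:")
    for cues in tests:
        acts = activation_matrix(V, [cues])
        p = choice_probabilities(acts.iloc[0], rule="luce")
        print(f"  P(dog | {sorted(cues)}) = {p['dog']:.3f},  "
              f"P(rabbit | ...) = {p['rabbit']:.3f}")

print()
table = dog_rabbit_paradigm(1, order="label_first")
V = solve_equilibrium(moments_from_stream(table))
print("example 1, label-first equilibrium (weights = P(feature | label)):")
for feat in ("tail-wagging", "small", "barking", "big"):
    print(f"  'dog' -> {feat:<12} = {V.get('dog', feat):.3f}")

print()
print("Object-first choices are certain (1 and 0); label-first weights are")
print("the conditional feature probabilities given the label (4/5, 3/5, ...).")
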