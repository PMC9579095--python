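"""Cue competition and the blocking effect.

A light is trained alone to predict food, then a tone is added to the
compound.  Because the light already absorbs the whole prediction, the
redundant tone acquires (almost) no weight — Kamin blocking.  With the
reversed regimen the compound is trained first, and the tone keeps its
share untouched through the light-only phase.
"""

from edlsim import LearnerConfig, blocking_paradigm, train

for regimen in ("pretrained", "compound_first", "randomized"):
    stream = blocking_paradigm(regimen, n_single=300, n_compound=300, seed=0)
    weights, history = train(stream, LearnerConfig(eta=0.01), track=[("tone", "food")])
    tone = history.series("tone", "food")
    print(
        f"{regimen:>14}: light->food = {weights.get('light', 'food'):.3f}, "
        f"tone->food = {weights.get('tone', 'food'):.3f}"
    )
    if regimen == "compound_first":
        constant = bool((tone[300:] == tone[300]).all())
        print(f"{'':>14}  tone weight constant during the light-only phase: {constant}")

print()
print("A tone weight near 0 after pretraining is the blocking effect: the")
print("added cue is redundant, so cue competition leaves it nothing to predict.")
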