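"""Outcome competition learns conditional outcome probabilities.

One light predicts food two thirds of the time and water one third of
the time.  A single cue cannot fully predict two outcomes, so the
absent-outcome updates drive the weights to the conditional
probabilities P(outcome | light).  Disabling that mechanism lets both
weights climb to the activation ceiling of 1 instead.
"""

from edlsim import (
    LearnerConfig,
    moments_from_stream,
    outcome_competition_paradigm,
    solve_equilibrium,
    stream_from_table,
    train,
)

table = outcome_competition_paradigm()

V = solve_equilibrium(moments_from_stream(table))
print(f"equilibrium:  light->food = {V.get('light', 'food'):.4f}  "
      f"light->water = {V.get('light', 'water'):.4f}")

stream = stream_from_table(table, mode="sampled", n_trials=30_000, seed=1)
w, _ = train(stream, LearnerConfig(eta=0.01))
print(f"incremental:  light->food = {w.get('light', 'food'):.4f}  "
      f"light->water = {w.get('light', 'water'):.4f}")

w_ablated, _ = train(stream, LearnerConfig(disable_outcome_competition=True))
print(f"ablated:      light->food = {w_ablated.get('light', 'food'):.4f}  "
      f"light->water = {w_ablated.get('light', 'water'):.4f}")

print()
print("The intact learner matches P(food|light) = 2/3 and P(water|light) = 1/3;")
print("without absent-outcome updating both weights saturate at the limit 1.")
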