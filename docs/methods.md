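# Methods

## Model and assumptions

`edlsim` implements the minimal two-layer error-driven learning model:
discrete cue units fully connected to discrete outcome units, a linear
identity activation (an outcome's activation is the plain sum of the
weights from the present cues), and online delta-rule updating. No
hidden layers, no nonlinear activation during learning, no weight
decay, and no attention or salience *learning*: every dynamic the
simulator exhibits is attributable to the error-correction rule and the
trial distribution. Cues and outcomes are sets of string labels per
trial; presence is binary (a label cannot occur "twice" in one trial).

The update distinguishes three cases per (cue, outcome) pair: absent
cue — no change; present cue and present outcome — move toward the
ceiling λ in proportion to the prediction error; present cue and absent
outcome — move toward 0 in proportion to the (wrong) positive
expectation. The third case applies to *every* outcome the network
tracks, which is what produces outcome competition.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `eta` | 0.01 | learning rate of the delta rule (dimensionless step size) |
| `lambda_max` | 1.0 | target activation of a present outcome; pure scale |
| `alpha` | 1 per cue | cue salience in (0, 1], Rescorla–Wagner variant only |
| `beta_present` / `beta_absent` | = `eta` | separate rates for positive / negative evidence (RW) |
| `disable_outcome_competition` | off | skip absent-outcome updates (case 3) entirely |
| `disable_cue_competition` | off | use the single weight instead of the summed activation in the error term |

The defaults (η = 0.01, λ = 1) are the conventional choices for this
model family; λ only rescales weights, so there is no reason to vary it
unless matching data on another scale. Both rule variants share one
update kernel parameterized by per-cue present/absent rates, so the
reduction of the Rescorla–Wagner rule to the delta rule (α = 1,
β₁ = β₂ = η, λ = 1) is exact to the bit, and is asserted by a property
test rather than assumed.

## Numerical and design choices

* **Synchronous within-trial updates.** All deltas of a trial are
  computed from the pre-update weights and applied at once. The error
  term references the state at time t, so sequential within-trial
  updating was rejected; a side benefit is that cue/outcome enumeration
  order inside a trial cannot change results (tested bit-exactly).
* **Fixed outcome universe.** The set of outcomes participating in
  absent-outcome updates is declared before training as every outcome
  occurring anywhere in the stream (plus declared extras), so case 3
  applies from trial 1 even to outcomes not yet observed. The
  alternative — a universe that grows as outcomes are first observed —
  makes results order-dependent in a way that is easy to overlook; it
  is available as `growing_universe=True` for exploration.
* **Zero initialization** by default (tabula rasa); pretraining is
  expressed as an explicit earlier phase or by injecting an `initial`
  weight matrix, not as a prior.
* **No weight clipping during learning.** Activations can exceed λ or
  go negative transiently; only the response mapping clips (the Luce
  rule zeroes negative activations at choice time).
* **Equilibrium solve.** The convergence point is the least-squares
  solution of the design, obtained from the normal equations
  C V = B via the Moore–Penrose pseudoinverse. For singular designs
  (perfectly correlated cues) this selects the minimum-norm solution,
  which is deterministic and is the limit a zero-initialized
  incremental learner approaches, since its iterates never leave the
  design's row space. The residual is evaluated from the moments in
  closed form and clipped at 0 against floating-point undershoot
  (exactly fittable designs can evaluate to −1e−17).
* **Reserved characters.** `_` is the event-table cell separator and is
  forbidden in all labels; `+` joins configural compound labels
  (members sorted, so {Tone, Light} and {Light, Tone} name the same
  compound) and is forbidden in atomic labels. Configural expansion
  skips labels already containing `+`, making it idempotent at fixed
  order, and refuses to generate more than a configurable number of
  compounds per event (combinatorial explosion guard).
* **Lag-tagged chain cues.** The shift register tags cues by lag
  (`lag1:0`), so the same symbol at different distances is a distinct
  cue. Without tags the XOR sequence design degenerates (different
  targets share identical cue sets in both directions); untagged
  behavior is available via `tag_lags=False`.
* **Luce rule fallback.** If every activation clips to zero there is no
  evidence for any outcome; the maximum-entropy uniform distribution is
  returned. Threshold ties likewise split uniformly, preserving order.
  The logistic rule's (slope, midpoint) defaults to (1, 0).

## Built-in paradigms and their defaults

Exemplar frequencies for the worked designs are engineering defaults
chosen to satisfy the ordinal constraints that define each design; they
are not canonical values, and the qualitative results are verified (by
test) to be invariant across alternative assignments consistent with
those constraints.

* `blocking_paradigm`: light→food and {light, tone}→food; regimens
  `pretrained`, `compound_first`, `randomized`. 300 pretraining trials
  by default, from the closed form 1 − (1 − η)ⁿ > 0.95 at η = 0.01.
* `light_tone_paradigm`: `independent` (2:1) shows frequency mattering
  only within cue sets; `interacting` (3:2:1 over all cue pairs) shows
  interaction structure cancelling frequency entirely.
* `outcome_competition_paradigm`: light→food : light→water = 2 : 1.
* `dog_rabbit_paradigm`: example 1 types {big,tw}→dog, {small,tw}→dog,
  {small,bark}→dog, {small,hop}→rabbit at 2:2:1:3 (small dogs more
  frequent than barking dogs); example 2 types {big,tw}→dog,
  {small,bark}→dog, {small,hop}→rabbit, {big,hop}→rabbit at 4:1:4:1
  (dogs mostly big, big rabbits rare; the exact pairing of size and
  behavior features in example 2 is reconstructed from the reported
  choice probabilities). `order="label_first"` swaps cues and outcomes.
* `negative_patterning_paradigm`: Tone→food, Light→food,
  compound→water at equal frequencies, with the compound coded
  elementally, configurally, or mixed.
* Sequence generators: `cyclic_sequence` (deterministic successors),
  `permutation_sequence` (concatenated random permutations),
  `xor_sequence` (triplets [a, b, a⊕b] with a, b i.i.d. uniform bits —
  the sampling of the leading bits is uniform by choice, as the triplet
  notation alone does not fix it).

## What the generators emulate — and what they do not

The event generators produce idealized trial distributions: binary
presence cues, exact or i.i.d.-sampled trial orders, no perceptual
noise, no drifting environment, no learner fatigue. Passing tests
therefore show that the *mechanism* produces the expected dynamics
under the stated designs; they say nothing about fitted parameters for
real subjects, stimulus-level salience differences, or similarity-based
generalization between compounds (a configural cue shares nothing with
its elements unless the mixed coding includes them explicitly).

## Problem sizes used in tests and the acceptance script

Equilibrium-oracle comparisons train 10⁵ randomized trials at η = 0.001
(agreement within 0.02 of the solve on every built-in design; observed
agreement is typically < 10⁻⁴). Convergence-level incremental results
use 5 000–30 000 sampled trials at η = 0.01. The sequence contrast
trains on 2 002 cyclic elements and 2 000 XOR triplets and evaluates
500 sampled test choices (chance band ±3 binomial s.d.). The
cue-competition ablation uses η = 0.002 over 80 000 trials so the
stationary fluctuation around the conditional probabilities is small
relative to the 0.05 check tolerance.

## Known limitations

* Only endpoints are computed analytically; learning-trajectory shapes
  are validated by property (monotonicity, constancy, closed form in
  the one-pair case), not against figure-level curves, whose exact
  trial counts are not part of the built-in designs.
* The amplitude of the stationary fluctuation of the incremental
  learner around the equilibrium as a function of η is not
  characterized; the 0.02 oracle tolerance is an engineering margin.
* No similarity mechanism between configural cues, no probabilistic
  microfeature sampling, no salience/attention learning, no hidden
  layers — these are outside the model family this package isolates.
* Choice baselines depend on the number of alternatives; correcting a
  simulated baseline against an empirical one is left to the user.
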