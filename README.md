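# edlsim

Simulation and analysis of the simplest error-driven learning model: a
fully connected two-layer feed-forward network that learns association
weights between discrete **cues** (stimulus features, word forms,
context markers) and discrete **outcomes** (predicted items or events)
by incrementally minimizing prediction error. This minimal model — the
Widrow–Hoff delta rule, of which the Rescorla–Wagner model is a
parameterized variant — underlies a wide range of work in animal
conditioning, category learning and psycholinguistics, and `edlsim` is
aimed at researchers who want to explore its dynamics (cue competition,
outcome competition, blocking, asymmetry effects, negative patterning,
sequence learning) on designs of their own.

## The model

The activation of outcome $j$ at trial $t$ is the summed weight of the
present cues (linear identity activation):

$$\mathrm{act}_j^t = \sum_{x \in \mathrm{cues}(t)} V_{xj}^t$$

Weights update online, $V^{t+1}_{ij} = V^t_{ij} + \Delta V^t_{ij}$, with
the delta rule distinguishing three cases:

$$\Delta V_{ij}^t = \begin{cases} 0 & \text{cue } i \text{ absent} \\ \eta\,(1 - \mathrm{act}_j^t) & \text{cue } i \text{ and outcome } j \text{ present} \\ \eta\,(0 - \mathrm{act}_j^t) & \text{cue } i \text{ present, outcome } j \text{ absent} \end{cases}$$

with learning rate $\eta = 0.01$ by default. The Rescorla–Wagner
variant replaces $\eta$ by $\alpha_i\beta_1$ / $\alpha_i\beta_2$ and the
ceiling 1 by $\lambda$; with $\alpha_i = 1$, $\beta_1 = \beta_2 = \eta$
and $\lambda = 1$ it is identical to the delta rule. Case 2 produces
*cue competition* (present cues share a bounded total prediction),
case 3 *outcome competition* (weights to absent outcomes are
dissociated, driving weights toward conditional outcome probabilities);
either mechanism can be ablated to study it in isolation.

Under a fixed trial distribution the incremental learner asymptotes
toward the least-squares solution of the design — the weight matrix $V$
solving the equilibrium (Danks) normal equations $C\,V = B$, with $C$
the cue co-occurrence moments and $B$ the cue–outcome moments.
`edlsim` solves these directly (minimum-norm for singular designs) and
uses the solution both as an analysis tool and as a test oracle for the
incremental learner. Learned weights map to behavior through the
activation matrix, order-preserving choice rules (Luce with negative
activations clipped to zero, logistic, threshold) and reaction-time
proxies ($-\mathrm{act}$ or $\log(1/\mathrm{act})$).

## Worked example

One light predicts food on two trials out of three and water on the
third — more outcomes than cues, so full certainty is impossible and
outcome competition takes over:

```python
from edlsim import (LearnerConfig, moments_from_stream, outcome_competition_paradigm,
                    solve_equilibrium, stream_from_table, train)

table = outcome_competition_paradigm()                 # light -> food (2), light -> water (1)
V = solve_equilibrium(moments_from_stream(table))
print(V.get("light", "food"), V.get("light", "water"))

stream = stream_from_table(table, mode="sampled", n_trials=30_000, seed=1)
w, _ = train(stream, LearnerConfig(eta=0.01))
print(w.get("light", "food"), w.get("light", "water"))
```

```
0.6666666666666666 0.3333333333333333
0.6744232807158198 0.32557671928417997
```

The equilibrium weights are exactly the conditional probabilities
P(food | light) = 2/3 and P(water | light) = 1/3; the incremental
learner fluctuates around that point (here after 30 000 randomized
trials at η = 0.01). The `examples/` directory has one such narrative
script per capability: blocking, outcome competition, the dog–rabbit
asymmetry examples, negative patterning and chain sequence learning.

## Command line

Each subcommand takes one strict YAML config naming a built-in paradigm
or an event-table file (TSV with columns `cues`, `outcomes`,
`frequency`; labels within a cell joined by `_`), the learner settings
and an output directory:

```sh
edlsim train config.yaml        # incremental training -> weights.tsv (+ history.tsv)
edlsim equilibrium config.yaml  # least-squares solve -> equilibrium.tsv, residual.txt
edlsim choice config.yaml       # activations + choice probabilities for test cue sets
edlsim paradigm config.yaml     # export a built-in design as an event-table fixture
```

Every run logs its config hash, seed and versions to stderr, and all
outputs are byte-reproducible from (config, seed).

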