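# logicoop

Asynchronous multi-valued logical models of cellular regulatory networks:
attractor computation, Monte-Carlo reachability, read-out based phenotype
classification, and systematic in-silico perturbation screens that call
**cooperative interactions** between mutations and micro-environmental
signals.

## Who this is for

Systems biologists who use qualitative (Boolean / multi-valued) models of
signalling and gene-regulatory networks — the GINsim/bioLQM style of model —
and want a scriptable Python library to:

- simulate **unitary asynchronous dynamics** (each step moves one component
  one level toward its rule's target),
- enumerate **stable states** and find **complex attractors** (terminal
  strongly connected components of the state transition graph),
- estimate **reachability probabilities** `R/N` by seeded random walks, with
  an exact Markov-chain absorption solver as ground truth,
- classify attractors into phenotypes via designated read-out components
  (the EMT table over AJ assembly and FA recycling is built in), and
- run **single/double mutant screens** and **input scans**, calling a pair of
  conditions *cooperative* when the double gains a phenotype absent from both
  singles, or loses one present in both.

## The model in brief

A logical model is a set of components, each with a discrete level
`0..max_level` (`max_level = 1` for Boolean components). Designated *inputs*
encode external signals and are held constant; every other component `x` has
a logical rule — stored here as an explicit truth table over its regulators'
levels. In the asynchronous scheme a state `s` has one successor per
component whose target `f_x(s)` differs from `s_x`, moving that component by
±1 toward the target. Stable states are fixpoints (`f_x(s) = s_x` for all
`x`); attractors are terminal SCCs of the state transition graph. Reachability
from an initial state is the absorption probability of the uniform random
walk on that graph, estimated by `N` simulation runs as `R/N` or solved
exactly as a linear system. Mutations are *clamps*: a loss of function (`KO`)
blocks a component at 0, a gain of function (`E_v`) at level `v`.

## Worked example

The built-in four-component model (input `S`; `A = S AND NOT C`;
`B = NOT A`; `C = B AND NOT A`; states print as `ABCS`):

```python
import logicoop as lc

model = lc.set_inputs(lc.toy_model(), {"S": 1})
print(sorted(model.format_state(s) for s in lc.stable_states(model)))

init = model.parse_state("0001")
for a, p in lc.exact_absorption(model, init).items():
    print(model.format_state(a.state), p)

est = lc.estimate_reachability(model, init, n_runs=100_000, seed=7)
for a, r in est.counts.items():
    print(model.format_state(a.state), r / est.n_runs)
```

prints

```
['0111', '1001']
0111 0.25
1001 0.75
1001 0.74894
0111 0.25106
```

With the input on, the model is bistable; from `0001` the two fates are
reached with probability exactly 1/4 and 3/4 (the Monte-Carlo estimate
converges on the absorption solve; the binomial standard error at `N = 1e5`
is ≈ 0.0014). Blocking `A` at 0 (`lc.apply_perturbation(model,
lc.Perturbation.parse("A KO"))`) removes the `1001` attractor.

The `examples/` directory walks through each capability on runnable inputs:
toy-model dynamics, reachability versus the exact solve, micro-environment
phenotype scans on the bundled mini-EMT model, and the NOTCH-anchored
double-mutant screen with its cooperativity calls (`lost E1` for
NOTCH E1 × RAF E1; `gained H3` for NOTCH E1 × PI3K KO).

A thin CLI mirrors the library:

```bash
logicoop fixtures --write models/
logicoop stable --model models/toy.json --inputs S=1
logicoop reach  --model models/toy.json --inputs S=1 --initial 0001 --runs 100000 --seed 1
logicoop screen --model models/mini_emt.json --anchor "NOTCH E1" --exclude AJ --exclude FA
```

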