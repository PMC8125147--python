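# Methods

## Formalism and update semantics

A model is a finite set of components; each component `x` holds a discrete
level in `0..max_level(x)`. Input components represent external
(micro-environment) signals and are constant; each non-input component has a
logical rule `f_x` over the levels of its regulators. Rules are stored as
**explicit truth tables** over the regulator-level product space rather than
expression trees: totality, monotonicity (edge-sign consistency) and
brute-force oracles are then direct table scans, and every source dialect
(SBML-qual MathML, generated threshold rules, hand-written predicates) is
compiled to the same internal form at load time.

The only supported update scheme is **unitary asynchronous updating**: a
state `s` has one successor per component with `f_x(s) != s_x`, and that
successor changes `x` by exactly one level toward the target. Multi-valued
components therefore never jump levels. Synchronous or jump semantics are
out of scope (the brute-force oracle in the test suite independently
re-derives the same unitary relation; it is not an alternative semantics).

Perturbations are clamps — `KO` pins a component at 0, `E_v` at level `v`
(`E1` even for multi-valued components, following the usual GoF labelling).
A clamped component keeps its rule (so files round-trip) but is never
updated. Fixing inputs is deliberately a separate operation
(`set_inputs`): micro-environmental conditions and mutations are different
biological objects and the screens treat them differently. Inputs not named
in an assignment default to 0, matching the convention that scan conditions
list only the signals that are present.

## Stable states, attractors, STGs

Stable states are fixpoints of all rules. Enumeration uses branch-and-prune
over the free configuration space: components are assigned in declaration
order and a partial assignment is discarded as soon as a fully-determined
rule contradicts its target's level. This degenerates to exhaustive
enumeration in the worst case, so a budget guard (default 2^22
configurations) raises rather than silently thrashing. With *free* inputs
(no `set_inputs` call) the enumeration ranges over all input combinations —
this is what "phenotype compatibility" means in the mutant screens (see
below).

Attractors are the terminal strongly connected components of the state
transition graph (SCCs via networkx's iterative algorithm): singleton
terminal SCCs are stable states, larger ones complex (oscillatory)
attractors. Attractor identity is the state set; per-read-out level
summaries are carried along for phenotyping.

## Reachability

`estimate_reachability` runs `N` independent walks choosing uniformly among
enabled transitions. Uniform choice is the standard convention for
asynchronous random walks and reproduces the worked example's published
probabilities; no transition weighting is supported. Each run draws from its
own counter-derived substream (`default_rng([seed, run])`), so results are
deterministic given `(model, initial, N, seed)` and per-run streams do not
shift when `N` changes. Defaults: `N = 1e5` (the run count used for the
published scans) and `max_steps = 1e4`; truncated runs are counted
separately and never silently folded into an attractor.

Walks detect complex attractors on the fly: when a state is revisited, the
forward closure of the current state is expanded; because a closure is
closed under transitions, the walk is inside a terminal SCC **iff** that
closure is strongly connected, in which case the closure is the attractor.
The check re-arms with exponential backoff so long transients stay cheap.
This is a behavioural substitute for heavier adaptive simulation schemes:
what matters here are the absorption probabilities, and the exact solver
below is the ground truth the walks are tested against.

`exact_absorption` treats the reachable STG as an absorbing Markov chain:
terminal SCCs are lumped into absorbing macro-states and the dense linear
system `(I - Q) B = R` is solved. Probabilities sum to 1 within 1e-10; the
test suite requires Monte-Carlo agreement within 3 binomial standard errors
at `N = 1e4` (with the single statistical re-run that tolerance implies).

## Phenotype classification

Phenotypes are named by read-out components. The default table maps
`(AJ, FA)` pairs — AJ is adherens-junction assembly (0–2), FA focal-adhesion
recycling ability (0–3) — to eight labels: E1 (2,0); H1 (2,1); H2 (1,2);
H3 (2,3); U1 (0,0); M1 (0,1); M2 (0,2); M3 (0,3), classed epithelial /
hybrid / unknown / mesenchymal. The (0,0) row is unnamed in the source
classification and is labelled U1 here. An attractor whose read-outs are
constant but unmapped reports `unclassified`; non-constant read-outs report
`oscillatory` rather than being forced into a row. Tables are plain data and
can be replaced for non-EMT models.

## Screens

**Mutant screens** decide phenotype *compatibility* by stable states only.
Inputs are left free by default, i.e. stable states are enumerated across
every input combination. This choice resolves an ambiguity in the source
analyses: the unperturbed column of the published compatibility table ticks
all eight phenotypes, which is only possible if the screen ranges over input
conditions (with inputs fixed at the reference condition the unperturbed
model has a single epithelial stable state). A fixed input condition can
still be passed explicitly.

`enumerate_perturbations` yields, per non-input component with max level
`m`, the clamp set {KO, E1..Em} in declaration order. The EMT-style screens
exclude the two read-out components: clamping a read-out manufactures
phenotype calls that reflect the clamp itself rather than network logic
(e.g. pinning AJ at 1 trivially creates the (1, ·) rows). The exclusion is
an explicit argument, not a hard-coded rule. Double screens exclude the
anchor's own component from partners, so a Boolean anchor has two fewer
doubles than there are singles.

**Input scans** report reachable-phenotype probabilities. The initial state
is resolved by taking the unique stable state of a reference condition
carrying the requested phenotype (an error if not unique), then overwriting
the input levels with the scenario's values; if the resolved state is
already stable the distribution is the point mass, otherwise seeded walks
estimate it.

**Cooperativity**: for conditions X, Y, a phenotype is *gained* if present
under X+Y but absent under X alone and Y alone, and *lost* if absent under
X+Y but present under both singles. The implementation works row-wise on
single-condition tables; an independent set-algebra oracle checks it on
random tick tables in the tests.

## Synthetic models

`toy_model` is the four-component worked example. Only the rule of A is
published in full (`A = S AND NOT C`); the rules of B and C are
reconstructed as `B = NOT A`, `C = B AND NOT A`. The reconstruction is
validated, not assumed: the test suite solves the absorption system for
candidate wirings that share A's rule and the published stable states, and
only this wiring reproduces the published Monte-Carlo estimates
0.2514/0.7486 (exactly 1/4 and 3/4); e.g. `C = NOT A` gives ≈ 0.55 and
`C = B` gives 1/3 for the first fate.

`random_model` generates seeded models for oracle testing: a random signed
digraph within an in-degree bound, with each rule a random linear-threshold
function (positive weights for activators, negative for inhibitors, random
cut points over the attainable score range). Rules are monotone by
construction, so generated models always pass sign-consistency validation.
Generated models emulate the *structural* statistics the engine must handle
(small dense logical networks, mixed Boolean/multi-valued components); they
do not emulate biological degree distributions or canalisation, so passing
oracle tests demonstrates correctness of the dynamics engine, not biological
realism.

`mini_emt_model` is a hand-designed, version-pinned 12-component stand-in
for the deposited 39-node EMT network, which is distributed externally and
whose internal rules are not published. It preserves the *statistical
structure* the analyses assume — micro-environment inputs including a
protective RPTP ligand, Boolean internal signalling, two multi-valued
read-outs (AJ max 2, FA max 3), an epithelial reference state, a
probabilistic fate split, and engineered cooperative pairs:

- reference condition (`RPTP_L=1`, all else 0): unique stable state (2,0) = E1;
- switching ECM on from E1 races the RPTP guard against SNAIL: H1 and M3
  absorb with probability exactly 1/2 each;
- NOTCH is constitutively silent (no ligand modelled) and PI3K
  constitutively active, so `NOTCH E1` and `PI3K KO` are genuine mutations
  not reachable by any input combination — a prerequisite for engineered
  *gained* phenotypes, since with free inputs any input-drivable state
  already appears in single-mutant columns;
- engineered calls, frozen from exhaustive enumeration and recovered
  exactly by the screens with read-outs excluded: NOTCH E1 × RAF E1 loses
  E1 and U1; NOTCH E1 × PI3K KO loses E1, U1, H1 and gains H3. No other
  partner pair produces a call.

Results on this fixture demonstrate that the pipeline (dynamics →
phenotyping → screens → calls) is correct; they are not predictions about
the deposited EMT network, which can be analysed by loading its SBML-qual
export with `read_sbml_qual` when available.

## File formats

SBML-qual documents are read and written directly (XML via lxml).
Function terms are evaluated over all regulator tuples at load time —
supported MathML: `and/or/not/xor`, comparisons, `ci`, `cn`, `true/false`,
`piecewise` — so any dialect collapses to truth tables. Inputs are accepted
either as `constant="true"` species or as species never targeted by a
transition. Clamped components are written with their transition plus a
small annotation element recording the clamp, so perturbed models
round-trip without losing rules. The native format is a JSON document
listing components, rule tables, signed edges, clamps and input fixations;
it exists so fixtures and scenario inputs can live as readable text.

## Numerical and design choices

- Tolerances: absorption solves are checked to 1e-10; Monte-Carlo vs exact
  at 3 binomial standard errors.
- Tie-breaks: attractors are reported ordered by the smallest mixed-radix
  code of their member states; perturbations in declaration order, KO
  before E_v.
- Degenerate inputs: empty perturbations are identities; walks started in
  an attractor return it in 0 steps; `N = 1` yields a point estimate.
- Problem sizes in the test suite (random-model batches of 5–100 with
  configuration spaces ≤ 2^10–2^14, MC at N = 1e4 on a fixed subset) keep
  the whole suite under a minute while exercising every code path against
  the oracles.

## Known limitations

- No symbolic (decision-diagram) attractor detection or trap-space
  computation: state spaces must fit the explicit budgets. The deposited
  50-component EMT network's *stable states* are still computable via
  branch-and-prune, but full STG construction of such models is not.
- No transition-rate customisation or continuous-time semantics; uniform
  walk probabilities only.
- Complex attractors are phenotyped as `oscillatory` rather than by any
  averaging of read-outs; the published analyses rest on stable states.
- The GINsim native GINML dialect is not parsed; use SBML-qual exports.
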