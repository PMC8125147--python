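"""Reachability probabilities: Monte-Carlo walks versus the exact solve.

From state 0001 of the toy model (S=1) both stable states are reachable.
10^5 uniform asynchronous random walks estimate the absorption
probabilities; the exact Markov-chain solve gives 1/4 and 3/4.
"""

import logicoop as lc

model = lc.set_inputs(lc.toy_model(), {"S": 1})
init = model.parse_state("0001")

exact = lc.exact_absorption(model, init)
print("exact absorption probabilities:")
for attractor, p in exact.items():
    print(f"  {model.format_state(attractor.state)}: {p:.4f}")

est = lc.estimate_reachability(model, init, n_runs=100_000, seed=1)
print("Monte-Carlo estimates (N=1e5, seed=1):")
for attractor, r in sorted(est.counts.items(), key=lambda kv: -kv[1]):
    print(f"  {model.format_state(attractor.state)}: R={r}  R/N={r / est.n_runs:.4f}")
# R/N converges on the exact absorption probability; at N=1e5 the binomial
# standard error on a probability of 1/4 is ~0.0014.

osc = lc.negative_feedback_model()
attractor = lc.attractors(osc)[0]
print(f"negative-feedback loop: one {attractor.kind} attractor of "
      f"{len(attractor.states)} states (sustained oscillation, "
      "detected rather than walked forever)")
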