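"""Asynchronous dynamics of the four-component toy model.

Builds the toy network (input S; A = S AND NOT C; B = NOT A;
C = B AND NOT A), enumerates its stable states for both input levels, and
shows how a knock-out removes an attractor.  States print as ABCS digit
strings.
"""

import logicoop as lc

model = lc.toy_model()
print("components:", ", ".join(
    f"{c.name}{' (input)' if c.is_input else ''}" for c in model.components))

for s in (0, 1):
    fixed = lc.set_inputs(model, {"S": s})
    states = sorted(model.format_state(x) for x in lc.stable_states(fixed))
    print(f"S={s}: stable states {states}")

# With S=1 the model is bistable.  Blocking A at 0 (a loss-of-function
# mutation) removes the attractor in which A is active.
s1 = lc.set_inputs(model, {"S": 1})
ko = lc.apply_perturbation(s1, lc.Perturbation.parse("A KO"))
print("A KO, S=1: stable states",
      sorted(model.format_state(x) for x in lc.stable_states(ko)))

stg = lc.build_stg(s1, from_state=s1.parse_state("0001"))
print(f"states reachable from 0001: {len(stg.states)} "
      f"({len(stg.transitions)} transitions)")
# Both stable states sit in the reachable graph: the initial condition can
# commit to either fate depending on the order of asynchronous updates.
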