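"""Single/double mutant screen with cooperativity calls on the mini-EMT
model.

Every non-input, non-read-out component is perturbed (KO and E_v clamps);
doubles combine each partner with the NOTCH E1 anchor.  Phenotype
compatibility = stable states over all input combinations.  A pair
cooperates when the double gains a phenotype absent from both singles or
loses one present in both.
"""

import logicoop as lc

model, table = lc.mini_emt_model()
anchor = lc.Perturbation.parse("NOTCH E1")

singles = lc.enumerate_perturbations(model, exclude=("AJ", "FA"))
print(f"{len(singles)} single perturbations; "
      f"{len(singles) - 2} NOTCH-anchored doubles")

screen, calls = lc.anchored_double_screen(model, anchor,
                                          exclude=("AJ", "FA"), table=table)
for label in ("unperturbed", "NOTCH E1", "RAF E1", "NOTCH E1 + RAF E1"):
    print(f"  {label:>22}: {sorted(screen.ticks(label))}")

print("cooperativity calls:")
for call in calls:
    print(f"  {call.pair[0]} x {call.pair[1]}: {call.direction} {call.phenotype}")
# The NOTCH GoF cooperates with RAF GoF to lose the epithelial phenotype
# (present in both singles) and with PI3K loss to gain the H3 hybrid --
# the two engineered interaction patterns of the fixture.
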