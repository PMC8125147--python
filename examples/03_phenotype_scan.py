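"""Micro-environment input scan on the mini-EMT model.

Starting from the epithelial stable state of the reference condition (all
inputs absent except the protective RPTP ligand), each scenario switches
input signals and reports the probability of reaching each EMT phenotype
(E = epithelial, H = hybrid, M = mesenchymal, by the AJ/FA read-outs).
"""

import logicoop as lc
from logicoop.screens import Scenario

model, table = lc.mini_emt_model()
reference = lc.MINI_EMT_REFERENCE_INPUTS  # {"RPTP_L": 1}

scenarios = [
    Scenario(inputs={"RPTP_L": 1}),                 # reference: stays E1
    Scenario(inputs={"RPTP_L": 1, "ECM": 1}),       # stiff matrix, ligand on
    Scenario(inputs={"RPTP_L": 0, "ECM": 1}),       # stiff matrix, ligand lost
    Scenario(inputs={"RPTP_L": 1, "HGF": 1}),       # growth factor alone
]

scan = lc.input_scan(model, scenarios, reference_inputs=reference,
                     initial_phenotype="E1", table=table,
                     n_runs=20_000, seed=1)
with_rows = scan.data.loc[(scan.data > 0).any(axis=1)]
print(with_rows.round(3).to_string())
# A stiff ECM with the RPTP ligand present opens a race between the RPTP
# guard and SNAIL: half the runs keep junctions (H1), half go mesenchymal
# (M3) -- the exact absorption split is 1/2 each.  Losing the ligand under
# a stiff matrix makes the mesenchymal outcome certain.
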