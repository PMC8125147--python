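"""Scenario configuration files (YAML or JSON).

A scenario bundles everything one simulation condition needs:

.. code-block:: yaml

    model: mini_emt.json          # native JSON or SBML-qual (.sbml/.xml)
    inputs: {RPTP_L: 1, ECM: 1}   # unlisted inputs default to 0
    perturbations: ["NOTCH E1"]   # KO / E<v> labels
    initial: E1                   # phenotype label or explicit digit state
    reference_inputs: {RPTP_L: 1} # condition whose stable state seeds the scan
    runs: 100000
    seed: 1
    max_steps: 10000
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..model import LogicalModel, ModelError, Perturbation
from ..reachability import DEFAULT_MAX_STEPS, DEFAULT_N_RUNS


@dataclass
class ScenarioConfig:
    model_path: str
    inputs: dict = field(default_factory=dict)
    perturbations: list = field(default_factory=list)
    initial: str = "E1"
    reference_inputs: dict = field(default_factory=dict)
    runs: int = DEFAULT_N_RUNS
    seed: int = 0
    max_steps: int = DEFAULT_MAX_STEPS

    def __post_init__(self):
        if self.runs < 1:
            raise ModelError("runs must be >= 1")

    def load_model(self) -> LogicalModel:
        from .native import read_native
        from .sbmlqual import read_sbml_qual
        path = Path(self.model_path)
        if path.suffix in (".sbml", ".xml"):
            return read_sbml_qual(path)
        return read_native(path)

    def validate_against(self, model: LogicalModel) -> None:
        input_names = {c.name for c in model.inputs}
        for name in self.inputs:
            if name not in input_names:
                raise ModelError(f"scenario fixes unknown input {name!r}")
        for p in self.perturbations:
            for name, _ in p.entries:
                model.component(name)


def read_scenario(path) -> ScenarioConfig:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "model" not in doc:
        raise ModelError(f"{path}: scenario file must be a mapping with a 'model' key")
    perturbations = [Perturbation.parse(p) if isinstance(p, str) else p
                     for p in doc.get("perturbations", []) or []]
    model_path = doc["model"]
    if not Path(model_path).is_absolute():
        model_path = str(path.parent / model_path)
    return ScenarioConfig(
        model_path=model_path,
        inputs=dict(doc.get("inputs") or {}),
        perturbations=perturbations,
        initial=str(doc.get("initial", "E1")),
        reference_inputs=dict(doc.get("reference_inputs") or {}),
        runs=int(doc.get("runs", DEFAULT_N_RUNS)),
        seed=int(doc.get("seed", 0)),
        max_steps=int(doc.get("max_steps", DEFAULT_MAX_STEPS)),
    )
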