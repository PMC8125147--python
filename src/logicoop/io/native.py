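"""Native plain-text model format (a JSON dialect).

Human-readable and diff-friendly so fixtures can live in a test tree:

.. code-block:: json

    {
      "format": "logicoop-model",
      "version": 1,
      "components": [{"name": "A", "max_level": 1, "is_input": false}, ...],
      "rules": [{"target": "A", "regulators": ["S", "C"],
                 "table": [[[1, 0], 1], [[0, 0], 0], ...]}, ...],
      "edges": [["S", "A", "activation"], ...],
      "clamps": {"A": 0},
      "inputs": {"S": 1}
    }

Rule tables are explicit (one ``[key, value]`` pair per regulator-level
combination); ``inputs`` is present only when the model has its inputs
fixed.
"""

from __future__ import annotations

import json
from pathlib import Path

from ..model import (Component, LogicalModel, ModelError, RegulatoryEdge,
                     UpdateRule, make_model)

FORMAT_NAME = "logicoop-model"
FORMAT_VERSION = 1


def model_to_dict(model: LogicalModel) -> dict:
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "components": [
            {"name": c.name, "max_level": c.max_level, "is_input": c.is_input}
            for c in model.components
        ],
        "rules": [
            {"target": rule.target,
             "regulators": list(rule.regulators),
             "table": [[list(key), value] for key, value in sorted(rule.table.items())]}
            for rule in model.rules.values()
        ],
        "edges": [[e.source, e.target, e.sign] for e in model.edges],
        "clamps": dict(model.clamps),
    }
    if model.input_levels is not None:
        doc["inputs"] = dict(model.input_levels)
    return doc


def model_from_dict(doc: dict) -> LogicalModel:
    try:
        if doc.get("format") != FORMAT_NAME:
            raise ModelError(f"not a {FORMAT_NAME} document")
        components = [Component(c["name"], c.get("max_level", 1),
                                c.get("is_input", False))
                      for c in doc["components"]]
        rules = [UpdateRule(target=r["target"], regulators=tuple(r["regulators"]),
                            table={tuple(key): value for key, value in r["table"]})
                 for r in doc["rules"]]
        edges = [RegulatoryEdge(src, tgt, sign) for src, tgt, sign in doc.get("edges", [])] \
            or None
        return make_model(components, rules, edges,
                          clamps=doc.get("clamps") or {},
                          input_levels=doc.get("inputs"))
    except (KeyError, TypeError) as exc:
        raise ModelError(f"malformed model document: {exc}") from exc


def write_native(model: LogicalModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def read_native(path) -> LogicalModel:
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelError(f"{path}: parse error at line {exc.lineno}: {exc.msg}") from exc
    return model_from_dict(doc)
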