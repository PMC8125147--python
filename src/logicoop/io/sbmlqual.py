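"""SBML Level 3 qualitative-models ("qual") reading and writing.

Qualitative species map to components (``maxLevel`` honoured) and
transitions' MathML function terms are evaluated over every regulator-level
combination at load time, compiling each rule to an explicit truth table —
one internal semantics regardless of the source dialect.  The supported
MathML subset (``and/or/not/xor/eq/neq/lt/leq/gt/geq``, ``ci``, ``cn``,
``true/false``, ``piecewise``) covers documents written by this package and
the usual exports of logical-modelling tools.

Input components are accepted in either encoding found in the wild:
``constant="true"`` species, or species never targeted by a transition.
Perturbation clamps survive round-trips through a small annotation element
(the species keeps its transition so rule tables are preserved).
"""

from __future__ import annotations

import itertools
from pathlib import Path

from lxml import etree

from ..model import (ACTIVATION, INHIBITION, Component, LogicalModel,
                     ModelError, RegulatoryEdge, UpdateRule, make_model)

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATH_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://logicoop.dev/ns/clamp"

NSMAP = {None: SBML_NS, "qual": QUAL_NS}


def _q(tag: str) -> str:
    return f"{{{QUAL_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{MATH_NS}}}{tag}"


# ---------------------------------------------------------------------------
# writing


def _math_eq(parent, name: str, level: int) -> None:
    apply_ = etree.SubElement(parent, _m("apply"))
    etree.SubElement(apply_, _m("eq"))
    ci = etree.SubElement(apply_, _m("ci"))
    ci.text = f" {name} "
    cn = etree.SubElement(apply_, _m("cn"), attrib={"type": "integer"})
    cn.text = f" {level} "


def _term_math(parent, rule: UpdateRule, keys) -> None:
    """<math> selecting exactly the regulator tuples in ``keys``:
    an OR over per-tuple ANDs of equality tests."""
    math = etree.SubElement(parent, _m("math"))
    clauses = []
    for key in keys:
        if len(rule.regulators) == 1:
            holder = ("single", key)
        else:
            holder = ("and", key)
        clauses.append(holder)

    def emit_clause(node, key):
        if len(rule.regulators) == 1:
            _math_eq(node, rule.regulators[0], key[0])
        else:
            apply_ = etree.SubElement(node, _m("apply"))
            etree.SubElement(apply_, _m("and"))
            for name, level in zip(rule.regulators, key):
                _math_eq(apply_, name, level)

    if len(clauses) == 1:
        emit_clause(math, clauses[0][1])
    else:
        apply_ = etree.SubElement(math, _m("apply"))
        etree.SubElement(apply_, _m("or"))
        for _, key in clauses:
            emit_clause(apply_, key)


def write_sbml_qual(model: LogicalModel, path) -> None:
    """Serialise ``model`` as an SBML L3V1 document with the qual package."""
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=NSMAP)
    root.set("level", "3")
    root.set("version", "1")
    root.set(f"{{{QUAL_NS}}}required", "true")
    sbml_model = etree.SubElement(root, f"{{{SBML_NS}}}model", id="logical_model")
    los = etree.SubElement(sbml_model, _q("listOfQualitativeSpecies"))

    for comp in model.components:
        attrib = {
            _q("id"): comp.name,
            _q("maxLevel"): str(comp.max_level),
            _q("constant"): "true" if comp.is_input else "false",
        }
        if comp.is_input and model.input_levels is not None \
                and comp.name in model.input_levels:
            attrib[_q("initialLevel")] = str(model.input_levels[comp.name])
        species = etree.SubElement(los, _q("qualitativeSpecies"), attrib=attrib)
        if comp.name in model.clamps:
            annotation = etree.SubElement(species, f"{{{SBML_NS}}}annotation")
            etree.SubElement(annotation, f"{{{ANNOT_NS}}}clamp",
                             nsmap={"logicoop": ANNOT_NS},
                             attrib={"level": str(model.clamps[comp.name])})

    lot = etree.SubElement(sbml_model, _q("listOfTransitions"))
    for rule in model.rules.values():
        transition = etree.SubElement(lot, _q("transition"),
                                      attrib={_q("id"): f"tr_{rule.target}"})
        signs = {(e.source, e.target): e.sign for e in model.edges}
        if rule.regulators:
            loi = etree.SubElement(transition, _q("listOfInputs"))
            for reg in rule.regulators:
                attrib = {
                    _q("id"): f"tr_{rule.target}_in_{reg}",
                    _q("qualitativeSpecies"): reg,
                    _q("transitionEffect"): "none",
                }
                sign = signs.get((reg, rule.target))
                if sign is not None:
                    attrib[_q("sign")] = \
                        "positive" if sign == ACTIVATION else "negative"
                etree.SubElement(loi, _q("input"), attrib=attrib)
        loo = etree.SubElement(transition, _q("listOfOutputs"))
        etree.SubElement(loo, _q("output"), attrib={
            _q("id"): f"tr_{rule.target}_out",
            _q("qualitativeSpecies"): rule.target,
            _q("transitionEffect"): "assignmentLevel",
        })
        loft = etree.SubElement(transition, _q("listOfFunctionTerms"))
        by_level: dict = {}
        for key, value in rule.table.items():
            by_level.setdefault(value, []).append(key)
        # the most common level becomes the default term
        default_level = max(by_level, key=lambda lv: (len(by_level[lv]), -lv))
        for level, keys in sorted(by_level.items()):
            if level == default_level:
                continue
            term = etree.SubElement(loft, _q("functionTerm"),
                                    attrib={_q("resultLevel"): str(level)})
            _term_math(term, rule, sorted(keys))
        etree.SubElement(loft, _q("defaultTerm"),
                         attrib={_q("resultLevel"): str(default_level)})

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


# ---------------------------------------------------------------------------
# reading


def _eval_math(node, env: dict):
    """Evaluate a MathML node under regulator levels ``env``."""
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ModelError("math element must have exactly one child")
        return _eval_math(children[0], env)
    if tag == "ci":
        name = (node.text or "").strip()
        if name not in env:
            raise ModelError(f"rule references undeclared species {name!r}")
        return env[name]
    if tag == "cn":
        text = (node.text or "").strip()
        value = float(text)
        if value != int(value):
            raise ModelError(f"non-integer threshold {text!r}")
        return int(value)
    if tag == "true":
        return True
    if tag == "false":
        return False
    if tag == "piecewise":
        otherwise = None
        for child in node:
            ctag = etree.QName(child).localname
            parts = [c for c in child if isinstance(c.tag, str)]
            if ctag == "piece":
                value, cond = parts
                if _eval_math(cond, env):
                    return _eval_math(value, env)
            elif ctag == "otherwise":
                otherwise = parts[0]
        if otherwise is not None:
            return _eval_math(otherwise, env)
        raise ModelError("piecewise with no applicable piece")
    if tag != "apply":
        raise ModelError(f"unsupported MathML element <{tag}>")

    children = [c for c in node if isinstance(c.tag, str)]
    op = etree.QName(children[0]).localname
    args = children[1:]

    if op in ("and", "or", "xor", "not"):
        values = [bool(_eval_math(a, env)) for a in args]
        if op == "and":
            return all(values)
        if op == "or":
            return any(values)
        if op == "xor":
            return sum(values) % 2 == 1
        if len(values) != 1:
            raise ModelError("<not> takes one argument")
        return not values[0]

    values = [_eval_math(a, env) for a in args]
    if op == "eq":
        return values[0] == values[1]
    if op == "neq":
        return values[0] != values[1]
    if op == "lt":
        return values[0] < values[1]
    if op == "leq":
        return values[0] <= values[1]
    if op == "gt":
        return values[0] > values[1]
    if op == "geq":
        return values[0] >= values[1]
    raise ModelError(f"unsupported MathML operator <{op}>")


def read_sbml_qual(path) -> LogicalModel:
    """Parse an SBML L3 qual document into a :class:`LogicalModel`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ModelError(f"{path}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise ModelError(f"{path}: not an SBML document")
    if root.get("level") != "3":
        raise ModelError(f"{path}: unsupported SBML level {root.get('level')!r} "
                         "(level 3 with the qual package is required)")

    species = root.findall(f".//{_q('listOfQualitativeSpecies')}/{_q('qualitativeSpecies')}")
    if not species:
        raise ModelError(f"{path}: no qualitative species (qual package missing?)")

    transitions = root.findall(f".//{_q('listOfTransitions')}/{_q('transition')}")
    targeted = set()
    for transition in transitions:
        for output in transition.findall(f"{_q('listOfOutputs')}/{_q('output')}"):
            targeted.add(output.get(_q("qualitativeSpecies")))

    components = []
    clamps = {}
    input_levels = {}
    have_fixed_inputs = False
    for sp in species:
        name = sp.get(_q("id"))
        max_level = int(sp.get(_q("maxLevel"), "1"))
        constant = sp.get(_q("constant"), "false") == "true"
        clamp_el = sp.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}clamp")
        if clamp_el is not None:
            clamps[name] = int(clamp_el.get("level"))
            is_input = False
        else:
            is_input = constant or name not in targeted
        components.append(Component(name, max_level=max_level, is_input=is_input))
        if is_input and sp.get(_q("initialLevel")) is not None:
            input_levels[name] = int(sp.get(_q("initialLevel")))
            have_fixed_inputs = True

    by_name = {c.name: c for c in components}
    rules = []
    edges = []
    declared_signs = {}
    for transition in transitions:
        outputs = transition.findall(f"{_q('listOfOutputs')}/{_q('output')}")
        if len(outputs) != 1:
            raise ModelError("each transition must have exactly one output")
        target = outputs[0].get(_q("qualitativeSpecies"))
        if target not in by_name:
            raise ModelError(f"transition targets undeclared species {target!r}")
        regulators = []
        for inp in transition.findall(f"{_q('listOfInputs')}/{_q('input')}"):
            reg = inp.get(_q("qualitativeSpecies"))
            if reg not in by_name:
                raise ModelError(f"transition input references undeclared species {reg!r}")
            regulators.append(reg)
            sign = inp.get(_q("sign"))
            if sign in ("positive", "negative"):
                declared_signs[(reg, target)] = \
                    ACTIVATION if sign == "positive" else INHIBITION

        terms = transition.findall(f"{_q('listOfFunctionTerms')}/{_q('functionTerm')}")
        default = transition.find(f"{_q('listOfFunctionTerms')}/{_q('defaultTerm')}")
        if default is None:
            raise ModelError(f"transition for {target}: missing defaultTerm")
        default_level = int(default.get(_q("resultLevel")))

        table = {}
        for key in itertools.product(*[by_name[r].levels for r in regulators]):
            env = dict(zip(regulators, key))
            level = default_level
            for term in terms:
                math = term.find(_m("math"))
                if math is None:
                    raise ModelError(f"transition for {target}: functionTerm without math")
                if _eval_math(math, env):
                    level = int(term.get(_q("resultLevel")))
                    break
            table[key] = level
        rules.append(UpdateRule(target=target, regulators=tuple(regulators),
                                table=table))

    # honour declared signs where present, infer the rest from the tables
    from ..model import infer_edges
    inferred = infer_edges(components, {r.target: r for r in rules})
    for edge in inferred:
        sign = declared_signs.get((edge.source, edge.target), edge.sign)
        edges.append(RegulatoryEdge(edge.source, edge.target, sign))

    return make_model(components, rules, edges, clamps=clamps,
                      input_levels=input_levels if have_fixed_inputs else None)
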