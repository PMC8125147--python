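"""Core model construction, rule evaluation, clamps and input fixation."""

import pytest

import logicoop as lc
from logicoop.model import ModelError, SignConsistencyWarning


def test_toy_rule_evaluation(toy):
    """Published rule for A: active iff its activator S is present and its
    inhibitor C absent."""
    m = lc.set_inputs(toy, {"S": 1})
    assert lc.evaluate_target(m, "A", m.parse_state("0001")) == 1
    assert lc.evaluate_target(m, "A", m.parse_state("0111")) == 0
    assert lc.evaluate_target(m, "A", m.parse_state("0011")) == 0  # C alone blocks
    m0 = lc.set_inputs(toy, {"S": 0})
    assert lc.evaluate_target(m0, "A", m0.parse_state("0000")) == 0


def test_evaluate_target_pure_function_of_regulators(toy):
    """B depends only on A: states differing elsewhere give the same target."""
    m = lc.set_inputs(toy, {"S": 1})
    for c in (0, 1):
        assert lc.evaluate_target(m, "B", (0, 0, c, 1)) == \
            lc.evaluate_target(m, "B", (0, 1, c, 1))


def test_clamped_component_returns_clamp(toy):
    m = lc.apply_perturbation(toy, lc.Perturbation.parse("A KO"))
    for state in [(0, 0, 0, 1), (0, 1, 1, 0)]:
        assert lc.evaluate_target(m, "A", state) == 0


def test_apply_perturbation_leaves_original_unchanged(toy):
    perturbed = lc.apply_perturbation(toy, lc.Perturbation.parse("A E1"))
    assert perturbed.clamps == {"A": 1}
    assert toy.clamps == {}
    # empty perturbation is the identity
    same = lc.apply_perturbation(toy, lc.Perturbation(entries=()))
    assert same.clamps == toy.clamps


@pytest.mark.parametrize("bad, err", [
    ("S E1", "input"),              # inputs are fixed via set_inputs
    ("A E2", "outside"),            # beyond max level
])
def test_perturbation_errors(toy, bad, err):
    with pytest.raises(ModelError, match=err):
        lc.apply_perturbation(toy, lc.Perturbation.parse(bad))


def test_perturbation_labels_and_parse():
    p = lc.Perturbation.parse("NOTCH E1 + PI3K KO")
    assert p.entries == (("NOTCH", 1), ("PI3K", 0))
    assert p.label == "NOTCH E1 + PI3K KO"
    with pytest.raises(ModelError):
        lc.Perturbation.parse("NOTCH maybe")
    with pytest.raises(ModelError):
        lc.Perturbation(entries=(("A", 0), ("A", 1)))


def test_set_inputs_defaults_unlisted_to_zero(mini_emt):
    model, _ = mini_emt
    fixed = lc.set_inputs(model, {"RPTP_L": 1})
    assert fixed.input_levels == {"RPTP_L": 1, "ECM": 0, "HGF": 0}
    empty = lc.set_inputs(model, {})
    assert set(empty.input_levels.values()) == {0}
    with pytest.raises(ModelError, match="not an input"):
        lc.set_inputs(model, {"SNAIL": 1})


def test_make_model_rejects_partial_table():
    comps = [lc.Component("A"), lc.Component("B")]
    rules = [
        lc.UpdateRule("A", ("B",), {(0,): 1}),  # missing (1,)
        lc.boolean_rule("B", ["A"], lambda a: a),
    ]
    with pytest.raises(ModelError, match="not total"):
        lc.make_model(comps, rules)


def test_make_model_rejects_value_above_max_level():
    comps = [lc.Component("A"), lc.Component("B")]
    rules = [
        lc.UpdateRule("A", ("B",), {(0,): 0, (1,): 2}),
        lc.boolean_rule("B", ["A"], lambda a: a),
    ]
    with pytest.raises(ModelError, match="exceeds max level"):
        lc.make_model(comps, rules)


def test_make_model_rejects_duplicates_and_undeclared():
    with pytest.raises(ModelError, match="duplicate"):
        lc.make_model([lc.Component("A"), lc.Component("A")],
                      [lc.boolean_rule("A", [], lambda: 0)])
    with pytest.raises(ModelError, match="undeclared regulator"):
        lc.make_model([lc.Component("A")],
                      [lc.boolean_rule("A", ["Z"], lambda z: z)])


def test_sign_consistency_warning_on_contradictory_edge():
    comps = [lc.Component("A"), lc.Component("B")]
    rules = [
        lc.boolean_rule("A", ["B"], lambda b: not b),  # B inhibits A
        lc.boolean_rule("B", ["A"], lambda a: a),
    ]
    edges = [lc.RegulatoryEdge("B", "A", lc.ACTIVATION),   # wrong sign
             lc.RegulatoryEdge("A", "B", lc.ACTIVATION)]
    with pytest.warns(SignConsistencyWarning):
        lc.make_model(comps, rules, edges)


def test_toy_sign_consistency_accepted(recwarn, toy):
    """A increases in S, decreases in C: declared signs raise no warning."""
    lc.make_model(toy.components, toy.rules.values(), toy.edges)
    assert not [w for w in recwarn if issubclass(w.category, SignConsistencyWarning)]


def test_state_helpers_roundtrip(mini_emt):
    model, _ = mini_emt
    state = tuple(0 for _ in model.components)
    assert model.int_to_state(model.state_to_int(state)) == state
    top = tuple(c.max_level for c in model.components)
    assert model.state_to_int(top) == model.n_configurations() - 1
    assert model.parse_state(model.format_state(top)) == top
    assert model.state(model.state_dict(top)) == top
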