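"""Built-in models and the random-model generator."""

import numpy as np
import pytest

import logicoop as lc
from oracles import absorption_bf, stable_states_bf


def test_toy_reproduces_every_printed_fact(toy):
    s0 = lc.set_inputs(toy, {"S": 0})
    s1 = lc.set_inputs(toy, {"S": 1})
    fmt = toy.format_state
    assert {fmt(s) for s in lc.stable_states(s0)} == {"0110"}
    assert {fmt(s) for s in lc.stable_states(s1)} == {"0111", "1001"}
    stg = lc.build_stg(s1, from_state=s1.parse_state("0001"))
    assert {s1.parse_state("0111"), s1.parse_state("1001")} <= stg.states
    ko = lc.apply_perturbation(s1, lc.Perturbation.parse("A KO"))
    assert {fmt(s) for s in lc.stable_states(ko)} == {"0111"}


def _candidate(b_rule, c_regs, c_fn):
    """A toy-model variant sharing the published A rule but with an
    alternative wiring for B and C."""
    comps = [lc.Component("A"), lc.Component("B"), lc.Component("C"),
             lc.Component("S", is_input=True)]
    rules = [
        lc.boolean_rule("A", ["S", "C"], lambda s, c: s and not c),
        lc.boolean_rule("B", ["A"], b_rule),
        lc.boolean_rule("C", c_regs, c_fn),
    ]
    return lc.set_inputs(lc.make_model(comps, rules), {"S": 1})


def test_toy_reconstruction_selected_by_absorption_oracle():
    """Only rules whose unpublished parts are B = NOT A, C = B AND NOT A
    reproduce both the printed stable states and the printed Monte-Carlo
    estimates (0.2514 / 0.7486, i.e. 1/4 and 3/4); plausible alternatives
    are quantitatively rejected."""

    def absorption(model):
        init = model.parse_state("0001")
        return {model.format_state(next(iter(scc))): p
                for scc, p in absorption_bf(model, init).items()}

    chosen = _candidate(lambda a: not a, ["B", "A"], lambda b, a: b and not a)
    probs = absorption(chosen)
    assert probs["0111"] == pytest.approx(0.25, abs=1e-12)
    assert probs["1001"] == pytest.approx(0.75, abs=1e-12)
    se3 = 3 * np.sqrt(0.25 * 0.75 / 1e5)
    assert abs(probs["0111"] - 0.2514) <= se3

    # C = NOT A: same stable states, wrong split
    alt1 = _candidate(lambda a: not a, ["A"], lambda a: not a)
    assert {alt1.format_state(s) for s in stable_states_bf(alt1)} == \
        {"0111", "1001"}
    assert abs(absorption(alt1)["0111"] - 0.2514) > se3

    # C = B: same stable states, split 1/3 vs 2/3
    alt2 = _candidate(lambda a: not a, ["B"], lambda b: b)
    assert {alt2.format_state(s) for s in stable_states_bf(alt2)} == \
        {"0111", "1001"}
    assert absorption(alt2)["0111"] == pytest.approx(1 / 3, abs=1e-12)


def test_random_model_determinism_and_validity():
    spec = lc.GeneratorSpec(n_components=4, seed=7)
    a, b = lc.random_model(spec), lc.random_model(spec)
    assert a.components == b.components and a.rules == b.rules and a.edges == b.edges
    # construction passes full validation incl. sign consistency (no warning)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("error", lc.SignConsistencyWarning)
        lc.make_model(a.components, a.rules.values(), a.edges)


def test_random_model_covers_multivalued_components():
    hits = 0
    for seed in range(100):
        spec = lc.GeneratorSpec(n_components=5, frac_multivalued=0.5, seed=seed)
        model = lc.random_model(spec)
        if any(c.max_level > 1 for c in model.internals):
            hits += 1
    assert hits > 60  # ~1 - 0.5^4 of models should contain one


def test_random_model_respects_spec_bounds():
    spec = lc.GeneratorSpec(n_components=6, max_in_degree=3, n_inputs=2,
                            readout_max_levels=(2, 3), seed=1)
    model = lc.random_model(spec)
    assert len(model.inputs) == 2
    assert [c.max_level for c in model.components[-2:]] == [2, 3]
    assert all(len(r.regulators) <= 3 for r in model.rules.values())


def test_generator_spec_validation():
    with pytest.raises(lc.ModelError):
        lc.GeneratorSpec(n_components=3, max_in_degree=5)
    with pytest.raises(lc.ModelError):
        lc.GeneratorSpec(n_components=2, n_inputs=1, readout_max_levels=(2, 3))


def test_mini_emt_structure(mini_emt):
    model, table = mini_emt
    assert len(model.inputs) >= 2
    assert "RPTP_L" in {c.name for c in model.inputs}
    assert model.component("AJ").max_level == 2
    assert model.component("FA").max_level == 3
    assert table.readouts == ("AJ", "FA")


def test_mini_emt_stable_state_oracle_agreement(mini_emt):
    """Exhaustive oracle enumeration of the fixture's stable states matches
    the pruned search, with inputs free and fixed."""
    model, _ = mini_emt
    assert set(lc.stable_states(model)) == stable_states_bf(model)
    ref = lc.set_inputs(model, lc.MINI_EMT_REFERENCE_INPUTS)
    assert set(lc.stable_states(ref)) == stable_states_bf(ref)
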