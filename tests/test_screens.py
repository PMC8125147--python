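"""Perturbation screens, input scans and cooperativity calling."""

import numpy as np
import pytest

import logicoop as lc
from logicoop.model import ModelError
from logicoop.screens import GAINED, LOST, Scenario
from oracles import cooperativity_bf

from conftest import small_random_models

PHENOTYPES = list("ABCDEFGH")


def tick_table(ticks, condition):
    import pandas as pd
    from logicoop.screens import ScreenTable
    return ScreenTable(
        data=pd.DataFrame({condition: [p in ticks for p in PHENOTYPES]},
                          index=PHENOTYPES))


def test_enumerate_perturbations_order_and_counts(mini_emt):
    model, _ = mini_emt
    perts = lc.enumerate_perturbations(model)
    # Boolean non-input -> {KO, E1}; AJ (max 2) -> 3; FA (max 3) -> 4
    assert [p.label for p in perts[:4]] == ["NOTCH KO", "NOTCH E1",
                                            "PI3K KO", "PI3K E1"]
    expected = sum(c.max_level + 1 for c in model.internals)
    assert len(perts) == expected
    assert len(lc.enumerate_perturbations(model, exclude=("AJ", "FA"))) == \
        expected - 3 - 4


def test_enumeration_count_on_random_models():
    """Count = sum over non-inputs of (max_level + 1): one KO plus one E_v
    per attainable level."""
    for model in small_random_models(10, start_seed=500):
        perts = lc.enumerate_perturbations(model)
        assert len(perts) == sum(c.max_level + 1 for c in model.internals)
        assert len({p.label for p in perts}) == len(perts)


def test_detect_cooperativity_definition_cases():
    x = tick_table({"A", "C"}, "X")
    y = tick_table({"A", "C"}, "Y")
    xy_lost = tick_table({"A"}, "X + Y")
    calls = lc.detect_cooperativity(x, y, xy_lost)
    assert [(c.phenotype, c.direction) for c in calls] == [("C", LOST)]

    xy_gain = tick_table({"A", "C", "F"}, "X + Y")
    calls = lc.detect_cooperativity(x, y, xy_gain)
    assert [(c.phenotype, c.direction) for c in calls] == [("F", GAINED)]

    assert lc.detect_cooperativity(x, y, tick_table({"A", "C"}, "X + Y")) == []


def test_detect_cooperativity_matches_set_algebra_on_random_tables():
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        x, y, xy = (set(np.array(PHENOTYPES)[rng.random(8) < 0.5])
                    for _ in range(3))
        calls = lc.detect_cooperativity(tick_table(x, "X"), tick_table(y, "Y"),
                                        tick_table(xy, "X + Y"))
        got = {(c.phenotype, c.direction) for c in calls}
        assert got == cooperativity_bf(x, y, xy, PHENOTYPES)


def test_detect_cooperativity_row_mismatch():
    import pandas as pd
    from logicoop.screens import ScreenTable
    other = ScreenTable(data=pd.DataFrame({"Z": [True]}, index=["A"]))
    with pytest.raises(ModelError, match="rows"):
        lc.detect_cooperativity(tick_table(set(), "X"), tick_table(set(), "Y"), other)


def test_mutant_screen_unperturbed_ticks_designed_phenotypes(mini_emt):
    """With inputs free, the unperturbed column is compatible with every
    phenotype the fixture was designed to realise."""
    model, table = mini_emt
    screen = lc.mutant_screen(model, [[]], table=table)
    assert screen.ticks("unperturbed") == {"E1", "U1", "H1", "M3"}


def test_mutant_screen_fixed_inputs_reference_condition(mini_emt):
    model, table = mini_emt
    screen = lc.mutant_screen(model, [[]], input_assignment=lc.MINI_EMT_REFERENCE_INPUTS,
                              table=table)
    assert screen.ticks("unperturbed") == {"E1"}


def test_mutant_screen_rejects_overlapping_sets(mini_emt):
    model, _ = mini_emt
    p = lc.Perturbation.parse("SNAIL KO")
    q = lc.Perturbation.parse("SNAIL E1")
    with pytest.raises(ModelError, match="twice"):
        lc.mutant_screen(model, [[p, q]])


def test_anchored_screen_recovers_exactly_the_engineered_pairs(mini_emt):
    """The full NOTCH-E1-anchored double screen yields the engineered
    gained/lost calls and nothing else."""
    model, table = mini_emt
    screen, calls = lc.anchored_double_screen(
        model, lc.Perturbation.parse("NOTCH E1"),
        exclude=("AJ", "FA"), table=table)
    got = {}
    for call in calls:
        got.setdefault((call.pair[0], call.pair[1]), set()).add(
            (call.phenotype, call.direction))
    assert got == lc.MINI_EMT_ENGINEERED_CALLS


def test_anchor_gof_plus_partner_gof_unticks_epithelial_row(mini_emt):
    """E1 is compatible with NOTCH E1 and with RAF E1 singly, but lost in
    the double mutant."""
    model, table = mini_emt
    anchor = lc.Perturbation.parse("NOTCH E1")
    partner = lc.Perturbation.parse("RAF E1")
    screen = lc.mutant_screen(model, [[anchor], [partner], [anchor, partner]],
                              table=table)
    assert "E1" in screen.ticks("NOTCH E1")
    assert "E1" in screen.ticks("RAF E1")
    assert "E1" not in screen.ticks("NOTCH E1 + RAF E1")


def test_double_column_arithmetic(mini_emt):
    """Partners exclude the anchor's component: for a Boolean anchor the
    doubles number two fewer than the singles."""
    model, table = mini_emt
    singles = lc.enumerate_perturbations(model, exclude=("AJ", "FA"))
    screen, _ = lc.anchored_double_screen(
        model, lc.Perturbation.parse("NOTCH E1"), exclude=("AJ", "FA"),
        table=table)
    n_doubles = sum(1 for c in screen.conditions if " + " in c)
    assert n_doubles == len(singles) - 2
    # columns: unperturbed + anchor + partners + doubles
    assert len(screen.conditions) == 2 + (len(singles) - 2) + n_doubles


def test_input_scan_reference_is_stable_epithelial(mini_emt):
    model, table = mini_emt
    scan = lc.input_scan(model, [Scenario(inputs=lc.MINI_EMT_REFERENCE_INPUTS)],
                         reference_inputs=lc.MINI_EMT_REFERENCE_INPUTS,
                         n_runs=10, seed=0, table=table)
    col = scan.data[scan.conditions[0]]
    assert col["E1"] == 1.0
    assert col.sum() == pytest.approx(1.0)


def test_input_scan_ecm_switch_splits_half_half(mini_emt):
    """Switching the matrix stiffness input on from E1 races the RPTP guard
    against SNAIL: H1 and M3 are reached with probability 1/2 each."""
    model, table = mini_emt
    scenario = Scenario(inputs={"RPTP_L": 1, "ECM": 1})
    scan = lc.input_scan(model, [scenario],
                         reference_inputs=lc.MINI_EMT_REFERENCE_INPUTS,
                         n_runs=4000, seed=11, table=table)
    col = scan.data[scenario.label]
    # exact absorption check
    init, scoped = lc.resolve_initial_state(model, lc.MINI_EMT_REFERENCE_INPUTS,
                                            "E1", table, scenario.inputs)
    exact = lc.phenotype_distribution(
        lc.exact_absorption(scoped, init, readouts=table.readouts), table)
    assert exact == {"H1": pytest.approx(0.5, abs=1e-12),
                     "M3": pytest.approx(0.5, abs=1e-12)}
    se3 = 3 * (0.25 / 4000) ** 0.5
    assert col["H1"] == pytest.approx(0.5, abs=se3)
    assert col["M3"] == pytest.approx(0.5, abs=se3)
    assert col.sum() == pytest.approx(1.0)


def test_input_scan_with_perturbation(mini_emt):
    """A NOTCH GoF in the reference micro-environment keeps the model
    epithelial, as in the published scans."""
    model, table = mini_emt
    scenario = Scenario(inputs=lc.MINI_EMT_REFERENCE_INPUTS,
                        perturbations=(lc.Perturbation.parse("NOTCH E1"),))
    scan = lc.input_scan(model, [scenario],
                         reference_inputs=lc.MINI_EMT_REFERENCE_INPUTS,
                         n_runs=50, seed=3, table=table)
    assert scan.data[scenario.label]["E1"] == 1.0


def test_initial_state_not_resolvable_raises(mini_emt):
    model, table = mini_emt
    with pytest.raises(ModelError, match="not uniquely resolvable"):
        lc.resolve_initial_state(model, lc.MINI_EMT_REFERENCE_INPUTS, "M3",
                                 table, {"ECM": 1})


def test_screen_table_tsv_roundtrip(mini_emt, tmp_path):
    model, table = mini_emt
    screen = lc.mutant_screen(model, [[], [lc.Perturbation.parse("NOTCH E1")]],
                              table=table)
    path = tmp_path / "screen.tsv"
    screen.to_tsv(path)
    text = path.read_text()
    assert "unperturbed" in text and "NOTCH E1" in text and "x" in text
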