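"""Systematic perturbation screens and cooperativity calling.

Two kinds of screen mirror the two published analyses:

* **Mutant screens** (phenotype-compatibility tables): for each perturbation
  set, the stable states of the perturbed model are enumerated — with the
  micro-environment inputs left *free*, i.e. over every input combination —
  and each phenotype label is marked present if some stable state realises
  it.  Free inputs reproduce the published convention in which the
  unperturbed column of the compatibility table ticks all eight phenotypes.

* **Input scans** (reachability scans): starting from the epithelial stable
  state of a reference condition, input levels are switched to a scenario's
  values and the phenotype distribution of the reachable attractors is
  estimated by seeded random walks (exactly, when the initial state is
  already stable in the scenario).

Two conditions X and Y *cooperate* on a phenotype when the double condition
gains a phenotype absent from both singles, or loses one present in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dynamics import Attractor, stable_states, _summarise_readouts
from .model import (LogicalModel, ModelError, Perturbation, apply_perturbation,
                    set_inputs)
from .phenotypes import PhenotypeTable, classify_attractor, phenotype_distribution
from .reachability import DEFAULT_N_RUNS, estimate_reachability

GAINED = "gained"
LOST = "lost"


@dataclass
class ScreenTable:
    """Phenotype x condition table.

    ``data`` is a DataFrame indexed by phenotype label with one column per
    condition; cells are booleans (compatibility screens) or probabilities
    (reachability scans).  ``evidence`` records, per condition, the
    attractor/stable-state list or reachability estimate backing the column.
    """

    data: pd.DataFrame
    evidence: dict = field(default_factory=dict)

    @property
    def phenotypes(self) -> list:
        return list(self.data.index)

    @property
    def conditions(self) -> list:
        return list(self.data.columns)

    def ticks(self, condition: str) -> set:
        """Set of phenotype labels present under one condition."""
        col = self.data[condition]
        return {label for label, v in col.items() if bool(v)}

    def column(self, condition: str) -> "ScreenTable":
        return ScreenTable(data=self.data[[condition]],
                           evidence={condition: self.evidence.get(condition)})

    def to_tsv(self, path=None):
        out = self.data.copy()
        if out.dtypes.apply(lambda d: d == bool).all():
            out = out.replace({True: "x", False: ""})
        return out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class CooperativityCall:
    """A gained or lost phenotype for a condition pair."""

    pair: tuple        # (condition X label, condition Y label)
    phenotype: str
    direction: str     # GAINED | LOST


def enumerate_perturbations(model: LogicalModel,
                            exclude: Iterable[str] = ()) -> list:
    """All single perturbations: per non-input component with max level m,
    KO plus E_v for v = 1..m, in declaration order (KO first).

    ``exclude`` names components to skip (e.g. read-outs, whose clamps would
    manufacture phenotypes rather than probe the network logic).
    """
    exclude = set(exclude)
    out = []
    for comp in model.components:
        if comp.is_input or comp.name in exclude:
            continue
        for level in range(comp.max_level + 1):
            out.append(Perturbation.single(comp.name, level))
    return out


def _compatible_phenotypes(model: LogicalModel, table: PhenotypeTable):
    """Stable states of ``model`` and the set of phenotype labels they
    realise."""
    states = stable_states(model)
    attrs = [Attractor(kind="stable", states=frozenset([s]),
                       readout_levels=_summarise_readouts(model, [s], table.readouts))
             for s in sorted(states)]
    labels = {classify_attractor(a, table).label for a in attrs}
    return attrs, labels & set(table.labels)


def mutant_screen(model: LogicalModel,
                  perturbation_sets: Sequence[Sequence[Perturbation]],
                  input_assignment: Mapping[str, int] | None = None,
                  table: PhenotypeTable | None = None) -> ScreenTable:
    """Phenotype-compatibility table over perturbation sets (0, 1 or 2
    perturbations each).

    With ``input_assignment=None`` (default) inputs are free and stable
    states are enumerated over every input combination; otherwise the
    stated condition is fixed.
    """
    from .phenotypes import default_phenotype_table
    table = table or default_phenotype_table()
    base = set_inputs(model, input_assignment) if input_assignment is not None else model

    columns = {}
    evidence = {}
    for pset in perturbation_sets:
        pset = list(pset)
        if len(pset) > 2:
            raise ModelError("perturbation sets of size > 2 are not screened")
        seen: set = set()
        for p in pset:
            overlap = seen & p.components
            if overlap:
                raise ModelError(f"perturbation set clamps {sorted(overlap)} twice")
            seen |= p.components
        perturbed = base
        for p in pset:
            perturbed = apply_perturbation(perturbed, p)
        label = " + ".join(p.label for p in pset) or "unperturbed"
        attrs, present = _compatible_phenotypes(perturbed, table)
        columns[label] = [lab in present for lab in table.labels]
        evidence[label] = attrs

    data = pd.DataFrame(columns, index=list(table.labels))
    return ScreenTable(data=data, evidence=evidence)


def detect_cooperativity(table_x: ScreenTable, table_y: ScreenTable,
                         table_xy: ScreenTable) -> list:
    """Gained/lost phenotype calls from three single-condition tables.

    gained: absent in X alone and Y alone, present in X+Y;
    lost:   present in both singles, absent in the double.
    """
    tables = (table_x, table_y, table_xy)
    for t in tables:
        if len(t.conditions) != 1:
            raise ModelError("each table must carry exactly one condition")
    rows = tables[0].phenotypes
    if any(t.phenotypes != rows for t in tables[1:]):
        raise ModelError("tables do not share phenotype rows")
    x, y, xy = (t.ticks(t.conditions[0]) for t in tables)
    pair = (table_x.conditions[0], table_y.conditions[0])
    calls = []
    for phenotype in rows:
        if phenotype in xy and phenotype not in x and phenotype not in y:
            calls.append(CooperativityCall(pair=pair, phenotype=phenotype,
                                           direction=GAINED))
        elif phenotype not in xy and phenotype in x and phenotype in y:
            calls.append(CooperativityCall(pair=pair, phenotype=phenotype,
                                           direction=LOST))
    return calls


def anchored_double_screen(model: LogicalModel, anchor: Perturbation,
                           partners: Sequence[Perturbation] | None = None,
                           exclude: Iterable[str] = (),
                           input_assignment: Mapping[str, int] | None = None,
                           table: PhenotypeTable | None = None):
    """Full single + anchored-double mutant screen with cooperativity calls.

    Partners default to every single perturbation of the model except those
    touching the anchor's own component (no anchor+anchor doubles; for a
    Boolean anchor this is the published 80 -> 78 column arithmetic).
    Returns ``(screen_table, calls)`` where the table holds the unperturbed
    column, all singles, and all anchored doubles.
    """
    if partners is None:
        partners = enumerate_perturbations(model, exclude=exclude)
    partners = [p for p in partners if not (p.components & anchor.components)]

    psets = [[]] + [[anchor]] + [[p] for p in partners] \
        + [[anchor, p] for p in partners]
    screen = mutant_screen(model, psets, input_assignment=input_assignment, table=table)

    calls = []
    for partner in partners:
        double_label = f"{anchor.label} + {partner.label}"
        calls.extend(detect_cooperativity(screen.column(anchor.label),
                                          screen.column(partner.label),
                                          screen.column(double_label)))
    return screen, calls


def resolve_initial_state(model: LogicalModel, reference_inputs: Mapping[str, int],
                          phenotype_label: str, table: PhenotypeTable,
                          scenario_inputs: Mapping[str, int]):
    """Initial state for an input scan.

    The stable state of the reference condition carrying ``phenotype_label``
    is found (it must be unique), then its input levels are overwritten with
    the scenario's values.
    """
    reference = set_inputs(model, reference_inputs)
    matches = []
    for s in stable_states(reference):
        attr = Attractor(kind="stable", states=frozenset([s]),
                         readout_levels=_summarise_readouts(model, [s], table.readouts))
        if classify_attractor(attr, table).label == phenotype_label:
            matches.append(s)
    if len(matches) != 1:
        raise ModelError(
            f"initial phenotype {phenotype_label!r} is not uniquely resolvable "
            f"under the reference condition ({len(matches)} matches); "
            "supply an explicit state")
    scenario = set_inputs(model, scenario_inputs)
    state = list(matches[0])
    for name, level in scenario.input_levels.items():
        state[model.index(name)] = level
    return tuple(state), scenario


@dataclass(frozen=True)
class Scenario:
    """One input-scan condition: an input assignment (unlisted inputs 0)
    plus optional perturbations."""

    inputs: Mapping[str, int]
    perturbations: tuple = ()
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "inputs", dict(self.inputs))
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        if not self.label:
            bits = [f"{k}={v}" for k, v in self.inputs.items()]
            bits += [p.label for p in self.perturbations]
            object.__setattr__(self, "label", ", ".join(bits) or "reference")


def input_scan(model: LogicalModel, scenarios: Sequence[Scenario],
               reference_inputs: Mapping[str, int],
               initial_phenotype: str = "E1",
               table: PhenotypeTable | None = None,
               n_runs: int = DEFAULT_N_RUNS, seed: int = 0) -> ScreenTable:
    """Reachable-phenotype probabilities per scenario (probability table).

    Per scenario the initial state is the reference-condition stable state
    of ``initial_phenotype`` with inputs switched to the scenario's values.
    If that state is already stable its phenotype gets probability 1;
    otherwise seeded random walks estimate the distribution.
    """
    from .dynamics import is_stable
    from .phenotypes import default_phenotype_table
    table = table or default_phenotype_table()

    columns = {}
    evidence = {}
    labels_seen: list = list(table.labels)
    for scenario in scenarios:
        initial, scoped = resolve_initial_state(
            model, reference_inputs, initial_phenotype, table, scenario.inputs)
        for p in scenario.perturbations:
            scoped = apply_perturbation(scoped, p)
            state = list(initial)
            for name, level in p.entries:
                state[model.index(name)] = level
            initial = tuple(state)
        if is_stable(scoped, initial):
            attr = Attractor(kind="stable", states=frozenset([initial]),
                             readout_levels=_summarise_readouts(scoped, [initial],
                                                                table.readouts))
            dist = {classify_attractor(attr, table).label: 1.0}
            evidence[scenario.label] = [attr]
        else:
            est = estimate_reachability(scoped, initial, n_runs=n_runs, seed=seed,
                                        readouts=table.readouts)
            dist = phenotype_distribution(est, table)
            evidence[scenario.label] = est
        for lab in dist:
            if lab not in labels_seen:
                labels_seen.append(lab)
        columns[scenario.label] = dist

    data = pd.DataFrame(
        {cond: [dist.get(lab, 0.0) for lab in labels_seen]
         for cond, dist in columns.items()},
        index=labels_seen)
    return ScreenTable(data=data, evidence=evidence)
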