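"""Asynchronous dynamics: successors, stable states, STGs and attractors.

Updating is *unitary asynchronous*: at each step exactly one component whose
rule calls it to a different level moves by one level toward that target
(multi-valued components never jump).  This is the GINsim convention and the
single semantics supported here.

Attractors are the terminal strongly connected components of the state
transition graph: singletons are stable states (fixpoints), larger ones are
complex (oscillatory) attractors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .model import LogicalModel, ModelError, State, evaluate_target

#: Default cap on enumerated/explored configurations.  Chosen so that full
#: enumeration stays in memory for mid-sized models; larger spaces go through
#: the pruned stable-state search or must supply an initial state.
DEFAULT_STATE_BUDGET = 2 ** 22


class StateBudgetError(ModelError):
    """The requested construction would exceed the configured state budget."""


@dataclass(frozen=True, eq=False)
class Attractor:
    """A terminal SCC of the STG, with per-read-out level summaries.

    Identity (equality/hash) is the state set: the read-out summary is
    derived data, so the same attractor computed with different read-out
    requests compares equal.
    """

    kind: str                 # "stable" | "complex"
    states: frozenset         # of state tuples
    readout_levels: Mapping[str, tuple] = None  # name -> sorted tuple of levels seen

    def __post_init__(self):
        object.__setattr__(self, "states", frozenset(self.states))
        object.__setattr__(self, "readout_levels",
                           dict(self.readout_levels or {}))

    def __eq__(self, other):
        return isinstance(other, Attractor) and self.states == other.states

    def __hash__(self):
        return hash(self.states)

    @property
    def state(self) -> State:
        """The single state of a stable attractor."""
        if self.kind != "stable":
            raise ValueError("complex attractor has no single state")
        return next(iter(self.states))

    def key(self):
        """Hashable identity usable as a dict key across computations."""
        return self.states

    def constant_readouts(self) -> bool:
        return all(len(v) == 1 for v in self.readout_levels.values())


@dataclass
class StateTransitionGraph:
    """Explicit asynchronous STG over a set of states."""

    graph: nx.DiGraph
    root: State | None = None

    @property
    def states(self) -> set:
        return set(self.graph.nodes)

    @property
    def transitions(self) -> list:
        return list(self.graph.edges)

    def stable_states(self) -> set:
        return {s for s in self.graph.nodes if self.graph.out_degree(s) == 0}

    def to_edgelist(self, model: LogicalModel) -> str:
        """Plain-text edge list (one ``src tgt`` pair per line, compact digit
        states) for external graph viewers."""
        lines = [f"{model.format_state(u)} {model.format_state(v)}"
                 for u, v in self.graph.edges]
        for s in self.graph.nodes:
            if self.graph.degree(s) == 0:
                lines.append(model.format_state(s))
        return "\n".join(lines) + "\n"


def successors(model: LogicalModel, state: State) -> set:
    """Unitary asynchronous successors of ``state``.

    One successor per component whose target level differs from its current
    level; the successor moves that component by exactly one level toward
    the target.  Empty set iff the state is stable.
    """
    model.validate_state(state)
    out = set()
    for i, comp in enumerate(model.components):
        if comp.is_input or comp.name in model.clamps:
            continue
        target = evaluate_target(model, comp.name, state)
        current = state[i]
        if target != current:
            step = 1 if target > current else -1
            out.add(state[:i] + (current + step,) + state[i + 1:])
    return out


def is_stable(model: LogicalModel, state: State) -> bool:
    return not successors(model, state)


def _free_domains(model: LogicalModel) -> list:
    """(index, levels) per component, honouring clamps and input fixations."""
    domains = []
    for i, comp in enumerate(model.components):
        fixed = model.fixed_level(comp.name)
        if fixed is not None:
            domains.append((i, (fixed,)))
        else:
            domains.append((i, tuple(comp.levels)))
    return domains


def stable_states(model: LogicalModel, max_configurations: int = DEFAULT_STATE_BUDGET) -> set:
    """All fixpoints of the asynchronous dynamics.

    Branch-and-prune over the free configuration space: components are
    assigned in declaration order and a partial assignment is abandoned as
    soon as some fully-determined rule contradicts its target's assigned
    level.  With free inputs, enumeration ranges over all input
    combinations (inputs are trivially stable).  Degenerates to exhaustive
    enumeration in the worst case, hence the configurable budget guard.
    """
    n_conf = 1
    for i, comp in enumerate(model.components):
        n_conf *= 1 if model.fixed_level(comp.name) is not None else comp.max_level + 1
    if n_conf > max_configurations:
        raise StateBudgetError(
            f"{n_conf} configurations exceed budget {max_configurations}")

    domains = _free_domains(model)
    n = len(domains)
    index = {c.name: i for i, c in enumerate(model.components)}

    # rules checkable once all their participants are assigned (prefix order)
    check_at = [[] for _ in range(n)]
    for comp in model.components:
        if comp.is_input or comp.name in model.clamps:
            continue
        rule = model.rules[comp.name]
        last = max([index[comp.name]] + [index[r] for r in rule.regulators])
        check_at[last].append((index[comp.name], rule,
                               tuple(index[r] for r in rule.regulators)))

    found = set()
    assignment = [0] * n

    def consistent(depth: int) -> bool:
        for tgt_i, rule, reg_is in check_at[depth]:
            key = tuple(assignment[j] for j in reg_is)
            if rule.table[key] != assignment[tgt_i]:
                return False
        return True

    # iterative DFS over assignment prefixes
    stack = [(0, iter(domains[0][1]))] if n else []
    if n == 0:
        return {()}
    while stack:
        depth, levels = stack[-1]
        advanced = False
        for level in levels:
            assignment[depth] = level
            if not consistent(depth):
                continue
            if depth + 1 == n:
                found.add(tuple(assignment))
            else:
                stack.append((depth + 1, iter(domains[depth + 1][1])))
                advanced = True
                break
        if not advanced:
            stack.pop()
    return found


def build_stg(model: LogicalModel, from_state: State | None = None,
              max_states: int = DEFAULT_STATE_BUDGET) -> StateTransitionGraph:
    """Asynchronous STG, either the full fixed-input slice or the part
    reachable from ``from_state``."""
    graph = nx.DiGraph()
    if from_state is not None:
        model.validate_state(from_state)
        frontier = [tuple(from_state)]
        graph.add_node(tuple(from_state))
        seen = {tuple(from_state)}
        while frontier:
            state = frontier.pop()
            for nxt in successors(model, state):
                graph.add_edge(state, nxt)
                if nxt not in seen:
                    seen.add(nxt)
                    if len(seen) > max_states:
                        raise StateBudgetError(
                            f"reachable set exceeds budget {max_states}")
                    frontier.append(nxt)
        return StateTransitionGraph(graph=graph, root=tuple(from_state))

    domains = _free_domains(model)
    n_conf = 1
    for _, levels in domains:
        n_conf *= len(levels)
    if n_conf > max_states:
        raise StateBudgetError(f"{n_conf} configurations exceed budget {max_states}")

    import itertools
    for combo in itertools.product(*[levels for _, levels in domains]):
        graph.add_node(combo)
        for nxt in successors(model, combo):
            graph.add_edge(combo, nxt)
    return StateTransitionGraph(graph=graph)


def _summarise_readouts(model: LogicalModel, states: Iterable[State],
                        readouts: Iterable[str]) -> dict:
    summary = {}
    for name in readouts:
        idx = model.index(name)
        summary[name] = tuple(sorted({s[idx] for s in states}))
    return summary


def attractors(model: LogicalModel, from_state: State | None = None,
               readouts: Iterable[str] = (),
               max_states: int = DEFAULT_STATE_BUDGET) -> list:
    """Terminal SCCs of the STG, classified stable/complex.

    ``readouts`` names components whose level sets are summarised per
    attractor (used downstream for phenotype classification).
    """
    stg = build_stg(model, from_state=from_state, max_states=max_states)
    return attractors_of_stg(model, stg, readouts=readouts)


def attractors_of_stg(model: LogicalModel, stg: StateTransitionGraph,
                      readouts: Iterable[str] = ()) -> list:
    graph = stg.graph
    result = []
    for scc in nx.strongly_connected_components(graph):
        if any(v not in scc for u in scc for v in graph.successors(u)):
            continue  # not terminal
        kind = "stable" if len(scc) == 1 else "complex"
        result.append(Attractor(kind=kind, states=frozenset(scc),
                                readout_levels=_summarise_readouts(model, scc, readouts)))
    # deterministic report order: smallest mixed-radix code of member states
    result.sort(key=lambda a: min(model.state_to_int(s) for s in a.states))
    return result
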