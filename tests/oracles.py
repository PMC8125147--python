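"""Independent brute-force oracles used by the test suite.

Deliberately naive and independent of the library's dynamics code paths:
the full transition relation is materialised by scanning every state of the
configuration space and reading rule tables directly; SCCs come from an
iterative Kosaraju pass written here; absorption probabilities come from a
dense linear solve on the explicit transition matrix.
"""

from __future__ import annotations

import itertools

import numpy as np


def all_states(model):
    """Every state of the model's current slice (clamps/input fixations
    honoured, free inputs enumerated)."""
    domains = []
    for comp in model.components:
        fixed = model.fixed_level(comp.name)
        domains.append((fixed,) if fixed is not None else tuple(comp.levels))
    return [s for s in itertools.product(*domains)]


def transition_map(model):
    """state -> sorted tuple of unitary asynchronous successors, built by
    direct table lookups."""
    index = {c.name: i for i, c in enumerate(model.components)}
    moves = {}
    for state in all_states(model):
        succ = []
        for comp in model.components:
            i = index[comp.name]
            if comp.name in model.clamps:
                target = model.clamps[comp.name]
            elif comp.is_input:
                target = state[i]
            else:
                rule = model.rules[comp.name]
                target = rule.table[tuple(state[index[r]] for r in rule.regulators)]
            if target > state[i]:
                succ.append(state[:i] + (state[i] + 1,) + state[i + 1:])
            elif target < state[i]:
                succ.append(state[:i] + (state[i] - 1,) + state[i + 1:])
        moves[state] = tuple(sorted(succ))
    return moves


def stable_states_bf(model):
    return {s for s, succ in transition_map(model).items() if not succ}


def _kosaraju_sccs(nodes, succ):
    order = []
    seen = set()
    for root in nodes:
        if root in seen:
            continue
        stack = [(root, iter(succ[root]))]
        seen.add(root)
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, iter(succ[nxt])))
                    advanced = True
                    break
            if not advanced:
                order.append(node)
                stack.pop()
    pred = {n: [] for n in nodes}
    for u in nodes:
        for v in succ[u]:
            pred[v].append(u)
    assigned = set()
    sccs = []
    for root in reversed(order):
        if root in assigned:
            continue
        component = {root}
        assigned.add(root)
        stack = [root]
        while stack:
            node = stack.pop()
            for nxt in pred[node]:
                if nxt not in assigned:
                    assigned.add(nxt)
                    component.add(nxt)
                    stack.append(nxt)
        sccs.append(frozenset(component))
    return sccs


def attractors_bf(model):
    """Terminal SCC state-sets of the full slice STG."""
    moves = transition_map(model)
    nodes = list(moves)
    out = []
    for scc in _kosaraju_sccs(nodes, moves):
        if all(v in scc for u in scc for v in moves[u]):
            out.append(scc)
    return set(out)


def reachable(moves, initial):
    seen = {initial}
    frontier = [initial]
    while frontier:
        s = frontier.pop()
        for nxt in moves[s]:
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


def absorption_bf(model, initial):
    """Exact absorption probabilities (attractor state-set -> probability)
    by dense linear solve over the reachable states."""
    moves = transition_map(model)
    states = sorted(reachable(moves, tuple(initial)))
    attractor_sets = [a for a in attractors_bf(model) if a <= set(states)]
    in_attr = {}
    for k, scc in enumerate(attractor_sets):
        for s in scc:
            in_attr[s] = k
    if tuple(initial) in in_attr:
        return {attractor_sets[in_attr[tuple(initial)]]: 1.0}
    transient = [s for s in states if s not in in_attr]
    ti = {s: i for i, s in enumerate(transient)}
    Q = np.zeros((len(transient), len(transient)))
    R = np.zeros((len(transient), len(attractor_sets)))
    for s in transient:
        succ = moves[s]
        for nxt in succ:
            if nxt in in_attr:
                R[ti[s], in_attr[nxt]] += 1 / len(succ)
            else:
                Q[ti[s], ti[nxt]] += 1 / len(succ)
    B = np.linalg.solve(np.eye(len(transient)) - Q, R)
    row = B[ti[tuple(initial)]]
    return {scc: float(p) for scc, p in zip(attractor_sets, row)}


def cooperativity_bf(x: set, y: set, xy: set, phenotypes):
    """Literal set-algebra gained/lost calls over tick sets."""
    calls = set()
    for ph in phenotypes:
        if ph in xy and ph not in (x | y):
            calls.add((ph, "gained"))
        if ph not in xy and ph in (x & y):
            calls.add((ph, "lost"))
    return calls
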