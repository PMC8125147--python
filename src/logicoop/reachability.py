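"""Attractor reachability: seeded asynchronous random walks and the exact
Markov-chain absorption solve.

The Monte-Carlo estimator runs N independent walks from an initial state,
choosing uniformly at random among the enabled unitary transitions, and
reports R/N per attractor.  Uniform successor choice is the standard
asynchronous random-walk convention; it reproduces the published worked
example probabilities (1/4 vs 3/4 on the four-component toy model).

Walks detect complex attractors on the fly: when a state is revisited, the
set of states reachable from the current state is expanded and the walk
terminates if that set is strongly connected (i.e. the walk has entered a
terminal SCC).  The check is re-armed with exponential backoff so long
transients stay cheap.

:func:`exact_absorption` treats the reachable STG as a discrete Markov chain
with uniform transition probabilities, lumps each terminal SCC into an
absorbing macro-state, and solves the linear absorption system.  It is the
ground-truth oracle for the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import networkx as nx

from .dynamics import (Attractor, DEFAULT_STATE_BUDGET, _summarise_readouts,
                       build_stg, successors)
from .model import LogicalModel, State

DEFAULT_N_RUNS = 100_000   # runs used for the published scans ("10^5 runs")
DEFAULT_MAX_STEPS = 10_000


@dataclass(frozen=True)
class ReachabilityEstimate:
    """Monte-Carlo reachability estimate from one initial state.

    ``counts`` maps each reached :class:`Attractor` to its run count R;
    ``probabilities`` are R/N.  Runs exceeding ``max_steps`` are reported in
    ``truncated`` (and excluded from the probabilities, which then sum to
    < 1).
    """

    initial: State
    n_runs: int
    seed: int
    counts: Mapping[Attractor, int]
    truncated: int = 0

    def __post_init__(self):
        object.__setattr__(self, "counts", dict(self.counts))
        total = sum(self.counts.values()) + self.truncated
        if total != self.n_runs:
            raise ValueError(f"counts sum to {total}, expected {self.n_runs}")

    @property
    def probabilities(self) -> dict:
        return {a: r / self.n_runs for a, r in self.counts.items()}

    def probability_of_state(self, state: State) -> float:
        """Probability of the stable attractor at ``state`` (0 if unseen)."""
        for attractor, r in self.counts.items():
            if attractor.kind == "stable" and attractor.state == tuple(state):
                return r / self.n_runs
        return 0.0


def _successor_cache(model: LogicalModel):
    cache: dict = {}

    def get(state):
        succ = cache.get(state)
        if succ is None:
            succ = tuple(sorted(successors(model, state)))
            cache[state] = succ
        return succ

    return get


def _closure_is_terminal_scc(get_succ, state) -> frozenset | None:
    """Forward closure of ``state``; returned iff it is strongly connected.

    The closure R of a state is closed under transitions, so ``state`` lies
    in a terminal SCC iff every member of R can reach ``state`` back, i.e.
    iff R is a single SCC.
    """
    closure = {state}
    frontier = [state]
    edges = []
    while frontier:
        s = frontier.pop()
        for nxt in get_succ(s):
            edges.append((s, nxt))
            if nxt not in closure:
                closure.add(nxt)
                frontier.append(nxt)
    graph = nx.DiGraph(edges)
    graph.add_node(state)
    if nx.number_strongly_connected_components(graph) == 1:
        return frozenset(closure)
    return None


def simulate_walk(model: LogicalModel, initial: State, rng,
                  max_steps: int = DEFAULT_MAX_STEPS,
                  readouts=(), _get_succ=None) -> Attractor | None:
    """One uniform asynchronous random walk; returns the attractor reached,
    or ``None`` if truncated after ``max_steps``."""
    get_succ = _get_succ or _successor_cache(model)
    model.validate_state(initial)
    state = tuple(initial)
    visited = set()
    next_check = 0
    backoff = 4
    for step in range(max_steps + 1):
        succ = get_succ(state)
        if not succ:
            return Attractor(kind="stable", states=frozenset([state]),
                             readout_levels=_summarise_readouts(model, [state], readouts))
        if state in visited and step >= next_check:
            scc = _closure_is_terminal_scc(get_succ, state)
            if scc is not None:
                return Attractor(kind="complex", states=scc,
                                 readout_levels=_summarise_readouts(model, scc, readouts))
            backoff *= 2
            next_check = step + backoff
        visited.add(state)
        state = succ[rng.integers(len(succ))] if len(succ) > 1 else succ[0]
    return None


def estimate_reachability(model: LogicalModel, initial: State,
                          n_runs: int = DEFAULT_N_RUNS, seed: int = 0,
                          max_steps: int = DEFAULT_MAX_STEPS,
                          readouts=()) -> ReachabilityEstimate:
    """N independent seeded walks; deterministic given (model, initial,
    n_runs, seed).

    The global seed expands to per-run substreams by counter
    (``default_rng([seed, run])``), so estimates are reproducible and runs
    are independent of N.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    get_succ = _successor_cache(model)
    counts: dict = {}
    truncated = 0
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        attractor = simulate_walk(model, initial, rng, max_steps=max_steps,
                                  readouts=readouts, _get_succ=get_succ)
        if attractor is None:
            truncated += 1
        else:
            counts[attractor] = counts.get(attractor, 0) + 1
    return ReachabilityEstimate(initial=tuple(initial), n_runs=n_runs, seed=seed,
                                counts=counts, truncated=truncated)


def exact_absorption(model: LogicalModel, initial: State,
                     max_states: int = DEFAULT_STATE_BUDGET,
                     readouts=()) -> dict:
    """Exact absorption probability per attractor from ``initial``.

    The reachable STG is a finite absorbing Markov chain under uniform
    successor choice.  Terminal SCCs are lumped into absorbing macro-states;
    the transient part solves (I - Q) B = R.  Probabilities sum to 1.
    """
    stg = build_stg(model, from_state=tuple(initial), max_states=max_states)
    graph = stg.graph
    from .dynamics import attractors_of_stg
    attrs = attractors_of_stg(model, stg, readouts=readouts)
    in_attractor = {}
    for k, attractor in enumerate(attrs):
        for s in attractor.states:
            in_attractor[s] = k

    initial = tuple(initial)
    if initial in in_attractor:
        return {attrs[in_attractor[initial]]: 1.0}

    transient = [s for s in graph.nodes if s not in in_attractor]
    t_index = {s: i for i, s in enumerate(transient)}
    n_t, n_a = len(transient), len(attrs)
    Q = np.zeros((n_t, n_t))
    R = np.zeros((n_t, n_a))
    for s in transient:
        succ = list(graph.successors(s))
        p = 1.0 / len(succ)
        for nxt in succ:
            if nxt in in_attractor:
                R[t_index[s], in_attractor[nxt]] += p
            else:
                Q[t_index[s], t_index[nxt]] += p
    B = np.linalg.solve(np.eye(n_t) - Q, R)
    probs = B[t_index[initial]]
    return {attractor: float(p) for attractor, p in zip(attrs, probs)}
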