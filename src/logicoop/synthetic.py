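"""Built-in models: the four-component worked example, seeded random model
generation for oracle testing, and a hand-designed mini-EMT network with
engineered cooperative pairs.

The mini-EMT fixture is version-pinned (hand-written rules, not generated)
so that its absorption probabilities and screen outcomes are stable
surfaces for tests and documentation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import (ACTIVATION, INHIBITION, Component, LogicalModel, ModelError,
                    RegulatoryEdge, UpdateRule, boolean_rule, make_model)
from .phenotypes import PhenotypeTable, default_phenotype_table


def toy_model() -> LogicalModel:
    """The four-component worked example: input S and Boolean A, B, C.

    Rules: A = S AND NOT C; B = NOT A; C = B AND NOT A.  Only A's rule is
    published in full; the B and C rules are the unique reconstruction (up
    to the wirings tried in the test suite) that reproduces the published
    stable states and the 1/4 vs 3/4 absorption split from state 0001
    (states print as ABCS).
    """
    components = [
        Component("A"), Component("B"), Component("C"),
        Component("S", is_input=True),
    ]
    rules = [
        boolean_rule("A", ["S", "C"], lambda s, c: s and not c),
        boolean_rule("B", ["A"], lambda a: not a),
        boolean_rule("C", ["B", "A"], lambda b, a: b and not a),
    ]
    edges = [
        RegulatoryEdge("S", "A", ACTIVATION),
        RegulatoryEdge("C", "A", INHIBITION),
        RegulatoryEdge("A", "B", INHIBITION),
        RegulatoryEdge("B", "C", ACTIVATION),
        RegulatoryEdge("A", "C", INHIBITION),
    ]
    return make_model(components, rules, edges)


def negative_feedback_model() -> LogicalModel:
    """Two Boolean components, A -> B -| A: a single four-state complex
    attractor (the minimal oscillator)."""
    components = [Component("A"), Component("B")]
    rules = [
        boolean_rule("A", ["B"], lambda b: not b),
        boolean_rule("B", ["A"], lambda a: a),
    ]
    return make_model(components, rules)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-model generator.

    ``frac_multivalued`` is the probability that an internal component gets
    max level 2 (Boolean otherwise); read-outs get the stated max levels.
    """

    n_components: int
    max_in_degree: int = 2
    frac_multivalued: float = 0.0
    n_inputs: int = 1
    readout_max_levels: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_components < self.n_inputs + len(self.readout_max_levels):
            raise ModelError("n_components too small for inputs + read-outs")
        if self.max_in_degree > self.n_components - 1:
            raise ModelError("max_in_degree exceeds available regulators")


def random_model(spec: GeneratorSpec) -> LogicalModel:
    """Seeded random logical model with sign-consistent monotone rules.

    Regulators are drawn uniformly (within the in-degree bound) and each
    rule is a random linear-threshold function: activators get positive
    weights, inhibitors negative, and the weighted sum is cut at random
    thresholds into the target's levels.  Monotone by construction, so
    every generated model passes sign-consistency validation.
    """
    rng = np.random.default_rng(spec.seed)
    components = []
    for i in range(spec.n_components):
        name = f"X{i}"
        if i < spec.n_inputs:
            components.append(Component(name, max_level=1, is_input=True))
        elif spec.n_components - i <= len(spec.readout_max_levels):
            max_level = spec.readout_max_levels[
                i - (spec.n_components - len(spec.readout_max_levels))]
            components.append(Component(name, max_level=max_level))
        else:
            max_level = 2 if rng.random() < spec.frac_multivalued else 1
            components.append(Component(name, max_level=max_level))

    by_name = {c.name: c for c in components}
    rules = []
    edges = []
    names = [c.name for c in components]
    for comp in components:
        if comp.is_input:
            continue
        k = int(rng.integers(1, spec.max_in_degree + 1))
        candidates = [n for n in names if n != comp.name]
        regulators = list(rng.choice(candidates, size=min(k, len(candidates)),
                                     replace=False))
        signs = [ACTIVATION if rng.random() < 0.7 else INHIBITION
                 for _ in regulators]
        weights = [float(rng.uniform(0.5, 1.5)) * (1 if s == ACTIVATION else -1)
                   for s in signs]
        lo = sum(w * (by_name[r].max_level if w < 0 else 0)
                 for w, r in zip(weights, regulators))
        hi = sum(w * (by_name[r].max_level if w > 0 else 0)
                 for w, r in zip(weights, regulators))
        cuts = np.sort(rng.uniform(lo, hi, size=comp.max_level))
        table = {}
        for key in itertools.product(*[by_name[r].levels for r in regulators]):
            score = sum(w * v for w, v in zip(weights, key))
            table[key] = int(np.searchsorted(cuts, score, side="left"))
        rules.append(UpdateRule(target=comp.name, regulators=tuple(regulators),
                                table=table))
        edges.extend(RegulatoryEdge(r, comp.name, s)
                     for r, s in zip(regulators, signs))
    # a declared sign may be vacuous (weight too small to flip any cut);
    # both monotone directions then hold, so validation still passes.
    return make_model(components, rules, edges)


def mini_emt_model() -> tuple:
    """A 12-component EMT-style fixture with engineered cooperativity.

    Micro-environment inputs: RPTP_L (protective receptor ligand), ECM
    (matrix stiffness) and HGF (growth factor).  Internal skeleton: FAK
    senses matrix stiffness; RPTP integrates its ligand with FAK engagement
    and guards the epithelial programme; SNAIL drives EMT when FAK (or
    NOTCH together with RAF) signals and RPTP is off; ECAD opposes SNAIL.
    NOTCH is silent without its (unmodelled) ligand and PI3K is
    constitutively active, so NOTCH E1 and PI3K KO are genuine mutations
    rather than reachable input conditions.  Read-outs: AJ (max 2) and FA
    (max 3), classified by the default phenotype table.

    Engineered behaviour (all derivable by exhaustive enumeration):

    * reference condition (all inputs 0 except RPTP_L=1): unique stable
      state with (AJ, FA) = (2, 0), i.e. E1;
    * switching ECM on from E1 opens a race between RPTP (guard) and SNAIL:
      H1 and M3 are each absorbed with exact probability 1/2;
    * lost pair (NOTCH E1, RAF E1): E1 and U1 present in both single
      mutants, lost in the double;
    * gained/lost pair (NOTCH E1, PI3K KO): H3 gained (absent in both
      singles), E1/U1/H1 lost.
    """
    components = [
        Component("RPTP_L", is_input=True),
        Component("ECM", is_input=True),
        Component("HGF", is_input=True),
        Component("NOTCH"),
        Component("PI3K"),
        Component("RAF"),
        Component("FAK"),
        Component("RPTP"),
        Component("SNAIL"),
        Component("ECAD"),
        Component("AJ", max_level=2),
        Component("FA", max_level=3),
    ]
    rules = [
        # no ligand in the modelled micro-environment: silent unless mutated
        UpdateRule("NOTCH", (), {(): 0}),
        # basal activity: only a LoF mutation switches it off
        UpdateRule("PI3K", (), {(): 1}),
        boolean_rule("RAF", ["HGF"], lambda h: h),
        boolean_rule("FAK", ["ECM"], lambda e: e),
        boolean_rule("RPTP", ["FAK", "RPTP_L", "SNAIL"],
                     lambda fak, lig, sna: fak and lig and not sna),
        boolean_rule("SNAIL", ["FAK", "NOTCH", "RAF", "RPTP"],
                     lambda fak, ntc, raf, rptp: (fak or (ntc and raf)) and not rptp),
        boolean_rule("ECAD", ["SNAIL"], lambda sna: not sna),
        boolean_rule("AJ", ["ECAD", "RPTP_L"],
                     lambda ecad, lig: 2 if (ecad and lig) else 0,
                     target_max=2),
        boolean_rule("FA", ["SNAIL", "FAK", "NOTCH", "PI3K"],
                     lambda sna, fak, ntc, pik:
                         min(3, 2 * sna + fak + 2 * (ntc and not pik)),
                     target_max=3),
    ]
    model = make_model(components, rules)
    return model, default_phenotype_table()


#: Reference micro-environment of the mini-EMT fixture: a non-tumorigenic
#: context where only the protective RPTP ligand is present.
MINI_EMT_REFERENCE_INPUTS = {"RPTP_L": 1}

#: The fixture's engineered cooperative pairs (anchor NOTCH E1), frozen from
#: exhaustive stable-state enumeration; recovered by screens in the tests.
MINI_EMT_ENGINEERED_CALLS = {
    ("NOTCH E1", "RAF E1"): {("E1", "lost"), ("U1", "lost")},
    ("NOTCH E1", "PI3K KO"): {("E1", "lost"), ("U1", "lost"),
                              ("H1", "lost"), ("H3", "gained")},
}
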