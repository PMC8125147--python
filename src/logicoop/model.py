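"""Core representation of multi-valued logical regulatory models.

A logical model is a set of named components, each carrying a discrete
activity level in ``0..max_level`` (``max_level = 1`` for Boolean
components).  Designated *input* components embody external signals (the
micro-environment) and are held constant; every other component is governed
by an update rule, stored here as an explicit truth table over the levels of
its regulators.  Explicit tables make totality, monotonicity (edge-sign
consistency) and brute-force test oracles trivially checkable; expression
based formats are compiled to tables at load time.

Perturbations (loss-of-function ``KO`` = clamp to 0, gain-of-function
``E_v`` = clamp to level ``v``) are represented as *clamps*: the component
keeps its rule (for round-tripping) but is never updated.  Fixing inputs is
kept separate from perturbing internal components, mirroring the biological
distinction between micro-environmental signals and mutations.

States are plain tuples of levels ordered by component declaration; the
model provides conversions to and from dicts, compact digit strings and a
mixed-radix integer encoding.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

State = tuple  # a total assignment of levels, in component declaration order

ACTIVATION = "activation"
INHIBITION = "inhibition"


class ModelError(ValueError):
    """Raised for structurally invalid models, rules or perturbations."""


class SignConsistencyWarning(UserWarning):
    """A declared edge sign contradicts the monotonicity of a rule table."""


@dataclass(frozen=True)
class Component:
    """A model variable with levels ``0..max_level``.

    Inputs have no rule and keep a constant level throughout any trajectory.
    """

    name: str
    max_level: int = 1
    is_input: bool = False

    def __post_init__(self):
        if self.max_level < 1:
            raise ModelError(f"{self.name}: max_level must be >= 1")

    @property
    def levels(self) -> range:
        return range(self.max_level + 1)


@dataclass(frozen=True)
class UpdateRule:
    """Truth table of a non-input component.

    ``table`` maps every tuple of regulator levels (ordered as
    ``regulators``) to a target level.  The table must be total over the
    regulator-level product space.
    """

    target: str
    regulators: tuple
    table: Mapping[tuple, int]

    def __post_init__(self):
        object.__setattr__(self, "regulators", tuple(self.regulators))
        object.__setattr__(self, "table", dict(self.table))

    def __call__(self, regulator_levels: tuple) -> int:
        return self.table[tuple(regulator_levels)]


@dataclass(frozen=True)
class RegulatoryEdge:
    source: str
    target: str
    sign: str  # ACTIVATION or INHIBITION

    def __post_init__(self):
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ModelError(f"edge {self.source}->{self.target}: bad sign {self.sign!r}")


@dataclass(frozen=True)
class Perturbation:
    """A set of component clamps, e.g. ``NOTCH E1`` or ``PI3K KO``.

    KO clamps to 0; ``E_v`` clamps to ``v >= 1`` (``E1`` even for
    multi-valued components, following the GINsim labelling convention).
    """

    entries: tuple  # tuple of (component name, level)
    label: str = ""

    def __post_init__(self):
        entries = tuple(tuple(e) for e in self.entries)
        names = [n for n, _ in entries]
        if len(set(names)) != len(names):
            raise ModelError(f"perturbation {self.label!r}: component repeated")
        object.__setattr__(self, "entries", entries)
        if not self.label:
            object.__setattr__(self, "label", " + ".join(
                f"{n} KO" if v == 0 else f"{n} E{v}" for n, v in entries) or "unperturbed")

    @classmethod
    def single(cls, component: str, level: int) -> "Perturbation":
        return cls(entries=((component, level),))

    @classmethod
    def parse(cls, text: str) -> "Perturbation":
        """Parse labels like ``"NOTCH E1"``, ``"PI3K KO"`` or combinations
        joined by ``+``."""
        entries = []
        for part in text.split("+"):
            tokens = part.split()
            if len(tokens) != 2:
                raise ModelError(f"cannot parse perturbation {part!r}")
            name, what = tokens
            if what.upper() == "KO":
                entries.append((name, 0))
            elif what.upper().startswith("E") and what[1:].isdigit():
                entries.append((name, int(what[1:])))
            else:
                raise ModelError(f"cannot parse perturbation {part!r}")
        return cls(entries=tuple(entries))

    @property
    def components(self) -> set:
        return {n for n, _ in self.entries}


@dataclass(frozen=True)
class LogicalModel:
    """A validated logical model.

    ``clamps`` holds perturbation clamps (internal components forced to a
    level); ``input_levels``, when not ``None``, fixes every input component
    to a level (inputs absent from a :func:`set_inputs` assignment default
    to 0, the convention used for micro-environment scans).  When
    ``input_levels`` is ``None`` the inputs are *free*: dynamics still hold
    them constant within a trajectory, and stable-state enumeration ranges
    over all input combinations.
    """

    components: tuple
    rules: Mapping[str, UpdateRule]
    edges: tuple = ()
    clamps: Mapping[str, int] = field(default_factory=dict)
    input_levels: Mapping[str, int] | None = None

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "rules", dict(self.rules))
        object.__setattr__(self, "edges", tuple(self.edges))
        object.__setattr__(self, "clamps", dict(self.clamps))
        if self.input_levels is not None:
            object.__setattr__(self, "input_levels", dict(self.input_levels))
        object.__setattr__(self, "_index", {c.name: i for i, c in enumerate(self.components)})

    # -- lookups ---------------------------------------------------------

    @property
    def names(self) -> tuple:
        return tuple(c.name for c in self.components)

    @property
    def inputs(self) -> tuple:
        return tuple(c for c in self.components if c.is_input)

    @property
    def internals(self) -> tuple:
        return tuple(c for c in self.components if not c.is_input)

    def component(self, name: str) -> Component:
        try:
            return self.components[self._index[name]]
        except KeyError:
            raise ModelError(f"unknown component {name!r}") from None

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ModelError(f"unknown component {name!r}") from None

    # -- state helpers ---------------------------------------------------

    def state(self, levels: Mapping[str, int]) -> State:
        """Build a total state tuple from a name->level mapping."""
        missing = set(self.names) - set(levels)
        if missing:
            raise ModelError(f"state is not total; missing {sorted(missing)}")
        self._check_levels(levels.items())
        return tuple(levels[c.name] for c in self.components)

    def state_dict(self, state: State) -> dict:
        return dict(zip(self.names, state))

    def parse_state(self, text: str) -> State:
        """Parse either a compact digit string ("0111", declaration order)
        or a comma-separated ``name=level`` list."""
        text = text.strip()
        if "=" in text:
            levels = {}
            for part in text.split(","):
                name, _, value = part.partition("=")
                levels[name.strip()] = int(value)
            return self.state(levels)
        if len(text) != len(self.components):
            raise ModelError(
                f"state string {text!r} has {len(text)} digits, expected {len(self.components)}")
        return tuple(int(ch) for ch in text)

    def format_state(self, state: State) -> str:
        return "".join(str(v) for v in state)

    def state_to_int(self, state: State) -> int:
        """Mixed-radix integer encoding over declaration order."""
        code = 0
        for comp, level in zip(self.components, state):
            code = code * (comp.max_level + 1) + level
        return code

    def int_to_state(self, code: int) -> State:
        levels = []
        for comp in reversed(self.components):
            radix = comp.max_level + 1
            code, level = divmod(code, radix)
            levels.append(level)
        return tuple(reversed(levels))

    def n_configurations(self) -> int:
        n = 1
        for comp in self.components:
            n *= comp.max_level + 1
        return n

    def validate_state(self, state: State) -> None:
        if len(state) != len(self.components):
            raise ModelError("state length does not match component count")
        for comp, level in zip(self.components, state):
            if not 0 <= level <= comp.max_level:
                raise ModelError(f"{comp.name}: level {level} outside 0..{comp.max_level}")
        for name, level in self.clamps.items():
            if state[self._index[name]] != level:
                raise ModelError(f"state violates clamp {name}={level}")
        if self.input_levels is not None:
            for name, level in self.input_levels.items():
                if state[self._index[name]] != level:
                    raise ModelError(f"state violates input fixation {name}={level}")

    def _check_levels(self, items: Iterable) -> None:
        for name, level in items:
            comp = self.component(name)
            if not 0 <= level <= comp.max_level:
                raise ModelError(f"{name}: level {level} outside 0..{comp.max_level}")

    # -- derived structure ----------------------------------------------

    def fixed_level(self, name: str) -> int | None:
        """Constant level of a clamped or input-fixed component, else None."""
        if name in self.clamps:
            return self.clamps[name]
        if self.input_levels is not None and name in self.input_levels:
            return self.input_levels[name]
        return None

    def free_components(self) -> tuple:
        """Components whose level is not pinned by a clamp or input fixation.

        Free inputs (``input_levels is None``) are included: they are
        constant along trajectories but range over their levels when
        enumerating a full configuration space.
        """
        return tuple(c for c in self.components if self.fixed_level(c.name) is None)


def evaluate_target(model: LogicalModel, component: str, state: State) -> int:
    """Target level the update rule calls ``component`` to, in ``state``.

    Clamped components return their clamp, inputs their (constant) current
    level; otherwise the rule table is looked up at the regulator levels.
    A pure function of the component and the regulator levels.
    """
    comp = model.component(component)
    clamp = model.clamps.get(component)
    if clamp is not None:
        return clamp
    if comp.is_input:
        fixed = model.fixed_level(component)
        return fixed if fixed is not None else state[model.index(component)]
    rule = model.rules[component]
    key = tuple(state[model.index(r)] for r in rule.regulators)
    return rule.table[key]


def apply_perturbation(model: LogicalModel, perturbation: Perturbation) -> LogicalModel:
    """Return a copy of ``model`` with the perturbation's clamps added.

    Inputs cannot be perturbed here: micro-environmental signals are fixed
    via :func:`set_inputs`, mutations via clamps.
    """
    new_clamps = dict(model.clamps)
    for name, level in perturbation.entries:
        comp = model.component(name)
        if comp.is_input:
            raise ModelError(
                f"{name} is an input; fix it with set_inputs, not a perturbation")
        if not 0 <= level <= comp.max_level:
            raise ModelError(f"{name}: clamp level {level} outside 0..{comp.max_level}")
        if name in new_clamps and new_clamps[name] != level:
            raise ModelError(f"{name}: conflicting clamps")
        new_clamps[name] = level
    return replace(model, clamps=new_clamps)


def set_inputs(model: LogicalModel, input_assignment: Mapping[str, int]) -> LogicalModel:
    """Fix all input components; inputs not listed default to 0.

    Micro-environment scans state only the signals that are switched on;
    everything else is absent.
    """
    assignment = dict(input_assignment)
    input_names = {c.name for c in model.inputs}
    for name, level in assignment.items():
        if name not in input_names:
            raise ModelError(f"{name} is not an input component")
        comp = model.component(name)
        if not 0 <= level <= comp.max_level:
            raise ModelError(f"{name}: level {level} outside 0..{comp.max_level}")
    full = {name: assignment.get(name, 0) for name in input_names}
    return replace(model, input_levels=full)


def free_inputs(model: LogicalModel) -> LogicalModel:
    """Return a copy with no input fixation (inputs range freely)."""
    return replace(model, input_levels=None)


def _table_monotonicity(rule: UpdateRule, regulator: str) -> set:
    """Signs consistent with the table along one regulator axis.

    Returns a subset of {ACTIVATION, INHIBITION}: both if the table is
    constant in the regulator, empty if it is non-monotone.
    """
    axis = rule.regulators.index(regulator)
    non_decreasing = True
    non_increasing = True
    for key, value in rule.table.items():
        bumped = list(key)
        bumped[axis] += 1
        bumped = tuple(bumped)
        if bumped in rule.table:
            nxt = rule.table[bumped]
            if nxt < value:
                non_decreasing = False
            if nxt > value:
                non_increasing = False
    signs = set()
    if non_decreasing:
        signs.add(ACTIVATION)
    if non_increasing:
        signs.add(INHIBITION)
    return signs


def infer_edges(components: Sequence[Component], rules: Mapping[str, UpdateRule]) -> tuple:
    """Infer signed edges from the rule tables by monotonicity scan.

    A regulator that is both non-decreasing and non-increasing (i.e. the
    table ignores it) is still emitted as an activation so that the edge
    list and the regulator lists agree; non-monotone regulators raise.
    """
    edges = []
    for rule in rules.values():
        for reg in rule.regulators:
            signs = _table_monotonicity(rule, reg)
            if not signs:
                raise ModelError(
                    f"rule for {rule.target} is non-monotone in {reg}; "
                    "declare the edge sign explicitly")
            sign = ACTIVATION if ACTIVATION in signs else INHIBITION
            edges.append(RegulatoryEdge(reg, rule.target, sign))
    return tuple(edges)


def make_model(components: Sequence[Component],
               rules: Iterable[UpdateRule],
               edges: Iterable[RegulatoryEdge] | None = None,
               clamps: Mapping[str, int] | None = None,
               input_levels: Mapping[str, int] | None = None) -> LogicalModel:
    """Validate and assemble a :class:`LogicalModel`.

    Checks: unique names; exactly one total rule per non-input component;
    every table entry within the target's range; regulators declared; edge
    list agreeing with the rule regulator lists.  Declared edge signs are
    verified against table monotonicity; violations raise
    :class:`SignConsistencyWarning` (a warning, not an error, since curated
    models occasionally annotate dual regulators with a single sign).
    """
    components = tuple(components)
    names = [c.name for c in components]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ModelError(f"duplicate component names: {dupes}")
    by_name = {c.name: c for c in components}

    rule_map: dict = {}
    for rule in rules:
        if rule.target not in by_name:
            raise ModelError(f"rule targets undeclared component {rule.target!r}")
        if by_name[rule.target].is_input:
            raise ModelError(f"input component {rule.target!r} cannot have a rule")
        if rule.target in rule_map:
            raise ModelError(f"multiple rules for {rule.target!r}")
        for reg in rule.regulators:
            if reg not in by_name:
                raise ModelError(f"rule for {rule.target}: undeclared regulator {reg!r}")
        domain = list(itertools.product(*[by_name[r].levels for r in rule.regulators]))
        missing = [k for k in domain if k not in rule.table]
        if missing:
            raise ModelError(
                f"rule for {rule.target}: table not total, missing entry {missing[0]}")
        extra = [k for k in rule.table if k not in set(domain)]
        if extra:
            raise ModelError(f"rule for {rule.target}: entry {extra[0]} outside domain")
        bad = [v for v in rule.table.values()
               if not 0 <= v <= by_name[rule.target].max_level]
        if bad:
            raise ModelError(
                f"rule for {rule.target}: entry value {bad[0]} exceeds max level "
                f"{by_name[rule.target].max_level}")
        rule_map[rule.target] = rule

    missing_rules = [c.name for c in components if not c.is_input and c.name not in rule_map]
    if missing_rules:
        raise ModelError(f"non-input components without a rule: {missing_rules}")

    if edges is None:
        edge_tuple = infer_edges(components, rule_map)
    else:
        edge_tuple = tuple(edges)
        declared = {(e.source, e.target) for e in edge_tuple}
        from_rules = {(reg, rule.target) for rule in rule_map.values()
                      for reg in rule.regulators}
        if declared != from_rules:
            raise ModelError(
                f"edge list and rule regulators disagree: "
                f"edges-only {sorted(declared - from_rules)}, "
                f"rules-only {sorted(from_rules - declared)}")
        for edge in edge_tuple:
            signs = _table_monotonicity(rule_map[edge.target], edge.source)
            if edge.sign not in signs:
                warnings.warn(
                    f"edge {edge.source}->{edge.target} declared {edge.sign} but the "
                    f"rule table is not monotone that way", SignConsistencyWarning,
                    stacklevel=2)

    if clamps:
        for name, level in clamps.items():
            if name not in by_name:
                raise ModelError(f"clamp on undeclared component {name!r}")
            if not 0 <= level <= by_name[name].max_level:
                raise ModelError(f"clamp {name}={level} outside range")

    return LogicalModel(components=components, rules=rule_map, edges=edge_tuple,
                        clamps=clamps or {}, input_levels=input_levels)


def boolean_rule(target: str, regulators: Sequence[str], fn,
                 max_levels: Mapping[str, int] | None = None,
                 target_max: int = 1) -> UpdateRule:
    """Compile a Python predicate/level function into a truth table.

    ``fn`` receives regulator levels (as positional ints, ordered as
    ``regulators``) and returns the target level (bools are coerced).
    ``max_levels`` gives regulator max levels (default: Boolean).
    """
    max_levels = max_levels or {}
    domains = [range(max_levels.get(r, 1) + 1) for r in regulators]
    table = {}
    for key in itertools.product(*domains):
        value = int(fn(*key))
        if not 0 <= value <= target_max:
            raise ModelError(f"rule for {target}: value {value} outside 0..{target_max}")
        table[key] = value
    return UpdateRule(target=target, regulators=tuple(regulators), table=table)
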