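"""Phenotype classification of attractors via read-out components.

EMT phenotypes are named by the levels of two read-outs: AJ (adherens
junction assembly, 0-2) and FA (focal adhesion recycling ability, 0-3).
The default table has eight rows:

=========  ====  ====  ============
label      AJ    FA    class
=========  ====  ====  ============
E1         2     0     epithelial
H1         2     1     hybrid
H2         1     2     hybrid
H3         2     3     hybrid
U1         0     0     unknown
M1         0     1     mesenchymal
M2         0     2     mesenchymal
M3         0     3     mesenchymal
=========  ====  ====  ============

Index assignment within the hybrid/mesenchymal classes follows the
published verbal attributions (ROS drives M2; IL6 drives M1 and H1; a stiff
ECM drives M3 and H3; growth factors without the RPTP ligand drive H2 and
M2); the unknown (0,0) phenotype, unnamed in the source table, is labelled
U1 here.  Other models can supply their own read-outs and rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .dynamics import Attractor
from .model import ModelError

EPITHELIAL = "epithelial"
HYBRID = "hybrid"
UNKNOWN = "unknown"
MESENCHYMAL = "mesenchymal"

OSCILLATORY = "oscillatory"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class PhenotypeTable:
    """Mapping from read-out level tuples to (label, class)."""

    readouts: tuple                    # read-out component names, in key order
    rows: Mapping[tuple, tuple]        # (levels...) -> (label, class)

    def __post_init__(self):
        object.__setattr__(self, "readouts", tuple(self.readouts))
        object.__setattr__(self, "rows", dict(self.rows))
        labels = [lab for lab, _ in self.rows.values()]
        if len(set(labels)) != len(labels):
            raise ModelError("phenotype labels must be unique")

    @property
    def labels(self) -> tuple:
        return tuple(lab for lab, _ in self.rows.values())

    def label_of(self, levels: tuple) -> str | None:
        row = self.rows.get(tuple(levels))
        return row[0] if row else None

    def class_of(self, label: str) -> str:
        for lab, klass in self.rows.values():
            if lab == label:
                return klass
        raise KeyError(label)


@dataclass(frozen=True)
class PhenotypeCall:
    """Classification of one attractor: a table label, ``unclassified`` for
    constant but unmapped read-outs, or ``oscillatory`` when a read-out is
    non-constant across the attractor."""

    attractor: Attractor
    label: str


def default_phenotype_table() -> PhenotypeTable:
    """The eight-row EMT table over read-outs (AJ, FA)."""
    rows = {
        (2, 0): ("E1", EPITHELIAL),
        (2, 1): ("H1", HYBRID),
        (1, 2): ("H2", HYBRID),
        (2, 3): ("H3", HYBRID),
        (0, 0): ("U1", UNKNOWN),
        (0, 1): ("M1", MESENCHYMAL),
        (0, 2): ("M2", MESENCHYMAL),
        (0, 3): ("M3", MESENCHYMAL),
    }
    return PhenotypeTable(readouts=("AJ", "FA"), rows=rows)


def classify_attractor(attractor: Attractor, table: PhenotypeTable) -> PhenotypeCall:
    """Label an attractor by its read-out levels.

    Requires the attractor to carry summaries for every read-out in the
    table (see the ``readouts`` argument of the dynamics/reachability
    functions).
    """
    missing = [r for r in table.readouts if r not in attractor.readout_levels]
    if missing:
        raise ModelError(f"attractor lacks read-out summaries for {missing}")
    level_sets = [attractor.readout_levels[r] for r in table.readouts]
    if any(len(ls) != 1 for ls in level_sets):
        return PhenotypeCall(attractor=attractor, label=OSCILLATORY)
    levels = tuple(ls[0] for ls in level_sets)
    label = table.label_of(levels)
    return PhenotypeCall(attractor=attractor, label=label or UNCLASSIFIED)


def phenotype_distribution(estimate, table: PhenotypeTable) -> dict:
    """Aggregate a :class:`~logicoop.reachability.ReachabilityEstimate` (or
    an exact attractor->probability mapping) by phenotype label.

    Attractors sharing a label pool their probability; total probability is
    preserved.
    """
    probabilities = estimate.probabilities if hasattr(estimate, "probabilities") \
        else dict(estimate)
    out: dict = {}
    for attractor, p in probabilities.items():
        call = classify_attractor(attractor, table)
        out[call.label] = out.get(call.label, 0.0) + p
    return out
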