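"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction

import pytest

from evimap import (
    Experiment,
    ExperimentClass,
    HypotheticalAssertion,
    Outcome,
    Phenomenon,
    Relation,
    ResearchMap,
)

C = ExperimentClass
O = Outcome
R = Relation


@pytest.fixture
def creb():
    return Phenomenon("CREB", "lateral amygdala", "during training")


@pytest.fixture
def arc(creb):
    return Phenomenon("number of Arc neurons", "lateral amygdala", "after training")


def mk(agent, target, exp_class, outcome, eid=""):
    return Experiment(
        agent=agent, target=target, exp_class=exp_class, outcome=outcome,
        experiment_id=eid,
    )


@pytest.fixture
def worked_example(creb, arc):
    """Two Positive Interventions and one Negative Intervention, all no-change."""
    return [
        mk(creb, arc, C.POS_INTERVENTION, O.NO_CHANGE, "e1"),
        mk(creb, arc, C.POS_INTERVENTION, O.NO_CHANGE, "e2"),
        mk(creb, arc, C.NEG_INTERVENTION, O.NO_CHANGE, "e3"),
    ]


@pytest.fixture
def worked_example_map(worked_example):
    m = ResearchMap(map_id="worked-example")
    for e in worked_example:
        m.add_experiment(e)
    return m


def signed_map(edges, map_id="signed"):
    """Build a map from (agent, target, relation) triples on named nodes.

    Each relation is realised by one Positive Intervention with the
    outcome that supports it, so every edge's assigned relation equals
    the requested one.
    """
    outcome_for = {
        R.EXCITATORY: O.INCREASE,
        R.INHIBITORY: O.DECREASE,
        R.NO_CONNECTION: O.NO_CHANGE,
    }
    nodes: dict[str, Phenomenon] = {}
    m = ResearchMap(map_id=map_id)
    for i, (a, b, rel) in enumerate(edges):
        pa = nodes.setdefault(a, Phenomenon(a))
        pb = nodes.setdefault(b, Phenomenon(b))
        m.add_experiment(
            mk(pa, pb, C.POS_INTERVENTION, outcome_for[rel], f"{map_id}-e{i}")
        )
    return m


#: Fig-13-style conflict scenario: two independence findings (A-B, C-D)
#: and an excitatory cycle through E that connects their endpoints.
CONFLICT_EDGES = [
    ("A", "B", R.NO_CONNECTION),
    ("C", "D", R.NO_CONNECTION),
    ("A", "C", R.EXCITATORY),
    ("D", "B", R.EXCITATORY),
    ("A", "E", R.EXCITATORY),
    ("E", "D", R.EXCITATORY),
    ("D", "E", R.EXCITATORY),
    ("E", "A", R.EXCITATORY),
]


@pytest.fixture
def conflict_map():
    return signed_map(CONFLICT_EDGES, map_id="conflict-demo")


# ---------------------------------------------------------------------------
# Independent scoring oracle: literally build the 4 x 3 pseudocount table
# (one in every cell), tally experiments into it by class and supported
# relation, and evaluate the posterior-mean/convergence/score formulas in
# exact rational arithmetic.

_ORACLE_CLASSES = [
    C.POS_INTERVENTION,
    C.POS_NONINTERVENTION,
    C.NEG_NONINTERVENTION,
    C.NEG_INTERVENTION,
]
_ORACLE_RELATIONS = [R.EXCITATORY, R.NO_CONNECTION, R.INHIBITORY]


def _oracle_supported_relation(exp_class, outcome):
    up = exp_class in (C.POS_INTERVENTION, C.POS_NONINTERVENTION)
    if outcome is O.NO_CHANGE:
        return R.NO_CONNECTION
    if outcome is O.INCREASE:
        return R.EXCITATORY if up else R.INHIBITORY
    return R.INHIBITORY if up else R.EXCITATORY


def oracle_score(experiments):
    """(relation, score) by direct table evaluation; score None on ties."""
    table = {c: {r: 1 for r in _ORACLE_RELATIONS} for c in _ORACLE_CLASSES}
    for e in experiments:
        table[e.exp_class][_oracle_supported_relation(e.exp_class, e.outcome)] += 1
    theta_bar = {}
    for r in _ORACLE_RELATIONS:
        acc = Fraction(0)
        for c in _ORACLE_CLASSES:
            row_total = sum(table[c].values())
            acc += Fraction(table[c][r], row_total)
        theta_bar[r] = acc / 4
    best = max(theta_bar.values())
    winners = [r for r in _ORACLE_RELATIONS if theta_bar[r] == best]
    if len(winners) > 1:
        return R.INDETERMINATE, None
    theta_o = Fraction(1, 3)
    return winners[0], float((best - theta_o) / (1 - theta_o))
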