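"""Domain types for causal evidence maps.

An evidence map is a directed graph in which nodes are biological
phenomena and edges summarise experimental evidence about a causal
relation between an *Agent* (the phenomenon intervened on or observed)
and a *Target* (the phenomenon measured).  Every experiment belongs to
one of four classes — Positive/Negative Intervention, Positive/Negative
Non-intervention — and reports whether the Target increased, decreased
or did not change.  Each (class, outcome) pair supports exactly one of
three relations: Excitatory, Inhibitory or No-connection.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "Phenomenon",
    "ExperimentClass",
    "Outcome",
    "Relation",
    "Experiment",
    "HypotheticalAssertion",
    "ResearchMap",
    "outcome_to_relation",
    "EvimapError",
    "normalize_text",
]


class EvimapError(Exception):
    """Base class for domain errors raised by this package."""


_WS = re.compile(r"\s+")


def normalize_text(s: str) -> str:
    """Trim, collapse internal whitespace and case-fold ``s``.

    Node identity and term matching both use this normalization; the
    original casing is kept for display.
    """
    return _WS.sub(" ", s.strip()).casefold()


@dataclass(frozen=True)
class Phenomenon:
    """A node: a biological phenomenon identified by What/Where/When.

    ``what`` names the entity (gene, protein, cell type, behaviour ...),
    ``where`` its location (region, species ...) and ``when`` the
    temporal context.  ``where`` and ``when`` may be empty but still
    participate in identity: the same protein measured in two locations
    is two distinct nodes.
    """

    what: str
    where: str = ""
    when: str = ""

    def __post_init__(self) -> None:
        if not normalize_text(self.what):
            raise EvimapError("Phenomenon 'what' must be non-empty")

    @property
    def key(self) -> tuple[str, str, str]:
        """Normalized identity triple (casefolded, whitespace-collapsed)."""
        return (
            normalize_text(self.what),
            normalize_text(self.where),
            normalize_text(self.when),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phenomenon):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __str__(self) -> str:
        parts = [self.what] + [p for p in (self.where, self.when) if p]
        return " / ".join(parts)


class ExperimentClass(enum.Enum):
    """The four connection-experiment classes.

    ``agent_direction`` is +1 when the Agent went up (by intervention or
    observation) and -1 when it went down; ``symbol`` is the display
    glyph drawn above empirical edges.
    """

    POS_INTERVENTION = ("↑", +1)
    POS_NONINTERVENTION = ("⌀↑", +1)
    NEG_NONINTERVENTION = ("⌀↓", -1)
    NEG_INTERVENTION = ("↓", -1)

    def __init__(self, symbol: str, agent_direction: int) -> None:
        self.symbol = symbol
        self.agent_direction = agent_direction

    @property
    def is_intervention(self) -> bool:
        return self in (
            ExperimentClass.POS_INTERVENTION,
            ExperimentClass.NEG_INTERVENTION,
        )


class Outcome(enum.Enum):
    """Measured change in the Target."""

    INCREASE = +1
    NO_CHANGE = 0
    DECREASE = -1


class Relation(enum.Enum):
    """Relation type an edge can evidence or assert.

    INDETERMINATE marks an edge whose evidence ties between relations;
    it never carries a score and never enters signed paths.
    """

    EXCITATORY = "E"
    NO_CONNECTION = "N"
    INHIBITORY = "I"
    INDETERMINATE = "?"

    @property
    def sign(self) -> Optional[int]:
        """+1 for excitatory, -1 for inhibitory, 0 for no-connection."""
        if self is Relation.EXCITATORY:
            return +1
        if self is Relation.INHIBITORY:
            return -1
        if self is Relation.NO_CONNECTION:
            return 0
        return None


def outcome_to_relation(exp_class: ExperimentClass, outcome: Outcome) -> Relation:
    """Map an experiment's class and outcome to the relation it supports.

    A relation is excitatory when Agent and Target move in the same
    direction (Agent up & Target up, or Agent down & Target down),
    inhibitory when they move in opposite directions, and no-connection
    whenever the Target did not change.  The function is total over the
    4 x 3 class/outcome grid.
    """
    if outcome is Outcome.NO_CHANGE:
        return Relation.NO_CONNECTION
    if exp_class.agent_direction * outcome.value > 0:
        return Relation.EXCITATORY
    return Relation.INHIBITORY


@dataclass(frozen=True)
class Experiment:
    """One empirical result on a directed Agent -> Target edge.

    ``p_value`` and the method/statistics fields are tracked metadata
    only; they never influence scores.  ``secondary_agent`` records the
    second Agent of a two-Agent intervention; such experiments count
    only toward the primary agent -> target edge.
    """

    agent: Phenomenon
    target: Phenomenon
    exp_class: ExperimentClass
    outcome: Outcome
    experiment_id: str = ""
    agent_method: str = ""
    target_method: str = ""
    stat_test: str = ""
    p_value: Optional[float] = None
    source_id: str = ""
    secondary_agent: Optional[Phenomenon] = None

    def __post_init__(self) -> None:
        if self.agent == self.target:
            raise EvimapError(
                f"self-loop experiment: agent and target are both {self.agent!s}"
            )
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise EvimapError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def supported_relation(self) -> Relation:
        return outcome_to_relation(self.exp_class, self.outcome)

    @property
    def edge(self) -> tuple[Phenomenon, Phenomenon]:
        return (self.agent, self.target)


@dataclass(frozen=True)
class HypotheticalAssertion:
    """A user-asserted putative connection with no direct evidence.

    Hypothetical edges carry neither scores nor experiment symbols.
    """

    agent: Phenomenon
    target: Phenomenon
    relation: Relation
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.agent == self.target:
            raise EvimapError("self-loop hypothesis")
        if self.relation is Relation.INDETERMINATE:
            raise EvimapError("a hypothesis must assert E, I or N, not indeterminate")

    @property
    def edge(self) -> tuple[Phenomenon, Phenomenon]:
        return (self.agent, self.target)


@dataclass
class ResearchMap:
    """A per-source evidence map: experiments plus hypothetical assertions.

    All experiments for a directed (agent, target) pair aggregate on one
    empirical edge; A->B and B->A are distinct edges.  ``highlighted``
    marks main-finding edges and is a presentation attribute only.
    """

    map_id: str = ""
    visibility: str = "public"
    experiments: list[Experiment] = field(default_factory=list)
    hypotheses: list[HypotheticalAssertion] = field(default_factory=list)
    highlighted: set[tuple[Phenomenon, Phenomenon]] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def add_experiment(self, e: Experiment) -> "ResearchMap":
        """Append an experiment, implicitly creating its nodes.

        Raises on a duplicate non-empty experiment_id.
        """
        if e.experiment_id and any(
            x.experiment_id == e.experiment_id for x in self.experiments
        ):
            raise EvimapError(f"duplicate experiment_id {e.experiment_id!r}")
        self.experiments.append(e)
        return self

    def add_hypothesis(self, h: HypotheticalAssertion) -> "ResearchMap":
        self.hypotheses.append(h)
        return self

    def highlight(self, agent: Phenomenon, target: Phenomenon) -> "ResearchMap":
        if (agent, target) not in self.empirical_edges() and (
            agent,
            target,
        ) not in {h.edge for h in self.hypotheses}:
            raise EvimapError(f"cannot highlight non-existent edge {agent!s} -> {target!s}")
        self.highlighted.add((agent, target))
        return self

    def nodes(self) -> set[Phenomenon]:
        out: set[Phenomenon] = set()
        for e in self.experiments:
            out.add(e.agent)
            out.add(e.target)
        for h in self.hypotheses:
            out.add(h.agent)
            out.add(h.target)
        return out

    def empirical_edges(self) -> dict[tuple[Phenomenon, Phenomenon], list[Experiment]]:
        """Experiments grouped by directed (agent, target) pair."""
        out: dict[tuple[Phenomenon, Phenomenon], list[Experiment]] = {}
        for e in self.experiments:
            out.setdefault(e.edge, []).append(e)
        return out

    def hypothetical_edges(self) -> dict[tuple[Phenomenon, Phenomenon], list[HypotheticalAssertion]]:
        out: dict[tuple[Phenomenon, Phenomenon], list[HypotheticalAssertion]] = {}
        for h in self.hypotheses:
            out.setdefault(h.edge, []).append(h)
        return out

    def validate(self) -> list[str]:
        """Return every invariant violation; empty list iff well-formed."""
        violations: list[str] = []
        seen_ids: set[str] = set()
        for i, e in enumerate(self.experiments):
            if e.experiment_id:
                if e.experiment_id in seen_ids:
                    violations.append(
                        f"experiments[{i}]: duplicate experiment_id {e.experiment_id!r}"
                    )
                seen_ids.add(e.experiment_id)
            if e.agent == e.target:
                violations.append(f"experiments[{i}]: self-loop on {e.agent!s}")
        edges = set(self.empirical_edges()) | {h.edge for h in self.hypotheses}
        for pair in sorted(
            self.highlighted, key=lambda p: (p[0].key, p[1].key)
        ):
            if pair not in edges:
                violations.append(
                    f"highlighted: {pair[0]!s} -> {pair[1]!s} has no edge"
                )
        if self.visibility not in ("public", "private"):
            violations.append(f"visibility: {self.visibility!r} not public/private")
        return violations


def validate_map(m: ResearchMap) -> list[str]:
    """Functional alias for :meth:`ResearchMap.validate`."""
    return m.validate()
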