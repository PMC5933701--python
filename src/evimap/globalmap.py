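"""Merging many evidence maps into one provenance-preserving global map.

Experiments from all source maps are pooled per directed node-pair and
the edge score is recomputed from the pooled count table (never averaged
across maps), so a global edge's score reflects the union of evidence.
Nodes can be keyed either by their full What/Where/When identity or by
What alone, which collapses the same entity measured in different
locations or at different times into a single node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .model import (
    EvimapError,
    Experiment,
    HypotheticalAssertion,
    Phenomenon,
    Relation,
    ResearchMap,
    normalize_text,
)
from .scoring import EvidenceCounts, EvidenceScore, PriorWeights, score_counts

__all__ = ["NodeKey", "GlobalEdge", "GlobalMap", "merge_maps", "edge_provenance"]


@dataclass(frozen=True, order=True)
class NodeKey:
    """Identity of a global-map node.

    ``mode`` is "full" (normalized What/Where/When triple) or
    "what_only" (normalized What alone; nodes differing only in Where or
    When collapse into one).
    """

    mode: str
    key: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("full", "what_only"):
            raise EvimapError(f"unknown key mode {self.mode!r}")

    @classmethod
    def of(cls, p: Phenomenon, mode: str = "full") -> "NodeKey":
        if mode == "what_only":
            return cls(mode, (normalize_text(p.what),))
        return cls(mode, p.key)

    def __str__(self) -> str:
        return " / ".join(x for x in self.key if x) or self.key[0]


@dataclass
class GlobalEdge:
    """One directed global-map edge with pooled evidence and provenance.

    An edge may be simultaneously empirical and hypothetical when
    different sources contribute experiments and assertions.  The
    evidence block always equals the score of the pooled experiments.
    """

    agent_key: NodeKey
    target_key: NodeKey
    experiments: list[tuple[str, Experiment]] = field(default_factory=list)
    hypotheses: list[tuple[str, HypotheticalAssertion]] = field(default_factory=list)
    pooled_counts: EvidenceCounts = field(default_factory=EvidenceCounts.zeros)
    evidence: Optional[EvidenceScore] = None

    @property
    def is_empirical(self) -> bool:
        return bool(self.experiments)

    @property
    def is_hypothetical(self) -> bool:
        return bool(self.hypotheses)

    @property
    def empirical_provenance(self) -> list[tuple[str, str]]:
        return [(m, e.experiment_id) for m, e in self.experiments]

    @property
    def hypothetical_provenance(self) -> list[tuple[str, Relation]]:
        return [(m, h.relation) for m, h in self.hypotheses]

    @property
    def relation(self) -> Optional[Relation]:
        """Assigned relation of the pooled evidence, if any experiments."""
        return self.evidence.relation if self.is_empirical else None

    @property
    def score(self) -> Optional[float]:
        return self.evidence.score if self.is_empirical and self.evidence else None


@dataclass
class GlobalMap:
    """Merged multi-source graph with per-edge provenance.

    Deterministic: merging the same multiset of maps in any order yields
    an identical GlobalMap (edges and provenance are kept sorted).
    """

    mode: str = "full"
    nodes: dict[NodeKey, Phenomenon] = field(default_factory=dict)
    edges: dict[tuple[NodeKey, NodeKey], GlobalEdge] = field(default_factory=dict)
    sources: set[str] = field(default_factory=set)
    priors: Optional[PriorWeights] = None

    def edge(self, agent_key: NodeKey, target_key: NodeKey) -> GlobalEdge:
        try:
            return self.edges[(agent_key, target_key)]
        except KeyError:
            raise EvimapError(
                f"no edge {agent_key!s} -> {target_key!s} in global map"
            ) from None

    def to_networkx(self) -> nx.DiGraph:
        """Attribute-carrying DiGraph view (relation, score, provenance)."""
        g = nx.DiGraph()
        for k in sorted(self.nodes):
            g.add_node(k, display=str(self.nodes[k]))
        for (a, b), e in sorted(self.edges.items()):
            g.add_edge(
                a,
                b,
                relation=e.relation,
                score=e.score,
                n_experiments=len(e.experiments),
                n_hypotheses=len(e.hypotheses),
                edge_obj=e,
            )
        return g


def merge_maps(
    maps: Iterable[ResearchMap],
    mode: str = "full",
    priors: Optional[PriorWeights] = None,
) -> GlobalMap:
    """Pool many evidence maps into one global map.

    Experiments land on the edge keyed by their (agent, target) node
    keys; the edge's score is recomputed from the pooled count table.
    Hypothetical assertions are attached with provenance but never touch
    the counts.  Source map_ids must be distinct.
    """
    maps = list(maps)
    ids = [m.map_id for m in maps]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise EvimapError(f"duplicate map_id(s): {dupes}")

    g = GlobalMap(mode=mode, priors=priors)
    # Sort sources so insertion order never leaks into the result.
    for m in sorted(maps, key=lambda m: m.map_id):
        g.sources.add(m.map_id)
        for e in m.experiments:
            a, b = NodeKey.of(e.agent, mode), NodeKey.of(e.target, mode)
            g.nodes.setdefault(a, e.agent)
            g.nodes.setdefault(b, e.target)
            if a == b:
                # distinct full nodes can collapse onto one what_only
                # key; such experiments cannot sit on a self-loop edge
                continue
            ge = g.edges.setdefault((a, b), GlobalEdge(a, b))
            ge.experiments.append((m.map_id, e))
        for h in m.hypotheses:
            a, b = NodeKey.of(h.agent, mode), NodeKey.of(h.target, mode)
            g.nodes.setdefault(a, h.agent)
            g.nodes.setdefault(b, h.target)
            if a == b:
                continue
            ge = g.edges.setdefault((a, b), GlobalEdge(a, b))
            ge.hypotheses.append((m.map_id, h))

    for ge in g.edges.values():
        ge.experiments.sort(key=lambda t: (t[0], t[1].experiment_id))
        ge.hypotheses.sort(key=lambda t: (t[0], t[1].relation.value, t[1].source_id))
        ge.pooled_counts = EvidenceCounts.from_experiments(e for _, e in ge.experiments)
        ge.evidence = score_counts(ge.pooled_counts, priors)
    return g


def edge_provenance(
    g: GlobalMap, agent_key: NodeKey, target_key: NodeKey
) -> list[dict]:
    """One row per contributing experiment or hypothesis on an edge.

    Empirical rows carry class/outcome/methods; hypothetical rows are
    flagged and carry only the asserted relation.
    """
    e = g.edge(agent_key, target_key)
    rows: list[dict] = []
    for map_id, x in e.experiments:
        rows.append(
            {
                "map_id": map_id,
                "kind": "empirical",
                "experiment_id": x.experiment_id,
                "class": x.exp_class.name,
                "outcome": x.outcome.name,
                "relation": x.supported_relation.value,
                "agent_method": x.agent_method,
                "target_method": x.target_method,
                "stat_test": x.stat_test,
                "p_value": x.p_value,
            }
        )
    for map_id, h in e.hypotheses:
        rows.append(
            {
                "map_id": map_id,
                "kind": "hypothetical",
                "experiment_id": None,
                "class": None,
                "outcome": None,
                "relation": h.relation.value,
            }
        )
    return rows
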