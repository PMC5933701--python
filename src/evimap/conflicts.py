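"""Structural conflict detection between signed pathways and independence.

A No-connection edge asserts that Agent and Target are independent.  A
directed pathway of Excitatory/Inhibitory edges between the same two
nodes asserts the opposite — some dependence of determinate sign — so
the pathway and the independence finding cannot all be true at once.
These conflicts are purely structural: once found, the template of
nodes and relation-labelled edges that produced one can be searched for
anywhere else, regardless of node identities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import networkx as nx

from .model import EvimapError, Relation, ResearchMap
from .globalmap import GlobalEdge, GlobalMap, NodeKey, merge_maps

__all__ = [
    "SignedPath",
    "Conflict",
    "path_sign",
    "detect_conflicts",
    "forbidden_causation",
    "match_template",
]


def path_sign(relations: Iterable[Relation]) -> int:
    """Sign of a causal pathway: product of edge signs (E=+1, I=-1)."""
    sign = 1
    n = 0
    for r in relations:
        if r not in (Relation.EXCITATORY, Relation.INHIBITORY):
            raise EvimapError(f"{r} has no determinate sign")
        sign *= 1 if r is Relation.EXCITATORY else -1
        n += 1
    if n == 0:
        raise EvimapError("empty pathway has no sign")
    return sign


@dataclass(frozen=True)
class SignedPath:
    """A simple directed pathway of signed (E/I) edges."""

    nodes: tuple[NodeKey, ...]
    relations: tuple[Relation, ...]
    sign: int
    min_edge_score: Optional[float]

    def __str__(self) -> str:
        arrows = {Relation.EXCITATORY: "→", Relation.INHIBITORY: "⊣"}
        parts = [str(self.nodes[0])]
        for r, n in zip(self.relations, self.nodes[1:]):
            parts.append(f" {arrows[r]} {n!s}")
        return "".join(parts)


@dataclass(frozen=True)
class Conflict:
    """A signed pathway contradicting an independence finding.

    ``independence_edge`` is the stored orientation of the No-connection
    edge; the pathway connects the same endpoints in either orientation.
    """

    independence_edge: tuple[NodeKey, NodeKey]
    independence_score: Optional[float]
    path: SignedPath
    explanation: str


def _edge_view(
    g: Union[GlobalMap, ResearchMap], include_hypothetical: bool
) -> list[tuple[NodeKey, NodeKey, Relation, Optional[float]]]:
    """Flatten a map into (agent, target, relation, score) records.

    Empirical edges contribute their assigned relation and score;
    indeterminate edges are dropped (they assert nothing definite).
    Hypothetical assertions contribute their asserted relation, unscored.
    """
    if isinstance(g, ResearchMap):
        g = merge_maps([g])
    out: list[tuple[NodeKey, NodeKey, Relation, Optional[float]]] = []
    for (a, b), e in sorted(g.edges.items()):
        if e.is_empirical and e.relation is not Relation.INDETERMINATE:
            out.append((a, b, e.relation, e.score))
        if include_hypothetical:
            for _, h in e.hypotheses:
                out.append((a, b, h.relation, None))
    return out


def _signed_graph(
    view: list[tuple[NodeKey, NodeKey, Relation, Optional[float]]],
    min_score: float,
) -> nx.DiGraph:
    sg = nx.DiGraph()
    for a, b, rel, score in view:
        if rel not in (Relation.EXCITATORY, Relation.INHIBITORY):
            continue
        if score is not None and score < min_score:
            continue
        # on label collision (empirical + hypothetical), empirical wins:
        # entries arrive empirical-first per edge
        if not sg.has_edge(a, b):
            sg.add_edge(a, b, relation=rel, score=score)
    return sg


def _make_path(sg: nx.DiGraph, nodes: list[NodeKey]) -> SignedPath:
    rels, scores = [], []
    for u, v in zip(nodes, nodes[1:]):
        d = sg.edges[u, v]
        rels.append(d["relation"])
        if d["score"] is not None:
            scores.append(d["score"])
    return SignedPath(
        nodes=tuple(nodes),
        relations=tuple(rels),
        sign=path_sign(rels),
        min_edge_score=min(scores) if scores else None,
    )


def detect_conflicts(
    g: Union[GlobalMap, ResearchMap],
    max_path_len: int = 4,
    min_score: float = 0.0,
    include_hypothetical: bool = False,
) -> list[Conflict]:
    """Report every signed pathway contradicting a No-connection edge.

    For each No-connection edge (A, B) — independence is orientation-free
    even though the edge is stored directed — every simple directed
    pathway A⇝B or B⇝A of length <= ``max_path_len`` over qualifying
    E/I edges is a conflict.  A pathway of either polarity conflicts:
    both imply dependence between the endpoints.
    """
    if max_path_len < 1:
        raise EvimapError("max_path_len must be >= 1")
    view = _edge_view(g, include_hypothetical)
    sg = _signed_graph(view, min_score)
    n_edges = [
        (a, b, score)
        for a, b, rel, score in view
        if rel is Relation.NO_CONNECTION
        and (score is None or score >= min_score)
    ]
    out: list[Conflict] = []
    for a, b, n_score in n_edges:
        for s, t in ((a, b), (b, a)):
            if s not in sg or t not in sg:
                continue
            for nodes in sorted(
                nx.all_simple_paths(sg, s, t, cutoff=max_path_len)
            ):
                p = _make_path(sg, nodes)
                kind = "excitatory" if p.sign > 0 else "inhibitory"
                out.append(
                    Conflict(
                        independence_edge=(a, b),
                        independence_score=n_score,
                        path=p,
                        explanation=(
                            f"the {kind} pathway {p!s} conflicts with the "
                            f"finding of independence between {a!s} and {b!s}"
                        ),
                    )
                )
    return out


def forbidden_causation(
    g: Union[GlobalMap, ResearchMap],
    max_path_len: int = 4,
    min_score: float = 0.0,
    include_hypothetical: bool = False,
) -> set[tuple[NodeKey, NodeKey]]:
    """Ordered pairs (X, Y) such that X cannot cause Y, directly or not.

    (X, Y) is forbidden when some node B is independent of X (a
    No-connection edge, either orientation) while Y already reaches B
    through a signed pathway of length <= ``max_path_len`` (or Y is B
    itself): any cause X⇝Y would complete a pathway X⇝B that
    contradicts the independence finding.
    """
    view = _edge_view(g, include_hypothetical)
    sg = _signed_graph(view, min_score)
    rev = sg.reverse(copy=False)
    out: set[tuple[NodeKey, NodeKey]] = set()
    for a, b, rel, score in view:
        if rel is not Relation.NO_CONNECTION:
            continue
        if score is not None and score < min_score:
            continue
        for x, bb in ((a, b), (b, a)):
            ancestors = {bb}
            if bb in rev:
                ancestors |= set(
                    nx.single_source_shortest_path_length(
                        rev, bb, cutoff=max_path_len
                    )
                )
            for y in ancestors:
                if y != x:
                    out.add((x, y))
    return out


def match_template(
    g: Union[GlobalMap, ResearchMap],
    template: nx.DiGraph,
    include_hypothetical: bool = False,
) -> list[dict]:
    """All bindings of a relation-labelled template onto the map.

    ``template`` is a small DiGraph (<= 6 nodes) whose edges carry a
    ``relation`` attribute.  A binding maps template nodes to map nodes
    such that every template edge exists with the same relation label;
    extra map edges among the bound nodes are allowed.  No-connection
    template edges match in either orientation (independence is
    symmetric).  Matching is purely structural, so an inference derived
    from one instance holds for every binding returned.
    """
    if template.number_of_nodes() > 6:
        raise EvimapError("template too large (max 6 nodes)")
    view = _edge_view(g, include_hypothetical)
    big = nx.DiGraph()
    for a, b, rel, _ in view:
        for u, v in ((a, b),) + (((b, a),) if rel is Relation.NO_CONNECTION else ()):
            if big.has_edge(u, v):
                big.edges[u, v]["relations"].add(rel)
            else:
                big.add_edge(u, v, relations={rel})

    def edge_match(big_attrs, tmpl_attrs):
        return tmpl_attrs["relation"] in big_attrs["relations"]

    matcher = nx.algorithms.isomorphism.DiGraphMatcher(
        big, template, edge_match=edge_match
    )
    seen: set[frozenset] = set()
    out: list[dict] = []
    for mapping in matcher.subgraph_monomorphisms_iter():
        binding = {tn: gn for gn, tn in mapping.items()}
        key = frozenset(binding.items())
        if key not in seen:
            seen.add(key)
            out.append(binding)
    out.sort(key=lambda b: sorted((str(k), str(v)) for k, v in b.items()))
    return out
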