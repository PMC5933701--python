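"""Search and neighborhood extraction over a global evidence map.

Queries start from a free-text term matched case-insensitively against
node What/Where/When fields, expand a bounded number of hops over edges
passing score filters, and can profile how many nodes become reachable
within k traversals — a measure of how densely a topic is connected to
the rest of the curated literature.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .model import EvimapError, normalize_text
from .globalmap import GlobalEdge, GlobalMap, NodeKey

__all__ = [
    "QuerySpec",
    "find_nodes",
    "neighborhood",
    "pair_search",
    "connectivity_profile",
]


@dataclass(frozen=True)
class QuerySpec:
    """Parameters of one global-map query.

    Score bounds are inclusive and apply to scored empirical edges;
    unscored empirical edges (indeterminate evidence) pass only with
    ``include_unscored`` and hypothesis-only edges only with
    ``include_hypothetical``.  ``direction`` controls traversal:
    "out" follows agent->target, "in" the reverse, "both" either.
    """

    term: str = ""
    pair: Optional[tuple[str, str]] = None
    max_hops: int = 1
    score_min: float = 0.0
    score_max: float = 1.0
    include_hypothetical: bool = True
    include_unscored: bool = False
    direction: str = "both"

    def __post_init__(self) -> None:
        if self.max_hops < 1:
            raise EvimapError("max_hops must be >= 1")
        if not 0.0 <= self.score_min <= self.score_max <= 1.0:
            raise EvimapError(
                f"need 0 <= score_min <= score_max <= 1, got "
                f"[{self.score_min}, {self.score_max}]"
            )
        if self.direction not in ("out", "in", "both"):
            raise EvimapError(f"unknown direction {self.direction!r}")


def _key_matches(g: GlobalMap, k: NodeKey, term_norm: str) -> bool:
    if term_norm in k.key or any(term_norm in part for part in k.key):
        return True
    p = g.nodes.get(k)
    if p is None:
        return False
    return any(
        term_norm in normalize_text(f) for f in (p.what, p.where, p.when)
    )


def find_nodes(g: GlobalMap, term: str) -> set[NodeKey]:
    """All node keys whose normalized fields contain the normalized term."""
    t = normalize_text(term)
    if not t:
        raise EvimapError("search term must be non-empty")
    return {k for k in g.nodes if _key_matches(g, k, t)}


def _edge_passes(e: GlobalEdge, spec: QuerySpec) -> bool:
    if e.is_empirical:
        if e.score is not None:
            return spec.score_min <= e.score <= spec.score_max
        return spec.include_unscored
    return spec.include_hypothetical


def neighborhood(g: GlobalMap, spec: QuerySpec) -> GlobalMap:
    """Hop-limited subgraph around the nodes matching ``spec.term``.

    Breadth-first expansion from the seed set, traversing only edges
    that pass the score/hypothetical filters, up to ``max_hops`` edge
    traversals.  The result contains the traversed nodes and every
    qualifying edge between them; no seed match yields an empty map.
    """
    seeds = sorted(find_nodes(g, spec.term)) if spec.term else []
    passing = {pair for pair, e in g.edges.items() if _edge_passes(e, spec)}

    fwd: dict[NodeKey, list[NodeKey]] = {}
    for a, b in passing:
        if spec.direction in ("out", "both"):
            fwd.setdefault(a, []).append(b)
        if spec.direction in ("in", "both"):
            fwd.setdefault(b, []).append(a)

    dist = {k: 0 for k in seeds}
    q = deque(seeds)
    while q:
        u = q.popleft()
        if dist[u] >= spec.max_hops:
            continue
        for v in sorted(fwd.get(u, [])):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)

    kept = set(dist)
    sub = GlobalMap(mode=g.mode, priors=g.priors, sources=set(g.sources))
    for k in sorted(kept):
        sub.nodes[k] = g.nodes[k]
    for (a, b) in sorted(passing):
        if a in kept and b in kept:
            sub.edges[(a, b)] = g.edges[(a, b)]
    return sub


def pair_search(g: GlobalMap, agent_term: str, target_term: str) -> list[GlobalEdge]:
    """Edges whose endpoints match the respective terms, in sorted order.

    Both empirical and hypothetical edges are returned; direction
    matters (agent term must match the edge's source node).
    """
    a_keys = find_nodes(g, agent_term)
    b_keys = find_nodes(g, target_term)
    return [
        g.edges[(a, b)]
        for (a, b) in sorted(g.edges)
        if a in a_keys and b in b_keys
    ]


def connectivity_profile(
    g: GlobalMap, seeds: Iterable[NodeKey], max_k: int
) -> dict[int, int]:
    """Cumulative count of nodes first reachable within k traversals.

    Traversal ignores edge direction; seeds themselves are excluded from
    the counts.  The profile is monotone non-decreasing in k and bounded
    by ``len(g.nodes) - len(seeds)``.
    """
    seeds = set(seeds)
    unknown = seeds - set(g.nodes)
    if unknown:
        raise EvimapError(f"seed keys not in map: {sorted(map(str, unknown))}")
    if max_k < 1:
        raise EvimapError("max_k must be >= 1")

    adj: dict[NodeKey, set[NodeKey]] = {}
    for a, b in g.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    dist = {k: 0 for k in seeds}
    q = deque(sorted(seeds))
    while q:
        u = q.popleft()
        if dist[u] >= max_k:
            continue
        for v in sorted(adj.get(u, ())):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)

    return {
        k: sum(1 for n, d in dist.items() if 0 < d <= k)
        for k in range(1, max_k + 1)
    }
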