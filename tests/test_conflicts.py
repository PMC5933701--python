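"""Conflict detection: signed pathways vs independence findings."""

import itertools

import networkx as nx
import numpy as np
import pytest

from evimap import (
    EvimapError,
    Phenomenon,
    Relation,
    ResearchMap,
    detect_conflicts,
    forbidden_causation,
    match_template,
    merge_maps,
    path_sign,
)

from conftest import C, CONFLICT_EDGES, O, R, mk, signed_map


class TestPathSign:
    @pytest.mark.parametrize(
        "relations,expected",
        [
            ([R.EXCITATORY] * 3, +1),
            ([R.EXCITATORY, R.INHIBITORY], -1),
            ([R.INHIBITORY, R.INHIBITORY], +1),
            ([R.INHIBITORY], -1),
        ],
    )
    def test_product_of_signs(self, relations, expected):
        assert path_sign(relations) == expected

    def test_unsigned_relations_rejected(self):
        with pytest.raises(EvimapError):
            path_sign([R.EXCITATORY, R.NO_CONNECTION])
        with pytest.raises(EvimapError):
            path_sign([])


class TestDetectConflicts:
    def test_two_pathway_conflicts_in_demo_graph(self, conflict_map):
        """Both independence findings are contradicted by one pathway each."""
        found = detect_conflicts(conflict_map)
        assert len(found) == 2
        summaries = {
            (
                tuple(n.key[0] for n in c.path.nodes),
                tuple(k.key[0] for k in c.independence_edge),
            )
            for c in found
        }
        assert summaries == {
            (("a", "e", "d", "b"), ("a", "b")),
            (("d", "e", "a", "c"), ("c", "d")),
        }
        assert all(c.path.sign == +1 for c in found)

    def test_signed_edges_alone_never_conflict(self):
        m = signed_map([("A", "B", R.EXCITATORY), ("B", "C", R.INHIBITORY)])
        assert detect_conflicts(m) == []

    def test_minimal_length_one_conflict(self):
        m = signed_map([("A", "B", R.NO_CONNECTION), ("A", "B", R.EXCITATORY)])
        # both results sit on the same directed pair: indeterminate, no conflict
        assert detect_conflicts(m) == []
        # stored on opposite orientations they do conflict (N is symmetric)
        m2 = signed_map([("B", "A", R.NO_CONNECTION), ("A", "B", R.EXCITATORY)])
        found = detect_conflicts(m2)
        assert len(found) == 1
        assert len(found[0].path.relations) == 1

    def test_inhibitory_pathway_also_conflicts(self):
        m = signed_map(
            [("A", "B", R.NO_CONNECTION), ("A", "X", R.INHIBITORY), ("X", "B", R.EXCITATORY)]
        )
        found = detect_conflicts(m)
        assert len(found) == 1
        assert found[0].path.sign == -1

    def test_independence_is_symmetric(self):
        # pathway runs B -> A while the N edge is stored A -> B
        m = signed_map([("A", "B", R.NO_CONNECTION), ("B", "A", R.EXCITATORY)])
        assert len(detect_conflicts(m)) == 1

    def test_relabeling_invariance(self, conflict_map):
        relabeled = signed_map(
            [(a.translate(str.maketrans("ABCDE", "VWXYZ")),
              b.translate(str.maketrans("ABCDE", "VWXYZ")), r)
             for a, b, r in CONFLICT_EDGES],
            map_id="relabeled",
        )
        orig = detect_conflicts(conflict_map)
        new = detect_conflicts(relabeled)
        assert len(orig) == len(new)
        assert sorted(len(c.path.relations) for c in orig) == sorted(
            len(c.path.relations) for c in new
        )

    def test_monotonic_in_path_length(self, conflict_map):
        for shorter, longer in [(1, 2), (2, 3), (3, 4)]:
            assert len(detect_conflicts(conflict_map, max_path_len=shorter)) <= len(
                detect_conflicts(conflict_map, max_path_len=longer)
            )

    def test_min_score_filter_never_adds_conflicts(self, conflict_map):
        lo = detect_conflicts(conflict_map, min_score=0.0)
        hi = detect_conflicts(conflict_map, min_score=0.5)
        assert len(hi) <= len(lo)


def brute_force_conflicts(edges, max_path_len):
    """Exhaustive oracle: enumerate all simple node sequences."""
    signed = {(a, b): r for a, b, r in edges if r in (R.EXCITATORY, R.INHIBITORY)}
    n_edges = [(a, b) for a, b, r in edges if r is R.NO_CONNECTION]
    nodes = sorted({x for a, b, _ in edges for x in (a, b)})
    found = []
    for a, b in n_edges:
        for s, t in ((a, b), (b, a)):
            for length in range(1, max_path_len + 1):
                for middle in itertools.permutations(
                    [n for n in nodes if n not in (s, t)], length - 1
                ):
                    seq = (s,) + middle + (t,)
                    if all((u, v) in signed for u, v in zip(seq, seq[1:])):
                        found.append((s, t, seq))
    return found


def test_brute_force_oracle_agreement_on_random_graphs():
    rng = np.random.default_rng(42)
    rels = [R.EXCITATORY, R.INHIBITORY, R.NO_CONNECTION]
    for trial in range(30):
        n = int(rng.integers(3, 8))
        names = [f"N{i}" for i in range(n)]
        pairs = [(a, b) for a in names for b in names if a < b]
        rng.shuffle(pairs)
        edges = []
        for a, b in pairs[: int(rng.integers(2, len(pairs) + 1))]:
            if rng.random() < 0.5:
                a, b = b, a
            edges.append((a, b, rels[rng.integers(3)]))
        m = signed_map(edges, map_id=f"rand{trial}")
        got = detect_conflicts(m, max_path_len=4)
        expected = brute_force_conflicts(edges, max_path_len=4)
        assert len(got) == len(expected)
        got_keys = sorted(tuple(n.key[0] for n in c.path.nodes) for c in got)
        exp_keys = sorted(tuple(x.casefold() for x in seq) for _, _, seq in expected)
        assert got_keys == exp_keys


class TestForbiddenCausation:
    def test_demo_black_edges(self):
        m = signed_map(
            [
                ("A", "B", R.NO_CONNECTION),
                ("C", "D", R.NO_CONNECTION),
                ("A", "C", R.EXCITATORY),
                ("D", "B", R.EXCITATORY),
            ]
        )
        fb = {(x.key[0], y.key[0]) for x, y in forbidden_causation(m)}
        assert ("a", "d") in fb and ("d", "a") in fb

    def test_no_independence_means_nothing_forbidden(self):
        m = signed_map([("A", "B", R.EXCITATORY)])
        assert forbidden_causation(m) == set()

    def test_empty_map(self):
        assert forbidden_causation(ResearchMap(map_id="empty")) == set()


class TestMatchTemplate:
    def test_conflict_motif_has_two_bindings(self, conflict_map):
        t = nx.DiGraph()
        t.add_edge("w", "x", relation=R.EXCITATORY)
        t.add_edge("x", "y", relation=R.EXCITATORY)
        t.add_edge("y", "z", relation=R.EXCITATORY)
        t.add_edge("w", "z", relation=R.NO_CONNECTION)
        bindings = match_template(conflict_map, t)
        assert len(bindings) == 2
        bound = {
            tuple(bindings[i][v].key[0] for v in "wxyz") for i in range(2)
        }
        assert bound == {("a", "e", "d", "b"), ("d", "e", "a", "c")}

    def test_absent_template(self, conflict_map):
        t = nx.DiGraph()
        t.add_edge("u", "v", relation=R.INHIBITORY)
        assert match_template(conflict_map, t) == []

    def test_single_edge_template_counts_edges(self):
        m = signed_map(
            [("A", "B", R.EXCITATORY), ("B", "C", R.EXCITATORY), ("C", "A", R.EXCITATORY)]
        )
        t = nx.DiGraph()
        t.add_edge("u", "v", relation=R.EXCITATORY)
        assert len(match_template(m, t)) == 3

    def test_oversized_template_rejected(self, conflict_map):
        t = nx.path_graph(7, create_using=nx.DiGraph)
        nx.set_edge_attributes(t, R.EXCITATORY, "relation")
        with pytest.raises(EvimapError):
            match_template(conflict_map, t)
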