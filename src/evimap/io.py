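"""Serialization and interchange for evidence maps.

JSON is the canonical on-disk format (sorted keys, explicit
schema_version).  Documents carry a ``derived`` block with each edge's
assigned relation and score for human inspection, but derived fields
are never trusted on load: they are recomputed and compared, and any
mismatch is reported as a warning with the recomputed value winning.
Graph structure can be exported to DOT or GraphML; bulk experiments can
be imported from CSV tables mirroring the map-entry form fields.
"""

from __future__ import annotations

import csv
import io as _io
import json
import warnings
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import networkx as nx

from .model import (
    EvimapError,
    Experiment,
    ExperimentClass,
    HypotheticalAssertion,
    Outcome,
    Phenomenon,
    Relation,
    ResearchMap,
)
from .globalmap import GlobalEdge, GlobalMap, NodeKey, merge_maps
from .scoring import CLASS_ORDER, score_edge

__all__ = [
    "SCHEMA_VERSION",
    "MapFormatError",
    "CSVImportError",
    "DerivedMismatchWarning",
    "save_map",
    "load_map",
    "save_global",
    "load_global",
    "export_graph",
    "import_experiments_csv",
]

SCHEMA_VERSION = "1"

PathOrStream = Union[str, Path, IO[str]]


class MapFormatError(EvimapError):
    """A document failed schema validation; message lists JSON paths."""


class CSVImportError(EvimapError):
    """One or more CSV rows failed to parse; message lists row numbers."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class DerivedMismatchWarning(UserWarning):
    """A stored derived field disagreed with its recomputed value."""


# ---------------------------------------------------------------------------
# JSON encoding

def _phen_to_json(p: Optional[Phenomenon]) -> Optional[dict]:
    if p is None:
        return None
    return {"what": p.what, "where": p.where, "when": p.when}


def _exp_to_json(e: Experiment) -> dict:
    return {
        "experiment_id": e.experiment_id,
        "agent": _phen_to_json(e.agent),
        "target": _phen_to_json(e.target),
        "class": e.exp_class.name,
        "outcome": e.outcome.name,
        "agent_method": e.agent_method,
        "target_method": e.target_method,
        "stat_test": e.stat_test,
        "p_value": e.p_value,
        "source_id": e.source_id,
        "secondary_agent": _phen_to_json(e.secondary_agent),
    }


def _hyp_to_json(h: HypotheticalAssertion) -> dict:
    return {
        "agent": _phen_to_json(h.agent),
        "target": _phen_to_json(h.target),
        "relation": h.relation.value,
        "source_id": h.source_id,
    }


def _derived_edges(m: ResearchMap) -> list[dict]:
    out = []
    for (a, b), exps in sorted(
        m.empirical_edges().items(), key=lambda kv: (kv[0][0].key, kv[0][1].key)
    ):
        ev = score_edge(exps)
        out.append(
            {
                "agent": _phen_to_json(a),
                "target": _phen_to_json(b),
                "relation": ev.relation.value,
                "score": ev.score,
                "symbols": ev.symbols(),
                "counts": ev.counts.x.tolist(),
            }
        )
    return out


def _doc_for_map(m: ResearchMap) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "research_map",
        "map": {
            "map_id": m.map_id,
            "visibility": m.visibility,
            "metadata": m.metadata,
            "experiments": [_exp_to_json(e) for e in m.experiments],
            "hypotheses": [_hyp_to_json(h) for h in m.hypotheses],
            "highlighted": sorted(
                (
                    {"agent": _phen_to_json(a), "target": _phen_to_json(b)}
                    for a, b in m.highlighted
                ),
                key=lambda d: json.dumps(d, sort_keys=True),
            ),
        },
        "derived": {"edges": _derived_edges(m)},
    }


def _dump(doc: dict, dest: PathOrStream) -> None:
    text = json.dumps(doc, sort_keys=True, ensure_ascii=False, indent=1)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text + "\n", encoding="utf-8")
    else:
        dest.write(text + "\n")


def _load_json(src: PathOrStream) -> dict:
    if isinstance(src, (str, Path)):
        text = Path(src).read_text(encoding="utf-8")
    else:
        text = src.read()
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise MapFormatError(
            f"invalid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc


def save_map(m: ResearchMap, dest: PathOrStream) -> None:
    """Write a map document (canonical JSON, derived block included)."""
    _dump(_doc_for_map(m), dest)


# ---------------------------------------------------------------------------
# JSON decoding with located errors

class _Reader:
    def __init__(self) -> None:
        self.errors: list[str] = []

    def fail(self, path: str, msg: str) -> None:
        self.errors.append(f"{path}: {msg}")

    def phen(self, d, path, required=True) -> Optional[Phenomenon]:
        if d is None:
            if required:
                self.fail(path, "missing phenomenon")
            return None
        if not isinstance(d, dict):
            self.fail(path, f"expected object, got {type(d).__name__}")
            return None
        try:
            return Phenomenon(
                what=str(d.get("what", "")),
                where=str(d.get("where", "")),
                when=str(d.get("when", "")),
            )
        except EvimapError as exc:
            self.fail(path, str(exc))
            return None

    def enum(self, cls, token, path):
        try:
            return cls[token]
        except KeyError:
            self.fail(path, f"unknown {cls.__name__} {token!r}")
            return None

    def relation(self, token, path) -> Optional[Relation]:
        try:
            return Relation(token)
        except ValueError:
            return self.enum(Relation, token, path)

    def experiment(self, d, path) -> Optional[Experiment]:
        if not isinstance(d, dict):
            self.fail(path, "expected object")
            return None
        agent = self.phen(d.get("agent"), f"{path}.agent")
        target = self.phen(d.get("target"), f"{path}.target")
        exp_class = self.enum(ExperimentClass, d.get("class"), f"{path}.class")
        outcome = self.enum(Outcome, d.get("outcome"), f"{path}.outcome")
        if None in (agent, target, exp_class, outcome):
            return None
        try:
            return Experiment(
                agent=agent,
                target=target,
                exp_class=exp_class,
                outcome=outcome,
                experiment_id=str(d.get("experiment_id", "")),
                agent_method=str(d.get("agent_method", "")),
                target_method=str(d.get("target_method", "")),
                stat_test=str(d.get("stat_test", "")),
                p_value=d.get("p_value"),
                source_id=str(d.get("source_id", "")),
                secondary_agent=self.phen(
                    d.get("secondary_agent"), f"{path}.secondary_agent", required=False
                ),
            )
        except EvimapError as exc:
            self.fail(path, str(exc))
            return None

    def hypothesis(self, d, path) -> Optional[HypotheticalAssertion]:
        if not isinstance(d, dict):
            self.fail(path, "expected object")
            return None
        agent = self.phen(d.get("agent"), f"{path}.agent")
        target = self.phen(d.get("target"), f"{path}.target")
        relation = self.relation(d.get("relation"), f"{path}.relation")
        if None in (agent, target, relation):
            return None
        try:
            return HypotheticalAssertion(
                agent=agent,
                target=target,
                relation=relation,
                source_id=str(d.get("source_id", "")),
            )
        except EvimapError as exc:
            self.fail(path, str(exc))
            return None


def _check_derived(m: ResearchMap, derived: dict, source: str) -> None:
    stored = {
        (
            json.dumps(e.get("agent"), sort_keys=True),
            json.dumps(e.get("target"), sort_keys=True),
        ): e
        for e in derived.get("edges", [])
        if isinstance(e, dict)
    }
    for e in _derived_edges(m):
        k = (
            json.dumps(e["agent"], sort_keys=True),
            json.dumps(e["target"], sort_keys=True),
        )
        s = stored.get(k)
        if s is None:
            continue
        same_rel = s.get("relation") == e["relation"]
        s_score, r_score = s.get("score"), e["score"]
        same_score = (s_score is None and r_score is None) or (
            s_score is not None
            and r_score is not None
            and abs(s_score - r_score) < 1e-9
        )
        if not (same_rel and same_score):
            warnings.warn(
                f"{source}: stored derived edge "
                f"{e['agent']['what']} -> {e['target']['what']} "
                f"(relation={s.get('relation')}, score={s_score}) disagrees with "
                f"recomputed (relation={e['relation']}, score={r_score}); "
                "recomputed values win",
                DerivedMismatchWarning,
                stacklevel=3,
            )


def load_map(src: PathOrStream) -> ResearchMap:
    """Read a map document, validating structure and recomputing scores.

    Raises :class:`MapFormatError` with JSON-path locations on schema
    violations; emits :class:`DerivedMismatchWarning` when stored
    derived fields disagree with recomputed ones.
    """
    doc = _load_json(src)
    r = _Reader()
    if not isinstance(doc, dict):
        raise MapFormatError("$: document must be a JSON object")
    if doc.get("kind", "research_map") != "research_map":
        raise MapFormatError(f"$.kind: expected 'research_map', got {doc.get('kind')!r}")
    body = doc.get("map")
    if not isinstance(body, dict):
        raise MapFormatError("$.map: missing or not an object")

    m = ResearchMap(
        map_id=str(body.get("map_id", "")),
        visibility=str(body.get("visibility", "public")),
        metadata=body.get("metadata") or {},
    )
    for i, d in enumerate(body.get("experiments", [])):
        e = r.experiment(d, f"$.map.experiments[{i}]")
        if e is not None:
            try:
                m.add_experiment(e)
            except EvimapError as exc:
                r.fail(f"$.map.experiments[{i}]", str(exc))
    for i, d in enumerate(body.get("hypotheses", [])):
        h = r.hypothesis(d, f"$.map.hypotheses[{i}]")
        if h is not None:
            m.add_hypothesis(h)
    for i, d in enumerate(body.get("highlighted", [])):
        if not isinstance(d, dict):
            r.fail(f"$.map.highlighted[{i}]", "expected object")
            continue
        a = r.phen(d.get("agent"), f"$.map.highlighted[{i}].agent")
        b = r.phen(d.get("target"), f"$.map.highlighted[{i}].target")
        if a is not None and b is not None:
            m.highlighted.add((a, b))
    if r.errors:
        raise MapFormatError("; ".join(r.errors))

    for v in m.validate():
        r.fail("$.map", v)
    if r.errors:
        raise MapFormatError("; ".join(r.errors))

    src_name = str(src) if isinstance(src, (str, Path)) else "<stream>"
    if isinstance(doc.get("derived"), dict):
        _check_derived(m, doc["derived"], src_name)
    return m


# ---------------------------------------------------------------------------
# Global-map documents

def _nodekey_to_json(k: NodeKey) -> dict:
    return {"mode": k.mode, "key": list(k.key)}


def save_global(g: GlobalMap, dest: PathOrStream) -> None:
    """Write a merged global map with full provenance blocks."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "global_map",
        "mode": g.mode,
        "sources": sorted(g.sources),
        "nodes": [
            {"key": _nodekey_to_json(k), "display": _phen_to_json(g.nodes[k])}
            for k in sorted(g.nodes)
        ],
        "edges": [
            {
                "agent_key": _nodekey_to_json(a),
                "target_key": _nodekey_to_json(b),
                "experiments": [
                    {"map_id": mid, "experiment": _exp_to_json(x)}
                    for mid, x in e.experiments
                ],
                "hypotheses": [
                    {"map_id": mid, "hypothesis": _hyp_to_json(h)}
                    for mid, h in e.hypotheses
                ],
                "derived": {
                    "relation": e.relation.value if e.relation else None,
                    "score": e.score,
                },
            }
            for (a, b), e in sorted(g.edges.items())
        ],
    }
    _dump(doc, dest)


def load_global(src: PathOrStream) -> GlobalMap:
    """Read a global-map document, recomputing pooled scores.

    Reconstructs per-source maps from the provenance blocks and
    re-merges them, so the loaded object is guaranteed internally
    consistent regardless of what the file claimed.
    """
    doc = _load_json(src)
    if doc.get("kind") != "global_map":
        raise MapFormatError(f"$.kind: expected 'global_map', got {doc.get('kind')!r}")
    mode = doc.get("mode", "full")
    r = _Reader()
    per_source: dict[str, ResearchMap] = {
        str(s): ResearchMap(map_id=str(s)) for s in doc.get("sources", [])
    }
    for i, ed in enumerate(doc.get("edges", [])):
        for j, rec in enumerate(ed.get("experiments", [])):
            path = f"$.edges[{i}].experiments[{j}]"
            mid = str(rec.get("map_id", ""))
            e = r.experiment(rec.get("experiment"), path)
            if e is not None:
                per_source.setdefault(mid, ResearchMap(map_id=mid)).experiments.append(e)
        for j, rec in enumerate(ed.get("hypotheses", [])):
            path = f"$.edges[{i}].hypotheses[{j}]"
            mid = str(rec.get("map_id", ""))
            h = r.hypothesis(rec.get("hypothesis"), path)
            if h is not None:
                per_source.setdefault(mid, ResearchMap(map_id=mid)).hypotheses.append(h)
    if r.errors:
        raise MapFormatError("; ".join(r.errors))
    return merge_maps(per_source.values(), mode=mode)


def load_any(src: PathOrStream) -> Union[ResearchMap, GlobalMap]:
    """Load either document kind, dispatching on the ``kind`` field."""
    if isinstance(src, (str, Path)):
        doc = _load_json(src)
        kind = doc.get("kind", "research_map")
        buf = _io.StringIO(json.dumps(doc))
        return load_global(buf) if kind == "global_map" else load_map(buf)
    doc = _load_json(src)
    buf = _io.StringIO(json.dumps(doc))
    kind = doc.get("kind", "research_map")
    return load_global(buf) if kind == "global_map" else load_map(buf)


# ---------------------------------------------------------------------------
# Graph exports

_ARROWHEADS = {
    Relation.EXCITATORY: ("normal", "solid"),
    Relation.INHIBITORY: ("tee", "solid"),
    Relation.NO_CONNECTION: ("odot", "dotted"),
    Relation.INDETERMINATE: ("diamond", "solid"),
}


def _display_records(g: Union[ResearchMap, GlobalMap]):
    """Uniform (nodes, empirical edges, hypothetical edges) view.

    Nodes are (id, three display lines); empirical edges carry relation,
    score, symbols and highlight flag.
    """
    if isinstance(g, ResearchMap):
        nodes = sorted(g.nodes(), key=lambda p: p.key)
        ids = {p: f"n{i}" for i, p in enumerate(nodes)}
        node_rows = [(ids[p], (p.what, p.where, p.when)) for p in nodes]
        emp = []
        for (a, b), exps in sorted(
            g.empirical_edges().items(), key=lambda kv: (kv[0][0].key, kv[0][1].key)
        ):
            ev = score_edge(exps)
            emp.append(
                (ids[a], ids[b], ev.relation, ev.score, ev.symbols(), (a, b) in g.highlighted)
            )
        hyp = []
        for (a, b), hs in sorted(
            g.hypothetical_edges().items(), key=lambda kv: (kv[0][0].key, kv[0][1].key)
        ):
            for h in hs:
                hyp.append((ids[a], ids[b], h.relation, (a, b) in g.highlighted))
        return node_rows, emp, hyp

    keys = sorted(g.nodes)
    ids = {k: f"n{i}" for i, k in enumerate(keys)}
    node_rows = []
    for k in keys:
        p = g.nodes[k]
        if k.mode == "what_only":
            node_rows.append((ids[k], (p.what, "", "")))
        else:
            node_rows.append((ids[k], (p.what, p.where, p.when)))
    emp, hyp = [], []
    for (a, b), e in sorted(g.edges.items()):
        if e.is_empirical:
            emp.append(
                (ids[a], ids[b], e.relation, e.score, e.evidence.symbols(), False)
            )
        for _, h in e.hypotheses:
            hyp.append((ids[a], ids[b], h.relation, False))
    return node_rows, emp, hyp


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def export_graph(g: Union[ResearchMap, GlobalMap], fmt: str) -> str:
    """Render a map's structure as DOT or GraphML text.

    Nodes show What/Where/When on three lines.  Empirical edges carry
    their relation (arrowhead: sharp = excitatory, blunt = inhibitory,
    circle on a dotted line = no-connection, diamond = indeterminate),
    score and experiment-class symbols.  Hypothetical edges are drawn
    lighter and dashed with no score or symbols.
    """
    fmt = fmt.lower()
    if fmt not in ("dot", "graphml"):
        raise EvimapError(f"unsupported export format {fmt!r} (use dot or graphml)")
    nodes, emp, hyp = _display_records(g)

    if fmt == "dot":
        lines = ["digraph evidence_map {", "  node [shape=box];"]
        for nid, (what, where, when) in nodes:
            label = _dot_escape("\\n".join([what, where, when]).rstrip("\\n"))
            lines.append(f'  {nid} [label="{label}"];')
        for a, b, rel, score, symbols, hi in emp:
            head, style = _ARROWHEADS[rel]
            label = symbols + (f"  {score:.4f}" if score is not None else "")
            attrs = [f'label="{_dot_escape(label)}"', f"arrowhead={head}", f"style={style}"]
            if hi:
                attrs.append('color=orange penwidth=2')
            lines.append(f"  {a} -> {b} [{' '.join(attrs)}];")
        for a, b, rel, hi in hyp:
            head, _ = _ARROWHEADS[rel]
            attrs = [f"arrowhead={head}", "style=dashed", "color=gray"]
            lines.append(f"  {a} -> {b} [{' '.join(attrs)}];")
        lines.append("}")
        return "\n".join(lines) + "\n"

    gx = nx.DiGraph()
    for nid, (what, where, when) in nodes:
        gx.add_node(nid, what=what, where=where, when=when)
    for a, b, rel, score, symbols, hi in emp:
        attrs = {"kind": "empirical", "relation": rel.value, "symbols": symbols,
                 "highlighted": hi}
        if score is not None:
            attrs["score"] = score
        gx.add_edge(a, b, **attrs)
    for a, b, rel, hi in hyp:
        if gx.has_edge(a, b):
            gx.edges[a, b]["kind"] = "empirical+hypothetical"
            gx.edges[a, b]["hypothetical_relation"] = rel.value
        else:
            gx.add_edge(a, b, kind="hypothetical", relation=rel.value, highlighted=hi)
    buf = _io.BytesIO()
    nx.write_graphml(gx, buf)
    return buf.getvalue().decode("utf-8")


# ---------------------------------------------------------------------------
# CSV experiment import

_CLASS_TOKENS = {
    "↑": ExperimentClass.POS_INTERVENTION,
    "↓": ExperimentClass.NEG_INTERVENTION,
    "⌀↑": ExperimentClass.POS_NONINTERVENTION,
    "⌀↓": ExperimentClass.NEG_NONINTERVENTION,
    "pos_intervention": ExperimentClass.POS_INTERVENTION,
    "neg_intervention": ExperimentClass.NEG_INTERVENTION,
    "pos_nonintervention": ExperimentClass.POS_NONINTERVENTION,
    "neg_nonintervention": ExperimentClass.NEG_NONINTERVENTION,
    "positive intervention": ExperimentClass.POS_INTERVENTION,
    "negative intervention": ExperimentClass.NEG_INTERVENTION,
    "positive non-intervention": ExperimentClass.POS_NONINTERVENTION,
    "negative non-intervention": ExperimentClass.NEG_NONINTERVENTION,
    "pi": ExperimentClass.POS_INTERVENTION,
    "ni": ExperimentClass.NEG_INTERVENTION,
    "pno": ExperimentClass.POS_NONINTERVENTION,
    "nno": ExperimentClass.NEG_NONINTERVENTION,
}

_OUTCOME_TOKENS = {
    "increase": Outcome.INCREASE,
    "no_change": Outcome.NO_CHANGE,
    "no change": Outcome.NO_CHANGE,
    "decrease": Outcome.DECREASE,
    "+": Outcome.INCREASE,
    "0": Outcome.NO_CHANGE,
    "-": Outcome.DECREASE,
    "b+": Outcome.INCREASE,
    "b0": Outcome.NO_CHANGE,
    "b-": Outcome.DECREASE,
}


def import_experiments_csv(src: PathOrStream) -> list[Experiment]:
    """Parse a CSV experiment table into Experiment records.

    Required columns: agent_what, target_what, class, outcome; optional:
    agent_where/when, target_where/when, methods, stat_test, p_value,
    source_id, experiment_id.  Class accepts both display symbols and
    names.  All row-level problems are collected and raised together
    with their row numbers.
    """
    if isinstance(src, (str, Path)):
        fh: IO[str] = open(src, newline="", encoding="utf-8")
        close = True
    else:
        fh, close = src, False
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CSVImportError(["row 1: missing header row"])
        missing = {"agent_what", "target_what", "class", "outcome"} - set(
            reader.fieldnames
        )
        if missing:
            raise CSVImportError([f"row 1: missing column(s) {sorted(missing)}"])
        out: list[Experiment] = []
        errors: list[str] = []
        for rownum, row in enumerate(reader, start=2):
            get = lambda k: (row.get(k) or "").strip()
            cls = _CLASS_TOKENS.get(get("class").casefold() or get("class"))
            if cls is None:
                cls = _CLASS_TOKENS.get(get("class"))
            if cls is None:
                errors.append(f"row {rownum}: unknown class token {get('class')!r}")
            outc = _OUTCOME_TOKENS.get(get("outcome").casefold())
            if outc is None:
                errors.append(f"row {rownum}: unknown outcome token {get('outcome')!r}")
            pv_raw = get("p_value")
            p_value: Optional[float] = None
            if pv_raw:
                try:
                    p_value = float(pv_raw)
                except ValueError:
                    errors.append(f"row {rownum}: bad p_value {pv_raw!r}")
            if cls is None or outc is None:
                continue
            try:
                out.append(
                    Experiment(
                        agent=Phenomenon(
                            get("agent_what"), get("agent_where"), get("agent_when")
                        ),
                        target=Phenomenon(
                            get("target_what"), get("target_where"), get("target_when")
                        ),
                        exp_class=cls,
                        outcome=outc,
                        experiment_id=get("experiment_id"),
                        agent_method=get("agent_method"),
                        target_method=get("target_method"),
                        stat_test=get("stat_test"),
                        p_value=p_value,
                        source_id=get("source_id"),
                    )
                )
            except EvimapError as exc:
                errors.append(f"row {rownum}: {exc}")
        if errors:
            raise CSVImportError(errors)
        return out
    finally:
        if close:
            fh.close()
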