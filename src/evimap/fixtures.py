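"""Seeded synthetic evidence-map generator.

Produces random but fully reproducible maps for tests, demos and
benchmarks.  Each empirical edge is given a designated "true" relation;
experiment outcomes then support that relation with probability
``agreement_prob`` and one of the other two relations otherwise, so the
generator controls how noisy the simulated literature is.  Default
sizes approximate a typical single-article curated map: about ten
phenomena, a dozen evidenced connections, and a mean of ~1.3
experiments per connection.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    EvimapError,
    Experiment,
    ExperimentClass,
    HypotheticalAssertion,
    Outcome,
    Phenomenon,
    Relation,
    outcome_to_relation,
)
from .model import ResearchMap
from .scoring import CLASS_ORDER

__all__ = ["generate_fixture"]

_WHERES = ["hippocampus", "amygdala", "cortex", "HEK293 cells", ""]
_WHENS = ["adult", "P21", "during training", ""]
_TRUE_RELATIONS = (Relation.EXCITATORY, Relation.NO_CONNECTION, Relation.INHIBITORY)


def _outcome_for(exp_class: ExperimentClass, relation: Relation) -> Outcome:
    """The unique outcome by which ``exp_class`` supports ``relation``."""
    for o in Outcome:
        if outcome_to_relation(exp_class, o) is relation:
            return o
    raise AssertionError("unreachable: mapping is total")


def generate_fixture(
    n_nodes: int = 10,
    n_empirical_edges: int = 13,
    n_hypothetical_edges: int = 3,
    experiments_per_edge_dist: Optional[Mapping[int, float]] = None,
    class_mix: Optional[Sequence[float]] = None,
    agreement_prob: float = 0.9,
    seed: int = 0,
    map_id: Optional[str] = None,
    shared_what_prob: float = 0.15,
) -> ResearchMap:
    """Generate a random evidence map, byte-reproducible for a given seed.

    Parameters
    ----------
    n_nodes, n_empirical_edges, n_hypothetical_edges
        Graph size; empirical and hypothetical edges occupy distinct
        directed node pairs.
    experiments_per_edge_dist
        Mapping count -> probability for the number of experiments per
        empirical edge (default {1: 0.75, 2: 0.2, 3: 0.05}).
    class_mix
        Probabilities over the four experiment classes in canonical
        order (default uniform).
    agreement_prob
        Probability that each experiment's outcome supports the edge's
        designated true relation.
    shared_what_prob
        Probability that a node reuses an earlier node's What with a
        different Where, so that what_only merging has something to
        collapse.

    The generation parameters are recorded in the map's metadata.
    """
    if n_nodes < 2:
        raise EvimapError("need at least 2 nodes")
    n_pairs = n_nodes * (n_nodes - 1)
    if n_empirical_edges + n_hypothetical_edges > n_pairs:
        raise EvimapError(
            f"{n_empirical_edges} empirical + {n_hypothetical_edges} hypothetical "
            f"edges exceed the {n_pairs} ordered pairs of {n_nodes} nodes"
        )
    if not 0.0 <= agreement_prob <= 1.0:
        raise EvimapError("agreement_prob must be in [0, 1]")
    dist = dict(experiments_per_edge_dist or {1: 0.75, 2: 0.2, 3: 0.05})
    if not dist or any(k < 1 for k in dist) or any(v < 0 for v in dist.values()):
        raise EvimapError("experiments_per_edge_dist must map counts >=1 to weights >=0")
    mix = np.asarray(class_mix if class_mix is not None else [0.25] * 4, dtype=float)
    if mix.shape != (4,) or (mix < 0).any() or mix.sum() == 0:
        raise EvimapError("class_mix must be 4 non-negative weights")
    mix = mix / mix.sum()

    rng = np.random.default_rng(seed)
    map_id = map_id if map_id is not None else f"synthetic-{seed}"

    nodes: list[Phenomenon] = []
    for i in range(n_nodes):
        if nodes and rng.random() < shared_what_prob:
            what = str(rng.choice([p.what for p in nodes]))
        else:
            what = f"Phen{i:02d}"
        where = str(rng.choice(_WHERES))
        when = str(rng.choice(_WHENS))
        p = Phenomenon(what, where, when)
        if p in nodes:  # identity collision: force a distinct node
            p = Phenomenon(f"Phen{i:02d}", where, when)
        if p in nodes:
            p = Phenomenon(f"Phen{i:02d}u", where, when)
        nodes.append(p)

    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    chosen = rng.choice(len(pairs), size=n_empirical_edges + n_hypothetical_edges,
                        replace=False)
    emp_pairs = [pairs[i] for i in chosen[:n_empirical_edges]]
    hyp_pairs = [pairs[i] for i in chosen[n_empirical_edges:]]

    counts = sorted(dist)
    weights = np.array([dist[k] for k in counts], dtype=float)
    weights = weights / weights.sum()

    m = ResearchMap(
        map_id=map_id,
        metadata={
            "generator": {
                "seed": int(seed),
                "n_nodes": n_nodes,
                "n_empirical_edges": n_empirical_edges,
                "n_hypothetical_edges": n_hypothetical_edges,
                "experiments_per_edge_dist": {str(k): dist[k] for k in counts},
                "class_mix": mix.tolist(),
                "agreement_prob": agreement_prob,
                "shared_what_prob": shared_what_prob,
            },
            "designated_relations": [],
        },
    )

    k = 0
    for (i, j) in emp_pairs:
        true_rel = _TRUE_RELATIONS[rng.integers(3)]
        m.metadata["designated_relations"].append(
            {
                "agent": {"what": nodes[i].what, "where": nodes[i].where, "when": nodes[i].when},
                "target": {"what": nodes[j].what, "where": nodes[j].where, "when": nodes[j].when},
                "relation": true_rel.value,
            }
        )
        n_exp = int(rng.choice(counts, p=weights))
        for _ in range(n_exp):
            exp_class = CLASS_ORDER[rng.choice(4, p=mix)]
            if rng.random() < agreement_prob:
                rel = true_rel
            else:
                others = [r for r in _TRUE_RELATIONS if r is not true_rel]
                rel = others[rng.integers(2)]
            m.add_experiment(
                Experiment(
                    agent=nodes[i],
                    target=nodes[j],
                    exp_class=exp_class,
                    outcome=_outcome_for(exp_class, rel),
                    experiment_id=f"{map_id}-e{k:04d}",
                    source_id=map_id,
                )
            )
            k += 1

    for (i, j) in hyp_pairs:
        m.add_hypothesis(
            HypotheticalAssertion(
                agent=nodes[i],
                target=nodes[j],
                relation=_TRUE_RELATIONS[rng.integers(3)],
                source_id=map_id,
            )
        )
    return m
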