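"""Bayesian evidence calculus for scoring empirical edges.

The evidence on one directed edge is summarised by a 4 x 3 count table
``x[c, r]``: the number of experiments of class ``c`` (Positive
Intervention, Positive Non-intervention, Negative Non-intervention,
Negative Intervention) supporting relation ``r`` (Excitatory,
No-connection, Inhibitory).  Each class's relation probabilities get a
Dirichlet prior (all-ones by default, i.e. Laplace add-one smoothing)
and a multinomial likelihood, so the posterior mean is

    E[theta_{c,r}] = (alpha_{c,r} + x_{c,r}) / (sum_r alpha_{c,r} + n_c).

Averaging each relation's component across the four classes gives the
convergence vector theta_bar; the edge's relation is theta_bar's unique
argmax and its score is

    score = (max theta_bar - theta_o) / (1 - theta_o),

where theta_o = 1/3 is the no-evidence baseline under uniform priors.
Repeated consistent results within one class raise the score by
diminishing amounts (consistency); agreeing results spread across
classes raise it faster (convergence).  Ties in theta_bar assign
neither a relation nor a score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    EvimapError,
    Experiment,
    ExperimentClass,
    Relation,
    outcome_to_relation,
)

__all__ = [
    "CLASS_ORDER",
    "RELATION_ORDER",
    "EvidenceCounts",
    "PriorWeights",
    "EvidenceScore",
    "posterior_means",
    "convergence_mean",
    "assign_relation",
    "edge_score",
    "baseline_theta",
    "score_counts",
    "score_edge",
    "score_trajectory",
    "TIE_TOL",
]

#: Canonical row order of the count/prior tables.
CLASS_ORDER: tuple[ExperimentClass, ...] = (
    ExperimentClass.POS_INTERVENTION,
    ExperimentClass.POS_NONINTERVENTION,
    ExperimentClass.NEG_NONINTERVENTION,
    ExperimentClass.NEG_INTERVENTION,
)

#: Canonical column order (scorable relations only).
RELATION_ORDER: tuple[Relation, ...] = (
    Relation.EXCITATORY,
    Relation.NO_CONNECTION,
    Relation.INHIBITORY,
)

_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}
_RELATION_INDEX = {r: j for j, r in enumerate(RELATION_ORDER)}

#: Absolute tolerance for the tie rule.  Counts are integers, so true
#: ties are exact in rational arithmetic; the tolerance only guards
#: float noise.
TIE_TOL = 1e-9


@dataclass(frozen=True)
class EvidenceCounts:
    """The 4 x 3 table x[c, r] of experiments per class per relation.

    Counts are the sufficient statistic of the calculus: any permutation
    of the same experiment multiset yields the same table and hence the
    same score.
    """

    x: np.ndarray  # shape (4, 3), non-negative integers

    def __post_init__(self) -> None:
        arr = np.asarray(self.x, dtype=np.int64)
        if arr.shape != (4, 3):
            raise EvimapError(f"counts table must be 4x3, got {arr.shape}")
        if (arr < 0).any():
            raise EvimapError("counts must be non-negative")
        object.__setattr__(self, "x", arr)
        arr.setflags(write=False)

    @classmethod
    def zeros(cls) -> "EvidenceCounts":
        return cls(np.zeros((4, 3), dtype=np.int64))

    @classmethod
    def from_experiments(cls, experiments: Iterable[Experiment]) -> "EvidenceCounts":
        x = np.zeros((4, 3), dtype=np.int64)
        for e in experiments:
            x[_CLASS_INDEX[e.exp_class], _RELATION_INDEX[e.supported_relation]] += 1
        return cls(x)

    def with_observation(
        self, exp_class: ExperimentClass, relation: Relation
    ) -> "EvidenceCounts":
        x = self.x.copy()
        x[_CLASS_INDEX[exp_class], _RELATION_INDEX[relation]] += 1
        return EvidenceCounts(x)

    @property
    def n_c(self) -> np.ndarray:
        """Per-class totals (row sums)."""
        return self.x.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.x.sum())

    def count(self, exp_class: ExperimentClass, relation: Relation) -> int:
        return int(self.x[_CLASS_INDEX[exp_class], _RELATION_INDEX[relation]])

    def __add__(self, other: "EvidenceCounts") -> "EvidenceCounts":
        return EvidenceCounts(self.x + other.x)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceCounts):
            return NotImplemented
        return bool((self.x == other.x).all())

    def __hash__(self) -> int:
        return hash(self.x.tobytes())


@dataclass(frozen=True)
class PriorWeights:
    """Dirichlet prior weights alpha[c, r], strictly positive.

    The all-ones default implements Laplace (add-one) smoothing and
    weights the four experiment classes equally; fields may be raised to
    favour evidence from particular classes.
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.alpha, dtype=float)
        if arr.shape != (4, 3):
            raise EvimapError(f"prior table must be 4x3, got {arr.shape}")
        if not (arr > 0).all():
            raise EvimapError("prior weights must be strictly positive")
        object.__setattr__(self, "alpha", arr)
        arr.setflags(write=False)

    @classmethod
    def laplace(cls) -> "PriorWeights":
        return cls(np.ones((4, 3)))


def posterior_means(
    counts: EvidenceCounts, priors: Optional[PriorWeights] = None
) -> np.ndarray:
    """Per-class Dirichlet posterior means, a 4 x 3 row-stochastic table.

    Entry (c, r) is (alpha_{c,r} + x_{c,r}) / (sum_r alpha_{c,r} + n_c);
    with all-ones priors this is add-one smoothing, (1 + x) / (3 + n).
    """
    priors = priors or PriorWeights.laplace()
    num = priors.alpha + counts.x
    return num / num.sum(axis=1, keepdims=True)


def convergence_mean(theta: np.ndarray) -> np.ndarray:
    """Average each relation's component across the four classes.

    The result theta_bar expresses convergence: it is large for a
    relation only when several classes' posteriors lean toward it.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (4, 3):
        raise EvimapError(f"theta must be 4x3, got {theta.shape}")
    return theta.mean(axis=0)


def assign_relation(theta_bar: np.ndarray, tol: float = TIE_TOL) -> Relation:
    """The relation with the strictly largest theta_bar component.

    Any tie for the maximum (within ``tol``) yields INDETERMINATE: the
    evidence does not single out one relation.
    """
    theta_bar = np.asarray(theta_bar, dtype=float)
    top = theta_bar.max()
    winners = np.flatnonzero(theta_bar >= top - tol)
    if len(winners) > 1:
        return Relation.INDETERMINATE
    return RELATION_ORDER[int(winners[0])]


def baseline_theta(priors: Optional[PriorWeights] = None) -> float:
    """No-evidence baseline theta_o.

    Under uniform priors this is 1/3.  For non-uniform priors it is the
    largest component of the zero-evidence convergence vector, so that
    the score is zero when no experiments have been recorded.
    """
    if priors is None:
        return 1.0 / 3.0
    theta0 = posterior_means(EvidenceCounts.zeros(), priors)
    return float(convergence_mean(theta0).max())


def edge_score(
    theta_bar: np.ndarray,
    theta_o: float = 1.0 / 3.0,
    tol: float = TIE_TOL,
) -> Optional[float]:
    """Scalar edge score (max theta_bar - theta_o) / (1 - theta_o).

    Returns None when the maximum is tied (no relation assignable).
    """
    if assign_relation(theta_bar, tol=tol) is Relation.INDETERMINATE:
        return None
    return float((np.asarray(theta_bar).max() - theta_o) / (1.0 - theta_o))


@dataclass(frozen=True)
class EvidenceScore:
    """Full scoring state of one directed edge."""

    counts: EvidenceCounts
    theta: np.ndarray  # 4x3 posterior means
    theta_bar: np.ndarray  # 3-vector
    theta_o: float
    relation: Relation
    score: Optional[float]

    def symbols(self) -> str:
        """Experiment-class glyphs, one per recorded experiment."""
        out = []
        for i, c in enumerate(CLASS_ORDER):
            out.extend([c.symbol] * int(self.counts.n_c[i]))
        return " ".join(out)


def score_counts(
    counts: EvidenceCounts, priors: Optional[PriorWeights] = None
) -> EvidenceScore:
    """Score a count table: posteriors, convergence, relation, score."""
    theta = posterior_means(counts, priors)
    tb = convergence_mean(theta)
    to = baseline_theta(priors)
    rel = assign_relation(tb)
    sc = None if rel is Relation.INDETERMINATE else edge_score(tb, to)
    return EvidenceScore(
        counts=counts, theta=theta, theta_bar=tb, theta_o=to, relation=rel, score=sc
    )


def score_edge(
    experiments: Sequence[Experiment], priors: Optional[PriorWeights] = None
) -> EvidenceScore:
    """Score the evidence of one directed edge.

    All experiments must share the same (agent, target) pair; the score
    depends only on the resulting count table, not on input order.
    """
    experiments = list(experiments)
    pairs = {e.edge for e in experiments}
    if len(pairs) > 1:
        raise EvimapError(
            f"experiments span {len(pairs)} distinct (agent, target) pairs"
        )
    return score_counts(EvidenceCounts.from_experiments(experiments), priors)


def score_trajectory(
    experiments: Sequence[Experiment], priors: Optional[PriorWeights] = None
) -> list[EvidenceScore]:
    """Score every prefix of an ordered experiment list.

    Element k is the EvidenceScore after the first k+1 experiments,
    tracing how the edge's score grows (or drops) as results accrue.
    """
    experiments = list(experiments)
    pairs = {e.edge for e in experiments}
    if len(pairs) > 1:
        raise EvimapError(
            f"experiments span {len(pairs)} distinct (agent, target) pairs"
        )
    out: list[EvidenceScore] = []
    counts = EvidenceCounts.zeros()
    for e in experiments:
        counts = counts.with_observation(e.exp_class, e.supported_relation)
        out.append(score_counts(counts, priors))
    return out
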