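"""Evidence-calculus tests: posterior means, convergence, relation, score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evimap import (
    CLASS_ORDER,
    EvidenceCounts,
    EvimapError,
    Phenomenon,
    PriorWeights,
    Relation,
    assign_relation,
    baseline_theta,
    convergence_mean,
    edge_score,
    posterior_means,
    score_counts,
    score_edge,
    score_trajectory,
)

from conftest import C, O, R, mk, oracle_score


def experiments_on(pair, spec):
    """[(class, outcome), ...] -> experiments on one fixed edge."""
    a, b = pair
    return [
        mk(a, b, c, o, f"e{i}") for i, (c, o) in enumerate(spec)
    ]


@pytest.fixture
def ab():
    return (Phenomenon("A"), Phenomenon("B"))


class TestPosteriorMeans:
    def test_no_evidence_is_uniform(self):
        theta = posterior_means(EvidenceCounts.zeros())
        assert np.allclose(theta, 1.0 / 3.0)

    @pytest.mark.parametrize(
        "n_row,expected",
        [
            ((0, 1, 0), (0.25, 0.50, 0.25)),
            ((0, 2, 0), (0.2, 0.6, 0.2)),
        ],
    )
    def test_laplace_smoothing_row(self, n_row, expected):
        x = np.zeros((4, 3), dtype=int)
        x[0] = n_row
        theta = posterior_means(EvidenceCounts(x))
        assert np.allclose(theta[0], expected)
        assert np.allclose(theta[1:], 1.0 / 3.0)

    def test_rows_sum_to_one_under_any_priors(self):
        x = np.arange(12).reshape(4, 3)
        priors = PriorWeights(np.full((4, 3), 0.5))
        theta = posterior_means(EvidenceCounts(x), priors)
        assert np.allclose(theta.sum(axis=1), 1.0)

    def test_non_positive_prior_rejected(self):
        with pytest.raises(EvimapError):
            PriorWeights(np.zeros((4, 3)))


class TestConvergenceMean:
    def test_uniform_rows(self):
        assert np.allclose(convergence_mean(np.full((4, 3), 1 / 3)), 1 / 3)

    def test_single_informative_row(self):
        theta = np.full((4, 3), 1 / 3)
        theta[0] = (0.25, 0.5, 0.25)
        assert convergence_mean(theta)[1] == pytest.approx(0.375)

    def test_two_informative_rows(self):
        theta = np.full((4, 3), 1 / 3)
        theta[0] = (0.2, 0.6, 0.2)
        theta[3] = (0.25, 0.5, 0.25)
        assert convergence_mean(theta)[1] == pytest.approx(0.4417, abs=5e-5)


class TestAssignRelation:
    def test_uniform_is_indeterminate(self):
        assert assign_relation(np.array([1 / 3] * 3)) is R.INDETERMINATE

    def test_two_way_tie_is_indeterminate(self):
        assert assign_relation(np.array([0.45, 0.45, 0.10])) is R.INDETERMINATE

    def test_dominant_middle_component(self):
        tb = np.array([0.3208, 0.4208, 0.2583])
        assert assign_relation(tb) is R.NO_CONNECTION

    def test_near_tie_within_tolerance(self):
        tb = np.array([0.4, 0.4 + 1e-12, 0.2])
        assert assign_relation(tb) is R.INDETERMINATE


class TestEdgeScore:
    @pytest.mark.parametrize("theta_n,expected", [(0.375, 0.0625), (0.4, 0.1000)])
    def test_paper_values(self, theta_n, expected):
        rest = (1 - theta_n) / 2
        tb = np.array([rest, theta_n, rest])
        assert edge_score(tb) == pytest.approx(expected)

    def test_tied_maximum_has_no_score(self):
        assert edge_score(np.array([1 / 3] * 3)) is None

    def test_nonuniform_prior_baseline_gives_zero_at_no_evidence(self):
        priors = PriorWeights(np.array([[4.0, 1, 1]] + [[1.0, 1, 1]] * 3))
        ev = score_counts(EvidenceCounts.zeros(), priors)
        # relation may be assignable from the prior alone, but the score
        # starts at zero because theta_o is the zero-evidence maximum
        if ev.score is not None:
            assert ev.score == pytest.approx(0.0, abs=1e-12)


class TestScoreEdge:
    def test_worked_example_final_state(self, worked_example):
        ev = score_edge(worked_example)
        assert ev.relation is R.NO_CONNECTION
        assert ev.score == pytest.approx(0.1625)

    def test_conflicting_fourth_nonintervention(self, worked_example, creb, arc):
        ev = score_edge(
            worked_example + [mk(creb, arc, C.POS_NONINTERVENTION, O.INCREASE, "e4")]
        )
        assert ev.relation is R.NO_CONNECTION  # still-dominant evidence
        assert round(ev.score, 4) == 0.1313

    def test_conflicting_fourth_same_class(self, worked_example, creb, arc):
        ev = score_edge(
            worked_example + [mk(creb, arc, C.POS_INTERVENTION, O.INCREASE, "e4")]
        )
        assert ev.score == pytest.approx(0.1250)

    def test_convergent_excitatory_configuration(self, ab):
        # four agent-up interventions with increases plus one conflicting
        # positive non-intervention and one agreeing negative one
        spec = [(C.POS_INTERVENTION, O.INCREASE)] * 4 + [
            (C.POS_NONINTERVENTION, O.DECREASE),
            (C.NEG_NONINTERVENTION, O.DECREASE),
        ]
        ev = score_edge(experiments_on(ab, spec))
        assert ev.relation is R.EXCITATORY
        assert ev.counts.x[:, 0].sum() == 5  # five experiments count excitatory
        assert ev.counts.x[:, 2].sum() == 1  # one counts inhibitory
        assert ev.score == pytest.approx(39 / 224)

    def test_mixed_pairs_rejected(self, ab):
        a, b = ab
        c = Phenomenon("C")
        with pytest.raises(EvimapError, match="distinct"):
            score_edge(
                [
                    mk(a, b, C.POS_INTERVENTION, O.INCREASE, "e1"),
                    mk(a, c, C.POS_INTERVENTION, O.INCREASE, "e2"),
                ]
            )


class TestScoreTrajectory:
    def test_worked_example_sequence(self, worked_example):
        traj = score_trajectory(worked_example)
        assert [pytest.approx(t.score) for t in traj] == [0.0625, 0.1000, 0.1625]
        assert np.allclose(traj[0].theta[0], (0.25, 0.50, 0.25))

    def test_consistency_increments_decay(self, ab):
        traj = score_trajectory(
            experiments_on(ab, [(C.POS_INTERVENTION, O.NO_CHANGE)] * 2)
        )
        assert traj[0].score == pytest.approx(0.0625)
        assert traj[1].score - traj[0].score == pytest.approx(0.0375)

    def test_one_per_class_reaches_quarter(self, ab):
        traj = score_trajectory(
            experiments_on(ab, [(c, O.NO_CHANGE) for c in CLASS_ORDER])
        )
        assert traj[-1].score == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# Properties

def test_consistency_only_growth_is_increasing_with_decaying_increments(ab):
    traj = score_trajectory(
        experiments_on(ab, [(C.POS_INTERVENTION, O.NO_CHANGE)] * 8)
    )
    scores = [t.score for t in traj]
    increments = np.diff([0.0] + scores)
    assert (increments > 0).all()
    assert (np.diff(increments) < 0).all()


@pytest.mark.parametrize("k", [2, 3, 4])
def test_convergence_dominates_consistency(ab, k):
    one_class = score_trajectory(
        experiments_on(ab, [(C.POS_INTERVENTION, O.NO_CHANGE)] * k)
    )[-1].score
    spread = score_trajectory(
        experiments_on(ab, [(c, O.NO_CHANGE) for c in CLASS_ORDER[:k]])
    )[-1].score
    assert spread > one_class


def test_class_contribution_bounds(ab):
    # a fully agreeing class contributes (3/8)(theta_c - 1/3) in (0, 0.25)
    for n in range(1, 20):
        spec = [(C.POS_INTERVENTION, O.NO_CHANGE)] * n
        ev = score_edge(experiments_on(ab, spec))
        contrib = (3 / 8) * (ev.theta[0][1] - 1 / 3)
        assert 0 < contrib < 0.25


_random_specs = st.lists(
    st.tuples(st.sampled_from(list(C)), st.sampled_from(list(O))),
    min_size=1,
    max_size=12,
)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(spec=_random_specs, perm_seed=st.integers(0, 2**31 - 1))
def test_order_invariance_and_oracle_agreement(spec, perm_seed):
    """Scores match the brute-force table oracle and ignore input order."""
    a, b = Phenomenon("A"), Phenomenon("B")
    exps = experiments_on((a, b), spec)
    ev = score_edge(exps)
    rel, score = oracle_score(exps)
    assert ev.relation is rel
    if score is None:
        assert ev.score is None
    else:
        assert ev.score == pytest.approx(score, abs=1e-12)
        assert 0 < ev.score < 1

    rng = np.random.default_rng(perm_seed)
    shuffled = [exps[i] for i in rng.permutation(len(exps))]
    ev2 = score_edge(shuffled)
    assert ev2.relation is ev.relation
    assert ev2.score == ev.score


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    n_agree=st.integers(1, 8),
    conflicting=st.tuples(st.sampled_from(list(C)), st.sampled_from([O.INCREASE, O.DECREASE])),
)
def test_conflicting_result_strictly_decreases_score(n_agree, conflicting):
    """One disagreeing experiment lowers the score while N stays dominant."""
    a, b = Phenomenon("A"), Phenomenon("B")
    base = experiments_on(
        (a, b), [(CLASS_ORDER[i % 4], O.NO_CHANGE) for i in range(n_agree)]
    )
    before = score_edge(base)
    after = score_edge(base + experiments_on((a, b), [conflicting]))
    if after.relation is R.NO_CONNECTION:
        assert after.score < before.score
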