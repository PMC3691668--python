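"""Differential-evolution search: moves, population invariants, convergence."""

import math

import numpy as np
import pytest

from falcongo.dag import is_consistent, up_propagate
from falcongo.objectives import EPS, ObjectiveSpec
from falcongo.optimizer import (
    OptimizerConfig,
    Population,
    evolve,
    initialize_population,
    make_scorer,
    predict_protein,
    propose_candidate,
)
from falcongo.oracle import exhaustive_best
from falcongo.synthetic import random_dag

SPEC_EQ1 = ObjectiveSpec("eq1")


def make_population(members, dag, theta=None, priors=None, spec=SPEC_EQ1):
    members = np.asarray(members, bool)
    theta = theta if theta is not None else np.full(dag.n_terms, 0.5)
    priors = priors if priors is not None else np.full(dag.n_terms, 0.5)
    scorer = make_scorer(theta, priors, dag, spec)
    return Population(members=members, scores=np.array([scorer(m) for m in members]))


class TestInitializePopulation:
    def test_default_size_is_twice_terms(self, dag6, rng):
        pop = initialize_population(
            rng.random(6), np.full(6, 0.5), dag6, SPEC_EQ1, OptimizerConfig(), rng
        )
        assert pop.size == 12

    def test_all_members_consistent(self, dag15, rng):
        pop = initialize_population(
            rng.random(15), np.full(15, 0.5), dag15, SPEC_EQ1, OptimizerConfig(), rng
        )
        assert all(is_consistent(m, dag15) for m in pop.members)

    def test_extreme_low_theta_gives_near_empty_population(self, dag6, rng):
        pop = initialize_population(
            np.full(6, EPS), np.full(6, 0.5), dag6, SPEC_EQ1, OptimizerConfig(), rng
        )
        assert pop.members.sum() == 0

    def test_extreme_high_theta_gives_full_population(self, dag6, rng):
        pop = initialize_population(
            np.full(6, 1 - EPS), np.full(6, 0.5), dag6, SPEC_EQ1,
            OptimizerConfig(), rng,
        )
        # all random members full; only the seeded empty member is not
        assert pop.members[1:].all()

    def test_empty_labeling_always_representable(self, dag6, rng):
        pop = initialize_population(
            rng.random(6), np.full(6, 0.5), dag6, SPEC_EQ1, OptimizerConfig(), rng
        )
        assert not pop.members[0].any()

    def test_scores_match_objective(self, dag6, rng):
        theta, priors = rng.random(6), np.full(6, 0.5)
        pop = initialize_population(
            theta, priors, dag6, SPEC_EQ1, OptimizerConfig(), rng
        )
        scorer = make_scorer(theta, priors, dag6, SPEC_EQ1)
        np.testing.assert_allclose(
            pop.scores, [scorer(m) for m in pop.members]
        )


class TestProposeCandidate:
    def test_from_all_zero_population_candidate_is_e(self, dag6, rng):
        pop = make_population(np.zeros((4, 6)), dag6)
        for strategy in ("S1", "S2", "S3", "S4"):
            cand = propose_candidate(0, pop, dag6, strategy, rng)
            assert is_consistent(cand, dag6)
            assert cand.any()  # e is never empty

    def test_union_absorbs_full_member(self, dag6, rng):
        members = np.zeros((4, 6), bool)
        members[1] = True  # R1 or R2 will sometimes be the full labeling
        pop = make_population(members, dag6)
        full_seen = any(
            propose_candidate(0, pop, dag6, "S3", rng).all() for _ in range(50)
        )
        assert full_seen

    def test_small_population_rejected(self, dag6, rng):
        pop = make_population(np.zeros((2, 6)), dag6)
        with pytest.raises(ValueError, match="at least 3"):
            propose_candidate(0, pop, dag6, "S1", rng)

    def test_alternative_s4_grouping_is_subset_of_target_plus_e(self, dag6, rng):
        members = np.ones((5, 6), bool)
        members[0] = up_propagate(["t2"], dag6)
        pop = make_population(members, dag6)
        cand = propose_candidate(0, pop, dag6, "S4", rng, s4_grouping="local_pair")
        # (Ri ∧ (R1∨R2)) ∨ e with Ri small: candidate ⊆ Ri ∪ e
        assert is_consistent(cand, dag6)

    def test_proposals_always_consistent_on_random_dag(self, rng):
        dag = random_dag(20, 2, rng)
        members = np.zeros((8, 20), bool)
        for i in range(8):
            members[i] = up_propagate(
                [dag.terms[int(rng.integers(20))]], dag
            )
        pop = make_population(members, dag)
        strategies = ("S1", "S2", "S3", "S4")
        for k in range(2000):
            cand = propose_candidate(
                int(rng.integers(8)), pop, dag, strategies[k % 4], rng
            )
            assert is_consistent(cand, dag)


class TestEvolve:
    def test_single_node_positive_theta(self):
        dag = random_dag(1, 1, 0)
        res = evolve(
            np.array([0.9]), np.array([0.5]), dag, SPEC_EQ1,
            OptimizerConfig(max_generations=50, plateau_generations=10,
                            stale_rounds=2),
            np.random.default_rng(0),
        )
        assert res.best.tolist() == [True]
        assert res.best_score == pytest.approx(math.log(0.9))

    def test_deltal_null_best_is_zero(self, dag6, rng):
        theta = rng.random(6)
        res = evolve(
            theta, theta, dag6, ObjectiveSpec("deltal"),
            OptimizerConfig(max_generations=200, plateau_generations=20,
                            stale_rounds=2),
            rng,
        )
        assert res.best_score == pytest.approx(0.0, abs=1e-9)

    def test_best_score_non_decreasing(self, dag15, rng):
        res = evolve(rng.random(15), np.full(15, 0.5), dag15, SPEC_EQ1,
                     OptimizerConfig(max_generations=500), rng)
        assert np.all(np.diff(res.history) >= 0)
        assert is_consistent(res.best, dag15)

    def test_seeded_runs_bit_reproducible(self, dag6):
        theta = np.random.default_rng(5).random(6)
        runs = [
            evolve(theta, np.full(6, 0.5), dag6, SPEC_EQ1,
                   OptimizerConfig(max_generations=300),
                   np.random.default_rng(42))
            for _ in range(2)
        ]
        assert runs[0].best_score == runs[1].best_score
        assert (runs[0].best == runs[1].best).all()
        assert runs[0].history == runs[1].history

    def test_never_exceeds_exhaustive_optimum(self, dag6, rng):
        for _ in range(10):
            theta = rng.random(6)
            res = evolve(theta, np.full(6, 0.5), dag6, SPEC_EQ1,
                         OptimizerConfig(max_generations=500), rng)
            ex = exhaustive_best(dag6, theta, np.full(6, 0.5), SPEC_EQ1)
            assert res.best_score <= ex.best_score + 1e-9

    def test_all_diamond_labelings_reachable_as_optima(self, diamond_dag):
        """Each of the 6 consistent diamond labelings is recovered when the
        probability vector makes it the unique optimum."""
        hi, lo = 0.95, 0.05
        targets = {
            (0, 0, 0, 0): [lo, lo, lo, lo],
            (1, 0, 0, 0): [hi, lo, lo, lo],
            (1, 1, 0, 0): [hi, hi, lo, lo],
            (1, 0, 1, 0): [hi, lo, hi, lo],
            (1, 1, 1, 0): [hi, hi, hi, lo],
            (1, 1, 1, 1): [hi, hi, hi, hi],
        }
        for target, theta in targets.items():
            res = evolve(
                np.array(theta), np.full(4, 0.5), diamond_dag, SPEC_EQ1,
                OptimizerConfig(max_generations=400), np.random.default_rng(7),
            )
            assert tuple(res.best.astype(int)) == target


class TestPredictProtein:
    def test_theta_below_priors_deltal_predicts_nothing(self, dag6, rng):
        theta = np.full(6, 0.2)
        priors = np.full(6, 0.6)
        pred = predict_protein(
            theta, priors, dag6, ObjectiveSpec("deltal"),
            OptimizerConfig(max_generations=300), rng,
        )
        assert pred.terms == ()

    def test_confident_path_recovered(self, dag6, rng):
        truth = up_propagate(["t6"], dag6)
        theta = np.where(truth, 1 - EPS, EPS)
        pred = predict_protein(
            theta, np.full(6, 0.5), dag6, SPEC_EQ1,
            OptimizerConfig(max_generations=300), rng,
        )
        assert set(pred.terms) == {t for t, v in zip(dag6.terms, truth) if v}

    def test_output_ancestrally_closed(self, dag15, rng):
        pred = predict_protein(
            rng.random(15), np.full(15, 0.5), dag15, SPEC_EQ1,
            OptimizerConfig(max_generations=300), rng,
        )
        closed = up_propagate(pred.terms, dag15)
        assert set(pred.terms) == {
            t for t, v in zip(dag15.terms, closed) if v
        }
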