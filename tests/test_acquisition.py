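import math

import numpy as np
import pytest

from almol.acquisition import (
    _mi_matrix,
    epig_scores,
    greedy_scores,
    pairwise_mi,
    select_batch,
    target_distribution,
    uncertainty_scores,
    TargetDistribution,
)
from almol.errors import ConfigurationError, DegenerateDistributionError
from almol.scoring import ScoredMolecule
from conftest import synthetic_molecule

LN2 = math.log(2)


class FakeForest:
    """A predictor stub whose per-tree outcomes are fixed per molecule.

    Molecules are identified by the integer stored at fingerprint position 0,
    which indexes rows of the outcome matrix.
    """

    def __init__(self, outcomes, task="classification"):
        self.outcomes = np.asarray(outcomes, dtype=float)
        self.task = task

    def tree_predictions(self, X):
        rows = np.atleast_2d(X)[:, 0].astype(int)
        return self.outcomes[rows]


def _indexed_molecules(n, dim=4):
    mols = []
    for i in range(n):
        fp = np.zeros(dim, dtype=np.int64)
        fp[0] = i
        mols.append(synthetic_molecule(f"idx{i}", fp))
    return mols


def brute_force_mi(votes_x, votes_y):
    """Independent MI oracle: enumerate the 2x2 joint by counting trees."""
    B = len(votes_x)
    joint = np.zeros((2, 2))
    for vx, vy in zip(votes_x, votes_y):
        joint[int(vx), int(vy)] += 1.0 / B
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log(joint[a, b] / (px[a] * py[b]))
    return mi


class TestTargetDistribution:
    def _scored(self, totals):
        mols = _indexed_molecules(len(totals))
        return [
            ScoredMolecule(m, {"predictor": t}, t) for m, t in zip(mols, totals)
        ]

    def test_weights_proportional_to_scores(self):
        target = target_distribution(self._scored([0.6, 0.2]), k=2)
        np.testing.assert_allclose(sorted(target.weights), [0.25, 0.75])

    def test_equal_scores_give_uniform_weights(self):
        target = target_distribution(self._scored([0.4] * 5), k=5)
        np.testing.assert_allclose(target.weights, 0.2)

    def test_weights_sum_to_one_and_top_k_respected(self):
        target = target_distribution(self._scored([0.9, 0.5, 0.1, 0.3]), k=2)
        assert target.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(target.members) == 2
        assert {m.smiles for m in target.members} == {"idx0", "idx1"}

    def test_all_zero_scores_raise(self):
        with pytest.raises(DegenerateDistributionError):
            target_distribution(self._scored([0.0, 0.0]), k=2)

    def test_empty_pool_rejected(self):
        with pytest.raises(ConfigurationError):
            target_distribution([], k=5)


class TestPairwiseMI:
    def test_perfectly_coupled_outcomes_give_ln2(self):
        forest = FakeForest([[0, 1], [0, 1]])
        x, x_star = _indexed_molecules(2)
        assert pairwise_mi(forest, x, x_star) == pytest.approx(LN2, abs=1e-12)

    def test_constant_target_outcome_gives_zero(self):
        forest = FakeForest([[0, 1], [1, 1]])
        x, x_star = _indexed_molecules(2)
        assert pairwise_mi(forest, x, x_star) == pytest.approx(0.0, abs=1e-12)

    def test_independent_outcomes_give_zero(self):
        forest = FakeForest([[0, 0, 1, 1], [0, 1, 0, 1]])
        x, x_star = _indexed_molecules(2)
        assert pairwise_mi(forest, x, x_star) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 150:
            B = int(rng.integers(2, 9))
            votes = rng.integers(0, 2, size=(2, B))
            forest = FakeForest(votes)
            x, x_star = _indexed_molecules(2)
            expected = brute_force_mi(votes[0], votes[1])
            assert pairwise_mi(forest, x, x_star) == pytest.approx(
                expected, abs=1e-12
            )
            checked += 1

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            B = int(rng.integers(2, 9))
            votes = rng.integers(0, 2, size=(2, B))
            forest = FakeForest(votes)
            x, x_star = _indexed_molecules(2)

            def entropy(v):
                p = v.mean()
                if p in (0.0, 1.0):
                    return 0.0
                return -(p * math.log(p) + (1 - p) * math.log(1 - p))

            mi = pairwise_mi(forest, x, x_star)
            assert mi <= min(entropy(votes[0]), entropy(votes[1])) + 1e-12


class TestEpigScores:
    def test_agreeing_trees_give_zero_everywhere(self):
        forest = FakeForest([[1, 1], [1, 1], [1, 1]])
        mols = _indexed_molecules(3)
        target = TargetDistribution(
            members=(mols[2],), weights=np.array([1.0])
        )
        scores = epig_scores(forest, mols[:2], target)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in scores.values())

    def test_reduces_to_pairwise_mi_for_single_target(self):
        forest = FakeForest([[0, 1], [0, 1]])
        mols = _indexed_molecules(2)
        target = TargetDistribution(members=(mols[1],), weights=np.array([1.0]))
        scores = epig_scores(forest, [mols[0]], target)
        assert scores["idx0"] == pytest.approx(LN2, abs=1e-12)

    def test_nonnegative_for_random_forests(self):
        rng = np.random.default_rng(5)
        votes = rng.integers(0, 2, size=(10, 6))
        forest = FakeForest(votes)
        mols = _indexed_molecules(10)
        target = TargetDistribution(
            members=tuple(mols[:4]), weights=np.full(4, 0.25)
        )
        scores = epig_scores(forest, mols, target)
        assert all(v >= 0 for v in scores.values())

    def test_invariant_to_duplicating_members_with_halved_weights(self):
        rng = np.random.default_rng(6)
        votes = rng.integers(0, 2, size=(6, 8))
        forest = FakeForest(votes)
        mols = _indexed_molecules(6)
        members = tuple(mols[:3])
        base = epig_scores(
            forest, mols[3:], TargetDistribution(members, np.full(3, 1 / 3))
        )
        doubled = epig_scores(
            forest,
            mols[3:],
            TargetDistribution(members + members, np.full(6, 1 / 6)),
        )
        for key in base:
            assert base[key] == pytest.approx(doubled[key], abs=1e-12)

    def test_empty_target_rejected(self):
        forest = FakeForest([[0, 1]])
        mols = _indexed_molecules(1)
        target = TargetDistribution(members=(), weights=np.array([1.0]))
        with pytest.raises(ConfigurationError):
            epig_scores(forest, mols, target)


class TestUncertaintyScores:
    def test_classification_entropy_closed_forms(self):
        forest = FakeForest([[0, 1], [1, 1], [0, 0]])
        mols = _indexed_molecules(3)
        scores = uncertainty_scores(forest, mols)
        assert scores["idx0"] == pytest.approx(LN2, abs=1e-12)
        assert scores["idx1"] == pytest.approx(0.0, abs=1e-12)
        assert scores["idx2"] == pytest.approx(0.0, abs=1e-12)

    def test_regression_population_variance(self):
        forest = FakeForest([[1, 2, 3]], task="regression")
        mols = _indexed_molecules(1)
        scores = uncertainty_scores(forest, mols)
        assert scores["idx0"] == pytest.approx(2 / 3, abs=1e-12)

    def test_entropy_symmetric_about_half_and_maximal_there(self):
        # vote fractions p and 1-p give equal entropy, maximized at 1/2
        forest = FakeForest(
            [[1, 0, 0, 0], [1, 1, 1, 0], [1, 1, 0, 0]]
        )
        mols = _indexed_molecules(3)
        scores = uncertainty_scores(forest, mols)
        assert scores["idx0"] == pytest.approx(scores["idx1"], abs=1e-12)
        assert scores["idx2"] > scores["idx0"]
        assert scores["idx2"] == pytest.approx(LN2, abs=1e-12)


class TestGreedyAndSelection:
    def _scored(self, totals):
        mols = _indexed_molecules(len(totals))
        return [ScoredMolecule(m, {"predictor": t}, t) for m, t in zip(mols, totals)]

    def test_greedy_is_identity_on_stored_scores(self):
        pool = self._scored([0.9, 0.3])
        assert greedy_scores(pool) == {"idx0": 0.9, "idx1": 0.3}
        assert greedy_scores(pool, "predictor") == {"idx0": 0.9, "idx1": 0.3}
        assert greedy_scores([]) == {}

    def test_top_t_selection(self):
        pool = self._scored([0.9, 0.5, 0.1])
        mols = [s.molecule for s in pool]
        result = select_batch(
            {"idx0": 0.9, "idx1": 0.5, "idx2": 0.1}, mols, T=2, criterion="greedy"
        )
        assert [m.smiles for m in result.batch] == ["idx0", "idx1"]

    def test_ties_break_lexicographically(self):
        mols = _indexed_molecules(3)
        scores = {m.smiles: 0.5 for m in mols}
        result = select_batch(scores, mols, T=2, criterion="uncertainty")
        assert [m.smiles for m in result.batch] == ["idx0", "idx1"]

    def test_random_selection_is_seeded(self):
        mols = _indexed_molecules(20)
        scores = {m.smiles: 0.0 for m in mols}
        a = select_batch(scores, mols, T=5, criterion="random", seed=99)
        b = select_batch(scores, mols, T=5, criterion="random", seed=99)
        assert [m.smiles for m in a.batch] == [m.smiles for m in b.batch]
        assert len({m.smiles for m in a.batch}) == 5

    def test_excluded_molecules_never_selected(self):
        mols = _indexed_molecules(4)
        scores = {m.smiles: float(i) for i, m in enumerate(mols)}
        result = select_batch(
            scores, mols, T=4, criterion="greedy", exclude={"idx3", "idx2"}
        )
        assert {m.smiles for m in result.batch} == {"idx0", "idx1"}

    def test_oversized_t_returns_whole_pool(self):
        mols = _indexed_molecules(3)
        scores = {m.smiles: 1.0 for m in mols}
        result = select_batch(scores, mols, T=10, criterion="greedy")
        assert len(result.batch) == 3

    def test_fully_excluded_pool_yields_empty_batch(self):
        mols = _indexed_molecules(2)
        result = select_batch(
            {m.smiles: 1.0 for m in mols}, mols, T=1, criterion="greedy",
            exclude={"idx0", "idx1"},
        )
        assert result.batch == ()


def test_mi_matrix_agrees_with_real_forest_votes(toy_classifier, separable_set):
    # an actual fitted forest: MI computed by the vectorized joint must match
    # the brute-force enumeration of tree votes for every pair
    from almol.chemio import fingerprint_matrix

    X = fingerprint_matrix(separable_set.molecules[:6])
    votes = toy_classifier.tree_predictions(X)
    mi = _mi_matrix(votes, votes)
    for i in range(6):
        for j in range(6):
            assert mi[i, j] == pytest.approx(
                brute_force_mi(votes[i], votes[j]), abs=1e-12
            )
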