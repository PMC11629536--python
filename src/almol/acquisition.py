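"""Acquisition criteria for querying the expert: EPIG, uncertainty, greedy,
random.

The forest's B trees are treated as B posterior parameter samples, so every
molecule carries a B-vector of predictive outcomes.  EPIG scores a candidate
x by the expected mutual information between its outcome and the outcome at
target inputs x* drawn from a score-weighted distribution over the top-k
pool molecules: informative candidates are those whose label would most
reduce uncertainty where the generator is succeeding.

Predictive outcomes are binary: classification trees vote {0, 1} natively;
regression tree outputs are binarized through the scoring transform at 0.5
("predicted in the desired range" vs not), which matches the high-scoring
semantics of the target distribution and keeps the closed-form 2x2 mutual
information for both tasks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chemio import Molecule, fingerprint_matrix
from .errors import ConfigurationError, DegenerateDistributionError
from .predictor import EnsemblePredictor
from .scoring import ScoredMolecule, Transform


@dataclass(frozen=True)
class TargetDistribution:
    """Score-weighted distribution over the top-k pool molecules."""

    members: tuple[Molecule, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("target weights must sum to 1")


@dataclass(frozen=True)
class AcquisitionResult:
    """Scores over the pool and the ordered query batch drawn from them."""

    criterion: str
    scores: Mapping[str, float]  # canonical SMILES -> score
    batch: tuple[Molecule, ...]


def target_distribution(pool: Sequence[ScoredMolecule], k: int) -> TargetDistribution:
    """Top-min(k, |pool|) molecules by transformed score, weighted by score.

    Raises :class:`DegenerateDistributionError` when every member score is 0
    (the caller decides whether to fall back to uniform).
    """
    if len(pool) == 0:
        raise ConfigurationError("target distribution needs a nonempty pool")
    # sort by score desc, ties broken by canonical SMILES for determinism
    ranked = sorted(pool, key=lambda s: (-s.total, s.smiles))
    top = ranked[: min(k, len(ranked))]
    scores = np.array([s.total for s in top], dtype=float)
    total = scores.sum()
    if total <= 0:
        raise DegenerateDistributionError("all top-k scores are zero")
    return TargetDistribution(
        members=tuple(s.molecule for s in top), weights=scores / total
    )


def binary_outcomes(
    predictor: EnsemblePredictor,
    molecules: Sequence[Molecule],
    transform: Transform | None = None,
) -> np.ndarray:
    """Per-tree binary outcome matrix of shape (n, B).

    Classification: the tree votes themselves.  Regression: each tree output
    is passed through ``transform`` and thresholded at 0.5.
    """
    preds = predictor.tree_predictions(fingerprint_matrix(molecules))
    if predictor.task == "classification":
        return (preds > 0.5).astype(np.float64)
    if transform is None:
        raise ConfigurationError(
            "regression acquisition requires the scoring transform to binarize tree outputs"
        )
    return (np.asarray(transform(preds)) >= 0.5).astype(np.float64)


def _mi_matrix(outcomes: np.ndarray, target_outcomes: np.ndarray) -> np.ndarray:
    """Pairwise mutual information (nats) between binary outcome rows.

    For each (candidate, target) pair the 2x2 joint is the empirical
    distribution of (y, y*) over the B trees; MI is its KL divergence from
    the product of marginals, with 0 log 0 := 0.
    """
    B = outcomes.shape[1]
    a = outcomes.mean(axis=1)            # P(y=1), shape (M,)
    b = target_outcomes.mean(axis=1)     # P(y*=1), shape (K,)
    p11 = outcomes @ target_outcomes.T / B
    p10 = a[:, None] - p11
    p01 = b[None, :] - p11
    p00 = 1.0 - a[:, None] - b[None, :] + p11

    def term(p, pa, pb):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = p * np.log(p / (pa * pb))
        return np.where(p > 1e-15, t, 0.0)

    mi = (
        term(p11, a[:, None], b[None, :])
        + term(p10, a[:, None], 1 - b[None, :])
        + term(p01, 1 - a[:, None], b[None, :])
        + term(p00, 1 - a[:, None], 1 - b[None, :])
    )
    return np.maximum(mi, 0.0)


def pairwise_mi(
    predictor: EnsemblePredictor,
    x: Molecule,
    x_star: Molecule,
    transform: Transform | None = None,
) -> float:
    """Mutual information between the predictive outcomes at x and x*."""
    o = binary_outcomes(predictor, [x, x_star], transform)
    return float(_mi_matrix(o[:1], o[1:])[0, 0])


def epig_scores(
    predictor: EnsemblePredictor,
    pool: Sequence[Molecule],
    target: TargetDistribution,
    transform: Transform | None = None,
) -> dict[str, float]:
    """EPIG(x) = sum over target members of weight * MI(x; x*), exactly.

    The expectation over the target distribution is an exact weighted sum
    over its members (no Monte-Carlo sampling).
    """
    if len(target.members) == 0:
        raise ConfigurationError("empty target distribution")
    pool_outcomes = binary_outcomes(predictor, pool, transform)
    target_outcomes = binary_outcomes(predictor, list(target.members), transform)
    mi = _mi_matrix(pool_outcomes, target_outcomes)
    values = mi @ target.weights
    return {m.smiles: float(v) for m, v in zip(pool, values)}


def uncertainty_scores(
    predictor: EnsemblePredictor, pool: Sequence[Molecule]
) -> dict[str, float]:
    """Tree disagreement: population variance of tree outputs (regression)
    or binary Shannon entropy of the mean vote, in nats (classification)."""
    preds = predictor.tree_predictions(fingerprint_matrix(pool))
    if predictor.task == "regression":
        values = preds.var(axis=1)  # 1/B normalization
    else:
        p = preds.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = -(p * np.log(p) + (1 - p) * np.log(1 - p))
        values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return {m.smiles: float(v) for m, v in zip(pool, values)}


def greedy_scores(
    pool: Sequence[ScoredMolecule], component: str | None = None
) -> dict[str, float]:
    """The transformed predictor score itself (exploitation).

    With ``component`` unset the stored total is used, which coincides with
    the predictor component score in mono-objective runs.
    """
    if component is None:
        return {s.smiles: s.total for s in pool}
    return {s.smiles: s.component_scores[component] for s in pool}


def select_batch(
    scores: Mapping[str, float],
    pool: Sequence[Molecule],
    T: int,
    criterion: str,
    seed: int = 0,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> AcquisitionResult:
    """Select up to T molecules: top-T by score, or a seeded uniform draw
    without replacement for ``random``.

    Molecules in ``exclude`` (already queried this run) are never selected.
    Ties break by canonical SMILES lexicographic order.  An entirely
    excluded pool yields an empty batch, signalling the caller to stop.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    candidates = [m for m in pool if m.smiles not in exclude]
    if criterion == "random":
        rng = np.random.default_rng(seed)
        order = sorted(candidates, key=lambda m: m.smiles)
        idx = rng.permutation(len(order))[: min(T, len(order))]
        batch = tuple(order[i] for i in idx)
    else:
        ranked = sorted(candidates, key=lambda m: (-scores[m.smiles], m.smiles))
        batch = tuple(ranked[: min(T, len(ranked))])
    return AcquisitionResult(criterion=criterion, scores=dict(scores), batch=batch)
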