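"""Generator contract, desk-scale proposal agent, diversity-filter memory
and pool construction.

The production-scale system uses a SMILES RNN trained by policy-gradient
reinforcement learning against the scoring function.  The contribution
under test here is the surrounding active-learning loop, so the default
agent is a *library-reweighting* stand-in: it samples proposals from a
fixed molecule library with per-molecule weights and sharpens those weights
multiplicatively toward high-scoring molecules.  That preserves the one
property the loop relies on — proposal quality increases under a static
scorer — while remaining exactly reproducible at desk scale.  The
squared-difference loss between the reward-augmented prior likelihood and
the agent likelihood is provided as a pure function for plugging in a real
sequence-model agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemio import Molecule
from .errors import DimensionError
from .scoring import ScoredMolecule


def reinvent_loss(
    prior_loglik: np.ndarray,
    agent_loglik: np.ndarray,
    scores: np.ndarray,
    lam: float = 128.0,
    augment_sign: int = +1,
) -> float:
    """Mean squared gap between augmented prior and agent log-likelihoods:

        (1/P) sum_p [ log p_prior(x_p) + sign * lambda * s(x_p) - log p_agent(x_p) ]^2

    With ``augment_sign=+1`` (default) the reward *raises* the augmented
    likelihood, so minimizing the loss pulls the agent toward high-scoring
    molecules; ``augment_sign=-1`` exposes the opposite convention.
    """
    prior = np.asarray(prior_loglik, dtype=float)
    agent = np.asarray(agent_loglik, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not (prior.shape == agent.shape == s.shape):
        raise DimensionError("prior, agent and scores must have equal length")
    if prior.size < 1:
        raise DimensionError("batch must contain at least one molecule")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    gap = prior + augment_sign * lam * s - agent
    return float(np.mean(gap**2))


class LibraryAgent:
    """Proposal agent over a fixed library with multiplicative-weight updates.

    The frozen prior is the uniform distribution over the library; the agent
    state is a positive weight per molecule.  ``propose`` draws with
    replacement proportionally to the weights (a sequence generator can also
    emit duplicates); ``update`` applies w <- w * exp(eta * s) for scored
    batch members and renormalizes, so the expected proposal score is
    nondecreasing under a static scorer.
    """

    def __init__(self, library: Sequence[Molecule], seed: int = 0):
        if len(library) == 0:
            raise ValueError("library must be nonempty")
        self.library = list(library)
        self._index = {m.smiles: i for i, m in enumerate(self.library)}
        n = len(self.library)
        self.prior_weights = np.full(n, 1.0 / n)  # frozen psi_0
        self.weights = np.full(n, 1.0 / n)        # mutable psi
        self._rng = np.random.default_rng(seed)

    def log_prior(self, mols: Sequence[Molecule]) -> np.ndarray:
        return np.log([self.prior_weights[self._index[m.smiles]] for m in mols])

    def log_agent(self, mols: Sequence[Molecule]) -> np.ndarray:
        return np.log([self.weights[self._index[m.smiles]] for m in mols])

    def propose(self, P: int) -> list[Molecule]:
        """Seeded draw of P molecules with probability proportional to the
        current weights (with replacement)."""
        if P < 0:
            raise ValueError("P must be >= 0")
        if P == 0:
            return []
        idx = self._rng.choice(len(self.library), size=P, p=self.weights)
        return [self.library[i] for i in idx]

    def update(self, scored_batch: Sequence[ScoredMolecule], eta: float = 1.0) -> None:
        """Multiplicative-weights step toward high-scoring batch members."""
        if eta < 0:
            raise ValueError("eta must be >= 0")
        for sm in scored_batch:
            i = self._index[sm.smiles]
            self.weights[i] *= np.exp(eta * sm.total)
        self.weights /= self.weights.sum()

    def checkpoint(self) -> dict:
        """JSON-serializable agent state."""
        return {
            "library": [m.smiles for m in self.library],
            "weights": self.weights.tolist(),
        }


@dataclass
class MemoryBuckets:
    """Scaffold-bucketed store of high-scoring molecules (diversity filter).

    A molecule enters the bucket of its Murcko scaffold key only if its total
    score reaches ``score_threshold``, the bucket is below ``capacity`` and
    the canonical SMILES is not already stored; full buckets discourage
    over-generation of one scaffold.
    """

    capacity: int = 25
    score_threshold: float = 0.4
    buckets: dict[str, list[ScoredMolecule]] = field(default_factory=dict)

    def add(self, sm: ScoredMolecule) -> str:
        """Try to store a scored molecule; returns ``accepted`` or
        ``rejected:<reason>`` (low_score, duplicate, bucket_full)."""
        if sm.total < self.score_threshold:
            return "rejected:low_score"
        bucket = self.buckets.setdefault(sm.molecule.scaffold_key, [])
        if any(x.smiles == sm.smiles for x in bucket):
            return "rejected:duplicate"
        if len(bucket) >= self.capacity:
            return "rejected:bucket_full"
        bucket.append(sm)
        return "accepted"

    def molecules(self) -> list[ScoredMolecule]:
        """All stored molecules, in deterministic scaffold/insertion order."""
        out = []
        for key in sorted(self.buckets):
            out.extend(self.buckets[key])
        return out

    def __len__(self) -> int:
        return sum(len(b) for b in self.buckets.values())


@dataclass(frozen=True)
class Pool:
    """Deduplicated candidate molecules for one AL round."""

    molecules: tuple[ScoredMolecule, ...]

    def __len__(self) -> int:
        return len(self.molecules)


def build_pool(
    memory: MemoryBuckets,
    component: str | None = None,
    min_component_score: float = 0.5,
) -> Pool:
    """Deduplicate memory contents into the round's query pool.

    In multi-objective mode ``component`` names the predictor component and
    only molecules with that component score strictly above
    ``min_component_score`` enter the pool; in mono-objective mode the
    memory threshold already applies and no extra filter is used.
    """
    seen: dict[str, ScoredMolecule] = {}
    for sm in memory.molecules():
        if component is not None and sm.component_scores[component] <= min_component_score:
            continue
        if sm.smiles not in seen:
            seen[sm.smiles] = sm
    return Pool(molecules=tuple(seen.values()))
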