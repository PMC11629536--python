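"""Ground-truth oracles and simulated noisy experts.

An oracle is the deterministic ground-truth evaluator standing in for a
wet-lab measurement.  A simulated expert wraps an oracle with additive
Gaussian noise — clipped to [0, 1] for probability-valued oracles — to
model a human whose judgement deviates from the truth.  Expert agreement
scores are converted into training labels h_t and confidence weights u_t
for fine-tuning the property predictor.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from rdkit.Chem import Descriptors

from .chemio import Molecule, _mol_from_smiles
from .errors import DimensionError, ParameterError


def _sa_scorer():
    from rdkit.Chem import RDConfig

    sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if sa_dir not in sys.path:
        sys.path.append(sa_dir)
    import sascorer

    return sascorer


def penalized_logp(mol: Molecule | str) -> float:
    """Octanol-water partition estimate minus SA score minus the number of
    rings larger than six atoms.  Deterministic."""
    smiles = mol.smiles if isinstance(mol, Molecule) else mol
    rdmol = _mol_from_smiles(smiles)
    logp = Descriptors.MolLogP(rdmol)
    sa = _sa_scorer().calculateScore(rdmol)
    long_cycles = sum(
        1 for ring in rdmol.GetRingInfo().AtomRings() if len(ring) > 6
    )
    return logp - sa - long_cycles


class PenalizedLogPOracle:
    """Real-valued lipophilicity oracle (see :func:`penalized_logp`)."""

    kind = "penalized_logp"

    def __call__(self, mol: Molecule) -> float:
        return penalized_logp(mol)


class SyntheticLinearOracle:
    """Linear test oracle over fingerprint counts: w . x + bias.

    With ``squash=True`` the value is passed through a logistic, giving a
    probability-valued oracle for classification-style experiments.  Used
    for parameter-recovery studies where the ground truth is known exactly.
    """

    kind = "synthetic_linear"

    def __init__(self, weights: np.ndarray, bias: float = 0.0, squash: bool = False):
        self.weights = np.asarray(weights, dtype=float)
        self.bias = float(bias)
        self.squash = squash

    def __call__(self, mol: Molecule) -> float:
        if mol.fingerprint.shape != self.weights.shape:
            raise DimensionError(
                f"fingerprint length {mol.fingerprint.shape} != weights {self.weights.shape}"
            )
        value = float(self.weights @ mol.fingerprint + self.bias)
        if self.squash:
            return float(1.0 / (1.0 + np.exp(-value)))
        return value

    @classmethod
    def from_library(
        cls,
        library: Sequence[Molecule],
        seed: int,
        n_active_positions: int = 64,
        target_mean: float = 3.0,
        target_std: float = 2.0,
        squash: bool = False,
    ) -> "SyntheticLinearOracle":
        """Draw sparse random weights, then rescale so the oracle values over
        ``library`` have the requested mean and spread.

        The rescaling keeps the synthetic landscape commensurate with a
        lipophilicity-style objective (values spread around the desired
        interval), independent of fingerprint sparsity.
        """
        rng = np.random.default_rng(seed)
        D = library[0].fingerprint.shape[0]
        fps = np.vstack([m.fingerprint for m in library]).astype(float)
        active_cols = np.flatnonzero(fps.sum(axis=0) > 0)
        chosen = rng.choice(active_cols, size=min(n_active_positions, len(active_cols)),
                            replace=False)
        w = np.zeros(D)
        w[chosen] = rng.normal(0.0, 1.0, size=len(chosen))
        raw = fps @ w
        std = raw.std()
        if std == 0:
            raise ParameterError("degenerate library: constant oracle values")
        scale = target_std / std
        bias = target_mean - raw.mean() * scale
        return cls(weights=w * scale, bias=bias, squash=squash)


def binary_labels(values: Sequence[float], delta: float) -> np.ndarray:
    """Threshold real values into {0, 1}: 1 iff value > delta (strict)."""
    return (np.asarray(values, dtype=float) > delta).astype(int)


@dataclass
class ExpertModel:
    """A simulated expert: oracle plus seeded Gaussian noise.

    ``clip=True`` models probability-valued feedback (the noisy value is
    clamped to [0, 1]); ``clip=False`` returns the unbounded noisy value.
    With ``sigma_eps=0`` the expert reproduces the oracle exactly.  Noise
    draws come from a dedicated per-expert stream so they are reproducible
    independently of any other randomness.
    """

    oracle: Callable[[Molecule], float]
    sigma_eps: float = 0.0
    clip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_eps < 0:
            raise ParameterError("sigma_eps must be >= 0")
        self._rng = np.random.default_rng(self.seed)
        self.n_queries = 0

    def query(self, mol: Molecule) -> float:
        """One noisy evaluation; clipped to [0, 1] when ``clip`` is set."""
        self.n_queries += 1
        value = self.oracle(mol)
        if self.sigma_eps > 0:
            value += self._rng.normal(0.0, self.sigma_eps)
        if self.clip:
            value = float(np.clip(value, 0.0, 1.0))
        return float(value)


def simulate_regression_expert(expert: ExpertModel, mol: Molecule) -> float:
    """Noisy real-valued assessment: f*(x) + eps, eps ~ N(0, sigma_eps)."""
    if expert.clip:
        raise ParameterError("regression experts must not clip")
    return expert.query(mol)


def simulate_classification_expert(expert: ExpertModel, mol: Molecule) -> float:
    """Noisy agreement score clamped to [0, 1]."""
    if not expert.clip:
        raise ParameterError("classification experts must clip to [0, 1]")
    return expert.query(mol)


@dataclass(frozen=True)
class FeedbackRecord:
    """One expert answer: agreement a, derived label h_t and confidence u_t."""

    molecule: Molecule
    agreement: float
    label: float
    confidence: float


def agreement_to_feedback(agreement: float, task: str) -> tuple[float, float]:
    """Convert an agreement score into a training label and confidence.

    Classification: the slider value a in [0, 1] yields h_t = 1{a >= 0.5}
    and u_t = a if h_t = 1 else 1 - a, i.e. u_t = max(a, 1 - a) — the
    distance-from-midpoint confidence (a 40% slider gives label 0 with 60%
    confidence).  The tie a = 0.5 maps to label 1 with the minimal
    confidence 0.5, where its retraining influence is smallest.

    Regression: the expert's value estimate is used directly as the label
    with unit confidence (no confidence notion exists on an unbounded
    scale).
    """
    if task == "regression":
        return float(agreement), 1.0
    if not 0.0 <= agreement <= 1.0:
        raise ParameterError(f"agreement must lie in [0, 1], got {agreement}")
    label = 1.0 if agreement >= 0.5 else 0.0
    confidence = agreement if label == 1.0 else 1.0 - agreement
    return label, confidence


def make_feedback(mol: Molecule, agreement: float, task: str) -> FeedbackRecord:
    label, confidence = agreement_to_feedback(agreement, task)
    return FeedbackRecord(mol, float(agreement), label, confidence)
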