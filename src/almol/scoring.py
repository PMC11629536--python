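"""Transforms and the weighted multi-component score s(x).

The total score of a molecule is the weight-normalized sum of transformed
component scores,

    s(x) = sum_i w_i * sigma_i(c_i(x)) / sum_i w_i ,

where each component c_i is an analytic property, a fitted property
predictor, or a max-Tanimoto similarity to a reference set, and each
transform sigma_i maps raw values into [0, 1].  A score near 1 means the
molecule satisfies the full objective profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chemio import Molecule, fingerprint_matrix, tanimoto_matrix
from .errors import ConfigurationError, ParameterError


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def double_sigmoid(
    x: np.ndarray | float, low: float, high: float, steepness: float = 10.0
):
    """Reward plateau over [low, high]: the product of two opposed logistics.

    ``logistic(k (x - low)) * logistic(-k (x - high))`` is ~1 well inside the
    interval, decays to 0 far outside, and equals ~0.5 at each boundary when
    the interval is wide relative to 1/steepness.
    """
    if low >= high:
        raise ParameterError(f"double_sigmoid requires low < high, got {low}, {high}")
    if steepness <= 0:
        raise ParameterError("steepness must be positive")
    x = np.asarray(x, dtype=float)
    out = _logistic(steepness * (x - low)) * _logistic(-steepness * (x - high))
    return float(out) if out.ndim == 0 else out


def flip(p: np.ndarray | float):
    """Probability flip 1 - p, for objectives that reward *low* probabilities."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ParameterError("flip requires probabilities in [0, 1]")
    out = 1.0 - p
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Transform:
    """Maps raw component values into [0, 1].

    kinds: ``identity`` (already a probability), ``sigmoid`` (increasing
    logistic centered at ``low``), ``double_sigmoid`` (plateau over
    [low, high]), ``flip`` (1 - p).
    """

    kind: str = "identity"
    low: float = 0.0
    high: float = 1.0
    steepness: float = 10.0

    def __call__(self, values: np.ndarray | float):
        v = np.asarray(values, dtype=float)
        if self.kind == "identity":
            out = v
        elif self.kind == "sigmoid":
            out = _logistic(self.steepness * (v - self.low))
        elif self.kind == "double_sigmoid":
            return double_sigmoid(v, self.low, self.high, self.steepness)
        elif self.kind == "flip":
            return flip(v)
        else:
            raise ConfigurationError(f"unknown transform kind: {self.kind!r}")
        return float(out) if out.ndim == 0 else out


@dataclass
class ScoringComponent:
    """One named objective: an evaluator, a transform, and a positive weight.

    ``kind`` is ``predictor`` (evaluator is an EnsemblePredictor),
    ``analytic`` (evaluator is a callable Molecule -> float), or
    ``similarity`` (evaluator is a reference list of Molecules; the raw value
    is the max presence-bit Tanimoto to that set).
    """

    name: str
    kind: str
    weight: float
    transform: Transform = field(default_factory=Transform)
    evaluator: object = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ConfigurationError(f"component {self.name!r}: weight must be > 0")
        if self.kind not in ("predictor", "analytic", "similarity"):
            raise ConfigurationError(f"component {self.name!r}: unknown kind {self.kind!r}")

    def raw_values(self, molecules: Sequence[Molecule]) -> np.ndarray:
        if self.kind == "predictor":
            return self.evaluator.predict_mean(fingerprint_matrix(molecules))
        if self.kind == "analytic":
            return np.array([self.evaluator(m) for m in molecules], dtype=float)
        # similarity
        return similarity_component(molecules, self.evaluator)


def similarity_component(
    molecules: Sequence[Molecule], reference: Sequence[Molecule]
) -> np.ndarray:
    """Max presence-bit Tanimoto of each molecule to a nonempty reference set."""
    if reference is None or len(reference) == 0:
        raise ConfigurationError("similarity component requires a nonempty reference set")
    sims = tanimoto_matrix(fingerprint_matrix(molecules), fingerprint_matrix(reference))
    return sims.max(axis=1)


def aggregate(weights: Sequence[float], values: Sequence[float]) -> float:
    """Weight-normalized sum: sum(w v) / sum(w).  Monotone in every value."""
    if len(weights) == 0:
        raise ConfigurationError("aggregate requires at least one component")
    w = np.asarray(weights, dtype=float)
    v = np.asarray(values, dtype=float)
    if w.shape != v.shape:
        raise ParameterError("weights and values must have equal length")
    return float(w @ v / w.sum())


@dataclass(frozen=True)
class ScoredMolecule:
    """A molecule with its per-component transformed scores and total."""

    molecule: Molecule
    component_scores: Mapping[str, float]
    total: float

    @property
    def smiles(self) -> str:
        return self.molecule.smiles


class ScoringFunction:
    """Weighted multi-component scoring function over molecules."""

    def __init__(self, components: Sequence[ScoringComponent]):
        if len(components) == 0:
            raise ConfigurationError("scoring function needs at least one component")
        names = [c.name for c in components]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate component names: {names}")
        self.components = list(components)

    def score(self, molecules: Sequence[Molecule]) -> list[ScoredMolecule]:
        """Score a batch; each total lies in [0, 1]."""
        if len(molecules) == 0:
            return []
        per_component = {}
        for comp in self.components:
            raw = comp.raw_values(molecules)
            per_component[comp.name] = np.asarray(comp.transform(raw), dtype=float)
        weights = [c.weight for c in self.components]
        scored = []
        for i, mol in enumerate(molecules):
            comp_scores = {name: float(vals[i]) for name, vals in per_component.items()}
            total = aggregate(weights, [comp_scores[c.name] for c in self.components])
            scored.append(ScoredMolecule(mol, comp_scores, total))
        return scored

    def replace_evaluator(self, name: str, evaluator: object) -> None:
        """Swap a component's evaluator in place (e.g. a fine-tuned predictor)."""
        for comp in self.components:
            if comp.name == name:
                comp.evaluator = evaluator
                return
        raise ConfigurationError(f"no scoring component named {name!r}")
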