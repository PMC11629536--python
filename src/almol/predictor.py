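"""Random-forest property predictor with per-tree access.

The ensemble prediction is the arithmetic mean of the B individual tree
outputs: real values for regression, hard {0, 1} votes for classification
(so the classification mean is the fraction of trees voting positive).
Per-tree outputs are exposed because the acquisition criteria treat each
tree as one posterior parameter sample.

"Fine-tuning" is realized as a weighted refit from scratch on the union of
the initial data and all acquired feedback batches: forests have no
incremental update, and the weighted refit minimizes the same two-term
weighted empirical risk (initial records at 1/N0 each, acquired records of
a batch of size T at u_t/T each, u_t the expert confidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression

from .chemio import Molecule, fingerprint_matrix
from .errors import FitError, StateError

REGRESSION_DEFAULTS = {"n_estimators": 300, "min_samples_split": 2, "max_depth": None}
CLASSIFICATION_DEFAULTS = {"n_estimators": 200, "min_samples_split": 2, "max_depth": 10}


@dataclass
class LabeledSet:
    """Molecules with labels and per-record weights.

    Regression labels are real; classification labels are in {0, 1}.
    ``weights`` default to 1 per record; acquired feedback carries the expert
    confidence u_t as its weight.
    """

    molecules: list[Molecule]
    labels: np.ndarray
    weights: np.ndarray | None = None
    origin: str = "initial"  # "initial" | "acquired"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.molecules) != len(self.labels):
            raise FitError("molecules and labels must have equal length")
        if self.weights is None:
            self.weights = np.ones(len(self.labels))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise FitError("weights must be >= 0")

    def __len__(self) -> int:
        return len(self.molecules)


@dataclass
class FitConfig:
    """Forest hyperparameters; defaults follow common QSAR practice
    (300 trees for regression; 200 trees with depth 10 for classification)."""

    task: str = "regression"  # "regression" | "classification"
    n_estimators: int | None = None
    max_depth: int | None = None
    min_samples_split: int = 2

    def resolved(self) -> dict:
        defaults = (
            REGRESSION_DEFAULTS if self.task == "regression" else CLASSIFICATION_DEFAULTS
        )
        return {
            "n_estimators": self.n_estimators or defaults["n_estimators"],
            "max_depth": self.max_depth if self.max_depth is not None else defaults["max_depth"],
            "min_samples_split": self.min_samples_split,
        }


class EnsemblePredictor:
    """A fitted random forest with per-tree prediction access."""

    def __init__(self, task: str, config: FitConfig, seed: int):
        if task not in ("regression", "classification"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.config = config
        self.seed = seed
        self.model = None
        self.training_snapshot: dict | None = None

    # -- internals -----------------------------------------------------------

    def _fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray) -> None:
        params = self.config.resolved()
        if self.task == "regression":
            model = RandomForestRegressor(random_state=self.seed, n_jobs=1, **params)
        else:
            classes = np.unique(y)
            if len(classes) < 2:
                raise FitError(
                    f"classification requires both classes in training data, got {classes}"
                )
            model = RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)
        model.fit(X, y.astype(int) if self.task == "classification" else y,
                  sample_weight=sample_weight)
        self.model = model
        self.training_snapshot = {"n": int(len(y)), "total_weight": float(sample_weight.sum())}

    def _require_fitted(self) -> None:
        if self.model is None:
            raise StateError("predictor has not been fitted")

    @property
    def n_trees(self) -> int:
        self._require_fitted()
        return len(self.model.estimators_)

    # -- prediction ----------------------------------------------------------

    def tree_predictions(self, X: np.ndarray) -> np.ndarray:
        """Per-tree outputs, shape (n, B); classification trees vote in {0, 1}."""
        self._require_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=np.float32))
        cols = [tree.predict(X) for tree in self.model.estimators_]
        return np.column_stack(cols).astype(float)

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        """Mean over trees: real value (regression) or positive fraction
        (classification).

        Regression uses the forest's own averaged prediction (identical to
        the per-tree mean up to float summation order); classification
        averages the hard tree votes, which is not the same as averaging
        leaf probabilities.
        """
        self._require_fitted()
        if self.task == "regression":
            X = np.atleast_2d(np.asarray(X, dtype=np.float32))
            return self.model.predict(X)
        return self.tree_predictions(X).mean(axis=1)

    def predict_mean_one(self, mol: Molecule) -> float:
        return float(self.predict_mean(mol.fingerprint[None, :])[0])


def fit_initial(data: LabeledSet, config: FitConfig, seed: int) -> EnsemblePredictor:
    """Fit a forest on the initial labeled set, each record at weight 1/N0.

    Deterministic per seed; a later weighted refit with no acquired data
    goes through the identical code path and reproduces it exactly.
    """
    if len(data) < 2:
        raise FitError("need at least 2 labeled records to fit")
    predictor = EnsemblePredictor(config.task, config, seed)
    X = fingerprint_matrix(data.molecules)
    w = np.full(len(data), 1.0 / len(data))
    predictor._fit(X, data.labels, w)
    return predictor


def fine_tune(
    predictor: EnsemblePredictor,
    initial: LabeledSet,
    acquired_batches: Sequence[LabeledSet],
    seed: int,
) -> EnsemblePredictor:
    """Weighted refit on initial data plus confidence-weighted feedback.

    Initial records weigh 1/N0 each; records of an acquired batch of size T
    weigh u_t/T each, so higher-confidence feedback exerts more influence and
    each batch keeps its own normalization across rounds.  Zero-weight
    records are dropped before fitting, so zero-confidence feedback leaves
    the seeded refit identical to a refit on the initial data alone.
    """
    mols = list(initial.molecules)
    labels = [initial.labels]
    weights = [
        np.full(len(initial), 1.0 / len(initial)) if len(initial) else np.zeros(0)
    ]
    for batch in acquired_batches:
        if len(batch) == 0:
            continue
        mols.extend(batch.molecules)
        labels.append(batch.labels)
        weights.append(batch.weights / len(batch))
    y = np.concatenate(labels)
    w = np.concatenate(weights)
    keep = w > 0
    if not np.any(keep):
        raise FitError("all record weights are zero; nothing to fit")
    mols = [m for m, k in zip(mols, keep) if k]
    out = EnsemblePredictor(predictor.task, predictor.config, seed)
    out._fit(fingerprint_matrix(mols), y[keep], w[keep])
    return out


@dataclass
class PlattCalibrator:
    """Monotone logistic mapping of raw classifier mean scores to
    calibrated probabilities."""

    predictor: EnsemblePredictor
    _lr: LogisticRegression = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        raw = self.predictor.predict_mean(X)
        return self._lr.predict_proba(raw[:, None])[:, 1]

    # so a calibrated predictor can stand in for a raw one in scoring
    predict_mean = predict


def platt_calibrate(predictor: EnsemblePredictor, holdout: LabeledSet) -> PlattCalibrator:
    """Fit a logistic regression on raw mean scores against holdout labels."""
    if predictor.task != "classification":
        raise FitError("Platt scaling applies to classification predictors only")
    y = holdout.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise FitError("holdout must contain both classes")
    raw = predictor.predict_mean(fingerprint_matrix(holdout.molecules))
    lr = LogisticRegression(C=1e6)
    lr.fit(raw[:, None], y)
    return PlattCalibrator(predictor, lr)
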