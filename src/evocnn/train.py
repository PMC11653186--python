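"""Training harness: architecture spec + labeled images -> evaluation.

This is the GA's real fitness evaluator.  :func:`genome_fitness` builds the
network for a chromosome, trains it for the per-genome budget, and maps the
result to a scalar fitness (percentage validation accuracy by default).  A
deterministic surrogate mode bypasses training entirely so the evolutionary
mechanics can be exercised in milliseconds.

:class:`ConvNetClassifier` wraps the same machinery as a scikit-learn
estimator (``fit`` / ``predict`` / ``predict_proba`` / ``score``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .arch import ArchitectureSpec, ShapeError, build_cnn_spec
from .backend import BackendError, NumpyNet
from .data import LabeledImageSet
from .genome import ConvGenome
from .metrics import (
    ConfusionCounts,
    EvalResult,
    bce_loss,
    error_rate,
    fitness_accuracy_pct,
    fitness_confusion,
)

__all__ = [
    "TrainBudget",
    "TrainerError",
    "train_and_score",
    "genome_fitness",
    "surrogate_fitness",
    "ConvNetClassifier",
]


class TrainerError(RuntimeError):
    """Structured training failure; the GA records it as fitness 0."""


@dataclass(frozen=True)
class TrainBudget:
    """Gradient-descent budget for one model."""

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _stacked(dataset: LabeledImageSet) -> tuple[np.ndarray, np.ndarray]:
    X = dataset.stack().astype(np.float32)
    return X, dataset.labels.astype(np.float32)


def train_and_score(
    spec: ArchitectureSpec,
    data: Mapping[str, LabeledImageSet],
    budget: TrainBudget,
    eval_split: str = "test",
) -> EvalResult:
    """Train on ``data['train']`` and report accuracy/loss/error on
    ``data[eval_split]``.

    Shape mismatches and numerical blow-ups raise :class:`TrainerError`.
    """
    if "train" not in data or eval_split not in data:
        raise TrainerError(f"data must provide 'train' and '{eval_split}' splits")
    X_train, y_train = _stacked(data["train"])
    X_eval, y_eval = _stacked(data[eval_split])
    if len(X_train) == 0 or len(X_eval) == 0:
        raise TrainerError("empty split")
    try:
        net = NumpyNet(spec, seed=budget.seed)
        net.fit(
            X_train,
            y_train,
            epochs=budget.epochs,
            batch_size=budget.batch_size,
            learning_rate=budget.learning_rate,
            shuffle_rng=np.random.default_rng(budget.seed + 1),
        )
        p_train = net.predict_proba(X_train)
        p_eval = net.predict_proba(X_eval)
    except (BackendError, ShapeError, ValueError) as exc:
        raise TrainerError(str(exc)) from exc
    if not (np.all(np.isfinite(p_train)) and np.all(np.isfinite(p_eval))):
        raise TrainerError("non-finite predictions")
    yhat_train = (p_train >= 0.5).astype(int)
    yhat_eval = (p_eval >= 0.5).astype(int)
    return EvalResult(
        train_accuracy=float(np.mean(yhat_train == y_train.astype(int))),
        test_accuracy=float(np.mean(yhat_eval == y_eval.astype(int))),
        loss=bce_loss(y_eval, p_eval),
        error_rate=error_rate(y_eval.astype(int), yhat_eval),
    )


def surrogate_fitness(target: ConvGenome):
    """Deterministic stand-in fitness: negative L1 distance to a hidden
    target chromosome (0 at the target, lower elsewhere).

    Chromosomes of a different length pay the full magnitude of each
    unmatched layer's genes.
    """

    def fitness(g: ConvGenome) -> float:
        dist = 0
        for i in range(max(len(g), len(target))):
            a = g.layers[i] if i < len(g) else (0, 0)
            b = target.layers[i] if i < len(target) else (0, 0)
            dist += abs(a[0] - b[0]) + abs(a[1] - b[1])
        return -float(dist)

    return fitness


def genome_fitness(
    genome: ConvGenome,
    data: Mapping[str, LabeledImageSet],
    budget: TrainBudget,
    fitness_kind: str = "accuracy_pct",
    eval_split: str = "val",
) -> float:
    """Scalar fitness of a chromosome: build, train once, score on the
    validation split.  Training failures score 0 (such configurations are
    simply discarded by selection)."""
    if fitness_kind not in ("accuracy_pct", "confusion"):
        raise ValueError(f"unknown fitness_kind {fitness_kind!r}")
    sample = data["train"].images[0]
    input_shape = (sample.shape[0], sample.shape[1], 1)
    X_train, y_train = _stacked(data["train"])
    X_eval, y_eval = _stacked(data[eval_split])
    try:
        spec = build_cnn_spec(genome, input_shape)
        net = NumpyNet(spec, seed=budget.seed)
        net.fit(
            X_train,
            y_train,
            epochs=budget.epochs,
            batch_size=budget.batch_size,
            learning_rate=budget.learning_rate,
            shuffle_rng=np.random.default_rng(budget.seed + 1),
        )
        p_eval = net.predict_proba(X_eval)
    except (BackendError, ShapeError, ValueError):
        return 0.0
    if not np.all(np.isfinite(p_eval)):
        return 0.0
    yhat = (p_eval >= 0.5).astype(int)
    y = y_eval.astype(int)
    if fitness_kind == "accuracy_pct":
        return fitness_accuracy_pct(int(np.sum(yhat == y)), len(y))
    counts = ConfusionCounts(
        tp=int(np.sum((yhat == 1) & (y == 1))),
        fp=int(np.sum((yhat == 1) & (y == 0))),
        fn=int(np.sum((yhat == 0) & (y == 1))),
        tn=int(np.sum((yhat == 0) & (y == 0))),
    )
    try:
        return fitness_confusion(counts)
    except ValueError:
        return 0.0


class ConvNetClassifier(ClassifierMixin, BaseEstimator):
    """Binary image classifier built from a conv chromosome.

    Parameters
    ----------
    genome : ConvGenome or list of (filters, kernel) pairs, default one
        8-filter 3x3 layer.
    epochs, batch_size, learning_rate : training budget.
    random_state : seed for weight init and batch shuffling.

    Attributes (after ``fit``)
    --------------------------
    classes_ : array of the two class labels.
    spec_ : the built :class:`ArchitectureSpec`.
    net_ : the trained network.
    loss_curve_ : mean training loss per epoch.
    """

    def __init__(
        self,
        genome=((8, 3),),
        epochs: int = 10,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ) -> None:
        self.genome = genome
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _genome(self) -> ConvGenome:
        if isinstance(self.genome, ConvGenome):
            return self.genome
        return ConvGenome(tuple(tuple(pair) for pair in self.genome))

    @staticmethod
    def _check_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4 and X.shape[-1] == 1:
            X = X[..., 0]
        if X.ndim != 3:
            raise ValueError(f"X must be (n_samples, height, width), got {X.shape}")
        return X

    def fit(self, X, y) -> "ConvNetClassifier":
        X = self._check_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"binary classifier, got classes {self.classes_}")
        y01 = (y == self.classes_[1]).astype(np.float32)
        input_shape = (X.shape[1], X.shape[2], 1)
        self.spec_ = build_cnn_spec(self._genome(), input_shape)
        self.net_ = NumpyNet(self.spec_, seed=self.random_state)
        self.loss_curve_ = self.net_.fit(
            X,
            y01,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            shuffle_rng=np.random.default_rng(self.random_state + 1),
        )
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise NotFittedError("call fit before predict")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        p1 = self.net_.predict_proba(self._check_X(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    def evaluate(
        self, X_train, y_train, X_test, y_test
    ) -> EvalResult:
        """EvalResult over already-fitted model (no retraining)."""
        self._check_fitted()
        p_tr = self.predict_proba(X_train)[:, 1]
        p_te = self.predict_proba(X_test)[:, 1]
        y_tr = (np.asarray(y_train) == self.classes_[1]).astype(int)
        y_te = (np.asarray(y_test) == self.classes_[1]).astype(int)
        return EvalResult(
            train_accuracy=float(np.mean((p_tr >= 0.5).astype(int) == y_tr)),
            test_accuracy=float(np.mean((p_te >= 0.5).astype(int) == y_te)),
            loss=bce_loss(y_te, p_te),
            error_rate=error_rate(y_te, (p_te >= 0.5).astype(int)),
        )
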