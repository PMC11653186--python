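"""Scoring formulas used by the architecture search.

Two fitness definitions are supported: a confusion-matrix fitness
``F = TP / (TP + FP + FN)`` (the fraction of true positives among all
positive calls and misses), and a percentage accuracy
``100 * correct / total``.  Losses are the usual binary and categorical
cross-entropies with natural logarithms, and the error rate is the mean
absolute difference between true and predicted label vectors, which for
hard binary labels equals the misclassification fraction.  The structural
cost ``alpha*L + beta*F + gamma*E`` trades network size against error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import CostWeights

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "fitness_confusion",
    "fitness_accuracy_pct",
    "bce_loss",
    "cce_loss",
    "error_rate",
    "arch_cost",
    "EPS",
]

EPS = 1e-7  # probability clipping for the log losses


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts (positive class = diseased)."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class EvalResult:
    """Train/test summary of one trained model."""

    train_accuracy: float
    test_accuracy: float
    loss: float
    error_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.train_accuracy <= 1.0:
            raise ValueError("train_accuracy must be in [0, 1]")
        if not 0.0 <= self.test_accuracy <= 1.0:
            raise ValueError("test_accuracy must be in [0, 1]")
        if self.loss < 0 or self.error_rate < 0:
            raise ValueError("loss and error_rate must be nonnegative")

    def to_row(self) -> dict:
        return {
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "loss": self.loss,
            "error_rate": self.error_rate,
        }


def fitness_confusion(c: ConfusionCounts) -> float:
    """Fitness ``TP / (TP + FP + FN)``; true negatives do not enter."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("fitness undefined: TP + FP + FN == 0")
    return c.tp / denom


def fitness_accuracy_pct(correct: int, total: int) -> float:
    """Percentage accuracy ``100 * correct / total``."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    return 100.0 * correct / total


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def bce_loss(labels, probs) -> float:
    """Mean binary cross-entropy, natural log, probabilities clipped to
    ``[EPS, 1-EPS]``."""
    y = np.asarray(labels, dtype=float).ravel()
    p = _clip(np.asarray(probs, dtype=float).ravel())
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def cce_loss(onehot, probs, row_tol: float = 1e-6) -> float:
    """Mean categorical cross-entropy over samples.

    ``probs`` rows must sum to 1 within ``row_tol``; each row of
    ``onehot`` marks the true class.
    """
    t = np.asarray(onehot, dtype=float)
    g = np.asarray(probs, dtype=float)
    if t.shape != g.shape or t.ndim != 2:
        raise ValueError(f"shape mismatch: {t.shape} vs {g.shape}")
    sums = g.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=row_tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"probability row {bad} sums to {sums[bad]}, not 1")
    return float(-np.mean(np.sum(t * np.log(_clip(g)), axis=1)))


def error_rate(real_labels, predicted_labels) -> float:
    """Mean absolute difference between the label vectors."""
    y = np.asarray(real_labels, dtype=float).ravel()
    yhat = np.asarray(predicted_labels, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(y - yhat)))


def arch_cost(L: int, F: int, E: float, w: CostWeights) -> float:
    """Structural cost ``alpha*L + beta*F + gamma*E`` for L layers, F total
    filters and error rate E."""
    if L < 0 or F < 0 or E < 0:
        raise ValueError("L, F and E must be nonnegative")
    return w.alpha * L + w.beta * F + w.gamma * E
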