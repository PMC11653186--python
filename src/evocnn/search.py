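"""scikit-learn estimator wrapping the full architecture search.

``EvolvedCNNClassifier.fit`` carves a validation split off the training
data, evolves conv chromosomes against validation fitness, then refits the
best chromosome on the full training data at the final budget.  The test
data a user passes to ``score``/``predict`` is never touched during the
search, so the reported generalization is leak-free.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import train_test_split

from .data import LabeledImageSet
from .ga import RunHistory, evolve
from .genome import ConvGenome, GAConfig
from .train import ConvNetClassifier, TrainBudget, genome_fitness

__all__ = ["EvolvedCNNClassifier"]


class EvolvedCNNClassifier(ClassifierMixin, BaseEstimator):
    """Genetic-algorithm search over small CNN architectures.

    Parameters mirror :class:`~evocnn.genome.GAConfig` plus the two
    training budgets (a cheap per-genome budget during the search, a full
    budget for the final refit).

    Attributes (after ``fit``)
    --------------------------
    best_genome_ : the winning chromosome.
    best_fitness_ : its validation fitness (percent accuracy by default).
    history_ : :class:`~evocnn.ga.RunHistory` of the search.
    best_estimator_ : a :class:`ConvNetClassifier` refit at the full budget.
    classes_ : the two class labels.
    """

    def __init__(
        self,
        population_size: int = 6,
        max_generations: int = 4,
        max_layers: int = 3,
        max_filters: int = 32,
        max_filter_size: int = 5,
        crossover_prob: float = 0.5,
        mutation_rate: float = 0.2,
        elitism_k: int | None = None,
        patience: int = 3,
        fitness_kind: str = "accuracy_pct",
        search_epochs: int = 5,
        final_epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        val_fraction: float = 0.2,
        random_state: int = 0,
    ) -> None:
        self.population_size = population_size
        self.max_generations = max_generations
        self.max_layers = max_layers
        self.max_filters = max_filters
        self.max_filter_size = max_filter_size
        self.crossover_prob = crossover_prob
        self.mutation_rate = mutation_rate
        self.elitism_k = elitism_k
        self.patience = patience
        self.fitness_kind = fitness_kind
        self.search_epochs = search_epochs
        self.final_epochs = final_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            max_layers=self.max_layers,
            max_filters=self.max_filters,
            max_filter_size=self.max_filter_size,
            crossover_prob=self.crossover_prob,
            mutation_rate=self.mutation_rate,
            elitism_k=self.elitism_k,
            patience=self.patience,
            seed=self.random_state,
            fitness_kind=self.fitness_kind,
        )

    def fit(self, X, y) -> "EvolvedCNNClassifier":
        X = ConvNetClassifier._check_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"binary classifier, got classes {self.classes_}")
        y01 = (y == self.classes_[1]).astype(int)

        idx_tr, idx_val = train_test_split(
            np.arange(len(X)),
            test_size=self.val_fraction,
            random_state=self.random_state,
            stratify=y01,
        )
        data = {
            "train": LabeledImageSet(
                [X[i] for i in idx_tr], y01[idx_tr], split="train"
            ),
            "val": LabeledImageSet([X[i] for i in idx_val], y01[idx_val], split="val"),
        }
        config = self._ga_config()
        search_budget = TrainBudget(
            epochs=self.search_epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.random_state,
        )

        def fitness(genome: ConvGenome) -> float:
            return genome_fitness(
                genome, data, search_budget, fitness_kind=self.fitness_kind
            )

        best, history = evolve(config, fitness)
        self.best_genome_: ConvGenome = best.genome
        self.best_fitness_: float = best.fitness
        self.history_: RunHistory = history
        self.stop_reason_: str = history.stop_reason

        self.best_estimator_ = ConvNetClassifier(
            genome=self.best_genome_,
            epochs=self.final_epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
        ).fit(X, y)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "best_estimator_"):
            raise NotFittedError("call fit before predict")

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.best_estimator_.predict(X)

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.best_estimator_.predict_proba(X)
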