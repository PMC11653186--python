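"""Chromosome encodings and run configuration for the architecture search.

A convolutional architecture is encoded as a variable-length chromosome of
``(filter_count, filter_size)`` gene pairs, one pair per convolutional
layer.  The dense-head variant (used when searching the classifier head on
top of a frozen feature extractor) is a chromosome of dense-layer widths.
All genes are integers with inclusive bounds held in :class:`GAConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ConvGenome",
    "DenseHeadGenome",
    "CostWeights",
    "MutationDelta",
    "GAConfig",
    "ConfigError",
    "DecodeError",
    "random_genome",
    "random_head_genome",
    "encode",
    "decode",
]


class ConfigError(ValueError):
    """Raised when a run configuration violates its invariants."""


class DecodeError(ValueError):
    """Raised when a flat gene vector cannot be decoded into a valid genome."""


@dataclass(frozen=True)
class ConvGenome:
    """Variable-length chromosome: one ``(filter_count, filter_size)`` pair per conv layer.

    ``filter_count`` is the number of convolution filters in the layer and
    ``filter_size`` the square kernel side in pixels.  The chromosome length
    (number of layers) is itself evolvable.
    """

    layers: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("a ConvGenome needs at least one layer")
        for i, pair in enumerate(self.layers):
            if len(pair) != 2:
                raise ValueError(f"layer {i} is not a (count, size) pair: {pair!r}")
            count, size = pair
            if int(count) != count or int(size) != size:
                raise ValueError(f"layer {i} has non-integer genes: {pair!r}")
            if count < 1 or size < 1:
                raise ValueError(f"layer {i} has non-positive genes: {pair!r}")
        # normalize to plain int tuples (guards against numpy scalars leaking in)
        object.__setattr__(
            self, "layers", tuple((int(c), int(s)) for c, s in self.layers)
        )

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def filter_counts(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.layers)

    @property
    def filter_sizes(self) -> tuple[int, ...]:
        return tuple(s for _, s in self.layers)

    def to_json(self) -> str:
        """Serialize as a JSON list of ``[count, size]`` pairs."""
        return json.dumps([[c, s] for c, s in self.layers])

    @classmethod
    def from_json(cls, text: str) -> "ConvGenome":
        return cls(tuple((int(c), int(s)) for c, s in json.loads(text)))


@dataclass(frozen=True)
class DenseHeadGenome:
    """Chromosome of dense-layer widths for the frozen-backbone head search."""

    widths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.widths) < 1:
            raise ValueError("a DenseHeadGenome needs at least one dense layer")
        if any(int(w) != w or w < 1 for w in self.widths):
            raise ValueError(f"widths must be positive integers: {self.widths!r}")
        object.__setattr__(self, "widths", tuple(int(w) for w in self.widths))

    def __len__(self) -> int:
        return len(self.widths)

    def to_json(self) -> str:
        return json.dumps(list(self.widths))

    @classmethod
    def from_json(cls, text: str) -> "DenseHeadGenome":
        return cls(tuple(int(w) for w in json.loads(text)))


@dataclass(frozen=True)
class CostWeights:
    """Weights (alpha, beta, gamma) on layer count, total filters and error rate."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigError(f"cost weight {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class MutationDelta:
    """Bounded additive perturbation for integer genes.

    The perturbation is drawn uniformly from ``{-d, ..., -1, 1, ..., d}``
    with ``d = max(1, ceil(frac * (hi - lo)))`` for a gene bounded by
    ``[lo, hi]``; the mutated gene is clamped back into its bounds.
    """

    frac: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.frac <= 1:
            raise ConfigError(f"mutation_delta.frac must be in (0, 1], got {self.frac}")

    def magnitude(self, lo: int, hi: int) -> int:
        return max(1, math.ceil(self.frac * (hi - lo)))

    def draw(self, lo: int, hi: int, rng: np.random.Generator) -> int:
        d = self.magnitude(lo, hi)
        step = int(rng.integers(1, d + 1))
        return step if rng.random() < 0.5 else -step


_FITNESS_KINDS = ("confusion", "accuracy_pct", "surrogate")


@dataclass(frozen=True)
class GAConfig:
    """Every control parameter of the evolutionary search.

    Defaults follow the strongest reported search setting: population 20,
    up to 11 generations, at most 6 convolutional layers, filter counts up
    to 256 and kernel sizes up to 7, dense-head widths in [200, 600].
    """

    population_size: int = 20
    max_generations: int = 11
    max_layers: int = 6
    max_filters: int = 256
    max_filter_size: int = 7
    min_neurons: int = 200
    max_neurons: int = 600
    crossover_prob: float = 0.5
    mutation_rate: float = 0.1
    mutation_delta: MutationDelta = field(default_factory=MutationDelta)
    structural_mutation: bool = False
    elitism_k: int | None = None
    patience: int = 3
    seed: int = 0
    fitness_kind: str = "accuracy_pct"
    cost_weights: CostWeights | None = None

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ConfigError("population_size must be >= 1")
        if self.max_generations < 1:
            raise ConfigError("max_generations must be >= 1")
        if self.max_layers < 1:
            raise ConfigError("max_layers must be >= 1")
        if self.max_filters < 1 or self.max_filter_size < 1:
            raise ConfigError("gene upper bounds must be >= 1")
        if not 1 <= self.min_neurons <= self.max_neurons:
            raise ConfigError("need 1 <= min_neurons <= max_neurons")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ConfigError("crossover_prob must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation_rate must be in [0, 1]")
        if self.elitism_k is None:
            object.__setattr__(
                self, "elitism_k", max(1, math.ceil(self.population_size / 4))
            )
        if not 1 <= self.elitism_k <= self.population_size:
            raise ConfigError("need 1 <= elitism_k <= population_size")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.fitness_kind not in _FITNESS_KINDS:
            raise ConfigError(
                f"fitness_kind must be one of {_FITNESS_KINDS}, got {self.fitness_kind!r}"
            )

    # -- gene bounds -------------------------------------------------------

    def conv_bounds(self, gene_index: int) -> tuple[int, int]:
        """Inclusive bounds for flat-vector position ``gene_index`` (even =
        filter count, odd = filter size)."""
        if gene_index % 2 == 0:
            return 1, self.max_filters
        return 1, self.max_filter_size

    def head_bounds(self) -> tuple[int, int]:
        return self.min_neurons, self.max_neurons

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cost_weights is None:
            d.pop("cost_weights")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        d = dict(d)
        if "mutation_delta" in d and isinstance(d["mutation_delta"], dict):
            d["mutation_delta"] = MutationDelta(**d["mutation_delta"])
        if "cost_weights" in d and isinstance(d["cost_weights"], dict):
            d["cost_weights"] = CostWeights(**d["cost_weights"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "GAConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(payload.get("ga", payload))


# ---------------------------------------------------------------------------
# Sampling and flat-vector codec
# ---------------------------------------------------------------------------


def random_genome(config: GAConfig, rng: np.random.Generator) -> ConvGenome:
    """Draw a chromosome uniformly: length on ``[1, max_layers]``, each
    filter count on ``[1, max_filters]``, each kernel size on
    ``[1, max_filter_size]``."""
    n_layers = int(rng.integers(1, config.max_layers + 1))
    counts = rng.integers(1, config.max_filters + 1, size=n_layers)
    sizes = rng.integers(1, config.max_filter_size + 1, size=n_layers)
    return ConvGenome(tuple(zip(counts.tolist(), sizes.tolist())))


def random_head_genome(
    config: GAConfig, rng: np.random.Generator, n_layers: int | None = None
) -> DenseHeadGenome:
    """Draw a dense-head chromosome with widths uniform on
    ``[min_neurons, max_neurons]``; depth uniform on [1, 2] unless given."""
    if n_layers is None:
        n_layers = int(rng.integers(1, 3))
    widths = rng.integers(config.min_neurons, config.max_neurons + 1, size=n_layers)
    return DenseHeadGenome(tuple(widths.tolist()))


def encode(genome: ConvGenome) -> list[int]:
    """Flatten to ``[count_1, size_1, count_2, size_2, ...]``."""
    return [g for pair in genome.layers for g in pair]


def decode(vector: Sequence[int], config: GAConfig) -> ConvGenome:
    """Rebuild a genome from its flat vector, validating every gene bound.

    Raises :class:`DecodeError` naming the offending flat index on an
    odd-length vector or an out-of-bounds gene.
    """
    vec = list(vector)
    if len(vec) < 2 or len(vec) % 2 != 0:
        raise DecodeError(
            f"gene vector length must be even and >= 2, got {len(vec)}"
        )
    if len(vec) // 2 > config.max_layers:
        raise DecodeError(
            f"vector encodes {len(vec) // 2} layers, config allows {config.max_layers}"
        )
    for i, gene in enumerate(vec):
        lo, hi = config.conv_bounds(i)
        if int(gene) != gene:
            raise DecodeError(f"gene at index {i} is not an integer: {gene!r}")
        if not lo <= gene <= hi:
            raise DecodeError(
                f"gene at index {i} out of bounds [{lo}, {hi}]: {gene}"
            )
    pairs = tuple((int(vec[i]), int(vec[i + 1])) for i in range(0, len(vec), 2))
    return ConvGenome(pairs)
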