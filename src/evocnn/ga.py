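"""Evolutionary loop: elitist retention, two crossover sub-operators,
bounded additive mutation, and plateau-based stopping.

The search object is a variable-length chromosome (see :mod:`evocnn.genome`).
Because chromosome length encodes network depth, crossover splits into two
sub-operators: a *length* crossover that changes the number of chromosome
columns (and hence the number of convolutional layers), and a per-gene
*uniform* crossover applied between equal-length parents.  Survivor
selection keeps the top-k individuals by fitness under a deterministic
total order, so the best fitness never decreases while ``elitism_k >= 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    ConvGenome,
    DenseHeadGenome,
    GAConfig,
    MutationDelta,
    random_genome,
)

__all__ = [
    "Individual",
    "Population",
    "RunHistory",
    "EvolutionError",
    "initialize_population",
    "uniform_crossover",
    "length_crossover",
    "mutate",
    "select_survivors",
    "evolve",
]

Genome = ConvGenome | DenseHeadGenome

_IMPROVEMENT_TOL = 1e-9  # strict-improvement tolerance for plateau detection


class EvolutionError(RuntimeError):
    """A fitness evaluation raised; carries the generation and genome."""


@dataclass
class Individual:
    genome: Genome
    fitness: float | None = None
    generation_born: int = 0

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None

    def sort_key(self) -> tuple:
        """Total order: higher fitness first, then earlier generation, then
        lexicographically smaller genome serialization."""
        return (-self.fitness, self.generation_born, self.genome.to_json())


@dataclass
class Population:
    individuals: list[Individual]
    generation: int = 0

    def __len__(self) -> int:
        return len(self.individuals)

    def best(self) -> Individual:
        return min(self.individuals, key=Individual.sort_key)


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_genome: Genome


@dataclass
class RunHistory:
    """Per-generation best/mean fitness and best genome, plus stop reason."""

    records: list[GenerationRecord] = field(default_factory=list)
    stop_reason: str = ""

    def append(self, pop: Population) -> None:
        fits = [ind.fitness for ind in pop.individuals]
        best = pop.best()
        self.records.append(
            GenerationRecord(
                generation=pop.generation,
                best_fitness=best.fitness,
                mean_fitness=float(np.mean(fits)),
                best_genome=best.genome,
            )
        )

    def best_fitnesses(self) -> list[float]:
        return [r.best_fitness for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [r.generation for r in self.records],
                "best_fitness": [r.best_fitness for r in self.records],
                "mean_fitness": [r.mean_fitness for r in self.records],
                "best_genome_json": [r.best_genome.to_json() for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------


def initialize_population(config: GAConfig, rng: np.random.Generator) -> Population:
    """Population of ``population_size`` uniformly random genomes, generation 0."""
    individuals = [
        Individual(genome=random_genome(config, rng), generation_born=0)
        for _ in range(config.population_size)
    ]
    return Population(individuals=individuals, generation=0)


def _genes(g: Genome) -> tuple:
    return g.layers if isinstance(g, ConvGenome) else g.widths


def _rebuild(template: Genome, genes: Sequence) -> Genome:
    if isinstance(template, ConvGenome):
        return ConvGenome(tuple(genes))
    return DenseHeadGenome(tuple(genes))


def uniform_crossover(
    p1: Genome, p2: Genome, p_c: float, rng: np.random.Generator
) -> Genome:
    """Per-gene uniform crossover between equal-length parents.

    Gene ``i`` of the child comes from ``p1`` with probability ``p_c``,
    else from ``p2``.  For conv chromosomes a gene is a whole
    ``(count, size)`` layer pair, so layers stay intact.
    """
    g1, g2 = _genes(p1), _genes(p2)
    if len(g1) != len(g2):
        raise ValueError(
            f"uniform_crossover needs equal-length parents, got {len(g1)} and "
            f"{len(g2)}; apply length_crossover first"
        )
    mask = rng.random(len(g1)) < p_c
    child = [g1[i] if mask[i] else g2[i] for i in range(len(g1))]
    return _rebuild(p1, child)


def length_crossover(
    p1: Genome, p2: Genome, rng: np.random.Generator, config: GAConfig
) -> Genome:
    """Length-altering crossover (the column-count sub-operator).

    The child's length is uniform on ``[min(L1,L2), max(L1,L2)]`` clipped to
    ``[1, max_layers]``; each child position is copied from a uniformly
    chosen parent among those long enough to supply it.
    """
    g1, g2 = _genes(p1), _genes(p2)
    lo, hi = sorted((len(g1), len(g2)))
    max_len = config.max_layers if isinstance(p1, ConvGenome) else hi
    lo, hi = max(1, min(lo, max_len)), min(hi, max_len)
    length = int(rng.integers(lo, hi + 1))
    child = []
    for i in range(length):
        donors = [g for g in (g1, g2) if i < len(g)]
        child.append(donors[int(rng.integers(len(donors)))][i])
    return _rebuild(p1, child)


def mutate(
    g: Genome,
    mutation_rate: float,
    mutation_delta: MutationDelta,
    config: GAConfig,
    rng: np.random.Generator,
) -> Genome:
    """Independently perturb each scalar gene with probability
    ``mutation_rate`` by a bounded integer step, clamping into bounds."""
    if isinstance(g, ConvGenome):
        flat = [v for pair in g.layers for v in pair]
        bounds = [config.conv_bounds(i) for i in range(len(flat))]
    else:
        flat = list(g.widths)
        bounds = [config.head_bounds()] * len(flat)

    out = []
    for v, (lo, hi) in zip(flat, bounds):
        if rng.random() < mutation_rate:
            v = int(np.clip(v + mutation_delta.draw(lo, hi, rng), lo, hi))
        out.append(v)

    if isinstance(g, ConvGenome):
        pairs = [(out[i], out[i + 1]) for i in range(0, len(out), 2)]
        genome = ConvGenome(tuple(pairs))
        if config.structural_mutation and rng.random() < mutation_rate:
            genome = _structural_mutation(genome, config, rng)
        return genome
    return DenseHeadGenome(tuple(out))


def _structural_mutation(
    g: ConvGenome, config: GAConfig, rng: np.random.Generator
) -> ConvGenome:
    """Insert or delete one random layer, respecting [1, max_layers]."""
    layers = list(g.layers)
    can_insert = len(layers) < config.max_layers
    can_delete = len(layers) > 1
    if not (can_insert or can_delete):
        return g
    if can_insert and (not can_delete or rng.random() < 0.5):
        pos = int(rng.integers(len(layers) + 1))
        count = int(rng.integers(1, config.max_filters + 1))
        size = int(rng.integers(1, config.max_filter_size + 1))
        layers.insert(pos, (count, size))
    else:
        layers.pop(int(rng.integers(len(layers))))
    return ConvGenome(tuple(layers))


def select_survivors(population: Population, k: int) -> Population:
    """The ``k`` highest-fitness individuals under the deterministic total
    order (fitness desc, generation_born asc, genome JSON asc)."""
    if not 1 <= k <= len(population):
        raise ValueError(f"need 1 <= k <= {len(population)}, got {k}")
    for ind in population.individuals:
        if not ind.evaluated:
            raise ValueError("select_survivors requires every individual evaluated")
    ranked = sorted(population.individuals, key=Individual.sort_key)
    return Population(individuals=ranked[:k], generation=population.generation)


# ---------------------------------------------------------------------------
# The loop
# ---------------------------------------------------------------------------


def _evaluate(pop: Population, fitness_fn: Callable[[Genome], float]) -> None:
    for ind in pop.individuals:
        if ind.evaluated:
            continue
        try:
            f = float(fitness_fn(ind.genome))
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise EvolutionError(
                f"fitness evaluation raised at generation {pop.generation} "
                f"for genome {ind.genome.to_json()}: {exc}"
            ) from exc
        if not np.isfinite(f):
            raise EvolutionError(
                f"non-finite fitness {f} at generation {pop.generation} "
                f"for genome {ind.genome.to_json()}"
            )
        ind.fitness = f


def _make_child(
    elites: list[Individual],
    config: GAConfig,
    rng: np.random.Generator,
    generation: int,
) -> Individual:
    i = int(rng.integers(len(elites)))
    j = int(rng.integers(len(elites)))
    p1, p2 = elites[i].genome, elites[j].genome
    if len(_genes(p1)) != len(_genes(p2)):
        child = length_crossover(p1, p2, rng, config)
    else:
        child = uniform_crossover(p1, p2, config.crossover_prob, rng)
    child = mutate(child, config.mutation_rate, config.mutation_delta, config, rng)
    return Individual(genome=child, generation_born=generation)


def evolve(
    config: GAConfig,
    fitness_fn: Callable[[Genome], float],
    rng: np.random.Generator | None = None,
    initial: Population | None = None,
) -> tuple[Individual, RunHistory]:
    """Run the search; returns the best-ever individual and the history.

    Each generation: evaluate everyone, keep the ``elitism_k`` best, refill
    to ``population_size`` with mutated crossover children of uniformly
    chosen elite parents.  The loop stops at ``max_generations`` or once the
    best fitness has not strictly improved (beyond 1e-9) for ``patience``
    consecutive generations.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = initial if initial is not None else initialize_population(config, rng)

    history = RunHistory()
    best_ever: Individual | None = None
    stale = 0

    for gen in range(config.max_generations):
        pop.generation = gen
        _evaluate(pop, fitness_fn)
        history.append(pop)

        gen_best = pop.best()
        if best_ever is None or gen_best.fitness > best_ever.fitness + _IMPROVEMENT_TOL:
            best_ever = Individual(
                genome=gen_best.genome,
                fitness=gen_best.fitness,
                generation_born=gen_best.generation_born,
            )
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                history.stop_reason = (
                    f"plateau: no improvement for {config.patience} generations"
                )
                return best_ever, history

        if gen == config.max_generations - 1:
            break

        elites = select_survivors(pop, config.elitism_k).individuals
        # Refill avoiding duplicate genomes where possible: re-evaluating an
        # identical chromosome wastes a (potentially expensive) training run.
        seen = {ind.genome.to_json() for ind in elites}
        children = []
        for _ in range(config.population_size - len(elites)):
            child = _make_child(elites, config, rng, gen + 1)
            for _retry in range(10):
                if child.genome.to_json() not in seen:
                    break
                child = _make_child(elites, config, rng, gen + 1)
            seen.add(child.genome.to_json())
            children.append(child)
        pop = Population(individuals=list(elites) + children, generation=gen + 1)

    history.stop_reason = f"max_generations: reached {config.max_generations}"
    return best_ever, history


def run_manifest(
    config: GAConfig, best: Individual, history: RunHistory, extra: dict | None = None
) -> dict:
    """JSON-serializable record sufficient to re-run the search in
    surrogate mode."""
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "best_genome": json.loads(best.genome.to_json()),
        "best_fitness": best.fitness,
        "generations_run": len(history.records),
        "stop_reason": history.stop_reason,
    }
    if extra:
        manifest.update(extra)
    return manifest
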