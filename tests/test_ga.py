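"""Evolutionary mechanics: operators, selection, stopping, reproducibility."""

import itertools

import numpy as np
import pytest

from evocnn import (
    ConvGenome,
    GAConfig,
    Individual,
    Population,
    evolve,
    initialize_population,
    length_crossover,
    mutate,
    select_survivors,
    uniform_crossover,
)
from evocnn.ga import EvolutionError
from evocnn.genome import MutationDelta
from evocnn.train import surrogate_fitness


class TestInitialization:
    def test_size_and_unevaluated(self, small_config, rng):
        pop = initialize_population(small_config, rng)
        assert len(pop) == small_config.population_size
        assert pop.generation == 0
        assert all(not ind.evaluated for ind in pop.individuals)

    def test_deterministic_under_seed(self, small_config):
        p1 = initialize_population(small_config, np.random.default_rng(5))
        p2 = initialize_population(small_config, np.random.default_rng(5))
        assert [i.genome for i in p1.individuals] == [i.genome for i in p2.individuals]

    def test_all_lengths_within_bounds(self):
        config = GAConfig(population_size=20, max_layers=6)
        pop = initialize_population(config, np.random.default_rng(0))
        assert all(1 <= len(ind.genome) <= 6 for ind in pop.individuals)


class TestUniformCrossover:
    p1 = ConvGenome(((1, 1), (2, 2), (3, 3), (4, 4)))
    p2 = ConvGenome(((11, 5), (12, 5), (13, 5), (14, 5)))

    def test_degenerate_probabilities(self, rng):
        assert uniform_crossover(self.p1, self.p2, 1.0, rng) == self.p1
        assert uniform_crossover(self.p1, self.p2, 0.0, rng) == self.p2

    def test_child_genes_come_from_parents(self, rng):
        for _ in range(50):
            child = uniform_crossover(self.p1, self.p2, 0.5, rng)
            assert len(child) == len(self.p1)
            for i, layer in enumerate(child.layers):
                assert layer in (self.p1.layers[i], self.p2.layers[i])

    def test_gene_origin_frequency_matches_pc(self):
        """Each gene's P1-origin frequency over 10,000 children must lie
        within 3 binomial sigma of p_c = 0.5."""
        rng = np.random.default_rng(77)
        n = 10_000
        from_p1 = np.zeros(len(self.p1), dtype=int)
        for _ in range(n):
            child = uniform_crossover(self.p1, self.p2, 0.5, rng)
            for i, layer in enumerate(child.layers):
                from_p1[i] += layer == self.p1.layers[i]
        sigma = np.sqrt(n * 0.25)
        assert np.all(np.abs(from_p1 - n * 0.5) <= 3 * sigma)

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="length_crossover"):
            uniform_crossover(self.p1, ConvGenome(((1, 1),)), 0.5, rng)


class TestLengthCrossover:
    def test_equal_lengths_preserved(self, small_config, rng):
        p = ConvGenome(((1, 1), (2, 2)))
        q = ConvGenome(((3, 3), (4, 4)))
        assert len(length_crossover(p, q, rng, small_config)) == 2

    def test_identical_parents_give_identical_child(self, small_config, rng):
        p = ConvGenome(((5, 2), (6, 3)))
        assert length_crossover(p, p, rng, small_config) == p

    def test_length_distribution_uniform(self):
        """Child lengths of a 4-layer x 6-layer cross are uniform over
        {4, 5, 6} within 3 sigma at 10,000 trials."""
        config = GAConfig(max_layers=6, max_filters=16, max_filter_size=5)
        p1 = ConvGenome(tuple((i + 1, 1) for i in range(4)))
        p2 = ConvGenome(tuple((i + 1, 2) for i in range(6)))
        rng = np.random.default_rng(3)
        n = 10_000
        counts = {4: 0, 5: 0, 6: 0}
        for _ in range(n):
            child = length_crossover(p1, p2, rng, config)
            counts[len(child)] += 1
        assert set(counts) == {4, 5, 6}
        p = 1 / 3
        sigma = np.sqrt(n * p * (1 - p))
        for length in (4, 5, 6):
            assert abs(counts[length] - n * p) <= 3 * sigma

    def test_length_clipped_to_max_layers(self, rng):
        config = GAConfig(max_layers=3, max_filters=16, max_filter_size=5)
        p1 = ConvGenome(((1, 1),))
        p2 = ConvGenome(((2, 2),) * 3)
        for _ in range(30):
            child = length_crossover(p1, p2, rng, config)
            assert 1 <= len(child) <= 3


class TestMutation:
    def test_zero_rate_is_identity(self, small_config, rng):
        g = ConvGenome(((8, 3), (16, 5)))
        assert mutate(g, 0.0, small_config.mutation_delta, small_config, rng) == g

    def test_clamped_at_bounds(self):
        config = GAConfig(max_layers=2, max_filters=16, max_filter_size=5)
        g = ConvGenome(((16, 5),))  # every gene at its upper bound
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = mutate(g, 1.0, config.mutation_delta, config, rng)
            count, size = m.layers[0]
            assert 1 <= count <= 16
            assert 1 <= size <= 5

    def test_mean_absolute_change_matches_delta_distribution(self):
        """With rate 1 on a mid-range gene (no clamping), the empirical mean
        |change| over 10,000 trials must match the enumerated mean of the
        perturbation distribution within 3 sigma."""
        config = GAConfig(max_layers=1, max_filters=101, max_filter_size=3)
        delta = MutationDelta(frac=0.1)
        d = delta.magnitude(1, 101)  # = 10
        support = [k for k in range(-d, d + 1) if k != 0]
        mean_abs = np.mean(np.abs(support))
        var_abs = np.var(np.abs(support))
        g = ConvGenome(((50, 2),))  # 50 +- 10 stays inside [1, 101]
        rng = np.random.default_rng(9)
        n = 10_000
        changes = []
        for _ in range(n):
            m = mutate(g, 1.0, delta, config, rng)
            changes.append(abs(m.layers[0][0] - 50))
        se = np.sqrt(var_abs / n)
        assert abs(np.mean(changes) - mean_abs) <= 3 * se

    def test_structural_mutation_changes_length_within_bounds(self):
        config = GAConfig(
            max_layers=3, max_filters=8, max_filter_size=3, structural_mutation=True
        )
        g = ConvGenome(((4, 2), (5, 3)))
        rng = np.random.default_rng(2)
        lengths = {
            len(mutate(g, 1.0, config.mutation_delta, config, rng)) for _ in range(200)
        }
        assert lengths <= {1, 2, 3}
        assert len(lengths) > 1  # insertions/deletions actually happen


class TestSelection:
    def _random_population(self, rng, n=20):
        inds = [
            Individual(
                genome=ConvGenome(((int(rng.integers(1, 16)), 3),)),
                fitness=float(rng.normal()),
                generation_born=int(rng.integers(0, 5)),
            )
            for _ in range(n)
        ]
        return Population(individuals=inds, generation=0)

    def test_k_equals_size_returns_same_set(self, rng):
        pop = self._random_population(rng)
        survivors = select_survivors(pop, len(pop))
        assert {id(i) for i in survivors.individuals} == {
            id(i) for i in pop.individuals
        }

    def test_k_one_is_argmax(self, rng):
        pop = self._random_population(rng)
        top = select_survivors(pop, 1).individuals[0]
        assert top.fitness == max(i.fitness for i in pop.individuals)

    def test_matches_brute_force_sort(self, rng):
        """Top-5 must equal the head of a full sort by (fitness desc,
        generation asc, genome JSON asc)."""
        for _ in range(20):
            pop = self._random_population(rng)
            expected = sorted(
                pop.individuals,
                key=lambda i: (-i.fitness, i.generation_born, i.genome.to_json()),
            )[:5]
            got = select_survivors(pop, 5).individuals
            assert [id(i) for i in got] == [id(i) for i in expected]

    def test_unevaluated_individual_rejected(self):
        pop = Population([Individual(genome=ConvGenome(((1, 1),)))])
        with pytest.raises(ValueError, match="evaluated"):
            select_survivors(pop, 1)

    def test_tie_break_is_deterministic(self):
        a = Individual(ConvGenome(((2, 2),)), fitness=1.0, generation_born=1)
        b = Individual(ConvGenome(((1, 1),)), fitness=1.0, generation_born=0)
        c = Individual(ConvGenome(((3, 3),)), fitness=1.0, generation_born=0)
        pop = Population([a, b, c])
        got = select_survivors(pop, 2).individuals
        assert got[0] is b and got[1] is c  # earlier generation, then smaller JSON


class TestEvolve:
    def test_constant_fitness_stops_after_patience_plus_one(self, small_config):
        config = GAConfig(
            population_size=5, max_generations=50, max_layers=2,
            max_filters=8, max_filter_size=3, patience=3, seed=0,
        )
        best, history = evolve(config, lambda g: 1.0)
        assert len(history.records) == config.patience + 1
        assert "plateau" in history.stop_reason
        assert best.fitness == 1.0

    def test_elitism_makes_best_fitness_monotone(self):
        """Best fitness non-decreasing across every generation of 20 seeded
        runs on a noisy-but-deterministic landscape."""
        for seed in range(20):
            config = GAConfig(
                population_size=8, max_generations=15, max_layers=3,
                max_filters=16, max_filter_size=5, elitism_k=2,
                patience=15, seed=seed, mutation_rate=0.3,
            )
            fitness = surrogate_fitness(ConvGenome(((9, 3), (4, 2))))
            _, history = evolve(config, fitness)
            best_seq = history.best_fitnesses()
            assert all(b >= a - 1e-12 for a, b in itertools.pairwise(best_seq))

    def test_bit_reproducible_under_seed(self, small_config):
        fitness = surrogate_fitness(ConvGenome(((5, 3),)))
        b1, h1 = evolve(small_config, fitness)
        b2, h2 = evolve(small_config, fitness)
        assert b1.genome == b2.genome
        assert h1.best_fitnesses() == h2.best_fitnesses()
        assert [r.best_genome for r in h1.records] == [r.best_genome for r in h2.records]

    def test_every_genome_respects_bounds_across_a_run(self):
        config = GAConfig(
            population_size=10, max_generations=10, max_layers=4,
            max_filters=12, max_filter_size=4, patience=10, seed=4,
            mutation_rate=0.5, structural_mutation=True,
        )
        seen = []

        def fitness(g):
            seen.append(g)
            return -float(sum(c + s for c, s in g.layers))

        evolve(config, fitness)
        assert len(seen) >= config.population_size
        for g in seen:
            assert 1 <= len(g) <= 4
            for count, size in g.layers:
                assert 1 <= count <= 12
                assert 1 <= size <= 4

    def test_surrogate_optimum_recovered(self):
        """On a ~5,000-point landscape the GA (population 20, patience 5)
        finds the brute-force optimum."""
        target = ConvGenome(((7, 3), (4, 6)))
        fitness = surrogate_fitness(target)
        config = GAConfig(
            population_size=20, max_generations=50, max_layers=2,
            max_filters=10, max_filter_size=7, patience=5, seed=1,
            mutation_rate=0.2,
        )
        best, _ = evolve(config, fitness)
        assert best.genome == target
        assert best.fitness == 0.0

    def test_failing_fitness_aborts_with_context(self, small_config):
        def bad(g):
            raise RuntimeError("boom")

        with pytest.raises(EvolutionError, match="generation 0"):
            evolve(small_config, bad)

    def test_history_serialization(self, tmp_path, small_config):
        _, history = evolve(small_config, surrogate_fitness(ConvGenome(((5, 3),))))
        path = tmp_path / "history.csv"
        history.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == [
            "generation", "best_fitness", "mean_fitness", "best_genome_json",
        ]
        assert len(df) == len(history.records)
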