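import math

import numpy as np
import pandas as pd
import pytest

from kernelscape.resistance import SourcePointSet
from kernelscape.simulate import (
    PopulationState,
    SimParams,
    global_genetic_summary,
    inbreeding_coefficient,
    init_population,
    movement_weight,
    run_replicates,
    step_generation,
)


def grid_sources(n, spacing_cells=3, cols=None):
    cols = cols or int(np.ceil(np.sqrt(n)))
    pts = [[(i // cols) * spacing_cells, (i % cols) * spacing_cells] for i in range(n)]
    return SourcePointSet(np.asarray(pts), threshold=0.0, seed=0)


def panmictic_costs(n, cost=2000.0):
    cm = np.full((n, n), cost)
    np.fill_diagonal(cm, 0.0)
    return cm


class TestInitPopulation:
    def test_full_initial_occupancy(self):
        params = SimParams(seed=1)
        state = init_population(grid_sources(30), params)
        assert state.n == 30
        assert len(np.unique(state.locations)) == 30

    def test_initial_he_matches_uniform_alleles(self):
        params = SimParams(seed=2)
        state = init_population(grid_sources(200), params)
        he = global_genetic_summary(state).he
        # uniform 10 alleles: E[He] = 0.9, sampling SE across 30 loci x 400 copies
        assert abs(he - 0.9) < 3 * 0.01

    def test_identical_seed_identical_genotypes(self):
        params = SimParams(seed=3)
        a = init_population(grid_sources(20), params)
        b = init_population(grid_sources(20), params)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.sexes, b.sexes)

    def test_needs_two_sources(self):
        with pytest.raises(ValueError):
            init_population(grid_sources(1), SimParams())


class TestMovementWeight:
    def test_hard_truncation(self):
        p = SimParams(max_cost_distance=10_000.0)
        assert movement_weight(10_001.0, p) == 0.0
        assert movement_weight(np.inf, p) == 0.0

    def test_inverse_square_selection_probabilities(self):
        p = SimParams()
        w = movement_weight(np.array([1000.0, 2000.0]), p)
        probs = w / w.sum()
        np.testing.assert_allclose(probs, [4 / 5, 1 / 5])

    def test_zero_cost_floored_at_one_cell(self):
        p = SimParams(cell_size=1000.0)
        assert movement_weight(0.0, p) == movement_weight(1000.0, p)
        assert np.isfinite(movement_weight(0.0, p))


class TestStepGeneration:
    def two_individual_state(self, params, allele_a=0, allele_b=1):
        geno = np.empty((2, params.n_loci, 2), dtype=np.int64)
        geno[0] = allele_a
        geno[1] = allele_b
        return PopulationState(
            locations=np.array([0, 1]),
            sexes=np.array([True, False]),
            genotypes=geno,
            generation=0,
            n_locations=4,
            next_allele=params.n_init_alleles,
        )

    def test_mendelian_cross_all_heterozygous(self, rng):
        params = SimParams(mutation_rate=0.0, max_cost_distance=50_000.0, seed=0)
        state = self.two_individual_state(params)
        nxt, _ = step_generation(state, panmictic_costs(4), params, rng)
        assert nxt.n > 0
        summary = global_genetic_summary(nxt)
        assert summary.ho == 1.0  # every offspring carries one 0 and one 1

    def test_isolated_female_produces_nothing(self, rng):
        params = SimParams(max_cost_distance=1000.0, seed=0)
        state = self.two_individual_state(params)
        costs = np.full((4, 4), 1e9)
        np.fill_diagonal(costs, 0.0)
        nxt, _ = step_generation(state, costs, params, rng)
        assert nxt.extinct

    def test_allele_set_never_grows_without_mutation(self, rng):
        params = SimParams(mutation_rate=0.0, max_cost_distance=1e6, n_reps=1, seed=5)
        n = 20
        state = init_population(grid_sources(n), params)
        costs = panmictic_costs(n)
        alleles_before = [set(np.unique(state.genotypes[:, l, :])) for l in range(params.n_loci)]
        for _ in range(10):
            state, _ = step_generation(state, costs, params, rng)
            for l in range(params.n_loci):
                now = set(np.unique(state.genotypes[:, l, :]))
                assert now <= alleles_before[l]
                alleles_before[l] = now

    def test_population_never_exceeds_locations(self, rng):
        params = SimParams(max_cost_distance=1e6, offspring_mean=6.0, seed=6)
        n = 15
        state = init_population(grid_sources(n), params)
        costs = panmictic_costs(n)
        for _ in range(5):
            state, _ = step_generation(state, costs, params, rng)
            assert state.n <= n

    def test_capacity_maintained_in_panmixia(self, rng):
        params = SimParams(max_cost_distance=1e6, seed=7, maintain_capacity=True)
        n = 30
        state = init_population(grid_sources(n), params)
        costs = panmictic_costs(n)
        for _ in range(20):
            state, _ = step_generation(state, costs, params, rng)
            assert state.n == n

    def test_mutation_introduces_novel_identifiers(self, rng):
        params = SimParams(mutation_rate=0.05, max_cost_distance=1e6, seed=8)
        n = 20
        state = init_population(grid_sources(n), params)
        costs = panmictic_costs(n)
        for _ in range(5):
            state, _ = step_generation(state, costs, params, rng)
        assert state.genotypes.max() >= params.n_init_alleles
        assert state.next_allele > params.n_init_alleles


class TestGeneticSummary:
    def test_inbreeding_identity(self):
        assert inbreeding_coefficient(0.887, 0.777) == pytest.approx(0.124, abs=5e-4)

    def test_monomorphic_population_signals_undefined_f(self):
        geno = np.zeros((5, 30, 2), dtype=np.int64)
        state = PopulationState(np.arange(5), np.zeros(5, dtype=bool), geno, 0, 5, 10)
        s = global_genetic_summary(state)
        assert s.he == 0.0 and s.ho == 0.0
        assert math.isnan(s.f)
        assert s.total_alleles == 30

    def test_two_individual_frequencies(self):
        geno = np.zeros((2, 1, 2), dtype=np.int64)
        geno[0] = [0, 1]
        geno[1] = [2, 3]
        state = PopulationState(np.arange(2), np.zeros(2, dtype=bool), geno, 0, 2, 10)
        s = global_genetic_summary(state)
        assert s.he == pytest.approx(0.75)
        assert s.ho == 1.0
        assert s.total_alleles == 4


class TestRunReplicates:
    def test_deterministic_for_fixed_seed(self):
        params = SimParams(generations=10, n_reps=2, max_cost_distance=1e6, seed=9)
        costs = panmictic_costs(12)
        a, _ = run_replicates(costs, params)
        b, _ = run_replicates(costs, params)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    def test_connected_population_stays_at_capacity(self):
        params = SimParams(generations=30, n_reps=2, max_cost_distance=1e6, seed=10)
        traj, finals = run_replicates(panmictic_costs(20), params)
        for t in traj:
            assert t.iloc[-1]["n"] == 20

    def test_two_islands_drift_faster_than_one(self):
        # equal total N: one connected deme of 24 vs two isolated demes of 12
        params = SimParams(
            generations=80, n_reps=4, mutation_rate=0.0, max_cost_distance=5000.0, seed=11
        )
        one = panmictic_costs(24, cost=2000.0)
        two = panmictic_costs(24, cost=2000.0)
        two[:12, 12:] = 1e9
        two[12:, :12] = 1e9
        traj_one, _ = run_replicates(one, params)
        traj_two, _ = run_replicates(two, params)
        # within-individual diversity (Ho) erodes faster in the split system
        ho_one = np.mean([t.iloc[-1]["ho"] for t in traj_one])
        ho_two = np.mean([t.iloc[-1]["ho"] for t in traj_two])
        assert ho_two < ho_one
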