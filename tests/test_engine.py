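"""Wright-Fisher generation step, fixation handling, full-run contracts."""

import numpy as np
import pytest

from podsim import (
    ExtinctionError,
    Population,
    SelectionModel,
    SimParams,
    allele_counts,
    run_simulation,
    sweep_fixations,
    wf_generation,
)

from conftest import build_population

CONST = SelectionModel(mode="constant", s_const=-0.005)
NEUTRAL = SelectionModel(mode="constant", s_const=0.0)


class TestWfGeneration:
    def test_zero_fitness_parent_never_chosen(self, rng):
        # individual 1 is homozygous for a lethal (s = -1) allele
        pop = build_population(
            [[[], []], [[0], [0]]], ploidy=2, s=-1.0, h=0.0
        )
        assert pop.individuals[1].fitness == 0.0
        new = wf_generation(pop, CONST, rng)
        assert np.all(new.last_parent_indices == 0)

    def test_census_constant(self, rng):
        params = SimParams(N=30, ploidy=4, L=1000, mu=1e-4, rho=1e-6,
                           generations=1)
        pop = Population.founders(params)
        for _ in range(50):
            pop = wf_generation(pop, CONST, rng)
            assert len(pop.individuals) == 30
            assert all(ind.ploidy == 4 for ind in pop.individuals)

    def test_extinct_population_raises(self):
        pop = build_population([[[0], [0]], [[0], [0]]], ploidy=2, s=-1.0)
        with pytest.raises(ExtinctionError):
            wf_generation(pop, CONST, np.random.default_rng(0))

    def test_neutral_reproductive_success_variance(self, rng):
        # neutral WF: offspring number per parent is multinomial(2N, 1/N);
        # its variance is 2(1 - 1/N)
        N = 50
        params = SimParams(N=N, ploidy=2, L=1000, mu=0.0, rho=0.0, generations=1)
        pop = Population.founders(params)
        variances = []
        for _ in range(600):
            pop = wf_generation(pop, NEUTRAL, rng)
            counts = np.bincount(pop.last_parent_indices, minlength=N)
            variances.append(np.var(counts, ddof=1))
        expected = 2 * (1 - 1 / N)
        assert abs(np.mean(variances) - expected) < 0.1

    def test_parent_multiset_recorded(self, rng):
        pop = build_population([[[], []], [[], []], [[], []]], ploidy=2)
        new = wf_generation(pop, CONST, rng)
        assert new.last_parent_indices.shape == (6,)
        assert new.last_parent_fitnesses.shape == (6,)
        assert new.generation == pop.generation + 1


class TestSweepFixations:
    def test_fixed_mutation_moves_to_substitutions(self):
        pop = build_population(
            [[[0, 1], [0]], [[0], [0, 2]]], ploidy=2, s=-0.005
        )
        pop.generation = 7
        before = {int(i) for i in allele_counts(pop)[0]}
        assert before == {0, 1, 2}
        sweep_fixations(pop)
        assert [rec.id for rec, gen in pop.substitutions] == [0]
        assert pop.substitutions[0][1] == 7
        remaining, counts = allele_counts(pop)
        assert set(map(int, remaining)) == {1, 2}
        assert np.all(counts >= 1) and np.all(counts < 2 * pop.params.N)

    def test_fitness_recomputed_after_removal(self):
        # both individuals homozygous for allele 0: fixation lifts fitness to 1
        pop = build_population([[[0], [0]], [[0], [0]]], ploidy=2, s=-0.1)
        assert pop.individuals[0].fitness == pytest.approx(0.9)
        sweep_fixations(pop)
        assert all(ind.fitness == 1.0 for ind in pop.individuals)

    def test_noop_without_fixation(self):
        pop = build_population([[[0], []], [[], []]], ploidy=2)
        haps_before = [ind.haplotypes for ind in pop.individuals]
        sweep_fixations(pop)
        assert pop.substitutions == []
        assert [ind.haplotypes for ind in pop.individuals] == haps_before


class TestRunSimulation:
    def test_zero_generations_initial_row(self):
        params = SimParams(N=10, ploidy=2, L=1000, mu=1e-4, rho=0.0,
                           generations=0)
        traj = run_simulation(params, CONST)
        assert len(traj.rows) == 1
        row = traj.rows[0]
        assert np.isnan(row.median_allele_freq)
        assert row.mean_fitness == 1.0
        assert row.n_segregating == 0 and row.n_fixed_cumulative == 0

    def test_seeded_determinism_byte_identical(self, tmp_path):
        params = SimParams(N=20, ploidy=4, L=5000, mu=5e-5, rho=1e-6,
                           generations=150, seed=42, record_every=10)
        for name in ("a.tsv", "b.tsv"):
            run_simulation(params, CONST).to_tsv(tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_neutral_substitution_rate_is_mu_L(self):
        # after the drift transient, neutral substitutions accrue at mu*L
        # per generation regardless of N and ploidy
        mu_L = 0.1
        for ploidy, seed in ((2, 1), (4, 2)):
            params = SimParams(N=50, ploidy=ploidy, L=100_000, mu=1e-6,
                               rho=1e-8, generations=3000, seed=seed,
                               record_every=10)
            traj = run_simulation(params, NEUTRAL)
            start = next(r for r in traj.rows if r.generation == 600)
            window = traj.rows[-1].generation - start.generation
            observed = traj.rows[-1].n_fixed_cumulative - start.n_fixed_cumulative
            expected = mu_L * window
            se = np.sqrt(expected)
            assert abs(observed - expected) < 3 * se

    def test_substitution_ledger_disjoint_from_genomes(self):
        params = SimParams(N=20, ploidy=2, L=10_000, mu=5e-5, rho=0.0,
                           generations=500, seed=9, record_every=100)
        traj = run_simulation(params, NEUTRAL)
        pop = traj.final_population
        fixed_ids = {rec.id for rec, _ in pop.substitutions}
        segregating = {int(i) for i in allele_counts(pop)[0]}
        assert fixed_ids.isdisjoint(segregating)
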