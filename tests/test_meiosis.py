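"""Bivalent pairing, recombination, segregation and gamete mutation."""

import numpy as np
import pytest
from scipy import stats

from podsim import (
    Gamete,
    SelectionModel,
    SimParams,
    gamete_dosage_pmf,
    make_gamete,
    mutate_gamete,
    pair_bivalents,
    recombine_pair,
)
from podsim.engine import _MATCHINGS

from conftest import QueueRNG, build_population


def _tetraploid_with_dosage(d):
    haps = [[0] if i < d else [] for i in range(4)]
    return build_population([haps], ploidy=4)


class TestPairBivalents:
    def test_uniform_over_three_matchings(self, rng):
        from collections import Counter

        pop = _tetraploid_with_dosage(1)
        ind = pop.individuals[0]
        n = 30_000
        counts = Counter(tuple(pair_bivalents(ind, rng)) for _ in range(n))
        assert set(counts) == set(_MATCHINGS)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for m in _MATCHINGS:
            assert abs(counts[m] / n - 1 / 3) < 4 * se

    def test_partition_is_perfect_matching(self, rng):
        pop = _tetraploid_with_dosage(0)
        pairs = pair_bivalents(pop.individuals[0], rng)
        assert sorted(i for pair in pairs for i in pair) == [0, 1, 2, 3]

    def test_seeded_determinism(self):
        pop = _tetraploid_with_dosage(0)
        ind = pop.individuals[0]
        r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
        s1 = [pair_bivalents(ind, r1) for _ in range(1000)]
        s2 = [pair_bivalents(ind, r2) for _ in range(1000)]
        assert s1 == s2

    def test_rejects_diploid(self, rng):
        pop = build_population([[[0], []]], ploidy=2)
        with pytest.raises(ValueError):
            pair_bivalents(pop.individuals[0], rng)


class TestRecombinePair:
    def test_zero_rate_identity(self, rng):
        pop = build_population([[[0, 1], [2]]], ploidy=2)
        hapA, hapB = pop.individuals[0].haplotypes
        outA, outB = recombine_pair(hapA, hapB, 0.0, 1000, rng,
                                    pop.registry.position)
        assert outA is hapA and outB is hapB

    def test_single_forced_breakpoint(self, rng):
        # mutation at position 10 on hapA; breakpoint at boundary 500
        pop = build_population([[[10], []]], ploidy=2, n_mutations=11)
        hapA, hapB = pop.individuals[0].haplotypes
        outA, outB = recombine_pair(
            hapA, hapB, 1e-9, 1000, rng, pop.registry.position,
            k=1, breakpoints=np.array([500]),
        )
        assert outA.tolist() == [10] and outB.tolist() == []

    def test_reciprocal_products_conserve_ids(self, rng):
        pop = build_population([[[0, 2, 4, 6], [1, 3, 5]]], ploidy=2, n_mutations=7)
        hapA, hapB = pop.individuals[0].haplotypes
        for k in (1, 2, 5):
            outA, outB = recombine_pair(hapA, hapB, 1e-9, 1000, rng,
                                        pop.registry.position, k=k)
            merged = sorted(np.concatenate([outA, outB]).tolist())
            assert merged == list(range(7))

    def test_crossover_count_poisson_mean(self):
        # dense marker haplotypes: switches of origin along a product count
        # the effective crossovers; mean must match rho*(L-1) ~= 0.1
        L = 1_000_000
        rho = 1e-7
        n_markers = 1000
        pop = build_population(
            [[list(range(n_markers)), list(range(n_markers, 2 * n_markers))]],
            ploidy=2, n_mutations=2 * n_markers, L=L,
        )
        # interleave marker positions: hapA at even kb, hapB at odd kb offsets
        pop.registry.position[:n_markers] = np.arange(n_markers) * 1000
        pop.registry.position[n_markers:2 * n_markers] = np.arange(n_markers) * 1000 + 500
        hapA, hapB = pop.individuals[0].haplotypes
        rng = np.random.default_rng(99)
        switches = 0
        n = 100_000
        for _ in range(n):
            outA, _ = recombine_pair(hapA, hapB, rho, L, rng, pop.registry.position)
            origin = outA < n_markers
            switches += int(np.count_nonzero(origin[1:] != origin[:-1]))
        mean = switches / n
        se = np.sqrt(0.1 / n)  # Poisson variance
        assert abs(mean - rho * (L - 1)) < 3 * se + 1e-4  # small slack: same-gap cancellation


class TestMakeGamete:
    @pytest.mark.parametrize("d", range(5))
    def test_dosage_distribution_matches_hypergeometric(self, d):
        pop = _tetraploid_with_dosage(d)
        ind = pop.individuals[0]
        rng = np.random.default_rng(d)
        n = 20_000
        obs = np.zeros(3)
        for _ in range(n):
            g = make_gamete(ind, pop.params, rng, pop.registry)
            obs[sum(h.size for h in g.haplotypes)] += 1
        expected = gamete_dosage_pmf(d) * n
        mask = expected > 0
        assert np.all(obs[~mask] == 0)
        chi2 = np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask])
        dof = mask.sum() - 1
        if dof > 0:
            assert chi2 < stats.chi2.ppf(0.999, dof)

    def test_exhaustive_enumeration_of_duplex(self):
        # all 3 pairings x 2x2 segregation picks, each path probability 1/12
        pop = _tetraploid_with_dosage(2)
        ind = pop.individuals[0]
        tally = np.zeros(3)
        for m in range(3):
            for p1 in range(2):
                for p2 in range(2):
                    g = make_gamete(ind, pop.params, QueueRNG([m, p1, p2]),
                                    pop.registry)
                    tally[sum(h.size for h in g.haplotypes)] += 1
        np.testing.assert_allclose(tally / 12, [1 / 6, 4 / 6, 1 / 6])

    def test_diploid_mendelian(self):
        pop = build_population([[[0], []]], ploidy=2)
        ind = pop.individuals[0]
        rng = np.random.default_rng(5)
        carried = sum(
            make_gamete(ind, pop.params, rng, pop.registry).haplotypes[0].size
            for _ in range(20_000)
        )
        se = np.sqrt(0.25 / 20_000)
        assert abs(carried / 20_000 - 0.5) < 4 * se

    def test_no_double_reduction(self, rng):
        # tag each chromosome with a private marker; a gamete must carry
        # two distinct tags (its chromosomes come from different bivalents)
        pop = build_population([[[0], [1], [2], [3]]], ploidy=4)
        ind = pop.individuals[0]
        for _ in range(5_000)   :
            g = make_gamete(ind, pop.params, rng, pop.registry)
            tags = sorted(int(h[0]) for h in g.haplotypes)
            assert len(g.haplotypes) == 2
            assert tags[0] != tags[1]


class TestMutateGamete:
    def _gamete(self):
        return Gamete((np.array([5], dtype=np.int64),))

    def test_zero_rate_unchanged(self, rng):
        pop = build_population([[[5], []]], ploidy=2, n_mutations=6)
        params = pop.params
        g = self._gamete()
        out = mutate_gamete(g, params, 1, pop.registry,
                            SelectionModel(mode="constant", s_const=-0.01), rng)
        assert out.haplotypes[0] is g.haplotypes[0]

    def test_poisson_mean_new_mutations(self):
        params = SimParams(N=2, ploidy=2, L=1_000_000, mu=1e-7, rho=0,
                           generations=1)
        pop = build_population([[[], []]], ploidy=2, L=params.L)
        model = SelectionModel(mode="constant", s_const=-0.01)
        rng = np.random.default_rng(3)
        n = 100_000
        before = len(pop.registry)
        for _ in range(n):
            mutate_gamete(Gamete((np.empty(0, np.int64),)), params, 1,
                          pop.registry, model, rng)
        mean = (len(pop.registry) - before) / n
        se = np.sqrt(0.1 / n)
        assert abs(mean - 0.1) < 3 * se

    def test_stacking_two_events_same_position(self):
        pop = build_population([[[], []]], ploidy=2, L=1000)
        params = pop.params
        model = SelectionModel(mode="constant", s_const=-0.01)
        rng = QueueRNG([100, 100])  # both new mutations at position 100
        out = mutate_gamete(Gamete((np.empty(0, np.int64),)), params, 5,
                            pop.registry, model, rng,
                            counts=np.array([2]))
        hap = out.haplotypes[0]
        assert hap.size == 2 and hap[0] != hap[1]
        assert pop.registry.position[hap[0]] == pop.registry.position[hap[1]] == 100
        assert all(pop.registry.origin_generation[h] == 5 for h in hap)

    def test_insertion_preserves_position_order(self, rng):
        pop = build_population([[[], []]], ploidy=2, L=10_000)
        model = SelectionModel(mode="constant", s_const=-0.01)
        g = Gamete((np.empty(0, np.int64),))
        for _ in range(50):
            g = mutate_gamete(g, pop.params, 1, pop.registry, model, rng,
                              counts=np.array([3]))
        pos = pop.registry.position[g.haplotypes[0]]
        assert np.all(np.diff(pos) >= 0)
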