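import numpy as np
import pytest
from hypothesis import settings

from podsim import Individual, MutationRegistry, Population, SimParams

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


class QueueRNG:
    """Deterministic stand-in for a Generator: integers() pops scripted values.

    Used to drive meiosis down a prescribed branch (pairing choice,
    segregation picks) so gamete distributions can be enumerated exactly.
    """

    def __init__(self, values):
        self.values = list(values)

    def integers(self, *args, **kwargs):
        size = kwargs.get("size")
        if size is not None:
            return np.array([self.values.pop(0) for _ in range(int(size))])
        return self.values.pop(0)

    def poisson(self, lam, size=None):
        if size is None:
            return 0
        return np.zeros(size, dtype=np.int64)


def build_population(haplotype_lists, ploidy, s=-0.005, h=0.0, L=1000,
                     n_mutations=None, mu=0.0, rho=0.0):
    """Hand-build a Population from per-individual lists of id-lists.

    ``haplotype_lists`` is a list of individuals, each a list of ``ploidy``
    lists of mutation ids. The registry holds ``n_mutations`` alleles (the
    max id + 1 by default) at distinct positions, all with effect (s, h).
    """
    if len(haplotype_lists) == 1:
        # census invariant requires N >= 2; pad with a mutation-free individual
        haplotype_lists = haplotype_lists + [[[] for _ in range(ploidy)]]
    N = len(haplotype_lists)
    params = SimParams(N=N, ploidy=ploidy, L=L, mu=mu, rho=rho,
                       generations=1, record_every=1)
    registry = MutationRegistry()
    if n_mutations is None:
        all_ids = [i for ind in haplotype_lists for hap in ind for i in hap]
        n_mutations = (max(all_ids) + 1) if all_ids else 0
    if n_mutations:
        registry.add(np.arange(n_mutations) % L,
                     np.full(n_mutations, s), np.full(n_mutations, h), 0)
    individuals = []
    for haps in haplotype_lists:
        assert len(haps) == ploidy
        arrays = tuple(np.array(sorted(hap), dtype=np.int64) for hap in haps)
        ind = Individual(arrays)
        ind.fitness = ind.compute_fitness(registry)
        individuals.append(ind)
    return Population(individuals=individuals, params=params, registry=registry)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_tetraploid():
    """Two tetraploids sharing one mutation (id 0) at various dosages."""
    return build_population(
        [[[0], [0], [], []], [[0], [], [], []]], ploidy=4
    )
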