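"""Forward-in-time Wright-Fisher engine for diploid and autotetraploid populations.

The model: a constant-size population of ``N`` individuals, each carrying
``ploidy`` (2 or 4) copies of a single chromosome of ``L`` base pairs.
Every generation, ``N`` offspring are produced; each offspring draws two
parents independently, with replacement, with probability proportional to
fitness (selfing is permitted at its incidental ~1/N rate). Each parent
contributes one gamete formed by bivalent meiosis: in tetraploids the four
chromosome copies form two bivalents, with all three perfect pairings
equally likely; crossovers occur within each bivalent at a Poisson rate of
``rho`` per base pair, and one recombinant product per bivalent is
transmitted. There is no double reduction: the two chromosomes of a
tetraploid gamete always descend from different bivalents. New mutations
(Poisson, ``mu`` per base pair per chromosome per generation) are added to
the gamete after meiosis; each mutation event is a distinct allele even
when it lands on an occupied site (infinite-alleles bookkeeping).

Populations start mutation-free: there is no burn-in, because approach to
equilibrium is itself the object of study. Mutations reaching frequency 1
are converted to substitutions, removed from all genomes and excluded from
reported fitness from then on.

Haplotypes are stored as numpy arrays of mutation ids, sorted by
(position, id); per-mutation attributes live in a columnar
:class:`MutationRegistry`. Haplotype arrays are treated as immutable and
may be shared between individuals across generations.

Reproducibility: all randomness flows from a single
``numpy.random.Generator`` seeded from ``SimParams.seed``. Within one
generation the draw order is fixed: parent indices, then bivalent pairings
for all gametes, then crossover counts, then segregation picks, then
per-chromosome mutation counts, then (per event, in offspring order)
crossover breakpoints, mutation positions and mutation effects. Identical
``(params, selection_model)`` and seed give bit-identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dfe import SelectionModel, fitness_from_dosages, sample_mutation_effect

__all__ = [
    "SimParams",
    "MutationRecord",
    "MutationRegistry",
    "Individual",
    "Gamete",
    "Population",
    "ExtinctionError",
    "pair_bivalents",
    "recombine_pair",
    "make_gamete",
    "mutate_gamete",
    "wf_generation",
    "sweep_fixations",
    "allele_counts",
    "run_simulation",
]

# the 3 perfect matchings of chromosomes {0,1,2,3} into 2 bivalents
_MATCHINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))

_EMPTY = np.empty(0, dtype=np.int64)


class ExtinctionError(RuntimeError):
    """All individuals have zero fitness; parent sampling is undefined."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of a single simulation run.

    ``mu`` and ``rho`` are per base pair per generation; ``L`` is the
    chromosome length in base pairs. ``record_every`` is the stride (in
    generations) at which trajectory rows are recorded;
    ``snapshot_generations`` lists generations at which the full
    offspring-fitness sample is retained.
    """

    N: int = 100
    ploidy: int = 2
    L: int = 1_000_000
    mu: float = 1e-7
    rho: float = 1e-10
    generations: int = 20_000
    seed: int = 0
    record_every: int = 10
    snapshot_generations: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mu < 0 or self.rho < 0:
            raise ValueError("mutation and recombination rates must be >= 0")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        object.__setattr__(self, "snapshot_generations", tuple(self.snapshot_generations))

    def rescaled(self, factor: int) -> "SimParams":
        """Shrink the chromosome by ``factor`` holding mu*L and rho*L fixed."""
        if factor < 1:
            raise ValueError("scale factor must be >= 1")
        return SimParams(
            N=self.N,
            ploidy=self.ploidy,
            L=max(self.L // factor, 1),
            mu=self.mu * factor,
            rho=self.rho * factor,
            generations=self.generations,
            seed=self.seed,
            record_every=self.record_every,
            snapshot_generations=self.snapshot_generations,
        )


@dataclass(frozen=True)
class MutationRecord:
    """One unique deleterious allele."""

    id: int
    position: int
    s: float
    h: float
    origin_generation: int


class MutationRegistry:
    """Columnar store of every mutation ever created in a run.

    Mutation ids are row indices; arrays grow by doubling. Haplotypes
    reference rows here rather than carrying records around.
    """

    def __init__(self, capacity: int = 1024):
        self._n = 0
        self.position = np.empty(capacity, dtype=np.int64)
        self.s = np.empty(capacity, dtype=np.float64)
        self.h = np.empty(capacity, dtype=np.float64)
        self.origin_generation = np.empty(capacity, dtype=np.int64)

    def __len__(self) -> int:
        return self._n

    def _grow(self, need: int) -> None:
        cap = len(self.position)
        if self._n + need <= cap:
            return
        new_cap = max(cap * 2, self._n + need)
        for name in ("position", "s", "h", "origin_generation"):
            arr = getattr(self, name)
            grown = np.empty(new_cap, dtype=arr.dtype)
            grown[: self._n] = arr[: self._n]
            setattr(self, name, grown)

    def add(self, positions, s, h, generation: int) -> np.ndarray:
        """Register new mutations; returns their ids (consecutive)."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        h = np.atleast_1d(np.asarray(h, dtype=np.float64))
        n = positions.size
        self._grow(n)
        ids = np.arange(self._n, self._n + n, dtype=np.int64)
        self.position[ids] = positions
        self.s[ids] = s
        self.h[ids] = h
        self.origin_generation[ids] = generation
        self._n += n
        return ids

    def record(self, mid: int) -> MutationRecord:
        if not 0 <= mid < self._n:
            raise KeyError(f"unknown mutation id {mid}")
        return MutationRecord(
            id=int(mid),
            position=int(self.position[mid]),
            s=float(self.s[mid]),
            h=float(self.h[mid]),
            origin_generation=int(self.origin_generation[mid]),
        )


class Individual:
    """``ploidy`` haplotypes plus a cached multiplicative fitness."""

    __slots__ = ("haplotypes", "fitness")

    def __init__(self, haplotypes: tuple[np.ndarray, ...], fitness: float = 1.0):
        self.haplotypes = tuple(haplotypes)
        self.fitness = fitness

    @property
    def ploidy(self) -> int:
        return len(self.haplotypes)

    def compute_fitness(self, registry: MutationRegistry) -> float:
        return _fitness_of_haplotypes(self.haplotypes, registry)


def _sorted_dosages(haplotypes) -> tuple[np.ndarray, np.ndarray]:
    """Distinct mutation ids and copy numbers across one individual's haplotypes."""
    ids = np.concatenate(haplotypes)
    if ids.size == 0:
        return _EMPTY, _EMPTY
    ids = np.sort(ids)
    starts = np.empty(ids.size, dtype=bool)
    starts[0] = True
    np.not_equal(ids[1:], ids[:-1], out=starts[1:])
    starts = np.flatnonzero(starts)
    counts = np.diff(np.append(starts, ids.size))
    return ids[starts], counts


def _fitness_of_haplotypes(haplotypes, registry: MutationRegistry) -> float:
    uniq, counts = _sorted_dosages(haplotypes)
    if uniq.size == 0:
        return 1.0
    return fitness_from_dosages(
        registry.s[uniq], registry.h[uniq], counts, len(haplotypes)
    )


def _recessive_fitness(haplotypes, s: float) -> float:
    """Fitness under the constant fully recessive model: (1+s)^n_homozygous.

    An allele is homozygous iff it appears on all ``ploidy`` haplotypes;
    with at most ``ploidy`` copies of any id, a sorted concatenation has
    ``arr[i] == arr[i + ploidy - 1]`` exactly once per such allele.
    """
    shift = len(haplotypes) - 1
    ids = np.concatenate(haplotypes)
    if ids.size <= shift:
        return 1.0
    ids = np.sort(ids)
    n_homo = int(np.count_nonzero(ids[shift:] == ids[:-shift]))
    return max((1.0 + s) ** n_homo, 0.0)


class Gamete:
    """The haploid (diploid parent) or diploid (tetraploid parent) product of meiosis."""

    __slots__ = ("haplotypes",)

    def __init__(self, haplotypes: tuple[np.ndarray, ...]):
        self.haplotypes = tuple(haplotypes)


@dataclass
class Population:
    individuals: list
    params: SimParams
    registry: MutationRegistry
    generation: int = 0
    substitutions: list = field(default_factory=list)
    # diagnostics of the most recent reproduction step
    last_parent_indices: np.ndarray | None = None
    last_parent_fitnesses: np.ndarray | None = None
    _counts_cache: tuple | None = None

    @classmethod
    def founders(cls, params: SimParams) -> "Population":
        """Mutation-free starting population (no burn-in)."""
        inds = [
            Individual(tuple(_EMPTY for _ in range(params.ploidy)), 1.0)
            for _ in range(params.N)
        ]
        return cls(individuals=inds, params=params, registry=MutationRegistry())

    @property
    def fitnesses(self) -> np.ndarray:
        return np.array([ind.fitness for ind in self.individuals])


def pair_bivalents(individual: Individual, rng: np.random.Generator):
    """Pick one of the 3 equally likely pairings of 4 chromosomes into 2 bivalents."""
    if individual.ploidy != 4:
        raise ValueError("bivalent pairing of 4 homologs requires a tetraploid")
    return list(_MATCHINGS[rng.integers(3)])


def recombine_pair(
    hapA: np.ndarray,
    hapB: np.ndarray,
    rho: float,
    L: int,
    rng: np.random.Generator,
    positions: np.ndarray,
    k: int | None = None,
    breakpoints: np.ndarray | None = None,
):
    """Crossover between two haplotypes; returns the two reciprocal products.

    The crossover count is Poisson with mean ``rho * (L - 1)`` (one
    opportunity per inter-site boundary) unless ``k`` is given;
    breakpoints fall uniformly on the ``L - 1`` boundaries, breakpoint
    ``b`` separating positions ``< b`` from positions ``>= b``. With no
    crossovers the inputs are returned unchanged (haplotypes are
    immutable, so sharing is safe). ``positions`` maps mutation id to
    base-pair coordinate.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if k is None:
        k = int(rng.poisson(rho * (L - 1)))
    if k == 0:
        return hapA, hapB
    if breakpoints is None:
        breakpoints = rng.integers(1, L, size=k)
    bp = np.sort(np.asarray(breakpoints))
    cutsA = np.searchsorted(positions[hapA], bp, side="left")
    cutsB = np.searchsorted(positions[hapB], bp, side="left")
    segsA = np.split(hapA, cutsA)
    segsB = np.split(hapB, cutsB)
    prod1 = [segsA[i] if i % 2 == 0 else segsB[i] for i in range(len(segsA))]
    prod2 = [segsB[i] if i % 2 == 0 else segsA[i] for i in range(len(segsA))]
    return np.concatenate(prod1), np.concatenate(prod2)


def make_gamete(
    individual: Individual,
    params: SimParams,
    rng: np.random.Generator,
    registry: MutationRegistry,
) -> Gamete:
    """One gamete by bivalent meiosis: pairing, crossover, segregation.

    Diploids transmit one of the two recombinant products; tetraploids
    transmit one product from each of the two bivalents (never two from
    the same bivalent, i.e. no double reduction). Mutation is applied
    separately by :func:`mutate_gamete`.
    """
    positions = registry.position
    if individual.ploidy == 2:
        a, b = recombine_pair(
            individual.haplotypes[0], individual.haplotypes[1],
            params.rho, params.L, rng, positions,
        )
        return Gamete(((a, b)[rng.integers(2)],))
    pairs = pair_bivalents(individual, rng)
    out = []
    for i, j in pairs:
        a, b = recombine_pair(
            individual.haplotypes[i], individual.haplotypes[j],
            params.rho, params.L, rng, positions,
        )
        out.append((a, b)[rng.integers(2)])
    return Gamete(tuple(out))


def mutate_gamete(
    gamete: Gamete,
    params: SimParams,
    generation: int,
    registry: MutationRegistry,
    model: SelectionModel,
    rng: np.random.Generator,
    counts: np.ndarray | None = None,
) -> Gamete:
    """Add Poisson(mu*L) new mutations per chromosome at uniform positions.

    Every event is a fresh allele (stacking on an occupied site allowed).
    Haplotype (position, id) order is preserved; new ids are larger than
    all existing ids, so ties at a shared position place the newer allele
    last.
    """
    if counts is None:
        counts = rng.poisson(params.mu * params.L, size=len(gamete.haplotypes))
    new_haps = []
    for hap, m in zip(gamete.haplotypes, counts):
        m = int(m)
        if m == 0:
            new_haps.append(hap)
            continue
        pos = rng.integers(0, params.L, size=m)
        s, h = sample_mutation_effect(model, rng, size=m)
        ids = registry.add(pos, s, h, generation)
        order = np.argsort(pos, kind="stable")
        pos_sorted, ids_sorted = pos[order], ids[order]
        where = np.searchsorted(registry.position[hap], pos_sorted, side="right")
        new_haps.append(np.insert(hap, where, ids_sorted))
    return Gamete(tuple(new_haps))


def wf_generation(
    pop: Population, selection_model: SelectionModel, rng: np.random.Generator
) -> Population:
    """One Wright-Fisher generation: selection, meiosis, mutation.

    Returns a new Population of exactly ``N`` offspring with the
    generation counter incremented; the parent index multiset and the
    parental mean fitness are stored on the returned population.
    """
    params = pop.params
    N, ploidy = params.N, params.ploidy
    n_chrom = ploidy // 2  # chromosomes per gamete
    fit = pop.fitnesses
    total = fit.sum()
    if total <= 0:
        raise ExtinctionError("all individuals have zero fitness")
    registry = pop.registry

    # batched draws, fixed order (see module docstring)
    parent_idx = rng.choice(N, size=2 * N, p=fit / total)
    if ploidy == 4:
        pairings = rng.integers(0, 3, size=2 * N).tolist()
    xovers = rng.poisson(params.rho * (params.L - 1), size=(2 * N, n_chrom)).tolist()
    seg = rng.integers(0, 2, size=(2 * N, n_chrom)).tolist()
    mut_counts = rng.poisson(params.mu * params.L, size=(2 * N, n_chrom)).tolist()

    rho, L = params.rho, params.L
    gen = pop.generation + 1
    fast_recessive = selection_model.mode == "constant"
    s_const = selection_model.s_const
    individuals = pop.individuals
    parents = parent_idx.tolist()
    positions = registry.position
    diploid_pairs = ((0, 1),)
    offspring = []
    for i in range(N):
        haps = []
        for g in (2 * i, 2 * i + 1):
            parent_haps = individuals[parents[g]].haplotypes
            pairs = diploid_pairs if ploidy == 2 else _MATCHINGS[pairings[g]]
            for c, (a_i, b_i) in enumerate(pairs):
                k = xovers[g][c]
                if k:
                    a, b = recombine_pair(
                        parent_haps[a_i], parent_haps[b_i],
                        rho, L, rng, positions, k=k,
                    )
                    hap = b if seg[g][c] else a
                else:
                    hap = parent_haps[b_i] if seg[g][c] else parent_haps[a_i]
                m = mut_counts[g][c]
                if m:
                    pos = rng.integers(0, L, size=m)
                    s_new, h_new = sample_mutation_effect(selection_model, rng, size=m)
                    ids = registry.add(pos, s_new, h_new, gen)
                    positions = registry.position  # may have been reallocated
                    order = np.argsort(pos, kind="stable")
                    where = np.searchsorted(positions[hap], pos[order], side="right")
                    hap = np.insert(hap, where, ids[order])
                haps.append(hap)
        ind = Individual(tuple(haps))
        ind.fitness = (
            _recessive_fitness(haps, s_const)
            if fast_recessive
            else _fitness_of_haplotypes(haps, registry)
        )
        offspring.append(ind)

    new_pop = Population(
        individuals=offspring,
        params=params,
        registry=registry,
        generation=pop.generation + 1,
        substitutions=pop.substitutions,
        last_parent_indices=parent_idx,
        last_parent_fitnesses=fit[parent_idx],
    )
    return new_pop


def allele_counts(pop: Population) -> tuple[np.ndarray, np.ndarray]:
    """Distinct segregating mutation ids and their chromosome counts."""
    cache = pop._counts_cache
    if cache is not None and cache[0] == pop.generation:
        return cache[1], cache[2]
    haps = [h for ind in pop.individuals for h in ind.haplotypes if h.size]
    if not haps:
        uniq, counts = _EMPTY, _EMPTY
    else:
        full = np.bincount(np.concatenate(haps), minlength=len(pop.registry))
        uniq = np.flatnonzero(full)
        counts = full[uniq]
    pop._counts_cache = (pop.generation, uniq, counts)
    return uniq, counts


def sweep_fixations(pop: Population) -> Population:
    """Convert alleles present on every chromosome into substitutions.

    Fixed mutations are removed from all haplotypes, appended to the
    substitution ledger with the current generation, and excluded from
    fitness from then on (so fixing a recessive deleterious allele lifts
    every reported fitness by the factor 1/(1+s) at once; the ledger keeps
    the full record). Lost mutations simply stop appearing.
    """
    uniq, counts = allele_counts(pop)
    n_total = pop.params.ploidy * pop.params.N
    fixed = uniq[counts == n_total]
    if fixed.size == 0:
        return pop
    for mid in fixed:
        pop.substitutions.append((pop.registry.record(int(mid)), pop.generation))
    for ind in pop.individuals:
        ind.haplotypes = tuple(
            h[~np.isin(h, fixed)] if h.size else h for h in ind.haplotypes
        )
        ind.fitness = ind.compute_fitness(pop.registry)
    keep = counts != n_total
    pop._counts_cache = (pop.generation, uniq[keep], counts[keep])
    return pop


def run_simulation(
    params: SimParams,
    selection_model: SelectionModel | None = None,
    replicate: int = 0,
    progress: bool = False,
):
    """Run a full simulation; returns a :class:`~podsim.trajectory.SimTrajectory`.

    Starts from mutation-free founders, iterates reproduction and
    fixation sweeping for ``params.generations`` steps, and records a
    trajectory row at generation 0, every ``record_every`` generations,
    and at the final generation. Bit-exact reproducible for fixed
    ``(params, selection_model)``.
    """
    from .trajectory import SimTrajectory, offspring_fitness_sample, summarize_generation

    if selection_model is None:
        selection_model = SelectionModel()
    rng = np.random.default_rng(params.seed)
    pop = Population.founders(params)
    rows = [summarize_generation(pop, None)]
    snapshots = {}
    snap_set = set(params.snapshot_generations)
    iterator = range(1, params.generations + 1)
    if progress:
        from tqdm import tqdm  # pragma: no cover

        iterator = tqdm(iterator)  # pragma: no cover
    for gen in iterator:
        pop = wf_generation(pop, selection_model, rng)
        pop = sweep_fixations(pop)
        if gen % params.record_every == 0 or gen == params.generations:
            rows.append(summarize_generation(pop, pop.last_parent_fitnesses))
        if gen in snap_set:
            snapshots[gen] = offspring_fitness_sample(pop)
    return SimTrajectory(
        rows=rows,
        params=params,
        selection_model=selection_model,
        replicate=replicate,
        seed=params.seed,
        offspring_fitness_samples=snapshots,
        final_population=pop,
    )
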