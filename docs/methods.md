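# Methods

## Model and assumptions

podsim implements a discrete-generation, constant-size Wright–Fisher
model with selection, mutation and recombination on a single chromosome,
for ploidy 2 and 4. The assumptions, in order of consequence:

- **Fitness-proportional parent sampling.** Each of the N offspring
  draws two parents independently with replacement, with probability
  proportional to multiplicative fitness. Selfing therefore occurs at
  its incidental rate (~1/N); the two gametes of a selfing event are
  independent meioses. We chose this hermaphroditic scheme because it is
  the minimal model consistent with "probability of reproduction
  proportional to fitness"; enforcing distinct parents would perturb
  results at O(1/N).
- **Multiplicative fitness over distinct alleles.** Every mutation event
  is a distinct allele even at an occupied site (infinite-alleles
  bookkeeping), and homozygosity is judged per allele id: a factor
  (1 + s) when the allele occupies all ploidy copies, (1 + h·s) for any
  partial dosage (1 of 4 through 3 of 4), 1 otherwise; the product is
  floored at 0. Applying the heterozygous factor uniformly across
  partial tetraploid dosages is an explicit simplification: it reduces
  exactly to diploid semantics and, at h = 0 (the main, fully recessive
  model), to "only full homozygotes are exposed", which is the mechanism
  the study isolates. A dosage-graded alternative would live entirely
  inside `fitness_from_dosages` and can be swapped without touching the
  engine.
- **Bivalent-only tetrasomic meiosis.** The four homologs form two
  bivalents, each of the 3 perfect matchings with probability 1/3;
  crossovers within a bivalent are Poisson with mean ρ(L−1), breakpoints
  uniform over inter-site boundaries, no interference, no gene
  conversion; one product per bivalent is transmitted, so there is no
  double reduction. Random pairing plus one-per-bivalent segregation is
  equivalent to sampling 2 of the 4 copies without replacement
  (hypergeometric gamete dosages) — the tests exploit this equivalence
  as an independent oracle.
- **Fixation handling.** Alleles reaching frequency 1 are removed from
  genomes, ledgered as substitutions, and excluded from reported fitness
  thereafter. Note the implied discontinuity: fixing a recessive
  deleterious allele multiplies every individual's *reported* fitness by
  1/(1+s) in that generation. We document rather than smooth this; the
  substitution ledger retains the full record.
- **No burn-in.** Founders are mutation-free. The approach to
  equilibrium is part of the phenomenon being characterized, so
  equilibration before recording would be wrong here.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| N | census size | 100 | constant each generation |
| ploidy | chromosome copies | 2 | 2 or 4 |
| L | chromosome length (bp) | 1e6 | single chromosome |
| μ | mutation rate /bp/gen | 1e-7 | per transmitted chromosome: μ·L |
| ρ | crossover rate /bp/gen | 1e-10 | per bivalent: ρ·(L−1) |
| s | selection coefficient | −0.005 | constant mode; h = 0 |
| α, β | gamma DFE of |s| | 0.16, 0.0092 | empirical mode |
| θᵢ, θᵣ | dominance–selection map | 0.978, 50 328 | h(s) = 1/(1/θᵢ − θᵣ·s) |

Two readings of the gamma parameter β exist in the literature's
notation: shape/scale (mean |s| = αβ ≈ 0.00147) and SLiM's (mean, shape)
convention (mean |s| = 0.0092). We default to shape/scale — α and β
conventionally denote shape and scale, and the rate reading (mean ≈ 17)
is impossible for a selection coefficient — and expose `beta_is_mean`
to select the other. The dominance map h(s) is the unique simple form
with h(0) = θᵢ, h monotonically decreasing in |s| and h → 0 as
s → −∞, which is how the map is described; weak mutations are nearly
dominant (h(0) = 0.978), strong ones effectively recessive.

A note on ρ = 1e-7 being described as roughly one crossover per
chromosome: with L = 1 Mb, ρ·L = 0.1 per generation, i.e. one crossover
per ten meioses. We implement the per-bp definition literally and do not
rescale.

## Randomness and reproducibility

All randomness flows from one PCG64 generator seeded by `SimParams.seed`.
Within a generation the consumption order is fixed: parent indices →
bivalent pairings (all 2N gametes) → crossover counts → segregation
picks → mutation counts → per-event breakpoints, mutation positions and
effects in offspring order. Batching the per-generation draws (rather
than drawing per offspring) keeps the pure-Python loop fast; the order
is part of the reproducibility contract, and identical (params, model,
seed) gives byte-identical trajectory files. Sweep runs derive per-run
seeds as the first 4 bytes of SHA-256(base_seed|N|s|μ|ρ|ploidy|replicate)
mod 2³¹, so cells are independent of execution order and reproducible in
isolation.

## Scaled-down runs

The population process depends on L, μ, ρ only through the
per-chromosome rates U = μL and R = ρL (positions matter only via
crossover placement). `SimParams.rescaled(f)` divides L by f and
multiplies μ, ρ by f, leaving U and R fixed. A Kolmogorov–Smirnov test
over 20 replicates per arm (end-state median allele frequency,
segregating count, mean fitness) cannot distinguish a 10× rescaled run
from the original (α = 0.01); the test suite re-checks this. Simulation
tests and the acceptance script therefore run at L = 1e5 (factor 10)
with 6000 generations and 5–10 replicates — enough for the illustrative
parameter set to reach its allele-frequency plateau (by ~generation
4000) — while the full-length, 20 000-generation, full-grid
configuration remains available via `scale_factor=1`.

## POD classifier calibration

The four criteria are qualitative; the thresholds in `PODConfig` are
this package's operationalization, calibrated once so that the
illustrative POD regime classifies positive while neutral drift,
mutation accumulation and the high-recombination mimic (elevated median
AF with crashing fitness and steady fixation) classify negative:

- windows: early = generations (500, 2500], late = last 2000 recorded;
- i: mean late-window median allele frequency ≥ 0.25;
- ii: OLS slope of late log mean fitness ≥ 0.5 × the early slope (when
  the early slope is negative), **or** within 2e-5/generation of zero —
  the absolute plateau tolerance (< 2% fitness loss per 1000
  generations) covers runs that equilibrate before the early window
  ends, where the ratio test degenerates to comparing noise;
- iii: late-window OLS slope of the segregating count > 0;
- iv: late fixation rate ≤ 0.5 × early rate (early rate 0 → late must
  be 0).

Log fitness is floored at 1e-12 before regression. Criterion iii can
genuinely fail on a plateaued POD run when a complementary haplotype
sub-lineage goes extinct and its private mutations drop out in one
generation; we accept this as real dynamical variance rather than
tune it away (9 of 10 illustrative tetraploid replicates classify
positive; the property asserted is ≥ 8 of 10).

## What the fixture generator does and does not emulate

`make_fixture_trajectory` emits piecewise-linear/exponential caricatures
of four regimes (po, ma, mimic, neutral) with optional Gaussian jitter.
They exercise the classifier's decision logic — windowing, slopes,
ratios, sentinel handling — not the simulator: they have no
autocorrelated drift noise, no purge dips in the segregating count, and
fitness noise is additive rather than multiplicative. Classifier
behavior on real dynamics is therefore tested separately on engine
output. Likewise, passing simulation tests shows the model behaves as
specified, not that real polyploid genomes (with multivalents, double
reduction, many chromosomes, non-constant maps) would behave
identically; those features are deliberately out of scope.

## Numerical choices and degenerate inputs

- Haplotypes are immutable, position-sorted (ties by allele id) int64
  arrays shared structurally between generations; per-individual dosage
  counting is a sort over ~ploidy × load elements, with a closed-form
  fast path ((1+s)^n_homozygous) for the constant recessive model.
- Median allele frequency with zero segregating mutations is NaN, never
  0, so early generations cannot fake a low-frequency signal; writers
  emit `NA`, aggregation drops NaN unless a cell is all-NaN.
- All-zero fitness raises an extinction error rather than renormalizing.
- μ = 0, ρ = 0, generations = 0 are valid degenerate inputs (no-ops at
  the respective stage).
- VCF snapshots are plain VCF 4.2, 1-based positions, one biallelic
  record per allele id (shared positions allowed), unphased GT of
  ploidy-many alleles.

## Known limitations

- Tetraploid partial-dosage dominance is two-valued (full vs partial),
  not dosage-graded (see above).
- No neutral marker loci: associative-overdominance statistics on linked
  neutral diversity cannot be computed from these runs.
- A single chromosome; no demography beyond constant N; no beneficial
  mutations; ploidies other than 2 and 4, multivalents and double
  reduction are unsupported by design.
- The classifier's thresholds are one defensible operationalization;
  cell-by-cell agreement with any particular published heatmap is not
  promised, and every threshold is exposed for recalibration.
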