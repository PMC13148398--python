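"""Per-generation summary statistics and trajectory serialization.

A trajectory is the time series a run emits: for each recorded
generation, the median allele frequency over segregating deleterious
mutations, the mean multiplicative fitness of the population, the mean
fitness of the parents actually drawn for reproduction (with
multiplicity), the number of segregating mutations and the cumulative
number of substitutions. These are the quantities from which
pseudo-overdominance is diagnosed: balanced complementary load haplotypes
show up as intermediate median allele frequencies, a fitness decline that
decelerates, a segregating count that keeps growing, and a fixation rate
that stalls.

Statistics are computed on the offspring population after the fixation
sweep, so frequency-1 alleles never appear and ``mean_fitness`` reflects
segregating mutations only. When nothing segregates the median allele
frequency is NaN (a sentinel), not 0 — early generations must not fake a
low-frequency signal.

Trajectories serialize to TSV with the full parameter set echoed in
``# key=value`` header lines, so any file is self-describing and can be
re-read into an equivalent object.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dfe import SelectionModel
from .engine import Population, SimParams, allele_counts

__all__ = [
    "TrajectoryRow",
    "SimTrajectory",
    "allele_frequencies",
    "summarize_generation",
    "offspring_fitness_sample",
    "read_trajectory_tsv",
]

ROW_COLUMNS = [
    "generation",
    "median_allele_freq",
    "mean_fitness",
    "parental_mean_fitness",
    "n_segregating",
    "n_fixed_cumulative",
]


@dataclass(frozen=True)
class TrajectoryRow:
    generation: int
    median_allele_freq: float  # NaN when nothing segregates
    mean_fitness: float
    parental_mean_fitness: float  # NaN for the founder row
    n_segregating: int
    n_fixed_cumulative: int


def allele_frequencies(pop: Population) -> dict[int, float]:
    """Map of segregating mutation id -> frequency (carriers / (ploidy*N))."""
    uniq, counts = allele_counts(pop)
    denom = pop.params.ploidy * pop.params.N
    return {int(m): c / denom for m, c in zip(uniq, counts)}


def summarize_generation(pop: Population, parent_fitnesses=None) -> TrajectoryRow:
    """Compute one trajectory row from the current population state.

    ``parent_fitnesses`` is the multiset (with multiplicity) of the
    fitnesses of the parents drawn to produce this generation; ``None``
    (the founder generation) records NaN.
    """
    uniq, counts = allele_counts(pop)
    denom = pop.params.ploidy * pop.params.N
    if uniq.size:
        median_af = float(np.median(counts / denom))
    else:
        median_af = math.nan
    mean_fit = float(np.mean([ind.fitness for ind in pop.individuals]))
    if parent_fitnesses is None:
        parental = math.nan
    else:
        parental = float(np.mean(parent_fitnesses))
    return TrajectoryRow(
        generation=pop.generation,
        median_allele_freq=median_af,
        mean_fitness=mean_fit,
        parental_mean_fitness=parental,
        n_segregating=int(uniq.size),
        n_fixed_cumulative=len(pop.substitutions),
    )


def offspring_fitness_sample(pop: Population) -> np.ndarray:
    """Fitness of every individual in the newly created offspring generation."""
    return pop.fitnesses


@dataclass
class SimTrajectory:
    """The recorded output of one simulation run."""

    rows: list
    params: SimParams
    selection_model: SelectionModel
    replicate: int = 0
    seed: int = 0
    offspring_fitness_samples: dict = field(default_factory=dict)
    final_population: Population | None = None

    def __post_init__(self) -> None:
        gens = [r.generation for r in self.rows]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("trajectory rows must be strictly increasing in generation")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.rows], columns=ROW_COLUMNS)
        df["replicate"] = self.replicate
        for key, val in self.param_items():
            df[key] = val
        return df

    def param_items(self) -> list[tuple[str, object]]:
        p, m = self.params, self.selection_model
        items = [
            ("N", p.N), ("ploidy", p.ploidy), ("L", p.L), ("mu", p.mu),
            ("rho", p.rho), ("generations", p.generations), ("seed", p.seed),
            ("record_every", p.record_every),
            ("selection_mode", m.mode),
        ]
        if m.mode == "constant":
            items.append(("s", m.s_const))
        else:
            items += [("alpha", m.alpha), ("beta", m.beta),
                      ("beta_is_mean", m.beta_is_mean),
                      ("theta_intercept", m.theta_intercept),
                      ("theta_rate", m.theta_rate)]
        return items

    def to_tsv(self, path) -> None:
        path = Path(path)
        header = "".join(f"# {k}={v}\n" for k, v in
                         self.param_items() + [("replicate", self.replicate)])
        with open(path, "w") as fh:
            fh.write(header)
            self.to_dataframe().to_csv(fh, sep="\t", index=False, na_rep="NA")

    def final_window_median_af(self, window_generations: int) -> float:
        """Mean of the per-generation median allele frequency over the last
        ``window_generations`` generations of the run (NaN rows excluded)."""
        last = self.rows[-1].generation
        vals = [r.median_allele_freq for r in self.rows
                if r.generation > last - window_generations
                and not math.isnan(r.median_allele_freq)]
        return float(np.mean(vals)) if vals else math.nan


def read_trajectory_tsv(path) -> SimTrajectory:
    """Re-read a trajectory TSV (header echo + rows) into a SimTrajectory."""
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip, na_values=["NA"])
    params = SimParams(
        N=int(meta["N"]), ploidy=int(meta["ploidy"]), L=int(meta["L"]),
        mu=float(meta["mu"]), rho=float(meta["rho"]),
        generations=int(meta["generations"]), seed=int(meta["seed"]),
        record_every=int(meta.get("record_every", 1)),
    )
    if meta.get("selection_mode", "constant") == "constant":
        model = SelectionModel(mode="constant", s_const=float(meta["s"]))
    else:
        model = SelectionModel(
            mode="empirical_hs", alpha=float(meta["alpha"]), beta=float(meta["beta"]),
            beta_is_mean=meta.get("beta_is_mean", "False") == "True",
            theta_intercept=float(meta["theta_intercept"]),
            theta_rate=float(meta["theta_rate"]),
        )
    rows = [
        TrajectoryRow(
            generation=int(r.generation),
            median_allele_freq=float(r.median_allele_freq)
            if pd.notna(r.median_allele_freq) else math.nan,
            mean_fitness=float(r.mean_fitness),
            parental_mean_fitness=float(r.parental_mean_fitness)
            if pd.notna(r.parental_mean_fitness) else math.nan,
            n_segregating=int(r.n_segregating),
            n_fixed_cumulative=int(r.n_fixed_cumulative),
        )
        for r in df.itertuples()
    ]
    return SimTrajectory(
        rows=rows, params=params, selection_model=model,
        replicate=int(meta.get("replicate", 0)), seed=params.seed,
    )
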