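"""Parameter-grid execution, replicate seeding, and heatmap aggregation.

A sweep runs every combination of population size, selection model,
mutation rate, recombination rate and ploidy for a fixed number of
replicates, classifies each run, and aggregates final median allele
frequencies into per-(mu, rho) heatmap tables. Each run's seed is a
stable hash of (base seed, cell parameters, replicate), so any single
cell can be reproduced in isolation and results are independent of
execution order.

``scale_factor`` shrinks the chromosome while holding the per-chromosome
mutation and recombination rates (mu*L, rho*L) fixed; the population
process depends on the per-chromosome rates only, so scaled runs are
statistically equivalent and much cheaper.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dfe import SelectionModel
from .engine import SimParams, run_simulation
from .pod import PODConfig, classify

__all__ = [
    "SweepConfig",
    "SweepResult",
    "derive_seed",
    "run_sweep",
    "aggregate_heatmap",
    "write_outputs",
]

#: grid defaults mirroring the study design (s value "empirical" selects
#: the gamma DFE with the h-s dominance relationship)
DEFAULT_N_GRID = (100, 200, 500)
DEFAULT_S_GRID = (-0.0005, -0.001, -0.005, -0.01, -0.02, "empirical")
DEFAULT_RHO_GRID = (1e-10, 1e-9, 5e-9, 1e-8, 5e-8, 1e-7)
DEFAULT_MU_GRID = (1e-10, 1e-9, 5e-9, 1e-8, 5e-8, 1e-7)


@dataclass(frozen=True)
class SweepConfig:
    N_grid: tuple = (100,)
    s_grid: tuple = DEFAULT_S_GRID
    rho_grid: tuple = DEFAULT_RHO_GRID
    mu_grid: tuple = DEFAULT_MU_GRID
    ploidy_grid: tuple = (2, 4)
    replicates: int = 10
    base_seed: int = 0
    generations: int = 20_000
    L: int = 1_000_000
    record_every: int = 10
    scale_factor: int = 1
    pod_config: PODConfig = field(default_factory=PODConfig)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")

    def cells(self):
        for N in self.N_grid:
            for s in self.s_grid:
                for mu in self.mu_grid:
                    for rho in self.rho_grid:
                        for ploidy in self.ploidy_grid:
                            yield (N, s, mu, rho, ploidy)

    def to_items(self) -> list[tuple[str, object]]:
        return [
            ("N_grid", ",".join(map(str, self.N_grid))),
            ("s_grid", ",".join(map(str, self.s_grid))),
            ("rho_grid", ",".join(map(str, self.rho_grid))),
            ("mu_grid", ",".join(map(str, self.mu_grid))),
            ("ploidy_grid", ",".join(map(str, self.ploidy_grid))),
            ("replicates", self.replicates),
            ("base_seed", self.base_seed),
            ("generations", self.generations),
            ("L", self.L),
            ("record_every", self.record_every),
            ("scale_factor", self.scale_factor),
        ]


def derive_seed(base_seed: int, N: int, s, mu: float, rho: float,
                ploidy: int, replicate: int) -> int:
    """Stable per-run seed: SHA-256 of the cell coordinates, below 2**31."""
    key = f"{base_seed}|{N}|{s}|{mu:.6g}|{rho:.6g}|{ploidy}|{replicate}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _selection_model(s) -> SelectionModel:
    if s == "empirical":
        return SelectionModel(mode="empirical_hs")
    return SelectionModel(mode="constant", s_const=float(s))


@dataclass
class SweepResult:
    config: SweepConfig
    trajectories: list = field(default_factory=list)
    calls: list = field(default_factory=list)  # aligned with trajectories
    master: pd.DataFrame | None = None
    failures: list = field(default_factory=list)
    run_log: list = field(default_factory=list)  # per-run seed + walltime


def run_sweep(cfg: SweepConfig, keep_trajectories: bool = True,
              classify_runs: bool = True, progress: bool = False) -> SweepResult:
    """Execute every grid cell x replicate; never aborts on a failed run.

    The master table has one row per run with the cell parameters, the
    derived seed, the final-row statistics, per-criterion POD verdicts
    and a status flag.
    """
    result = SweepResult(config=cfg)
    records = []
    cells = list(cfg.cells())
    iterator = cells
    if progress:  # pragma: no cover
        from tqdm import tqdm

        iterator = tqdm(cells)
    for N, s, mu, rho, ploidy in iterator:
        for rep in range(cfg.replicates):
            seed = derive_seed(cfg.base_seed, N, s, mu, rho, ploidy, rep)
            params = SimParams(
                N=N, ploidy=ploidy, L=cfg.L, mu=mu, rho=rho,
                generations=cfg.generations, seed=seed,
                record_every=cfg.record_every,
            ).rescaled(cfg.scale_factor)
            rec = {
                "N": N, "s": s, "mu": mu, "rho": rho, "ploidy": ploidy,
                "replicate": rep, "seed": seed, "status": "ok",
            }
            t0 = time.perf_counter()
            try:
                traj = run_simulation(params, _selection_model(s), replicate=rep)
            except Exception as exc:  # failed cells are recorded, not fatal
                rec["status"] = f"failed: {exc}"
                result.failures.append(rec)
                records.append(rec)
                continue
            result.run_log.append(
                dict(seed=seed, replicate=rep, N=N, s=s, mu=mu, rho=rho,
                     ploidy=ploidy, walltime_s=round(time.perf_counter() - t0, 3))
            )
            last = traj.rows[-1]
            rec.update(
                final_generation=last.generation,
                final_median_allele_freq=last.median_allele_freq,
                final_mean_fitness=last.mean_fitness,
                final_n_segregating=last.n_segregating,
                final_n_fixed=last.n_fixed_cumulative,
            )
            call = None
            if classify_runs:
                try:
                    call = classify(traj, cfg.pod_config)
                    rec.update(
                        criterion_i=call.criterion_i,
                        criterion_ii=call.criterion_ii,
                        criterion_iii=call.criterion_iii,
                        criterion_iv=call.criterion_iv,
                        is_pod=call.is_pod,
                    )
                except ValueError:
                    rec["status"] = "ok (too short to classify)"
            if keep_trajectories:
                traj.final_population = None  # drop heavy state
                result.trajectories.append(traj)
                result.calls.append(call)
            records.append(rec)
    result.master = pd.DataFrame(records)
    return result


def aggregate_heatmap(master: pd.DataFrame, N: int, s, ploidy: int) -> pd.DataFrame:
    """Mean final median allele frequency per (mu, rho) for one grid slice.

    Averages over replicates with sentinel (NaN) rows excluded; a cell is
    NaN only when every replicate is. Missing cells raise.
    """
    sl = master[(master.N == N) & (master.s == s) & (master.ploidy == ploidy)
                & master.status.str.startswith("ok")]
    if sl.empty:
        raise ValueError(f"no results for N={N}, s={s}, ploidy={ploidy}")
    table = sl.pivot_table(
        index="mu", columns="rho", values="final_median_allele_freq",
        aggfunc="mean",  # ignores NaN replicates by construction
        dropna=False,  # but keep cells where every replicate is sentinel
    )
    return table


def write_outputs(result: SweepResult, outdir) -> dict[str, Path]:
    """Write trajectory TSVs, the master table and heatmap tables.

    Every file carries the sweep configuration echoed in '# key=value'
    header lines. Returns the paths written, keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    header = "".join(f"# {k}={v}\n" for k, v in cfg.to_items())
    paths: dict[str, Path] = {}

    for traj in result.trajectories:
        p = traj.params
        name = (f"traj_N{p.N}_p{p.ploidy}_mu{p.mu:g}_rho{p.rho:g}"
                f"_rep{traj.replicate}_seed{p.seed}.tsv")
        traj.to_tsv(outdir / name)
    if result.trajectories:
        paths["trajectories"] = outdir

    master_path = outdir / "master_results.tsv"
    with open(master_path, "w") as fh:
        fh.write(header)
        result.master.to_csv(fh, sep="\t", index=False, na_rep="NA")
    paths["master"] = master_path

    if result.run_log:
        log_path = outdir / "run_log.tsv"
        with open(log_path, "w") as fh:
            fh.write(header)
            pd.DataFrame(result.run_log).to_csv(fh, sep="\t", index=False)
        paths["run_log"] = log_path

    if result.master is not None and not result.master.empty:
        ok = result.master[result.master.status.str.startswith("ok")]
        for (N, s, ploidy), _ in ok.groupby(["N", "s", "ploidy"]):
            table = aggregate_heatmap(result.master, N, s, ploidy)
            hp = outdir / f"heatmap_N{N}_s{s}_p{ploidy}.tsv"
            with open(hp, "w") as fh:
                fh.write(header)
                table.to_csv(fh, sep="\t", na_rep="NA")
            paths[f"heatmap_N{N}_s{s}_p{ploidy}"] = hp
    return paths
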