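"""Four-criterion classifier for pseudo-overdominant dynamics.

Pseudo-overdominance (POD) is apparent heterozygote advantage created by
complementary haplotypes carrying recessive deleterious mutations in
repulsion: only heterozygotes mask all load, so selection maintains both
haplotypes at intermediate frequency. A run is called POD-positive when,
comparing a late window of its trajectory against an early one, it shows

i.   elevated intermediate median allele frequencies,
ii.  a decelerated decline of log mean population fitness,
iii. a continually increasing number of segregating mutations, and
iv.  no concordant increase in the number of fixed mutations.

The criteria are qualitative by nature; this module operationalizes them
with explicit, configurable thresholds (see :class:`PODConfig`), chosen
so that the canonical balanced-haplotype regime classifies positive while
neutral drift and ordinary mutation accumulation classify negative. All
slopes are ordinary least squares over the recorded rows of a window;
log fitness is floored at a small positive value before logging.

``make_fixture_trajectory`` builds stylized trajectories of the named
regimes so the classifier can be tested without running the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dfe import SelectionModel
from .engine import SimParams
from .trajectory import SimTrajectory, TrajectoryRow

__all__ = [
    "PODConfig",
    "PODCall",
    "classify",
    "make_fixture_trajectory",
    "compare_ploidies",
]

_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class PODConfig:
    """Thresholds operationalizing the four POD criteria.

    ``early_window`` is a (start, stop] generation range capturing the
    initial approach; ``late_window_span`` takes the last so many
    generations of the run. ``af_threshold`` is the minimum mean median
    allele frequency in the late window (criterion i). ``decel_ratio``
    bounds how much of the early log-fitness decline may persist late
    (criterion ii: late slope >= decel_ratio * early slope, slopes being
    negative in decline); independently, a late log-fitness slope within
    ``plateau_slope_tol`` of zero counts as leveled off (the default,
    2e-5 per generation, is under 2% fitness loss per 1000 generations).
    ``seg_slope_min`` is the minimum late-window
    slope of the segregating count per generation (criterion iii).
    ``fix_ratio`` bounds the late/early fixation-rate ratio (criterion
    iv); an early rate of zero passes only with a zero late rate.
    """

    early_window: tuple[int, int] = (500, 2500)
    late_window_span: int = 2000
    af_threshold: float = 0.25
    decel_ratio: float = 0.5
    plateau_slope_tol: float = 2e-5
    seg_slope_min: float = 0.0
    fix_ratio: float = 0.5

    def windows(self, last_generation: int) -> tuple[tuple[int, int], tuple[int, int]]:
        late = (last_generation - self.late_window_span, last_generation)
        if self.early_window[0] >= self.early_window[1]:
            raise ValueError("early window is empty")
        if late[0] < 0 or self.early_window[1] > last_generation:
            raise ValueError(
                f"trajectory of {last_generation} generations is shorter than "
                f"the classifier windows"
            )
        return self.early_window, late


@dataclass(frozen=True)
class PODCall:
    """Per-criterion verdicts for one run; ``is_pod`` is their conjunction."""

    criterion_i: bool
    criterion_ii: bool
    criterion_iii: bool
    criterion_iv: bool
    diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def is_pod(self) -> bool:
        return (
            self.criterion_i
            and self.criterion_ii
            and self.criterion_iii
            and self.criterion_iv
        )


def _window_rows(traj: SimTrajectory, window: tuple[int, int]) -> list[TrajectoryRow]:
    lo, hi = window
    return [r for r in traj.rows if lo < r.generation <= hi]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return math.nan
    return float(np.polyfit(x, y, 1)[0])


def classify(traj: SimTrajectory, cfg: PODConfig | None = None) -> PODCall:
    """Apply the four POD criteria to one trajectory.

    Deterministic in (trajectory, config). Raises ``ValueError`` when the
    trajectory does not span both windows.
    """
    cfg = cfg or PODConfig()
    last = traj.rows[-1].generation
    early_w, late_w = cfg.windows(last)
    early = _window_rows(traj, early_w)
    late = _window_rows(traj, late_w)
    if len(early) < 2 or len(late) < 2:
        raise ValueError("windows contain fewer than 2 recorded rows")

    g_early = np.array([r.generation for r in early], dtype=float)
    g_late = np.array([r.generation for r in late], dtype=float)

    # i: elevated intermediate median allele frequency (sentinels excluded)
    late_af = np.array([r.median_allele_freq for r in late], dtype=float)
    late_af = late_af[~np.isnan(late_af)]
    mean_late_af = float(late_af.mean()) if late_af.size else math.nan
    crit_i = bool(late_af.size) and mean_late_af >= cfg.af_threshold

    # ii: decelerated decline of log mean fitness
    logf_early = np.log(np.maximum([r.mean_fitness for r in early], _LOG_FLOOR))
    logf_late = np.log(np.maximum([r.mean_fitness for r in late], _LOG_FLOOR))
    early_slope = _ols_slope(g_early, logf_early)
    late_slope = _ols_slope(g_late, logf_late)
    crit_ii = (
        late_slope >= cfg.decel_ratio * min(early_slope, 0.0)
        or late_slope >= -cfg.plateau_slope_tol
    )

    # iii: segregating mutations still accumulating
    seg_slope = _ols_slope(
        g_late, np.array([r.n_segregating for r in late], dtype=float)
    )
    crit_iii = seg_slope > cfg.seg_slope_min

    # iv: fixation rate stalls relative to the early window
    early_fix_rate = (early[-1].n_fixed_cumulative - early[0].n_fixed_cumulative) / (
        early[-1].generation - early[0].generation
    )
    late_fix_rate = (late[-1].n_fixed_cumulative - late[0].n_fixed_cumulative) / (
        late[-1].generation - late[0].generation
    )
    if early_fix_rate == 0:
        crit_iv = late_fix_rate == 0
    else:
        crit_iv = late_fix_rate <= cfg.fix_ratio * early_fix_rate

    return PODCall(
        criterion_i=bool(crit_i),
        criterion_ii=bool(crit_ii),
        criterion_iii=bool(crit_iii),
        criterion_iv=bool(crit_iv),
        diagnostics={
            "mean_late_median_af": mean_late_af,
            "early_logfit_slope": early_slope,
            "late_logfit_slope": late_slope,
            "late_seg_slope": seg_slope,
            "early_fix_rate": early_fix_rate,
            "late_fix_rate": late_fix_rate,
        },
    )


def make_fixture_trajectory(
    kind: str,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    generations: int = 10_000,
    record_every: int = 10,
) -> SimTrajectory:
    """Stylized trajectory of a named dynamical regime, for classifier tests.

    Kinds:

    * ``"po"`` -- median AF rises to a 0.4 plateau, fitness declines then
      plateaus, segregating count rises linearly, fixations stop early.
    * ``"ma"`` -- mutation accumulation: low AF, steadily falling
      fitness, steadily rising fixations.
    * ``"mimic"`` -- elevated median AF but steadily rising fixations and
      a steep, un-decelerated fitness decline (the high-recombination
      false positive).
    * ``"neutral"`` -- drift: intermediate-ish AF noise around a low
      level, flat fitness, fixations at a constant rate.

    ``noise_sd`` scales Gaussian jitter relative to each signal's
    amplitude.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    gens = np.arange(0, generations + 1, record_every, dtype=float)
    t = gens / generations  # 0..1
    ramp = np.minimum(t / 0.25, 1.0)  # saturates at a quarter of the run

    if kind == "po":
        af = 0.4 * ramp
        fitness = 0.55 + 0.45 * np.exp(-t / 0.08)  # decline then plateau
        seg = 20 + 400 * t
        fixed = 5 * ramp  # early fixations only
    elif kind == "ma":
        af = 0.05 * np.ones_like(t)
        fitness = np.exp(-2.0 * t)  # relentless log-linear decline
        seg = 40 + 10 * t
        fixed = 80 * t
    elif kind == "mimic":
        af = 0.35 * ramp
        fitness = np.exp(-3.0 * t)
        seg = 60 * np.ones_like(t)
        fixed = 120 * t
    elif kind == "neutral":
        af = 0.1 * np.ones_like(t)
        fitness = np.ones_like(t)
        seg = 30 * np.ones_like(t)
        fixed = 50 * t
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    if noise_sd > 0:
        af = af + rng.normal(0, noise_sd * 0.4, af.shape)
        fitness = fitness + rng.normal(0, noise_sd * 1.0, fitness.shape)
        seg = seg + rng.normal(0, noise_sd * np.ptp(seg) if np.ptp(seg) else noise_sd,
                               seg.shape)
        fixed = fixed + rng.normal(0, noise_sd * np.ptp(fixed) if np.ptp(fixed)
                                   else noise_sd, fixed.shape)

    af = np.clip(af, 1e-3, 1.0)
    fitness = np.clip(fitness, 1e-6, 1.0)
    seg = np.maximum(seg, 0)
    fixed = np.maximum.accumulate(np.maximum(fixed, 0))  # cumulative count

    rows = [
        TrajectoryRow(
            generation=int(g),
            median_allele_freq=float(a),
            mean_fitness=float(f),
            parental_mean_fitness=float(f),
            n_segregating=int(round(s)),
            n_fixed_cumulative=int(round(x)),
        )
        for g, a, f, s, x in zip(gens, af, fitness, seg, fixed)
    ]
    params = SimParams(N=100, ploidy=2, L=1000, mu=0.0, rho=0.0,
                       generations=generations, record_every=record_every)
    return SimTrajectory(rows=rows, params=params,
                         selection_model=SelectionModel(), replicate=0, seed=0)


def compare_ploidies(calls_tetra: dict, calls_diploid: dict, grid=None):
    """Summarize POD verdicts across a parameter grid for the two ploidies.

    ``calls_tetra`` and ``calls_diploid`` map grid-cell keys (e.g.
    ``(mu, rho)`` tuples) to lists of :class:`PODCall` replicates. Both
    must cover the same cells (``grid``, if given, restricts and orders
    them). Returns a dict with per-cell positive fractions (a cell is
    positive when a majority of replicates is) and the count and fraction
    of POD-positive cells per ploidy.
    """
    cells = list(grid) if grid is not None else sorted(calls_tetra)
    if set(cells) - set(calls_tetra) or set(cells) - set(calls_diploid):
        raise ValueError("call sets do not cover the same grid")

    def cell_stats(calls):
        frac = {c: float(np.mean([k.is_pod for k in calls[c]])) if calls[c] else math.nan
                for c in cells}
        positive = [c for c in cells if frac[c] >= 0.5]
        return frac, positive

    frac_t, pos_t = cell_stats(calls_tetra)
    frac_d, pos_d = cell_stats(calls_diploid)
    n = len(cells)
    return {
        "cells": cells,
        "fraction_positive_replicates": {"tetraploid": frac_t, "diploid": frac_d},
        "n_positive_cells": {"tetraploid": len(pos_t), "diploid": len(pos_d)},
        "fraction_positive_cells": {
            "tetraploid": len(pos_t) / n if n else math.nan,
            "diploid": len(pos_d) / n if n else math.nan,
        },
    }
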