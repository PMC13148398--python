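"""Selection models, dominance, and analytic genotype-probability helpers.

Two selection regimes are supported:

* ``constant`` -- every mutation has the same selection coefficient ``s``
  and is fully recessive (``h = 0``): the fitness of a carrier is reduced
  only when the allele occupies *all* chromosome copies.
* ``empirical_hs`` -- the selection coefficient is drawn from a gamma
  distribution (made negative), and the dominance coefficient is a
  deterministic, monotonically decreasing function of ``|s|``::

      h(s) = 1 / (1/theta_intercept - theta_rate * s),   s <= 0

  so weakly deleterious mutations are nearly additive-to-dominant
  (``h(0) = theta_intercept``) while strongly deleterious ones are
  effectively recessive (``h -> 0`` as ``s -> -inf``).

Fitness is multiplicative over distinct alleles (infinite-alleles
bookkeeping): an allele on all ``ploidy`` copies contributes ``1 + s``, an
allele on any partial dosage contributes ``1 + h*s``, and the product is
floored at zero.

The module also provides exact combinatorial helpers for tetrasomic
inheritance (gamete dosage distributions, cross homozygote fractions,
random-union homozygosity) used both by tests as independent oracles and
for the analytic results quoted in the README.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

__all__ = [
    "SelectionModel",
    "h_of_s",
    "sample_mutation_effect",
    "fitness_from_dosages",
    "individual_fitness",
    "hwe_homozygosity",
    "gamete_dosage_pmf",
    "cross_homozygote_fraction",
]


@dataclass(frozen=True)
class SelectionModel:
    """Distribution of fitness effects for new mutations.

    Parameters
    ----------
    mode :
        ``"constant"`` or ``"empirical_hs"``.
    s_const :
        Selection coefficient in constant mode (``<= 0``); dominance is
        fixed at 0 (fully recessive).
    alpha, beta :
        Gamma parameters of ``|s|`` in empirical mode. By default
        ``alpha`` is the shape and ``beta`` the scale (mean
        ``alpha * beta``); set ``beta_is_mean=True`` to read ``beta`` as
        the mean of the distribution instead (shape ``alpha``, scale
        ``beta / alpha``).
    theta_intercept :
        Dominance coefficient at ``s = 0``.
    theta_rate :
        Rate at which ``h`` approaches 0 as ``s`` becomes more negative.
    """

    mode: str = "constant"
    s_const: float = -0.005
    alpha: float = 0.16
    beta: float = 0.0092
    beta_is_mean: bool = False
    theta_intercept: float = 0.978
    theta_rate: float = 50_328.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "empirical_hs"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "constant" and self.s_const > 0:
            raise ValueError("s_const must be <= 0 (deleterious)")
        if self.mode == "empirical_hs":
            if self.alpha <= 0 or self.beta <= 0:
                raise ValueError("gamma parameters must be positive")
            if not 0 < self.theta_intercept <= 1:
                raise ValueError("theta_intercept must be in (0, 1]")
            if self.theta_rate <= 0:
                raise ValueError("theta_rate must be positive")

    @property
    def gamma_scale(self) -> float:
        """Scale of the gamma distribution of ``|s|`` under the chosen reading."""
        return self.beta / self.alpha if self.beta_is_mean else self.beta


def h_of_s(
    s: float,
    theta_intercept: float = 0.978,
    theta_rate: float = 50_328.0,
) -> float:
    """Dominance coefficient as a function of the selection coefficient.

    ``h = 1 / (1/theta_intercept - theta_rate * s)`` for ``s <= 0``.
    Since the denominator is ``>= 1/theta_intercept``, the result lies in
    ``(0, theta_intercept]``.
    """
    s = float(s)
    if s > 0:
        raise ValueError("h_of_s is defined for deleterious mutations (s <= 0)")
    return 1.0 / (1.0 / theta_intercept - theta_rate * s)


def sample_mutation_effect(
    model: SelectionModel, rng: np.random.Generator, size: int | None = None
):
    """Draw ``(s, h)`` for one or ``size`` new mutations.

    Constant mode returns ``(s_const, 0.0)``; empirical mode draws
    ``|s| ~ Gamma(alpha, scale)``, negates it, and sets
    ``h = h_of_s(s)``.
    """
    n = 1 if size is None else size
    if model.mode == "constant":
        s = np.full(n, model.s_const)
        h = np.zeros(n)
    else:
        s = -rng.gamma(model.alpha, model.gamma_scale, size=n)
        h = 1.0 / (1.0 / model.theta_intercept - model.theta_rate * s)
    if size is None:
        return float(s[0]), float(h[0])
    return s, h


def fitness_from_dosages(
    s: np.ndarray, h: np.ndarray, dosages: np.ndarray, ploidy: int
) -> float:
    """Multiplicative fitness from per-allele dosages.

    ``s`` and ``h`` are the effects of the distinct alleles an individual
    carries and ``dosages`` the corresponding copy numbers in
    ``[1, ploidy]``. Full dosage contributes ``1 + s``; any partial dosage
    contributes ``1 + h*s``. The product is clamped at 0 from below.
    """
    if len(s) == 0:
        return 1.0
    homo = dosages == ploidy
    factors = np.where(homo, 1.0 + s, 1.0 + h * s)
    w = float(np.prod(np.maximum(factors, 0.0)))
    return max(w, 0.0)


def individual_fitness(individual, registry) -> float:
    """Fitness of an individual from its haplotypes and the mutation registry.

    Counts the dosage of every distinct allele across the individual's
    haplotypes and applies :func:`fitness_from_dosages`.
    """
    ids = np.concatenate(individual.haplotypes) if individual.haplotypes else np.empty(0, np.int64)
    if ids.size == 0:
        return 1.0
    uniq, counts = np.unique(ids, return_counts=True)
    return fitness_from_dosages(
        registry.s[uniq], registry.h[uniq], counts, len(individual.haplotypes)
    )


def hwe_homozygosity(p: float, ploidy: int) -> float:
    """Probability an offspring is homozygous for either of two haplotypes.

    With a biallelic haplotype system at frequency ``p`` and each of the
    ``ploidy`` copies an independent draw (random union of gametes), the
    probability all copies are identical is ``p**k + (1-p)**k``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a frequency in [0, 1]")
    return p**ploidy + (1.0 - p) ** ploidy


def gamete_dosage_pmf(parent_dosage: int, ploidy: int = 4) -> np.ndarray:
    """Exact gamete mutant-copy distribution for a parent of given dosage.

    Random bivalent pairing with one chromosome transmitted per bivalent
    (no double reduction) is equivalent to drawing ``ploidy/2`` of the
    parent's ``ploidy`` chromosomes without replacement, so the mutant
    copy number in a gamete is hypergeometric(ploidy, parent_dosage,
    ploidy/2). Returns the pmf over ``0..ploidy/2`` copies.
    """
    k = ploidy // 2
    if not 0 <= parent_dosage <= ploidy:
        raise ValueError("parent dosage out of range")
    return np.array(
        [
            comb(parent_dosage, j) * comb(ploidy - parent_dosage, k - j) / comb(ploidy, k)
            if j <= parent_dosage and k - j <= ploidy - parent_dosage
            else 0.0
            for j in range(k + 1)
        ]
    )


def cross_homozygote_fraction(parent1_dosage: int, parent2_dosage: int) -> float:
    """Exact probability a tetraploid cross yields a fully homozygous offspring.

    For a two-haplotype (A/a) system with no recombination, combines the
    hypergeometric gamete distributions of the two parents and returns
    P(offspring is AAAA or aaaa).
    """
    p1 = gamete_dosage_pmf(parent1_dosage)
    p2 = gamete_dosage_pmf(parent2_dosage)
    # AAAA needs a 2-mutant gamete from each parent; aaaa a 0-mutant from each
    return float(p1[2] * p2[2] + p1[0] * p2[0])
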