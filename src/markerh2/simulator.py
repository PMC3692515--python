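"""Forward-in-time simulation of a partially selfing diploid population.

The population has constant size N, non-overlapping generations and
hermaphroditic individuals. Each offspring is produced by selfing a single
uniformly chosen parent with probability S, and otherwise by crossing two
distinct uniformly chosen parents. All loci (biallelic SNP markers plus
multi-allelic causal loci) are unlinked and segregate independently; there
is no mutation, selection or migration after the founder generation.

The quantitative trait is purely additive: the genotypic value of an
individual is the sum over causal loci of its two allelic effects, and the
phenotype adds an independent Gaussian environmental deviate. Allelic
effects are standard normal; the environmental variance alone is calibrated
so that the analyzed (final) generation realizes the target narrow-sense
heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig

__all__ = [
    "TraitArchitecture",
    "PedigreeRecord",
    "PopulationState",
    "draw_founder_frequencies",
    "draw_allelic_effects",
    "genotypic_value",
    "calibrate_env_variance",
    "assign_phenotypes",
    "draw_founder_genotypes",
    "advance_generation",
    "simulate",
    "marker_heterozygosity",
    "UNKNOWN_PARENT",
]

UNKNOWN_PARENT = -1


class SimulationError(RuntimeError):
    pass


@dataclass
class TraitArchitecture:
    """Additive architecture: one effect per allele per causal locus."""

    allelic_effects: np.ndarray  # (L_QTL, n_qtl_alleles)
    env_variance: float = np.nan

    def __post_init__(self) -> None:
        self.allelic_effects = np.asarray(self.allelic_effects, dtype=float)
        if self.allelic_effects.ndim != 2:
            raise ValueError("allelic_effects must be a 2-D (locus x allele) table")
        if not np.isnan(self.env_variance) and self.env_variance < 0:
            raise ValueError("env_variance must be non-negative")


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: integer id, parent ids (UNKNOWN_PARENT for founders)."""

    id: int
    sire: int
    dam: int
    generation: int


@dataclass
class PopulationState:
    """Genotypes, pedigree and phenotypes of one simulated replicate.

    Genotype arrays hold the *current* (final) generation only; the pedigree
    spans every generation. Individual k of generation g carries the global
    integer id g * N + k and the string label ``gen<g>_ind<k>``.
    """

    config: SimulationConfig
    marker_genotypes: np.ndarray  # (N, L_M, 2) allele indices in {0, 1}
    qtl_genotypes: np.ndarray  # (N, L_QTL, 2) allele indices
    pedigree: list  # list[PedigreeRecord], all generations
    trait: TraitArchitecture
    phenotypes: np.ndarray = field(default=None)
    genotypic_values: np.ndarray = field(default=None)
    marker_frequencies: np.ndarray = field(default=None)  # founder (L_M, 2)
    qtl_frequencies: np.ndarray = field(default=None)  # founder (L_QTL, A)
    generation: int = 0

    @property
    def ids(self) -> list:
        """String labels of the current generation, in row order."""
        N = self.config.N
        g = self.generation
        return [f"gen{g}_ind{k}" for k in range(N)]


def draw_founder_frequencies(L_M, L_QTL, n_qtl_alleles, theta, rng):
    """Founder allele frequencies at mutation-drift equilibrium.

    Each locus draws its frequency vector from a symmetric Dirichlet with
    concentration ``theta`` (Beta(theta, theta) for biallelic markers). Loci
    where any frequency lands exactly at 0 or 1 are redrawn so every founder
    locus is polymorphic in expectation.

    Returns (marker_freqs (L_M, 2), qtl_freqs (L_QTL, n_qtl_alleles)).
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive (got {theta})")

    def _draw(n_loci, n_alleles):
        freqs = rng.dirichlet(np.full(n_alleles, theta), size=n_loci)
        for _ in range(1000):
            bad = np.any((freqs <= 0.0) | (freqs >= 1.0), axis=1)
            if not bad.any():
                break
            freqs[bad] = rng.dirichlet(np.full(n_alleles, theta), size=int(bad.sum()))
        else:  # pragma: no cover - astronomically unlikely
            raise SimulationError("could not draw polymorphic founder frequencies")
        return freqs

    return _draw(L_M, 2), _draw(L_QTL, n_qtl_alleles)


def draw_allelic_effects(L_QTL, n_qtl_alleles, rng) -> np.ndarray:
    """Standard-normal effect for every allele at every causal locus.

    Effects are on a unit scale; the realized genetic variance is whatever
    the founder genotypes produce, and only the environmental variance is
    tuned afterwards to reach the target heritability.
    """
    if L_QTL < 1 or n_qtl_alleles < 1:
        raise ValueError("locus and allele counts must be >= 1")
    return rng.standard_normal((L_QTL, n_qtl_alleles))


def genotypic_value(qtl_genotypes: np.ndarray, trait: TraitArchitecture) -> np.ndarray:
    """Additive genotypic values: sum of the two allelic effects per locus.

    Accepts one individual (L_QTL, 2) or a population (N, L_QTL, 2).
    """
    g = np.asarray(qtl_genotypes)
    single = g.ndim == 2
    if single:
        g = g[None]
    eff = trait.allelic_effects
    L, A = eff.shape
    if g.shape[1] != L:
        raise ValueError(f"genotype covers {g.shape[1]} loci, trait has {L}")
    if g.min() < 0 or g.max() >= A:
        raise ValueError("allele index out of range for the effect table")
    locus_idx = np.arange(L)
    values = eff[locus_idx, g[:, :, 0]].sum(axis=1) + eff[locus_idx, g[:, :, 1]].sum(axis=1)
    return float(values[0]) if single else values


def calibrate_env_variance(founder_genetic_values: np.ndarray, target_h2: float) -> float:
    """Environmental variance giving the target founder heritability.

    sigma2_e = V_G0 (1 - h2) / h2, where V_G0 is the realized variance of
    founder genotypic values, so that V_G0 / (V_G0 + sigma2_e) = h2.
    """
    if not 0.0 < target_h2 < 1.0:
        raise ValueError("target_h2 must be in (0, 1)")
    v_g0 = float(np.var(np.asarray(founder_genetic_values, dtype=float)))
    if v_g0 <= 0.0:
        raise SimulationError("degenerate trait: founder genetic variance is zero")
    return v_g0 * (1.0 - target_h2) / target_h2


def assign_phenotypes(genetic_values: np.ndarray, env_variance: float, rng) -> np.ndarray:
    """Phenotype = genotypic value + N(0, sigma2_e) deviate, iid."""
    g = np.asarray(genetic_values, dtype=float)
    if env_variance < 0 or not np.isfinite(env_variance):
        raise ValueError("env_variance must be calibrated and non-negative")
    return g + rng.normal(0.0, np.sqrt(env_variance), size=g.shape)


def draw_founder_genotypes(freqs: np.ndarray, N: int, rng) -> np.ndarray:
    """Sample N diploid genotypes per locus from the founder frequencies.

    Alleles are drawn independently (founders unrelated and at
    Hardy-Weinberg proportions given their locus frequencies).
    """
    L, A = freqs.shape
    cum = np.cumsum(freqs, axis=1)
    u = rng.random((N, L, 2))
    geno = (u[..., None] > cum[None, :, None, :]).sum(axis=3)
    return geno.astype(np.int8)


def advance_generation(marker_genotypes, qtl_genotypes, S, rng):
    """Produce the next generation of N offspring.

    Each offspring independently selfs one uniform parent with probability S,
    or crosses two distinct uniform parents. One allele per locus is drawn
    uniformly from each parent, independently across loci (free
    recombination).

    Returns (markers, qtls, sires, dams) with parent row indices into the
    current generation.
    """
    N = marker_genotypes.shape[0]
    if N < 2 and S < 1.0:
        raise SimulationError("cannot outcross with fewer than 2 individuals")
    selfed = rng.random(N) < S
    sires = rng.integers(0, N, size=N)
    dams = sires.copy()
    n_out = int((~selfed).sum())
    if n_out:
        # second parent uniform over the other N-1 individuals
        shift = rng.integers(1, N, size=n_out)
        dams[~selfed] = (sires[~selfed] + shift) % N

    def _transmit(genos):
        L = genos.shape[1]
        loci = np.arange(L)[None, :]
        from_sire = genos[sires[:, None], loci, rng.integers(0, 2, size=(N, L))]
        from_dam = genos[dams[:, None], loci, rng.integers(0, 2, size=(N, L))]
        return np.stack([from_sire, from_dam], axis=2)

    return _transmit(marker_genotypes), _transmit(qtl_genotypes), sires, dams


def simulate(config: SimulationConfig, replicate: int = 0) -> PopulationState:
    """Run one replicate: founders, n_generations of mating, phenotypes.

    Reproducible: replicate r uses an RNG seeded with config.seed + r.
    The full pedigree is retained; genotypes and phenotypes describe the
    final generation.
    """
    rng = np.random.default_rng(config.seed + replicate)
    N = config.N

    marker_freqs, qtl_freqs = draw_founder_frequencies(
        config.L_M, config.L_QTL, config.n_qtl_alleles, config.theta, rng
    )
    markers = draw_founder_genotypes(marker_freqs, N, rng)
    qtls = draw_founder_genotypes(qtl_freqs, N, rng)

    effects = draw_allelic_effects(config.L_QTL, config.n_qtl_alleles, rng)
    trait = TraitArchitecture(allelic_effects=effects)

    pedigree = [
        PedigreeRecord(id=k, sire=UNKNOWN_PARENT, dam=UNKNOWN_PARENT, generation=0)
        for k in range(N)
    ]
    for g in range(1, config.n_generations + 1):
        markers, qtls, sires, dams = advance_generation(markers, qtls, config.S, rng)
        base_prev = (g - 1) * N
        pedigree.extend(
            PedigreeRecord(
                id=g * N + k,
                sire=base_prev + int(sires[k]),
                dam=base_prev + int(dams[k]),
                generation=g,
            )
            for k in range(N)
        )

    # Heritability is calibrated in the generation that is analyzed: the
    # environmental variance is set against the realized genotypic variance
    # of the final generation, so the simulated h2 is the heritability of
    # the population the estimators see. (Under selfing, the genetic
    # variance among individuals inflates by roughly (1 + F) relative to
    # the outbred founders, so founder-calibrated noise would shift every
    # estimator by a common offset unrelated to estimator quality.)
    values = genotypic_value(qtls, trait)
    trait.env_variance = calibrate_env_variance(values, config.target_h2)
    phenotypes = assign_phenotypes(values, trait.env_variance, rng)
    return PopulationState(
        config=config,
        marker_genotypes=markers,
        qtl_genotypes=qtls,
        pedigree=pedigree,
        trait=trait,
        phenotypes=phenotypes,
        genotypic_values=values,
        marker_frequencies=marker_freqs,
        qtl_frequencies=qtl_freqs,
        generation=config.n_generations,
    )


def marker_heterozygosity(marker_genotypes: np.ndarray) -> float:
    """Mean fraction of heterozygous marker genotypes in the sample."""
    g = np.asarray(marker_genotypes)
    return float((g[:, :, 0] != g[:, :, 1]).mean())
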