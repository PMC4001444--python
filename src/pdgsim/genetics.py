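"""Quantitative-genetic architecture of the budburst forcing requirement.

The forcing requirement F_critBB (degree-days above a base temperature
needed to trigger budburst) is controlled by ``n_loci`` independent
biallelic loci with purely additive effects.  A genotype contributes
``m_l + alpha_l``, ``m_l`` or ``m_l - alpha_l`` at locus ``l`` for the
A1A1 homozygote, the heterozygote and the A2A2 homozygote respectively.
All per-locus midpoints are equal to ``mu / n_loci`` so the all-heterozygote
value is exactly ``mu`` (190 degC by default).

Allelic effects follow an L-shaped QTL-effect distribution: each
``alpha_l`` is drawn from Normal(mu / (2 n_loci), mu / (8 n_loci)) and
redrawn until it falls inside ``[0, mu / n_loci]``, which keeps every
possible genotypic value inside ``[0, 2 mu]``.  Effects are constant over
the whole simulation; mutation and immigration are ignored and loci
recombine freely (gametes are drawn independently per locus).

Heritability handling: with h^2 = 1 the phenotype equals the genotypic
value; in the non-heritable control the phenotype is drawn from
Normal(mu, V_P) irrespective of the genotype; with 0 < h^2 < 1 a lifetime
environmental deviation Normal(0, V_E) is added, where ``V_E`` is chosen so
the target additive variance ``sigma2`` satisfies h^2 = V_A / (V_A + V_E).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AllelicEffects",
    "TraitModel",
    "draw_allelic_effects",
    "init_founder_genotypes",
    "genotypic_value",
    "phenotype_fcrit",
    "make_gametes",
    "cross",
    "allele_frequencies",
    "additive_variance",
]


@dataclass(frozen=True)
class AllelicEffects:
    """Per-locus midpoints ``m`` and additive effects ``alpha`` (degC)."""

    m: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, float)
        alpha = np.asarray(self.alpha, float)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "alpha", alpha)
        if m.shape != alpha.shape or m.ndim != 1:
            raise ValueError("m and alpha must be equal-length 1-D arrays")
        if not np.allclose(m, m[0]):
            raise ValueError("all per-locus midpoints must be identical")
        if np.any(alpha < 0) or np.any(alpha > m[0] + 1e-12):
            raise ValueError("alpha must lie in [0, mu / n_loci]")

    @property
    def n_loci(self) -> int:
        return self.m.size

    @property
    def mu(self) -> float:
        """Trait mean: the all-heterozygote genotypic value, sum of midpoints."""
        return float(self.m.sum())


@dataclass(frozen=True)
class TraitModel:
    """Heritability model for the forcing-requirement phenotype.

    ``sigma2`` is the reference variance (22 (degC)^2 by default): the full
    phenotypic variance of the control (h2 = 0) and the target additive
    variance in the partially heritable case.
    """

    h2: float = 1.0
    sigma2: float = 22.0
    mu: float = 190.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")

    @property
    def environmental_variance(self) -> float:
        """V_E implied by the mode: sigma2 at h2=0, 0 at h2=1, else sigma2*(1-h2)/h2."""
        if self.h2 == 0.0:
            return self.sigma2
        return self.sigma2 * (1.0 - self.h2) / self.h2


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_allelic_effects(
    n_loci: int = 10, mu: float = 190.0, seed: int | np.random.Generator = 0
) -> AllelicEffects:
    """Draw bounded Gaussian allelic effects (redrawn until within bounds)."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if mu <= 0:
        raise ValueError("mu must be positive")
    rng = _as_rng(seed)
    mean, sd, bound = mu / (2 * n_loci), mu / (8 * n_loci), mu / n_loci
    alpha = rng.normal(mean, sd, n_loci)
    bad = (alpha < 0) | (alpha > bound)
    while bad.any():
        alpha[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (alpha < 0) | (alpha > bound)
    return AllelicEffects(m=np.full(n_loci, bound), alpha=alpha)


def init_founder_genotypes(
    n_individuals: int,
    n_loci: int = 10,
    seed: int | np.random.Generator = 0,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Hardy-Weinberg founder genotypes at uniformly drawn allele frequencies.

    Returns ``(genotypes, freqs)`` where genotypes is an ``(n, n_loci)``
    array of A1-allele counts in {0, 1, 2} and ``freqs`` the per-locus A1
    frequency (drawn ~ Uniform(0, 1) unless supplied).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = _as_rng(seed)
    p = rng.uniform(0.0, 1.0, n_loci) if freqs is None else np.asarray(freqs, float)
    if p.size != n_loci or np.any(p < 0) or np.any(p > 1):
        raise ValueError("freqs must be n_loci values in [0, 1]")
    geno = rng.binomial(2, p, size=(n_individuals, n_loci)).astype(np.int8)
    return geno, p


def genotypic_value(genotypes: np.ndarray, effects: AllelicEffects) -> np.ndarray | float:
    """Additive genotypic value: sum over loci of ``m_l + alpha_l * (count_l - 1)``."""
    g = np.asarray(genotypes)
    if g.shape[-1] != effects.n_loci:
        raise ValueError("genotype length must equal the number of loci")
    val = effects.mu + (g - 1) @ effects.alpha
    return float(val) if g.ndim == 1 else val


def phenotype_fcrit(
    genetic_values: np.ndarray | float,
    model: TraitModel,
    rng: np.random.Generator,
) -> np.ndarray | float:
    """Lifetime-fixed phenotype under the trait model's heritability mode.

    The environmental deviate is drawn in every mode (scaled by zero at
    h2 = 1), so the amount of randomness consumed does not depend on the
    heritability setting and genotype dynamics stay comparable across
    scenarios under a shared seed.
    """
    gv = np.asarray(genetic_values, float)
    eps = rng.standard_normal(gv.shape)
    if model.h2 == 0.0:
        out = model.mu + np.sqrt(model.sigma2) * eps
    else:
        out = gv + np.sqrt(model.environmental_variance) * eps
    return float(out) if out.ndim == 0 else out


def make_gametes(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per genotype row: per-locus transmitted A1 count in {0, 1}.

    Homozygotes transmit their allele; heterozygotes transmit A1 with
    probability 1/2 independently across loci (free recombination, no
    mutation).
    """
    g = np.atleast_2d(np.asarray(genotypes))
    gam = (g == 2).astype(np.int8)
    het = g == 1
    gam[het] = rng.integers(0, 2, int(het.sum()), dtype=np.int8)
    return gam if np.asarray(genotypes).ndim > 1 else gam[0]


def cross(
    mother_genotypes: np.ndarray,
    father_genotypes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring genotypes from one maternal and one paternal gamete each."""
    return make_gametes(mother_genotypes, rng) + make_gametes(father_genotypes, rng)


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Per-locus A1 frequency of a genotype matrix."""
    g = np.atleast_2d(np.asarray(genotypes))
    return g.mean(axis=0) / 2.0


def additive_variance(freqs: np.ndarray, effects: AllelicEffects) -> float:
    """Additive genetic variance ``sum_l 2 p_l (1 - p_l) alpha_l^2``."""
    p = np.asarray(freqs, float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return float(np.sum(2.0 * p * (1.0 - p) * effects.alpha**2))
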