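"""Synthetic genotypes and traits for calibrating the vQTL tests.

Traits are generated under an explicit two-locus interaction model

    Y_j = beta1 * SNP1_j + beta2 * SNP2_j + beta_int * SNP1_j * SNP2_j + eps_j

with genotypes drawn under Hardy–Weinberg equilibrium, ``Binomial(2, MAF)``.
When ``beta_int != 0`` and the interaction partner is unmodelled, SNP1
becomes a variance QTL: the conditional variance of Y given SNP1 grows with
the allele count, which is exactly the signature the five tests hunt for.

The error term is drawn from one of three laws — standard normal, Student t
with 3 df (kurtotic), or chi-square with 6 df (right-skewed, the shape of
many biomarker traits) — and then z-scored to sample mean 0 / SD 1 per
replicate, so the variance explained by the genetic terms is comparable
across error laws.

An interaction with a three-level environmental exposure is formally
identical (replace SNP2 with an exposure coded 0/1/2), so the same machinery
calibrates GxE detection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import GenotypeVector

__all__ = ["SimScenario", "simulate_genotypes", "simulate_trait", "ERROR_DISTRIBUTIONS"]

ERROR_DISTRIBUTIONS = ("normal", "t3", "chisq6")


@dataclass(frozen=True)
class SimScenario:
    """Full parameterization of one simulation cell.

    Defaults are the without-main-effects null at N = 2,000 used for
    desk-scale calibration; set ``beta_int=0.3`` for power cells and
    ``beta1=beta2=0.3`` for the with-main-effects variants.
    """

    n_samples: int = 2000
    maf1: float = 0.3
    maf2: float = 0.3
    beta1: float = 0.0
    beta2: float = 0.0
    beta_int: float = 0.0
    error_dist: str = "normal"
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.maf1 <= 0.5 or not 0.0 < self.maf2 <= 0.5:
            raise ValueError("MAFs must lie in (0, 0.5]")
        if self.error_dist not in ERROR_DISTRIBUTIONS:
            raise ValueError(f"error_dist must be one of {ERROR_DISTRIBUTIONS}")
        if self.n_samples < 100:
            raise ValueError("n_samples < 100 gives meaningless dispersion tests")

    def with_(self, **kwargs) -> "SimScenario":
        return replace(self, **kwargs)


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> GenotypeVector:
    """Draw n hard calls from Binomial(2, maf) — Hardy–Weinberg equilibrium."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    return GenotypeVector(rng.binomial(2, maf, size=n).astype(float))


def _draw_errors(dist: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if dist == "normal":
        return rng.standard_normal(n)
    if dist == "t3":
        return rng.standard_t(3, size=n)
    if dist == "chisq6":
        return rng.chisquare(6, size=n)
    raise ValueError(f"unknown error distribution {dist!r}")


def simulate_trait(g1: GenotypeVector, g2: GenotypeVector, scenario: SimScenario,
                   rng: np.random.Generator) -> np.ndarray:
    """Generate one trait replicate under the two-locus interaction model.

    The raw errors are standardized with the *sample* mean and SD (ddof=1)
    of the replicate, so each replicate's stochastic part has exactly mean 0
    and SD 1 regardless of the error law.
    """
    x1, x2 = g1.calls, g2.calls
    n = x1.shape[0]
    if x2.shape[0] != n:
        raise ValueError("g1 and g2 must have the same length")
    eps = _draw_errors(scenario.error_dist, n, rng)
    eps = (eps - eps.mean()) / eps.std(ddof=1)
    return (scenario.beta1 * x1 + scenario.beta2 * x2
            + scenario.beta_int * x1 * x2 + eps)


def simulate_dataset(scenario: SimScenario, rng: np.random.Generator):
    """One replicate: (SNP1 genotypes, SNP2 genotypes, trait)."""
    g1 = simulate_genotypes(scenario.n_samples, scenario.maf1, rng)
    g2 = simulate_genotypes(scenario.n_samples, scenario.maf2, rng)
    y = simulate_trait(g1, g2, scenario, rng)
    return g1, g2, y
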