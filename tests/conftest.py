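import numpy as np
import pytest

from vqtlkit.preprocess import DeviationVector, ResidualVector


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_residuals(values, groups) -> ResidualVector:
    return ResidualVector(np.asarray(values, float), np.asarray(groups, int))


def make_deviations(values, groups) -> DeviationVector:
    return DeviationVector(np.asarray(values, float), np.asarray(groups, int))


def random_dispersion_data(rng, n=300, maf=0.3, sigma_slope=0.0):
    """Genotype + residual pair with optional per-allele log-SD slope."""
    g = rng.binomial(2, maf, size=n)
    while np.ptp(g) == 0:  # ensure polymorphic
        g = rng.binomial(2, maf, size=n)
    e = rng.normal(0.0, np.exp(0.5 * sigma_slope * g))
    e = e - e.mean()
    return e, g
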