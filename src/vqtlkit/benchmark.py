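"""False-positive-rate and power estimation for the vQTL tests.

Each replicate runs the complete analysis pipeline — simulate a two-locus
dataset, residualize the trait on the tested SNP's genotype indicators,
form the group-median deviations, apply the test — and the benchmark
summaries are rejection fractions over replicates:

* FPR   = fraction of null replicates (beta_int = 0) with p < alpha;
* power = fraction of signal replicates (beta_int != 0) with p < alpha.

Replicate seeds are spawned deterministically from the scenario seed, so
estimates are reproducible bit-exactly and invariant to how replicates
might be batched.

Desk-scale defaults (N in the low thousands, 1,000–2,000 replicates,
alpha = 0.05 for calibration and 1e-3 for power) keep a full method grid in
the minutes range on one CPU; genome-wide settings (N in the tens or
hundreds of thousands, 20,000 replicates, alpha = 5e-8) are a matter of
passing a bigger scenario.  The quantile-integral test costs roughly two
orders of magnitude more per replicate than its competitors and is
therefore opt-in rather than part of the default method set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import vartests
from .preprocess import group_median_deviations, residualize
from .simulate import SimScenario, simulate_dataset

__all__ = [
    "BenchmarkSummary",
    "replicate_pvalues",
    "estimate_fpr",
    "estimate_power",
    "qq_points",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("KW", "BF", "DRM", "DGLM", "DGLM_INT")


@dataclass
class BenchmarkSummary:
    """Rejection-rate estimate for one method under one scenario."""

    method: str
    alpha: float
    estimate: float
    mc_se: float
    n_replicates: int
    n_failures: int
    scenario: SimScenario
    kind: str  # "fpr" or "power"


def _run_method(method: str, res, dev, quail_k: int):
    if method == "KW":
        return vartests.kw_test(dev)
    if method == "BF":
        return vartests.bf_test(dev)
    if method == "DRM":
        return vartests.drm_test(dev)
    if method == "DGLM":
        return vartests.dglm_test(res)
    if method == "DGLM_INT":
        return vartests.dglm_test(res, apply_int=True)
    if method == "QUAIL":
        return vartests.quail_test(res, k=quail_k)
    raise ValueError(f"unknown method {method!r}")


def replicate_pvalues(scenario: SimScenario, methods=DEFAULT_METHODS,
                      quail_k: int = 100) -> pd.DataFrame:
    """p-values for every (replicate, method) under one scenario.

    Runs the full pipeline per replicate and shares the simulated data
    across methods, so benchmarking five tests costs little more than one.
    Method failures yield NaN p-values; callers count them rather than
    silently dropping replicates.
    """
    methods = [methods] if isinstance(methods, str) else list(methods)
    seeds = np.random.SeedSequence(scenario.seed).spawn(scenario.n_replicates)
    rows = np.empty((scenario.n_replicates, len(methods)))
    for r, seq in enumerate(seeds):
        rng = np.random.default_rng(seq)
        g1, _g2, y = simulate_dataset(scenario, rng)
        res = residualize(y, g1)
        dev = group_median_deviations(res)
        for c, method in enumerate(methods):
            try:
                rows[r, c] = _run_method(method, res, dev, quail_k).p_value
            except Exception:
                rows[r, c] = np.nan
    return pd.DataFrame(rows, columns=methods)


def _summarize(pvals: pd.Series, alpha: float, scenario: SimScenario,
               kind: str) -> BenchmarkSummary:
    ok = pvals.dropna()
    n = ok.shape[0]
    estimate = float((ok < alpha).mean()) if n else float("nan")
    mc_se = float(np.sqrt(estimate * (1.0 - estimate) / n)) if n else float("nan")
    return BenchmarkSummary(str(pvals.name), alpha, estimate, mc_se, n,
                            int(pvals.isna().sum()), scenario, kind)


def estimate_fpr(scenario: SimScenario, method="KW", alpha: float = 0.05,
                 quail_k: int = 100):
    """Empirical false-positive rate of one or more methods under a null scenario."""
    if scenario.beta_int != 0.0:
        raise ValueError("FPR estimation requires a null scenario (beta_int = 0)")
    pvals = replicate_pvalues(scenario, method, quail_k)
    out = {m: _summarize(pvals[m], alpha, scenario, "fpr") for m in pvals.columns}
    return out[method] if isinstance(method, str) else out


def estimate_power(scenario: SimScenario, method="KW", alpha: float = 1e-3,
                   quail_k: int = 100):
    """Empirical power of one or more methods under an interaction scenario."""
    if scenario.beta_int == 0.0:
        warnings.warn("beta_int = 0: 'power' collapses to the test size alpha",
                      stacklevel=2)
    pvals = replicate_pvalues(scenario, method, quail_k)
    out = {m: _summarize(pvals[m], alpha, scenario, "power") for m in pvals.columns}
    return out[method] if isinstance(method, str) else out


@dataclass
class QQData:
    """Expected vs observed -log10 p-values plus a median-based inflation slope."""

    expected: np.ndarray
    observed: np.ndarray
    slope: float


def qq_points(p_values) -> QQData:
    """Quantile–quantile data for a vector of p-values.

    Observed -log10 p sorted ascending against the uniform expectation
    ``-log10(k / (n + 1))``; the slope is observed/expected at the median
    point, a genomic-inflation-style one-number calibration summary
    (1 = calibrated, > 1 = inflated).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    observed = -np.log10(np.sort(p)[::-1])  # ascending -log10
    expected = -np.log10(np.arange(p.size, 0, -1) / (p.size + 1.0))
    mid = p.size // 2
    slope = float(observed[mid] / expected[mid]) if expected[mid] else float("nan")
    return QQData(expected, observed, slope)
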