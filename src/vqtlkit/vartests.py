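"""The five variance-QTL test statistics.

Each test maps (residuals or median deviations, genotype) to a p-value for
the null hypothesis of equal phenotypic dispersion across genotype groups:

* ``kw_test``    — Kruskal–Wallis rank test on the absolute median deviations
                   (non-parametric; robust to heavy tails).
* ``bf_test``    — Brown–Forsythe F test: one-way ANOVA of the absolute
                   median deviations on genotype *categories*.
* ``drm_test``   — deviation regression model: OLS of the absolute median
                   deviations on the minor-allele *count* (0/1/2).
* ``dglm_test``  — double generalized linear model: joint mean and
                   log-variance submodels, Wald test on the dispersion slope;
                   optionally preceded by a rank-based inverse-normal
                   transform (the DGLM_INT variant).
* ``quail_test`` — quantile-integral linear model: the average of upper-
                   minus-lower conditional quantile effects over a grid of K
                   quantile pairs, with inference from an integrated
                   rank-score regression.

All tests assume the input residuals were produced by
:func:`vqtlkit.preprocess.residualize`, so SNP main effects and covariates
are already removed and do not confound the dispersion signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import (
    DeviationVector,
    GenotypeVector,
    ResidualVector,
    inverse_normal_transform,
)

__all__ = [
    "VqtlResult",
    "kw_test",
    "bf_test",
    "drm_test",
    "dglm_test",
    "quail_test",
    "METHODS",
]

METHODS = ("KW", "BF", "DRM", "DGLM", "DGLM_INT", "QUAIL")


@dataclass
class VqtlResult:
    """Outcome of one vQTL test on one variant."""

    method: str
    statistic: float
    df: tuple
    p_value: float
    group_counts: tuple
    effect: float | None = None
    se_effect: float | None = None
    degenerate: bool = False
    converged: bool = True
    info: dict = field(default_factory=dict)


def _allele_counts(genotype) -> np.ndarray:
    if isinstance(genotype, GenotypeVector):
        return genotype.calls
    return np.asarray(genotype, dtype=float)


def kw_test(deviations: DeviationVector) -> VqtlResult:
    """Kruskal–Wallis test of the median deviations across genotype groups.

    Ranks all deviations jointly (average ranks for ties) and forms

        KW = (N - 1) * sum_i n_i (rbar_i - rbar)^2 / sum_ij (r_ij - rbar)^2

    which is chi-square with M-1 degrees of freedom under homoscedasticity,
    M being the number of genotype groups present.  The denominator already
    absorbs the tie correction, so no separate correction factor is applied.
    """
    d, groups = deviations.values, deviations.groups
    levels = np.unique(groups)
    m, n = levels.size, d.shape[0]
    if m < 2:
        raise ValueError("need at least two genotype groups")
    if n < m + 1:
        raise ValueError("too few samples for the rank test")
    if np.ptp(d) == 0:  # all deviations tied: statistic undefined
        return VqtlResult("KW", float("nan"), (m - 1,), 1.0,
                          deviations.group_counts, degenerate=True)
    ranks = stats.rankdata(d, method="average")
    grand = (n + 1) / 2.0
    between = 0.0
    for level in levels:
        r_i = ranks[groups == level]
        between += r_i.size * (r_i.mean() - grand) ** 2
    total = float(((ranks - grand) ** 2).sum())
    statistic = (n - 1) * between / total
    p = float(stats.chi2.sf(statistic, m - 1))
    return VqtlResult("KW", float(statistic), (m - 1,), max(p, np.nextafter(0, 1)),
                      deviations.group_counts)


def bf_test(deviations: DeviationVector) -> VqtlResult:
    """Brown–Forsythe test: one-way ANOVA F of median deviations on genotype group.

    BF = [sum_i n_i (Dbar_i - Dbar)^2 / (M-1)] / [sum_ij (D_ij - Dbar_i)^2 / (N-M)]

    referred to the F distribution on (M-1, N-M) degrees of freedom.  This is
    algebraically the ANOVA F for regressing D on the two genotype indicator
    variables, i.e. genotype treated as a categorical predictor.
    """
    d, groups = deviations.values, deviations.groups
    levels = np.unique(groups)
    m, n = levels.size, d.shape[0]
    if m < 2:
        raise ValueError("need at least two genotype groups")
    if n <= m:
        raise ValueError("need N > M for the denominator degrees of freedom")
    grand = d.mean()
    between = 0.0
    within = 0.0
    for level in levels:
        d_i = d[groups == level]
        between += d_i.size * (d_i.mean() - grand) ** 2
        within += float(((d_i - d_i.mean()) ** 2).sum())
    df = (m - 1, n - m)
    if within == 0.0:
        p = 1.0 if between == 0.0 else np.nextafter(0, 1)
        return VqtlResult("BF", float("inf") if between else 0.0, df, p,
                          deviations.group_counts, degenerate=True)
    statistic = (between / df[0]) / (within / df[1])
    p = float(stats.f.sf(statistic, *df))
    return VqtlResult("BF", float(statistic), df, max(p, np.nextafter(0, 1)),
                      deviations.group_counts)


def drm_test(deviations: DeviationVector, genotype=None) -> VqtlResult:
    """Deviation regression model: OLS of median deviations on allele count.

    Fits ``D = a + b * count`` where count is the minor-allele hard call
    (0/1/2) and reports the two-sided t test of ``b = 0`` on N-2 degrees of
    freedom.  Treating genotype as a continuous predictor sidesteps the
    per-group sparsity that destabilises BF at low minor-allele frequency.

    If ``genotype`` is omitted the group labels stored in ``deviations`` are
    used as the allele counts (the usual hard-call case).
    """
    d = deviations.values
    x = deviations.groups.astype(float) if genotype is None else _allele_counts(genotype)
    if x.shape[0] != d.shape[0]:
        raise ValueError("deviations and genotype are not aligned")
    if np.ptp(x) == 0:
        raise ValueError("allele count is constant: slope undefined")
    n = d.shape[0]
    xc = x - x.mean()
    sxx = float((xc ** 2).sum())
    beta = float((xc * d).sum() / sxx)
    alpha = d.mean() - beta * x.mean()
    sse = float(((d - alpha - beta * x) ** 2).sum())
    df = n - 2
    counts = deviations.group_counts
    if sse == 0.0:
        p = 1.0 if beta == 0.0 else np.nextafter(0, 1)
        return VqtlResult("DRM", 0.0 if beta == 0.0 else float("inf"), (df,), p,
                          counts, effect=beta, degenerate=True)
    se = np.sqrt(sse / df / sxx)
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return VqtlResult("DRM", float(t), (df,), max(p, np.nextafter(0, 1)),
                      counts, effect=beta, se_effect=float(se))


def _wls_solve(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def dglm_test(residuals: ResidualVector, genotype=None, apply_int: bool = False,
              max_iter: int = 50, tol: float = 1e-8) -> VqtlResult:
    """Double generalized linear model test for a genotype effect on dispersion.

    Mean submodel      e  = a + b * count + eps,  Var(eps) = sigma_j^2
    Dispersion submodel log sigma^2 = g0 + g1 * count

    Fitted by alternating (i) weighted least squares for the mean with
    weights 1 / sigma-hat^2, and (ii) a gamma GLM with log link on the
    squared mean-model residuals with prior weight 1/2 (squared normal
    residuals are sigma^2 * chi^2_1, a gamma variate), iterated until the
    relative change in the heteroscedastic-normal deviance falls below
    ``tol``.  Significance of ``g1`` is a Wald z test with covariance
    ``2 (Z'Z)^{-1}`` from the gamma-GLM information.

    With ``apply_int=True`` the residuals are first passed through the
    rank-based inverse-normal transform (the DGLM_INT variant), which
    restores calibration under heavy-tailed — though not skewed — traits.
    """
    e = residuals.values.copy()
    x = residuals.groups.astype(float) if genotype is None else _allele_counts(genotype)
    if x.shape[0] != e.shape[0]:
        raise ValueError("residuals and genotype are not aligned")
    if np.ptp(x) == 0:
        raise ValueError("allele count is constant")
    if apply_int:
        e = inverse_normal_transform(e)

    method = "DGLM_INT" if apply_int else "DGLM"
    n = e.shape[0]
    X = np.column_stack([np.ones(n), x])  # mean design
    Z = X  # dispersion design: intercept + allele count
    floor = 1e-10 * float(np.var(e))
    if floor == 0.0:
        return VqtlResult(method, float("nan"), (1,), 1.0,
                          residuals.group_counts, degenerate=True)

    log_s2 = np.full(n, np.log(np.var(e)))
    gamma = np.array([np.log(np.var(e)), 0.0])
    deviance = np.inf
    converged = False
    for _ in range(max_iter):
        w = np.exp(-log_s2)
        beta = _wls_solve(X, e, w)
        r2 = np.maximum((e - X @ beta) ** 2, floor)
        # gamma GLM, log link, constant prior weight 1/2: the IRLS weight
        # w * (dmu/deta)^2 / V(mu) is constant, so each scoring step is an
        # OLS solve on the working response.
        for _inner in range(25):
            mu = np.exp(Z @ gamma)
            z_work = Z @ gamma + (r2 - mu) / mu
            new_gamma, *_ = np.linalg.lstsq(Z, z_work, rcond=None)
            if np.max(np.abs(new_gamma - gamma)) < 1e-10:
                gamma = new_gamma
                break
            gamma = new_gamma
        log_s2 = Z @ gamma
        new_dev = float(np.sum(log_s2 + r2 * np.exp(-log_s2)))
        if np.isfinite(deviance) and abs(new_dev - deviance) <= tol * (abs(deviance) + tol):
            deviance = new_dev
            converged = True
            break
        deviance = new_dev
    if not converged:
        warnings.warn("DGLM did not converge; reporting the last iterate",
                      RuntimeWarning, stacklevel=2)

    # Wald covariance of gamma: phi * (Z' W Z)^{-1} with W = 1/2, phi = 1
    # (Var of sigma^2 chi^2_1 about its gamma mean fixes the scale).
    cov = 2.0 * np.linalg.inv(Z.T @ Z)
    se = float(np.sqrt(cov[1, 1]))
    z_stat = float(gamma[1] / se)
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return VqtlResult(method, z_stat, (1,), max(p, np.nextafter(0, 1)),
                      residuals.group_counts, effect=float(gamma[1]),
                      se_effect=se, converged=converged,
                      info={"gamma": gamma.copy(), "beta": beta.copy(),
                            "deviance": deviance})


def _quail_tau_grid(k: int) -> np.ndarray:
    """Midpoints of K equal bins of (0, 0.5): tau_k = (2k-1)/(4K)."""
    return (2 * np.arange(1, k + 1) - 1) / (4.0 * k)


def quail_test(residuals: ResidualVector, genotype=None, k: int = 100,
               compute_effect: bool = False) -> VqtlResult:
    """Quantile-integral test for a genotype effect on trait dispersion.

    The estimand is the quantile-integrated effect

        beta_QI = integral_0^0.5 (beta_{1-tau} - beta_tau) d tau,

    the accumulated difference between upper- and lower-quantile genotype
    effects — positive when higher allele counts widen the distribution.
    It is approximated by a midpoint rule over K rectangles of width 1/(2K):
    ``sum_k (beta-hat_{1-tau_k} - beta-hat_{tau_k}) / (2K)``.

    Inference uses the integrated rank-score construction rather than 2K
    quantile-regression fits: each sample receives the score

        eta_j = (1/K) * sum_k [psi_{1-tau_k}(e_j) - psi_{tau_k}(e_j)],
        psi_tau(e) = tau - 1{e <= Q-hat_tau},

    with Q-hat_tau the marginal sample quantile of the residuals, and the
    slope of the OLS regression of eta on allele count is tested (two-sided
    t).  Fitting 2K quantile regressions per variant is reserved for the
    point estimate (``compute_effect=True``) because it is far too slow for
    a genome-wide scan.

    Covariates are assumed to be already removed by the pre-residualization,
    so no covariate terms are re-fit inside the test.
    """
    e = residuals.values
    x = residuals.groups.astype(float) if genotype is None else _allele_counts(genotype)
    n = e.shape[0]
    if k < 2:
        raise ValueError("need K >= 2 quantile pairs")
    if k > n:
        raise ValueError("K exceeds the sample size")
    if n < 10 * k:
        warnings.warn(f"N={n} is small relative to K={k}; "
                      "quantile estimates will be noisy", stacklevel=2)
    if np.ptp(x) == 0:
        raise ValueError("allele count is constant")

    taus = _quail_tau_grid(k)
    q_lo = np.quantile(e, taus)
    q_hi = np.quantile(e, 1.0 - taus)
    # psi_{1-tau}(e) - psi_tau(e), vectorized over the K-point grid
    ind_lo = e[:, None] <= q_lo[None, :]
    ind_hi = e[:, None] <= q_hi[None, :]
    eta = ((1.0 - taus) - ind_hi - taus + ind_lo).mean(axis=1)

    xc = x - x.mean()
    sxx = float((xc ** 2).sum())
    slope = float((xc * eta).sum() / sxx)
    fitted = eta.mean() + slope * xc
    sse = float(((eta - fitted) ** 2).sum())
    df = n - 2
    if sse == 0.0:
        return VqtlResult("QUAIL", 0.0, (df,), 1.0, residuals.group_counts,
                          degenerate=True)
    t = slope / np.sqrt(sse / df / sxx)
    p = float(2.0 * stats.t.sf(abs(t), df))

    effect = None
    if compute_effect:
        effect = quail_beta_qi(e, x, k)
    return VqtlResult("QUAIL", float(t), (df,), max(p, np.nextafter(0, 1)),
                      residuals.group_counts, effect=effect)


def quail_beta_qi(e: np.ndarray, x: np.ndarray, k: int) -> float:
    """Rectangle-rule estimate of the quantile-integrated effect.

    Runs 2K quantile regressions of the residuals on allele count and sums
    the upper-minus-lower slope differences over the midpoint grid; the
    rectangle width 1/(2K) turns the sum into the integral estimate.
    Expensive — intended for follow-up on a handful of variants, not scans.
    """
    import statsmodels.api as sm

    taus = _quail_tau_grid(k)
    X = sm.add_constant(np.asarray(x, dtype=float))
    total = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QuantReg convergence chatter
        for tau in taus:
            b_lo = sm.QuantReg(e, X).fit(q=tau, p_tol=1e-12).params[1]
            b_hi = sm.QuantReg(e, X).fit(q=1.0 - tau, p_tol=1e-12).params[1]
            total += b_hi - b_lo
    return float(total / (2.0 * k))
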