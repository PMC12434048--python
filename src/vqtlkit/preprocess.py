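"""Covariate adjustment and dispersion measures for variance-QTL testing.

Every vQTL test in this package operates on *covariate-adjusted residuals*:
the residuals of an ordinary least-squares regression of the trait on an
intercept, two genotype-group indicator variables (so the SNP's additive and
dominance main effects are both removed), and any covariate columns.
Removing the SNP main effect before testing is essential — a large mean
effect otherwise inflates the false-positive rate of dispersion tests.

The group-median deviation ``D = |e - median(e | genotype group)|`` converts
the residuals into a per-sample measure of spread; regressions or rank tests
on ``D`` then probe variance heterogeneity across genotype groups.  The
median (rather than the mean) is used as the group centre for robustness to
outliers, matching the Brown–Forsythe convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeVector",
    "ResidualVector",
    "DeviationVector",
    "residualize",
    "group_median_deviations",
    "inverse_normal_transform",
]

MISSING = np.nan


@dataclass
class GenotypeVector:
    """Hard-call minor-allele counts for one variant.

    Parameters
    ----------
    calls
        Per-sample values in {0, 1, 2}; missing calls are ``nan``.  Dosage
        (non-integer) values are rejected: the genotype-group medians that
        the dispersion measures rely on are undefined for dosages.
    name
        Optional variant identifier.
    """

    calls: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=float)
        observed = calls[~np.isnan(calls)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError(
                "genotype calls must be hard calls in {0, 1, 2} (or missing); "
                "dosage input is not supported"
            )
        self.calls = calls

    @property
    def maf(self) -> float:
        """Minor-allele frequency of the *counted* allele among non-missing calls.

        By construction of the scan-level allele orientation this is in
        [0, 0.5]; for raw user input it is simply the counted-allele
        frequency folded onto [0, 0.5].
        """
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size == 0:
            return float("nan")
        freq = float(observed.mean() / 2.0)
        return min(freq, 1.0 - freq)

    def __len__(self) -> int:
        return int(self.calls.shape[0])


@dataclass
class ResidualVector:
    """Covariate-adjusted residuals with their genotype-group labels.

    ``values[k]`` is the OLS residual for the k-th *analyzed* sample (after
    listwise deletion), ``groups[k]`` its genotype hard call (0/1/2) and
    ``index[k]`` its position in the original input arrays.
    """

    values: np.ndarray
    groups: np.ndarray
    index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.index is None:
            self.index = np.arange(self.values.shape[0])
        if self.values.shape != self.groups.shape:
            raise ValueError("values and groups must be aligned")

    @property
    def group_counts(self) -> tuple[int, int, int]:
        return tuple(int((self.groups == g).sum()) for g in (0, 1, 2))

    def __len__(self) -> int:
        return int(self.values.shape[0])


@dataclass
class DeviationVector:
    """Absolute deviations from the genotype-group median, |e - med_i(e)|."""

    values: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.values.shape != self.groups.shape:
            raise ValueError("values and groups must be aligned")

    @property
    def group_counts(self) -> tuple[int, int, int]:
        return tuple(int((self.groups == g).sum()) for g in (0, 1, 2))

    def __len__(self) -> int:
        return int(self.values.shape[0])


def _covariate_design(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    """Coerce covariates into an (n, C) float array plus column names."""
    if covariates is None:
        return np.empty((n, 0)), []
    if hasattr(covariates, "to_numpy"):  # DataFrame / Series
        names = [str(c) for c in getattr(covariates, "columns", ["covariate"])]
        arr = np.asarray(covariates.to_numpy(), dtype=float)
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"covariate_{i}" for i in range(arr.shape[1])]
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        raise ValueError("covariates are not aligned with the phenotype")
    return arr, names


def _check_covariate_rank(cov: np.ndarray, names: list[str]) -> None:
    """Raise if the intercept + covariate design is column-rank deficient.

    The offending column is located by adding columns one at a time, so the
    error message names a concrete culprit rather than just reporting a rank.
    """
    n = cov.shape[0]
    design = np.ones((n, 1))
    for j in range(cov.shape[1]):
        candidate = np.column_stack([design, cov[:, j]])
        if np.linalg.matrix_rank(candidate) <= np.linalg.matrix_rank(design):
            raise ValueError(
                f"covariate column {names[j]!r} is collinear with the "
                "intercept and/or preceding covariates"
            )
        design = candidate


def residualize(phenotype, genotype, covariates=None) -> ResidualVector:
    """Regress the trait on genotype-group indicators and covariates; keep residuals.

    The model is ``Y ~ 1 + I(g=1) + I(g=2) + X``: two indicator variables
    separate the three genotype groups, so both additive and dominance mean
    effects of the SNP are removed along with the covariate effects.
    Samples with missing phenotype, genotype, or covariates are dropped
    listwise before fitting.

    Parameters
    ----------
    phenotype
        Per-sample trait values (array-like; ``nan`` = missing).
    genotype
        :class:`GenotypeVector` or array of hard calls {0,1,2,nan}.
    covariates
        Optional (N, C) array or DataFrame.

    Returns
    -------
    ResidualVector
        Residuals, genotype group per analyzed sample, and the positions of
        the analyzed samples in the input.
    """
    y = np.asarray(phenotype, dtype=float)
    if not isinstance(genotype, GenotypeVector):
        genotype = GenotypeVector(np.asarray(genotype, dtype=float))
    g = genotype.calls
    if g.shape[0] != y.shape[0]:
        raise ValueError("phenotype and genotype are not aligned")
    cov, cov_names = _covariate_design(covariates, y.shape[0])

    keep = np.isfinite(y) & ~np.isnan(g)
    if cov.shape[1]:
        keep &= np.isfinite(cov).all(axis=1)
    y, g = y[keep], g[keep].astype(int)
    cov = cov[keep]
    if y.shape[0] < 3:
        raise ValueError("fewer than 3 complete samples after listwise deletion")
    if cov.shape[1]:
        _check_covariate_rank(cov, cov_names)

    # Indicator columns for genotype groups 1 and 2; a group absent from the
    # analyzed samples yields a constant (all-zero) indicator, which is
    # simply dropped rather than treated as an error.
    columns = [np.ones_like(y)]
    for level in (1, 2):
        indicator = (g == level).astype(float)
        if 0 < indicator.sum() < y.shape[0]:
            columns.append(indicator)
    design = np.column_stack(columns + [cov]) if cov.shape[1] else np.column_stack(columns)

    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ coef
    return ResidualVector(residuals, g, np.flatnonzero(keep))


def group_median_deviations(residuals: ResidualVector) -> DeviationVector:
    """Absolute deviation of each residual from its genotype-group median.

    ``D = |e - med_i(e)|`` is the per-sample dispersion measure consumed by
    the Kruskal–Wallis, Brown–Forsythe and deviation-regression tests.  The
    absolute value makes the statistic a test of spread: on signed
    deviations those procedures would test location, which the group-median
    subtraction has already annihilated.
    """
    e = residuals.values
    if e.size == 0:
        raise ValueError("empty residual vector")
    deviations = np.empty_like(e)
    for level in np.unique(residuals.groups):
        mask = residuals.groups == level
        deviations[mask] = np.abs(e[mask] - np.median(e[mask]))
    return DeviationVector(deviations, residuals.groups)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps value ``v`` with (average, for ties) rank ``r`` among ``n``
    observations to ``Phi^{-1}((r - 3/8) / (n + 1/4))``.  The result is an
    approximately standard-normal, strictly rank-preserving re-expression of
    the input; it is used by the DGLM_INT variant to tame heavy tails.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.shape[0] < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.ptp(v) == 0:
        raise ValueError("all values identical: ranks are degenerate")
    ranks = stats.rankdata(v, method="average")
    c = 3.0 / 8.0
    return stats.norm.ppf((ranks - c) / (v.shape[0] - 2 * c + 1))
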