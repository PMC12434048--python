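"""Follow-up analyses after a variance-QTL scan.

A vQTL is a *symptom* of an unmodelled interaction; these routines do the
confirmatory work:

* :func:`clump` reduces a significant hit list to independent lead variants
  by greedy selection under a pairwise LD (squared-correlation) ceiling.
* :func:`gxe_scan` regresses the raw trait on each lead variant's allele
  count, all environmental factors, optional ancestry PCs, and one
  variant-by-environment product term per fit — the "direct GxE" analysis.
* :func:`gxg_scan` does the same for every unordered pair of lead variants
  with a count-by-count product term (values 0, 1, 2, 4) — "direct GxG".

Screening on vQTLs first is what makes this tractable: 30 leads and 7
exposures need only 30 x 7 = 210 GxE and C(30,2) = 435 GxG fits per trait,
against millions (GxE) or half a trillion (GxG) exhaustive tests.

Each fit reports a signed -log10 p for heat-map style summaries: the
magnitude is -log10 of the two-sided interaction p-value and the sign is
``sign(beta_int * beta_g)`` — positive when the partner *exacerbates* the
variant's effect (pushes it further from zero), negative when it attenuates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["InteractionFit", "clump", "gxe_scan", "gxg_scan", "signed_matrix"]


@dataclass
class InteractionFit:
    """One interaction regression: a (variant, partner) product-term fit."""

    variant: str
    partner: str
    beta_g: float
    beta_partner: float
    beta_int: float
    se_int: float
    p_int: float
    signed_log10p: float
    n: int


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two allele-count vectors (pairwise complete)."""
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def clump(results: pd.DataFrame, genotypes: pd.DataFrame,
          p_threshold: float = 5e-8, r2_threshold: float = 0.01) -> list[str]:
    """Greedy LD clumping of scan hits to independent lead variants.

    Visits variants in order of increasing p (ties broken by variant id,
    lexicographically) and keeps one iff its p-value beats ``p_threshold``
    and its squared correlation with every already-kept lead is below
    ``r2_threshold``.  No base-pair window or secondary threshold is
    applied: vQTL hit lists are short enough for the marginal-r2 rule.

    Parameters
    ----------
    results
        DataFrame with columns ``id`` and ``p``.
    genotypes
        Samples x variants allele-count matrix; columns are variant ids.
    """
    hits = results.loc[results["p"] < p_threshold, ["id", "p"]]
    hits = hits.sort_values(["p", "id"], kind="mergesort")
    missing = [v for v in hits["id"] if v not in genotypes.columns]
    if missing:
        raise KeyError(f"no genotype column for significant variant(s): {missing}")
    leads: list[str] = []
    for vid in hits["id"]:
        g = genotypes[vid].to_numpy(dtype=float)
        if all(pairwise_r2(g, genotypes[kept].to_numpy(dtype=float)) < r2_threshold
               for kept in leads):
            leads.append(str(vid))
    return leads


def _interaction_fit(y: np.ndarray, g: np.ndarray, partner: np.ndarray,
                     mains: np.ndarray, partner_idx: int,
                     label: tuple[str, str]) -> InteractionFit | None:
    """OLS of y on [1, g, mains..., g*partner]; t test on the product term.

    ``partner`` must also appear among ``mains`` (its position given by
    ``partner_idx`` within ``mains``) so the hierarchical structure — main
    effects below their interaction — is preserved.
    """
    product = g * partner
    X = np.column_stack([np.ones_like(y), g, mains, product])
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(f"collinear design for {label}; pair skipped", stacklevel=3)
        return None
    fit = sm.OLS(y, X).fit()
    beta_g = float(fit.params[1])
    beta_int = float(fit.params[-1])
    p_int = float(fit.pvalues[-1])
    p_int = max(p_int, np.nextafter(0, 1))
    sign = np.sign(beta_int * beta_g) or 1.0
    return InteractionFit(
        variant=label[0], partner=label[1],
        beta_g=beta_g,
        beta_partner=float(fit.params[2 + partner_idx]),
        beta_int=beta_int,
        se_int=float(fit.bse[-1]),
        p_int=p_int,
        signed_log10p=float(sign * -np.log10(p_int)),
        n=int(ok.sum()),
    )


def _drop_collinear_exposures(envs: pd.DataFrame) -> pd.DataFrame:
    """Drop exposure columns collinear with the intercept or earlier exposures.

    A constant exposure (say, nobody in the cohort smokes) would make every
    design in the scan rank-deficient, so such columns are removed up front
    with a warning and their pairs are simply not fitted.
    """
    kept: list[str] = []
    design = np.ones((len(envs), 1))
    for name in envs.columns:
        candidate = np.column_stack([design, envs[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(candidate) <= np.linalg.matrix_rank(design):
            warnings.warn(f"exposure {name!r} is collinear and is dropped "
                          "from the interaction scan", stacklevel=3)
            continue
        design = candidate
        kept.append(name)
    return envs[kept]


def _as_frame(table, kind: str) -> pd.DataFrame:
    if table is None:
        return pd.DataFrame()
    if not isinstance(table, pd.DataFrame):
        raise TypeError(f"{kind} must be a DataFrame with named columns")
    return table


def gxe_scan(phenotype, vqtls: pd.DataFrame, environments: pd.DataFrame,
             pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Direct gene-environment analysis over every (vQTL, exposure) pair.

    Each fit regresses the raw trait on the variant's allele count, *all*
    exposure columns as main effects, the ancestry PCs, and the product of
    the allele count with one exposure at a time.  Exposures whose product
    term makes the design collinear (e.g. a constant exposure) are skipped
    with a warning.  Returns one row per fitted pair.
    """
    y = np.asarray(phenotype, dtype=float)
    envs = _drop_collinear_exposures(_as_frame(environments, "environments"))
    pcs = _as_frame(pcs, "pcs")
    adj = pd.concat([envs, pcs], axis=1) if pcs.shape[1] else envs
    mains = adj.to_numpy(dtype=float)
    rows = []
    for vid in vqtls.columns:
        g = vqtls[vid].to_numpy(dtype=float)
        for j, ename in enumerate(envs.columns):
            e = envs[ename].to_numpy(dtype=float)
            fit = _interaction_fit(y, g, e, mains, j, (str(vid), str(ename)))
            if fit is not None:
                rows.append(fit)
    return pd.DataFrame([vars(f) for f in rows])


def gxg_scan(phenotype, vqtls: pd.DataFrame, environments: pd.DataFrame,
             pcs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Direct gene-gene analysis over every unordered pair of vQTLs.

    Each fit regresses the raw trait on both variants' allele counts, the
    exposure main effects, the ancestry PCs, and the count-by-count product
    (which takes the values 0, 1, 2 and 4).  Returns one row per pair:
    C(#vQTLs, 2) fits in total.
    """
    y = np.asarray(phenotype, dtype=float)
    envs = _drop_collinear_exposures(_as_frame(environments, "environments"))
    pcs = _as_frame(pcs, "pcs")
    rows = []
    for vid_a, vid_b in itertools.combinations(vqtls.columns, 2):
        ga = vqtls[vid_a].to_numpy(dtype=float)
        gb = vqtls[vid_b].to_numpy(dtype=float)
        adj = [gb[:, None], envs.to_numpy(dtype=float)]
        if pcs.shape[1]:
            adj.append(pcs.to_numpy(dtype=float))
        mains = np.column_stack(adj)
        fit = _interaction_fit(y, ga, gb, mains, 0, (str(vid_a), str(vid_b)))
        if fit is not None:
            rows.append(fit)
    return pd.DataFrame([vars(f) for f in rows])


def signed_matrix(fits: pd.DataFrame) -> pd.DataFrame:
    """Pivot interaction fits into a variants x partners signed -log10 p matrix.

    Rows are vQTL ids, columns partner labels (exposures for GxE, vQTL ids
    for GxG); the values are ready for external heat-map rendering.
    """
    return fits.pivot(index="variant", columns="partner", values="signed_log10p")
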