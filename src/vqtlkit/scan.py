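"""Genome-wide vQTL scanning and synthetic-cohort fixtures.

:func:`run_scan` wires the whole pipeline together per variant: align the
genotype, phenotype and covariate tables on sample id, orient each variant
to count its minor allele in the analyzed cohort, listwise-delete missing
data, residualize, form group-median deviations and apply the requested
test.  Variants failing a precondition (monomorphic, below the MAF floor,
degenerate dispersion) are emitted as NA rows with a reason code so the
output has exactly one row per input variant.

:func:`generate_fixture` writes a fully synthetic cohort — PLINK trio,
phenotype and covariate tables plus a ground-truth manifest — with optional
planted mean and dispersion effects, for pipeline testing and examples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from . import vartests
from .benchmark import qq_points
from .preprocess import GenotypeVector, group_median_deviations, residualize

__all__ = ["ScanConfig", "run_scan", "generate_fixture"]

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Everything a vQTL scan needs.

    ``genotypes`` is a PLINK prefix (``dialect="plink"``) or a delimited
    matrix path (``dialect="matrix"``).  ``maf_min`` defaults to 0.05 —
    interaction findings at rarer variants replicate poorly — and ``alpha``
    to the conventional genome-wide 5e-8 (used only for reporting).
    """

    genotypes: str
    phenotype: str
    dialect: str = "plink"
    phenotype_column: str | None = None
    covariates: str | None = None
    covariate_columns: list[str] | None = None
    method: str = "KW"
    maf_min: float = 0.05
    alpha: float = 5e-8
    quail_k: int = 100
    seed: int = 0
    out: str | None = None

    def __post_init__(self) -> None:
        if self.method not in vartests.METHODS:
            raise ValueError(f"method must be one of {vartests.METHODS}")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if self.dialect not in ("plink", "matrix"):
            raise ValueError("dialect must be 'plink' or 'matrix'")


def _load_genotypes(config: ScanConfig):
    if config.dialect == "plink":
        genotypes, bim, _fam = vio.read_plink(config.genotypes)
        meta = bim.set_index("id")[["chrom", "pos"]]
    else:
        genotypes = vio.read_genotype_matrix(config.genotypes)
        meta = pd.DataFrame({"chrom": "NA", "pos": -1},
                            index=genotypes.columns)
    return genotypes, meta


def analyze_variant(y: np.ndarray, calls: np.ndarray, covariates,
                     method: str, quail_k: int = 100) -> vartests.VqtlResult:
    """Run one test on one variant exactly as the scan does (library path)."""
    res = residualize(y, GenotypeVector(calls), covariates)
    if method in ("KW", "BF", "DRM"):
        dev = group_median_deviations(res)
        fn = {"KW": vartests.kw_test, "BF": vartests.bf_test,
              "DRM": vartests.drm_test}[method]
        return fn(dev)
    if method == "DGLM":
        return vartests.dglm_test(res)
    if method == "DGLM_INT":
        return vartests.dglm_test(res, apply_int=True)
    return vartests.quail_test(res, k=quail_k)


def run_scan(config: ScanConfig) -> pd.DataFrame:
    """Scan every variant with the configured test; write TSV if ``config.out``.

    MAF and minor-allele orientation are recomputed on the analyzed
    (post-listwise-deletion) samples of each variant; when the counted
    allele's frequency exceeds 0.5 the calls are flipped to ``2 - calls``
    (exact ties keep the file orientation).
    """
    genotypes, meta = _load_genotypes(config)
    pheno_table = vio.read_sample_table(config.phenotype)
    col = config.phenotype_column or pheno_table.columns[0]
    phenotype = pheno_table[col].astype(float)

    covariates = None
    if config.covariates is not None:
        covariates = vio.read_sample_table(config.covariates)
        if config.covariate_columns:
            covariates = covariates[list(config.covariate_columns)]

    samples = genotypes.index.intersection(phenotype.index)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
    unmatched = genotypes.index.difference(samples)
    if len(samples) == 0:
        raise ValueError("no samples shared across genotype and phenotype tables")
    if len(unmatched):
        logger.warning("%d genotyped samples have no phenotype/covariates "
                       "and are dropped: %s%s", len(unmatched),
                       ", ".join(map(str, unmatched[:5])),
                       "..." if len(unmatched) > 5 else "")
    genotypes = genotypes.loc[samples]
    y_all = phenotype.loc[samples].to_numpy(dtype=float)
    cov_all = covariates.loc[samples] if covariates is not None else None

    rows = []
    for vid in genotypes.columns:
        calls = genotypes[vid].to_numpy(dtype=float)
        row = {"chrom": meta.loc[vid, "chrom"], "pos": meta.loc[vid, "pos"],
               "id": vid, "maf": np.nan, "n0": 0, "n1": 0, "n2": 0,
               "method": config.method, "statistic": np.nan, "df": "NA",
               "effect": np.nan, "p": np.nan, "note": "."}
        ok = ~np.isnan(calls) & np.isfinite(y_all)
        if cov_all is not None:
            ok &= np.isfinite(cov_all.to_numpy(dtype=float)).all(axis=1)
        observed = calls[ok]
        if observed.size < 3 or np.ptp(observed) == 0:
            row["note"] = "monomorphic"
            rows.append(row)
            continue
        freq = observed.mean() / 2.0
        if freq > 0.5:
            calls = 2.0 - calls
            freq = 1.0 - freq
        row["maf"] = freq
        if freq < config.maf_min:
            row["note"] = "maf_below_threshold"
            rows.append(row)
            continue
        try:
            result = analyze_variant(y_all, calls, cov_all, config.method,
                                      config.quail_k)
        except Exception as exc:  # precondition failures become NA rows
            logger.warning("variant %s failed: %s", vid, exc)
            row["note"] = "test_failed"
            rows.append(row)
            continue
        row.update({
            "n0": result.group_counts[0], "n1": result.group_counts[1],
            "n2": result.group_counts[2], "statistic": result.statistic,
            "df": ",".join(str(d) for d in result.df),
            "effect": result.effect if result.effect is not None else np.nan,
            "p": result.p_value,
            "note": "degenerate" if result.degenerate else ".",
        })
        rows.append(row)

    results = pd.DataFrame(rows)
    tested = results["p"].dropna()
    if tested.size:
        logger.info("scan complete: %d tested, %d NA, QQ slope %.3f",
                    tested.size, len(results) - tested.size,
                    qq_points(tested.to_numpy()).slope)
    if config.out:
        vio.write_scan_results(config.out, results)
    return results


@dataclass
class PlantedVariant:
    """Ground truth for one fixture variant with non-null effects.

    ``disp_slope`` is the per-allele slope on log phenotypic variance;
    ``beta_main`` an additive mean effect in trait SD units.
    """

    index: int
    disp_slope: float = 0.0
    beta_main: float = 0.0


def generate_fixture(n_samples: int, n_variants: int, planted=(),
                     seed: int = 0, outdir=None, maf_range=(0.05, 0.5),
                     duplicate_planted: bool = False):
    """Create a synthetic cohort with optional planted vQTLs.

    Genotypes are Hardy–Weinberg draws at MAFs uniform over ``maf_range``.
    The trait is built from sex and age covariate effects, the planted mean
    effects, and normal noise whose per-sample log-variance is the sum of
    the planted dispersion slopes times the corresponding allele counts.
    With ``duplicate_planted`` each planted variant is copied into an extra
    column (suffix ``_dup``), giving an r² = 1 pair for clumping tests.

    Writes (if ``outdir``) a PLINK trio ``fixture.*``, ``phenotype.tsv``,
    ``covariates.tsv`` and ``manifest.json``; returns
    ``(genotypes, phenotype, covariates, manifest)`` regardless.
    """
    planted = [p if isinstance(p, PlantedVariant) else PlantedVariant(**p)
               for p in planted]
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=n_variants)
    calls = rng.binomial(2, mafs[None, :], size=(n_samples, n_variants)).astype(float)
    ids = [f"var{i:04d}" for i in range(n_variants)]
    genotypes = pd.DataFrame(calls, columns=ids,
                             index=[f"sample{j:05d}" for j in range(n_samples)])
    if duplicate_planted:
        for p in planted:
            genotypes[f"{ids[p.index]}_dup"] = genotypes[ids[p.index]]

    sex = rng.binomial(1, 0.5, size=n_samples).astype(float)
    age = rng.normal(50.0, 10.0, size=n_samples)
    covariates = pd.DataFrame({"sex": sex, "age": age}, index=genotypes.index)

    log_var = np.zeros(n_samples)
    mean = 0.25 * sex + 0.02 * (age - 50.0)
    for p in planted:
        g = calls[:, p.index]
        log_var = log_var + p.disp_slope * g
        mean = mean + p.beta_main * g
    y = mean + rng.normal(0.0, np.exp(0.5 * log_var))
    phenotype = pd.DataFrame({"trait": y}, index=genotypes.index)

    manifest = {
        "n_samples": n_samples, "n_variants": n_variants, "seed": seed,
        "planted": [{"id": ids[p.index], "index": p.index,
                     "disp_slope": p.disp_slope, "beta_main": p.beta_main}
                    for p in planted],
        "covariate_effects": {"sex": 0.25, "age_per_year": 0.02},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vio.write_plink(outdir / "fixture", genotypes)
        phenotype.rename_axis("iid").to_csv(outdir / "phenotype.tsv", sep="\t")
        covariates.rename_axis("iid").to_csv(outdir / "covariates.tsv", sep="\t")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return genotypes, phenotype, covariates, manifest
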