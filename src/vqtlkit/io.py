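"""File formats: PLINK1 binary genotypes, delimited matrices, scan output.

Genotypes are accepted in two dialects:

* PLINK1 trio ``.bed``/``.bim``/``.fam`` in the variant-major layout
  (magic bytes ``6c 1b 01``).  Each variant occupies ``ceil(N/4)`` bytes,
  two bits per sample: ``00`` = homozygous A1 (count 2), ``10`` =
  heterozygous (count 1), ``11`` = homozygous A2 (count 0), ``01`` =
  missing.  The counted allele is A1, PLINK's usual minor-allele slot.
* A delimited text matrix, variants as rows: first column the variant id,
  header row the sample ids, cells in {0, 1, 2, NA}.

Phenotype and covariate tables are tab- or comma-delimited text with a
header, first column the sample id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_plink",
    "write_plink",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_sample_table",
    "write_scan_results",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> A1 allele count (nan = missing), indexed by code value
_CODE_TO_CALL = np.array([2.0, np.nan, 1.0, 0.0])
_CALL_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}

BIM_COLUMNS = ["chrom", "id", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def read_plink(prefix) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK1 .bed/.bim/.fam trio.

    Returns ``(genotypes, bim, fam)`` where genotypes is a samples x
    variants DataFrame of A1 allele counts (NaN = missing) indexed by
    individual id with variant-id columns.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=BIM_COLUMNS, dtype={"chrom": str, "id": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=FAM_COLUMNS, dtype={"fid": str, "iid": str})
    n_samples, n_variants = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a variant-major PLINK1 .bed file")
    bytes_per_variant = (n_samples + 3) // 4
    body = raw[3:].reshape(n_variants, bytes_per_variant)
    # unpack the 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_variants, -1)[:, :n_samples]
    calls = _CODE_TO_CALL[codes]  # variants x samples
    genotypes = pd.DataFrame(calls.T, index=fam["iid"].tolist(),
                             columns=bim["id"].tolist())
    return genotypes, bim, fam


def write_plink(prefix, genotypes: pd.DataFrame, bim: pd.DataFrame | None = None,
                fam: pd.DataFrame | None = None) -> None:
    """Write a samples x variants allele-count DataFrame as a PLINK1 trio.

    Default ``bim``/``fam`` tables are fabricated from the DataFrame labels
    (chromosome 1, positions 1..V, alleles A/B, unknown parents and sex).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n_samples, n_variants = genotypes.shape
    if bim is None:
        bim = pd.DataFrame({
            "chrom": "1", "id": [str(c) for c in genotypes.columns],
            "cm": 0, "pos": np.arange(1, n_variants + 1),
            "a1": "A", "a2": "B",
        })
    if fam is None:
        iids = [str(i) for i in genotypes.index]
        fam = pd.DataFrame({"fid": iids, "iid": iids, "father": 0, "mother": 0,
                            "sex": 0, "phenotype": -9})
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    calls = genotypes.to_numpy(dtype=float).T  # variants x samples
    codes = np.full(calls.shape, 0b01, dtype=np.uint8)  # missing by default
    for call, code in _CALL_TO_CODE.items():
        codes[calls == call] = code
    pad = (-calls.shape[1]) % 4
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=0b01)
    grouped = codes.reshape(codes.shape[0], -1, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (grouped << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_genotype_matrix(path) -> pd.DataFrame:
    """Read a delimited variants x rows matrix into samples x variants form."""
    table = pd.read_csv(path, sep=None, engine="python", index_col=0,
                        na_values=["NA", "na", ""])
    genotypes = table.T.astype(float)
    genotypes.index = [str(i) for i in genotypes.index]
    genotypes.columns = [str(c) for c in genotypes.columns]
    bad = genotypes.stack().dropna()
    if bad.size and not np.isin(bad.to_numpy(), (0.0, 1.0, 2.0)).all():
        raise ValueError(f"{path}: genotype matrix entries must be 0, 1, 2 or NA")
    return genotypes


def write_genotype_matrix(path, genotypes: pd.DataFrame) -> None:
    """Write samples x variants genotypes as a variants-as-rows TSV with NA codes."""
    out = genotypes.T
    formatted = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    formatted.index.name = "variant"
    formatted.to_csv(path, sep="\t")


def read_sample_table(path) -> pd.DataFrame:
    """Read a tab- or comma-delimited table with header; first column = sample id."""
    table = pd.read_csv(path, sep=None, engine="python", index_col=0)
    table.index = [str(i) for i in table.index]
    return table


def write_scan_results(path, results: pd.DataFrame) -> None:
    """Write per-variant scan rows as TSV with a fixed column order."""
    columns = ["chrom", "pos", "id", "maf", "n0", "n1", "n2",
               "method", "statistic", "df", "effect", "p", "note"]
    results[columns].to_csv(path, sep="\t", index=False, na_rep="NA",
                            float_format="%.6g")
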