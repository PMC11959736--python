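"""Optional SNP-table preprocessing mirroring standard genomic-selection QC.

Replicated genotypes (rows sharing an ID) are averaged, SNP columns with too
many missing calls or too low a minor allele frequency are dropped, and any
remaining missing genotypes are mean-imputed per column. The thresholds are
inclusive on the failing side: a SNP with missingness >= ``max_missing`` or
MAF <= ``maf_min`` is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["FilterReport", "preprocess_genotypes", "average_replicates"]


@dataclass(frozen=True)
class FilterReport:
    n_snps_in: int
    n_dropped_missing: int
    n_dropped_maf: int
    n_snps_out: int
    n_rows_merged: int
    n_imputed_cells: int


def average_replicates(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Average rows that share an index ID (replicated genotypes/responses)."""
    if table.index.has_duplicates:
        merged = table.groupby(level=0, sort=False).mean()
        return merged, len(table) - len(merged)
    return table, 0


def preprocess_genotypes(
    table: pd.DataFrame,
    maf_min: float = 0.01,
    max_missing: float = 0.10,
    impute: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter a 0/1/2 genotype table by missingness and minor allele frequency.

    Columns with a fraction of missing calls >= ``max_missing`` or a minor
    allele frequency <= ``maf_min`` (computed from non-missing calls) are
    dropped, in that order. Remaining missing cells are mean-imputed per
    column when ``impute`` is set.
    """
    if not 0 <= maf_min < 0.5:
        raise InputError("maf_min must be in [0, 0.5)")
    table, n_merged = average_replicates(table)
    G = table.to_numpy(dtype=float)
    vals = G[~np.isnan(G)]
    if vals.size and (vals.min() < 0 or vals.max() > 2):
        raise InputError("genotypes must be coded 0/1/2 (dosages in [0, 2])")

    miss_frac = np.isnan(G).mean(axis=0)
    keep_missing = miss_frac < max_missing
    n_drop_missing = int((~keep_missing).sum())

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(G, axis=0) / 2.0  # allele frequency of the counted allele
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = keep_missing & (maf > maf_min)
    n_drop_maf = int((keep_missing & ~keep_maf).sum())

    if not keep_maf.any():
        raise InputError("all SNP columns were removed by the filters")

    out = table.loc[:, keep_maf].copy()
    n_imputed = 0
    if impute:
        arr = out.to_numpy(dtype=float)
        nan_mask = np.isnan(arr)
        n_imputed = int(nan_mask.sum())
        if n_imputed:
            col_means = np.nanmean(arr, axis=0)
            arr[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
            out = pd.DataFrame(arr, index=out.index, columns=out.columns)

    report = FilterReport(
        n_snps_in=table.shape[1],
        n_dropped_missing=n_drop_missing,
        n_dropped_maf=n_drop_maf,
        n_snps_out=int(keep_maf.sum()),
        n_rows_merged=n_merged,
        n_imputed_cells=n_imputed,
    )
    return out, report
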