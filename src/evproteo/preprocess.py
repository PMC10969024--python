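"""Filtering, imputation, normalization and row standardization.

Order of application in the pipeline: log2 conversion (at read time),
70%-presence filtering, left-censored normal imputation, quantile
normalization; row Z-scores are used for heatmap-style visualisation of
significant proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (FRACTIONS, IntensityMatrix, SampleSheet,
                        ValidationError)


@dataclass
class PresenceSummary:
    """Per-protein fraction of quantified samples per scope cell.

    ``per_cell`` columns are "group|fraction" labels; ``per_fraction``
    columns are fraction labels.  All values lie in [0, 1].
    """

    per_cell: pd.DataFrame
    per_fraction: pd.DataFrame


def _presence_table(data: pd.DataFrame, groups: dict[str, list[str]]
                    ) -> pd.DataFrame:
    cols = {}
    for label, samples in groups.items():
        sub = data[samples]
        cols[label] = sub.notna().sum(axis=1) / len(samples)
    return pd.DataFrame(cols, index=data.index)


def presence_summary(matrix: IntensityMatrix,
                     sheet: SampleSheet) -> PresenceSummary:
    sheet.validate_against(matrix)
    data = matrix.data
    cell_groups = {f"{g}|{f}": s for (g, f), s in sheet.cells().items()}
    frac_groups = {f: sheet.samples_in(fraction=f) for f in FRACTIONS
                   if sheet.samples_in(fraction=f)}
    return PresenceSummary(per_cell=_presence_table(data, cell_groups),
                           per_fraction=_presence_table(data, frac_groups))


def filter_by_presence(matrix: IntensityMatrix, sheet: SampleSheet,
                       threshold: float = 0.70, scope: str = "cell"
                       ) -> tuple[IntensityMatrix, PresenceSummary]:
    """Keep proteins quantified in >= ``threshold`` (inclusive) of the
    samples of at least one scope cell.

    ``scope`` is "cell" (each of the 9 group x fraction cells) or
    "fraction" (each of the 3 fractions pooled over groups).  Protein
    order is preserved.  An empty result is a warning, not an error.
    """
    if not (0 < threshold <= 1):
        raise ValidationError("threshold must be in (0, 1]")
    if scope not in ("cell", "fraction"):
        raise ValidationError("scope must be 'cell' or 'fraction'")
    summ = presence_summary(matrix, sheet)
    table = summ.per_cell if scope == "cell" else summ.per_fraction
    keep = (table >= threshold).any(axis=1)
    if not keep.any():
        warnings.warn("presence filter removed every protein", stacklevel=2)
    filtered = IntensityMatrix(matrix.data.loc[keep],
                               is_log2=matrix.is_log2)
    return filtered, summ


def impute_missing_normal(matrix: IntensityMatrix, width: float = 0.3,
                          downshift: float = 1.8, seed: int = 0,
                          per_sample: bool = True) -> IntensityMatrix:
    """Replace missing entries with draws from a downshifted normal.

    For each sample (column) with observed mean m and SD s, missing
    entries are drawn from Normal(m - downshift*s, (width*s)^2) — the
    standard left-censored imputation for label-free data, reflecting
    that unquantified proteins sit near the detection limit.  With
    ``per_sample=False`` the global observed mean/SD is used instead.
    Observed entries are never altered.
    """
    if width <= 0:
        raise ValidationError("width must be > 0")
    if not matrix.is_log2:
        raise ValidationError("imputation expects a log2 matrix")
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()
    if not per_sample:
        obs = data.to_numpy(dtype=float)
        m = np.nanmean(obs)
        s = np.nanstd(obs, ddof=1)
    for col in data.columns:
        col_vals = data[col]
        miss = col_vals.isna()
        if not miss.any():
            continue
        if per_sample:
            observed = col_vals.dropna()
            if len(observed) < 2:
                raise ValidationError(
                    f"sample {col!r} has < 2 observed values; cannot "
                    "estimate imputation distribution")
            m = observed.mean()
            s = observed.std(ddof=1)
        draws = rng.normal(m - downshift * s, width * s, size=int(miss.sum()))
        data.loc[miss, col] = draws
    return IntensityMatrix(data, is_log2=True)


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Force every sample onto the mean distribution of order statistics.

    After normalization every column's sorted vector equals the
    across-sample mean of sorted values.  Ties within a sample receive
    the mean of the reference values at their tied rank positions.
    Requires a complete (post-imputation) matrix.
    """
    if not matrix.is_complete():
        raise ValidationError("quantile normalization requires a complete "
                              "matrix (impute first)")
    vals = matrix.values
    n, k = vals.shape
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(vals)
    for j in range(k):
        col_sorted_ref = reference.copy()
        col = vals[:, j]
        # positions in sorted order; average reference over runs of ties
        idx = order[:, j]
        sorted_col = col[idx]
        # find tie runs in the sorted column
        start = 0
        assigned = np.empty(n)
        while start < n:
            end = start + 1
            while end < n and sorted_col[end] == sorted_col[start]:
                end += 1
            assigned[start:end] = col_sorted_ref[start:end].mean()
            start = end
        out[idx, j] = assigned
    return IntensityMatrix(
        pd.DataFrame(out, index=matrix.data.index,
                     columns=matrix.data.columns),
        is_log2=matrix.is_log2)


def zscore_rows(matrix: IntensityMatrix) -> IntensityMatrix:
    """Standardize each protein row to mean 0, SD 1 (population
    denominator).  Zero-variance rows are an error."""
    if not matrix.is_complete():
        raise ValidationError("zscore_rows requires a complete matrix")
    vals = matrix.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        bad = [p for p, f in zip(matrix.protein_ids, flat) if f]
        raise ValidationError(f"zero-variance rows: {bad}")
    z = (vals - mean) / sd
    return IntensityMatrix(
        pd.DataFrame(z, index=matrix.data.index,
                     columns=matrix.data.columns),
        is_log2=matrix.is_log2)
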