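"""Per-protein hypothesis testing and the comparison-intersection logic
that defines biomarker panels.

One-way ANOVA across the group x fraction cells screens for any change;
Welch t-tests drive the pairwise comparisons (PA-vs-CH, PA-vs-MB,
PA-vs-nonPA per fraction and pooled); Benjamini-Hochberg controls the
FDR; significance on the volcano plane combines a hyperbolic cutoff
curve y = |c/(x - x0)| with a q-value ceiling.  Panels are the proteins
recurrently significant across comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (FRACTIONS, IntensityMatrix, SampleSheet,
                        ValidationError)

#: the three contrasts of interest; sides are (case samples, control samples)
COMPARISONS = ("PA-vs-CH", "PA-vs-MB", "PA-vs-nonPA")


def comparison_sides(comparison: str) -> tuple[list[str], list[str]]:
    """Group labels on each side of a named comparison.  The first-named
    side (PA) is the case side: positive log2FC means higher in PA."""
    mapping = {
        "PA-vs-CH": (["PA"], ["CH"]),
        "PA-vs-MB": (["PA"], ["MB"]),
        "PA-vs-nonPA": (["PA"], ["CH", "MB"]),
    }
    if comparison not in mapping:
        raise ValidationError(f"unknown comparison {comparison!r}")
    return mapping[comparison]


def _cell_arrays(matrix: IntensityMatrix, sheet: SampleSheet,
                 cells: Sequence[Sequence[str]]) -> list[np.ndarray]:
    arrays = []
    for samples in cells:
        if len(samples) < 2:
            raise ValidationError(
                f"cell with samples {list(samples)} has < 2 samples")
        arrays.append(matrix.data[list(samples)].to_numpy(dtype=float))
    return arrays


def oneway_anova(matrix: IntensityMatrix, sheet: SampleSheet,
                 cells: Sequence[Sequence[str]] | None = None
                 ) -> pd.DataFrame:
    """Classic one-way ANOVA per protein across sample cells.

    ``cells`` defaults to all occupied group x fraction cells.  Returns
    a DataFrame with columns F and p.  Degenerate (zero within- and
    between-variance) proteins get F = 0, p = 1: never significant.
    """
    if not matrix.is_complete():
        raise ValidationError("ANOVA requires a complete matrix")
    if cells is None:
        sheet.validate_against(matrix)
        cells = list(sheet.cells().values())
    if len(cells) < 2:
        raise ValidationError("need >= 2 cells")
    arrays = _cell_arrays(matrix, sheet, cells)
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # degenerate (near-constant) rows are handled by the p = 1 policy
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.f_oneway(*arrays, axis=1)
    f = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(f)
    f[bad] = 0.0
    p[bad] = 1.0
    return pd.DataFrame({"F": f, "p": p}, index=matrix.protein_ids)


def welch_ttest(matrix: IntensityMatrix, sheet: SampleSheet,
                comparison: str, fraction: str | None = None
                ) -> pd.DataFrame:
    """Welch two-sample t-test per protein for a named comparison.

    ``fraction`` restricts both sides to one CSF fraction; None pools
    all fractions (each sample independent).  log2FC = mean(case) -
    mean(control); the matrix is already log2.  Zero-variance degenerate
    proteins get t = 0, p = 1.
    """
    if not matrix.is_complete():
        raise ValidationError("t-test requires a complete matrix")
    case_groups, ctrl_groups = comparison_sides(comparison)
    case = [s for g in case_groups
            for s in sheet.samples_in(group=g, fraction=fraction)]
    ctrl = [s for g in ctrl_groups
            for s in sheet.samples_in(group=g, fraction=fraction)]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValidationError(
            f"{comparison} ({fraction or 'pooled'}): each side needs >= 2 "
            f"samples (got {len(case)} vs {len(ctrl)})")
    a = matrix.data[case].to_numpy(dtype=float)
    b = matrix.data[ctrl].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    return pd.DataFrame({
        "mean_case": a.mean(axis=1),
        "mean_control": b.mean(axis=1),
        "log2fc": a.mean(axis=1) - b.mean(axis=1),
        "t": t,
        "p": p,
    }, index=matrix.protein_ids)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted scale, capped at 1,
    returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class DifferentialTable:
    """Per-protein differential-abundance results for one comparison."""

    table: pd.DataFrame  # columns: mean_case, mean_control, log2fc, t, p, q, neg_log10_q, significant
    comparison: str
    fraction: str  # a fraction label or "pooled"

    @property
    def significant_proteins(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["comparison"] = self.comparison
        out["fraction"] = self.fraction
        return out


def volcano_significance(table: pd.DataFrame, c: float,
                         x0: float = 0.0, q_max: float = 0.05
                         ) -> pd.Series:
    """Flag proteins above the hyperbolic cutoff y >= |c/(x - x0)| with
    q <= q_max.  The boundary is inclusive; at x = x0 the curve is
    infinite, so the protein is never significant."""
    if c <= 0:
        raise ValidationError("volcano c must be > 0")
    x = table["log2fc"].to_numpy(dtype=float)
    y = table["neg_log10_q"].to_numpy(dtype=float)
    q = table["q"].to_numpy(dtype=float)
    dx = x - x0
    with np.errstate(divide="ignore"):
        curve = np.abs(np.where(dx == 0, np.inf, c / dx))
    flags = (y >= curve) & (q <= q_max)
    return pd.Series(flags, index=table.index, name="significant")


def differential_table(matrix: IntensityMatrix, sheet: SampleSheet,
                       comparison: str, fraction: str | None = None,
                       c: float = float(-np.log10(0.05)), x0: float = 0.0,
                       q_max: float = 0.05) -> DifferentialTable:
    """Welch test + BH + volcano flags for one comparison x fraction."""
    tab = welch_ttest(matrix, sheet, comparison, fraction)
    tab["q"] = bh_adjust(tab["p"].to_numpy())
    with np.errstate(divide="ignore"):
        tab["neg_log10_q"] = -np.log10(tab["q"])
    tab["significant"] = volcano_significance(tab, c=c, x0=x0, q_max=q_max)
    return DifferentialTable(table=tab, comparison=comparison,
                             fraction=fraction or "pooled")


def run_all_comparisons(matrix: IntensityMatrix, sheet: SampleSheet,
                        c: float = float(-np.log10(0.05)), x0: float = 0.0,
                        q_max: float = 0.05
                        ) -> dict[tuple[str, str], DifferentialTable]:
    """All three comparisons per fraction plus pooled."""
    out: dict[tuple[str, str], DifferentialTable] = {}
    fracs = [f for f in FRACTIONS if sheet.samples_in(fraction=f)]
    for comp in COMPARISONS:
        for frac in fracs:
            out[(comp, frac)] = differential_table(
                matrix, sheet, comp, frac, c=c, x0=x0, q_max=q_max)
        out[(comp, "pooled")] = differential_table(
            matrix, sheet, comp, None, c=c, x0=x0, q_max=q_max)
    return out


def percent_of(count: int, total: int) -> float:
    """Percentage of a total, rounded to one decimal (panel bookkeeping
    convention)."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return round(100.0 * count / total, 1)


@dataclass
class PanelResult:
    venn: pd.DataFrame  # per fraction x region: count + pct of union
    both_controls_panel: set[str]
    all_comparisons_panel: set[str]


def _venn_regions(a: set, b: set, c: set) -> dict[str, set]:
    return {
        "A_only": a - b - c,
        "B_only": b - a - c,
        "C_only": c - a - b,
        "AB_only": (a & b) - c,
        "AC_only": (a & c) - b,
        "BC_only": (b & c) - a,
        "ABC": a & b & c,
    }


def intersect_comparisons(tables: Mapping[tuple[str, str], DifferentialTable]
                          ) -> PanelResult:
    """Derive the recurrence panels from per-fraction comparison tables.

    Emits (a) the three-set Venn partition per fraction (A = PA-vs-CH,
    B = PA-vs-MB, C = PA-vs-nonPA) with counts and percentages of the
    union, (b) the panel significant in both PA-vs-CH and PA-vs-MB
    within at least one common fraction, (c) the panel significant in
    every supplied comparison table.
    """
    fracs = sorted({f for (_, f) in tables if f != "pooled"},
                   key=lambda f: FRACTIONS.index(f) if f in FRACTIONS else 99)
    first = next(iter(tables.values())).table.index
    for t in tables.values():
        if not t.table.index.equals(first):
            raise ValidationError("mismatched protein universes across "
                                  "comparison tables")
    rows = []
    both_panel: set[str] = set()
    for frac in fracs:
        sets = {}
        for comp in COMPARISONS:
            if (comp, frac) not in tables:
                raise ValidationError(
                    f"missing table for {comp} in fraction {frac}")
            sets[comp] = tables[(comp, frac)].significant_proteins
        a, b, c = (sets[comp] for comp in COMPARISONS)
        union = a | b | c
        regions = _venn_regions(a, b, c)
        for region, members in regions.items():
            rows.append({
                "fraction": frac, "region": region,
                "count": len(members),
                "pct_of_union": percent_of(len(members), len(union))
                if union else 0.0,
                "proteins": ";".join(sorted(members)),
            })
        both_panel |= a & b
    all_sig_sets = [t.significant_proteins for t in tables.values()]
    all_panel = set.intersection(*all_sig_sets) if all_sig_sets else set()
    venn = pd.DataFrame(rows)
    return PanelResult(venn=venn, both_controls_panel=both_panel,
                       all_comparisons_panel=all_panel)
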