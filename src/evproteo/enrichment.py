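"""Rank-based 2D annotation enrichment and kinase-substrate enrichment.

The 2D statistic scores each annotation term in two conditions at once:
per dimension, proteins are ranked ascending by a per-protein statistic
(e.g. mean abundance in PA and in non-PA) and the term score
s = 2*(mean rank inside - mean rank outside)/n lies in [-1, 1], hitting
the bounds exactly when the term occupies the extreme ranks.  Terms off
the x = y diagonal beyond a permutation-calibrated band are enriched in
one of the two conditions.  Kinase enrichment is one-sided Fisher exact
over-representation of each kinase's substrate set within a query set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnnotationCollection, ValidationError
from .differential import bh_adjust


@dataclass
class Enrichment2DResult:
    """Per-term 2D rank enrichment table.

    Columns: n_members, s_x, s_y, p_x, p_y, q_x, q_y,
    off_diagonal_distance (= |s_x - s_y| / sqrt(2)).
    """

    table: pd.DataFrame
    universe_size: int
    membership: dict[str, list[int]]  # term -> universe row positions


def _term_score(ranks: np.ndarray, in_term: np.ndarray) -> float:
    n = ranks.size
    mean_in = ranks[in_term].mean()
    mean_out = ranks[~in_term].mean()
    return float(2.0 * (mean_in - mean_out) / n)


def rank_score_2d(stats_x: pd.Series, stats_y: pd.Series,
                  annotations: AnnotationCollection,
                  min_size: int = 5) -> Enrichment2DResult:
    """Score every annotation term in two rank dimensions.

    ``stats_x`` and ``stats_y`` are per-protein numeric vectors on a
    common protein universe (identical indices required).  Per
    dimension: rank ascending (average ranks on ties), score
    s = 2*(mean rank in term - mean rank out of term)/n in [-1, 1], and
    a two-sided Mann-Whitney p comparing in-term vs out-of-term values;
    BH across terms per dimension.  Terms smaller than ``min_size``
    after intersection with the universe are dropped; terms disjoint
    from the universe are skipped with a warning.
    """
    if not stats_x.index.equals(stats_y.index):
        raise ValidationError("stats_x and stats_y must share one universe")
    universe = list(stats_x.index)
    pos = {p: i for i, p in enumerate(universe)}
    n = len(universe)
    xv = stats_x.to_numpy(dtype=float)
    yv = stats_y.to_numpy(dtype=float)
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)

    rows = []
    membership: dict[str, list[int]] = {}
    for gs in annotations:
        idx = [pos[m] for m in gs.members if m in pos]
        if not idx:
            warnings.warn(f"term {gs.term_id!r} disjoint from universe; "
                          "skipped", stacklevel=2)
            continue
        if len(idx) < min_size or len(idx) == n:
            continue
        in_term = np.zeros(n, dtype=bool)
        in_term[idx] = True
        s_x = _term_score(rx, in_term)
        s_y = _term_score(ry, in_term)
        p_x = stats.mannwhitneyu(xv[in_term], xv[~in_term],
                                 alternative="two-sided").pvalue
        p_y = stats.mannwhitneyu(yv[in_term], yv[~in_term],
                                 alternative="two-sided").pvalue
        membership[gs.term_id] = idx
        rows.append({"term_id": gs.term_id, "description": gs.description,
                     "n_members": len(idx), "s_x": s_x, "s_y": s_y,
                     "p_x": float(p_x), "p_y": float(p_y)})
    table = pd.DataFrame(rows)
    if len(table):
        table = table.set_index("term_id")
        table["q_x"] = bh_adjust(table["p_x"].to_numpy())
        table["q_y"] = bh_adjust(table["p_y"].to_numpy())
        table["off_diagonal_distance"] = (
            np.abs(table["s_x"] - table["s_y"]) / np.sqrt(2.0))
    return Enrichment2DResult(table=table, universe_size=n,
                              membership=membership)


def classify_diagonal(result: Enrichment2DResult,
                      stats_x: pd.Series, stats_y: pd.Series,
                      ci_level: float = 0.95, n_permutations: int = 1000,
                      seed: int = 0) -> pd.Series:
    """Assign each term a side of the x = y diagonal.

    The null band half-width is the ``ci_level`` quantile of |s_x - s_y|
    under within-term membership permutation (each permutation redraws
    every term's members uniformly from the universe, preserving term
    sizes).  Terms whose observed |s_x - s_y| exceeds the band are
    "x-enriched" (s_x > s_y) or "y-enriched"; the rest are
    "on-diagonal".
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives an unstable band",
                      stacklevel=2)
    table = result.table
    if not len(table):
        return pd.Series(dtype=object)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(stats_x.to_numpy(dtype=float))
    ry = stats.rankdata(stats_y.to_numpy(dtype=float))
    n = result.universe_size
    null_d = []
    sizes = [len(result.membership[t]) for t in table.index]
    for _ in range(n_permutations):
        for m in sizes:
            idx = rng.choice(n, size=m, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            null_d.append(abs(_term_score(rx, mask) - _term_score(ry, mask)))
    band = float(np.quantile(null_d, ci_level))
    diff = table["s_x"] - table["s_y"]
    side = np.where(np.abs(diff) <= band, "on-diagonal",
                    np.where(diff > 0, "x-enriched", "y-enriched"))
    return pd.Series(side, index=table.index, name="side")


@dataclass
class KinaseEnrichmentResult:
    """Per-kinase over-representation of its substrate set in the query."""

    table: pd.DataFrame  # columns: n_substrates, overlap, odds_ratio, p, q


def kinase_enrichment(query_set: set[str],
                      kinase_sets: AnnotationCollection,
                      universe: set[str]) -> KinaseEnrichmentResult:
    """One-sided Fisher exact enrichment of each kinase's substrates.

    The 2x2 table is [overlap, query \\ set; set \\ query, rest] over the
    supplied universe.  Substrate sets are intersected with the universe
    first; the query must be a subset of the universe.  Results are BH
    adjusted and sorted by q then descending odds ratio.
    """
    if not universe:
        raise ValidationError("empty universe")
    query = set(query_set) & set(universe)
    if query != set(query_set):
        raise ValidationError("query set must be contained in the universe")
    rows = []
    n_u = len(universe)
    for gs in kinase_sets:
        members = gs.members & universe
        if not members:
            continue
        overlap = len(query & members)
        a = overlap
        b = len(query) - overlap
        c = len(members) - overlap
        d = n_u - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]],
                                     alternative="greater")
        rows.append({"kinase": gs.term_id, "n_substrates": len(members),
                     "overlap": overlap,
                     "odds_ratio": float(odds) if np.isfinite(odds)
                     else np.inf,
                     "p": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        table = table.set_index("kinase")
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["q", "odds_ratio"],
                                  ascending=[True, False])
    return KinaseEnrichmentResult(table=table)
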