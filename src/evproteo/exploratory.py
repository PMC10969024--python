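"""Unsupervised structure assessment.

Spearman correlation screen for outlying samples, classical
(Torgerson) multidimensional scaling with k-means on the embedding, and
agglomerative hierarchical clustering for heatmap dendrograms.  In the
intended use the MDS of all samples separates the three CSF fractions
(Tot/SEV/LEV) while the clinical groups remain mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from .datatypes import IntensityMatrix, SampleSheet, ValidationError


@dataclass
class Embedding:
    """Low-dimensional sample coordinates with eigenvalue diagnostics."""

    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray


@dataclass
class OutlierScreen:
    correlations: pd.DataFrame  # sample x sample Spearman rho
    median_correlation: pd.Series
    flagged: list[str]


def spearman_correlation_matrix(matrix: IntensityMatrix) -> pd.DataFrame:
    if not matrix.is_complete():
        raise ValidationError("correlation screen requires a complete matrix")
    vals = matrix.values
    if vals.shape[1] < 3:
        raise ValidationError("need >= 3 samples")
    rho = spearmanr(vals, axis=0).statistic
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=matrix.sample_ids,
                        columns=matrix.sample_ids)


def spearman_outlier_screen(matrix: IntensityMatrix,
                            sheet: SampleSheet | None = None,
                            k: float = 1.5) -> OutlierScreen:
    """Flag dissimilar samples by their median Spearman correlation.

    For each sample, the median correlation to its peers (same
    group x fraction cell when a sheet is given, otherwise all other
    samples) is computed; a sample is flagged when that median falls
    below median - k*IQR across samples.
    """
    corr = spearman_correlation_matrix(matrix)
    meds = {}
    for s in corr.index:
        if sheet is not None:
            g = sheet.group_of(s)
            f = sheet.fraction_of(s)
            peers = [p for p in sheet.samples_in(group=g, fraction=f)
                     if p != s and p in corr.columns]
        else:
            peers = [p for p in corr.columns if p != s]
        if not peers:
            raise ValidationError(f"sample {s!r} has no peers to compare to")
        meds[s] = float(corr.loc[s, peers].median())
    med_series = pd.Series(meds)
    q1, q3 = med_series.quantile([0.25, 0.75])
    cut = med_series.median() - k * (q3 - q1)
    flagged = list(med_series.index[med_series < cut])
    return OutlierScreen(correlations=corr, median_correlation=med_series,
                         flagged=flagged)


def spearman_distance_matrix(matrix: IntensityMatrix) -> pd.DataFrame:
    """1 - Spearman rho, the default MDS distance."""
    return 1.0 - spearman_correlation_matrix(matrix)


def classical_mds(distances: pd.DataFrame | np.ndarray,
                  k: int = 2) -> Embedding:
    """Torgerson classical scaling.

    Double-centres the squared distance matrix and embeds on the top-k
    eigenvectors scaled by sqrt(eigenvalue); deterministic up to sign
    (each axis is oriented so its largest-magnitude coordinate is
    positive).  Negative eigenvalues (non-Euclidean input) contribute
    zero coordinates.
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = [str(i) for i in range(d.shape[0])]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be square symmetric")
    if np.any(d < -1e-12) or np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValidationError("distances must be non-negative with zero "
                              "diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    idx = np.argsort(evals)[::-1][:k]
    lam = evals[idx]
    vec = evecs[:, idx]
    coords = vec * np.sqrt(np.clip(lam, 0.0, None))
    for a in range(coords.shape[1]):  # sign canonicalization
        col = coords[:, a]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    cols = [f"dim{a + 1}" for a in range(k)]
    return Embedding(
        coordinates=pd.DataFrame(coords, index=labels, columns=cols),
        eigenvalues=evals[np.argsort(evals)[::-1]])


def kmeans_cluster(points: pd.DataFrame | np.ndarray, k: int, seed: int = 0,
                   n_restarts: int = 10
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's k-means with k-means++ seeding, best of ``n_restarts``.

    Labels are canonicalized by lexicographic centroid order so equal
    partitions always receive equal labelings.
    """
    pts = points.to_numpy(dtype=float) if isinstance(points, pd.DataFrame) \
        else np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if k > pts.shape[0]:
        raise ValidationError(f"k={k} exceeds n={pts.shape[0]} points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    labels = km.fit_predict(pts)
    centroids = km.cluster_centers_
    order = np.lexsort(centroids.T[::-1])  # sort by dim1, then dim2, ...
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[labels], centroids[order]


def hierarchical_cluster(matrix: IntensityMatrix, axis: str = "rows",
                         linkage: str = "average",
                         metric: str = "correlation"
                         ) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of proteins (rows) or samples (columns).

    Returns the scipy linkage matrix and the dendrogram leaf order as
    identifiers.  Defaults: average linkage with correlation distance
    for rows; for columns Euclidean is conventional (pass
    ``metric="euclidean"``).
    """
    if axis not in ("rows", "columns"):
        raise ValidationError("axis must be 'rows' or 'columns'")
    if not matrix.is_complete():
        raise ValidationError("hierarchical clustering requires a complete "
                              "matrix")
    data = matrix.values if axis == "rows" else matrix.values.T
    ids = matrix.protein_ids if axis == "rows" else matrix.sample_ids
    try:
        dists = pdist(data, metric=metric)
        z = hierarchy.linkage(dists, method=linkage)
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc
    leaves = hierarchy.leaves_list(z)
    return z, [ids[i] for i in leaves]
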