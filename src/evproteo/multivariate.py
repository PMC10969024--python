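"""PLS-DA with VIP-based biomarker ranking.

Partial least squares discriminant analysis projects the protein matrix
onto latent components that maximize covariance with the class labels
(by default PA vs non-PA, one-hot encoded).  The per-protein variable
importance in projection (VIP) score summarizes each protein's
contribution across components; mean(VIP^2) = 1, so VIP > 1 marks
above-average discriminators.  k-means on the score plane quantifies
how well the latent space recovers the PA/non-PA partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import IntensityMatrix, SampleSheet, ValidationError
from .exploratory import kmeans_cluster


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge for some component."""


@dataclass
class PlsdaModel:
    """Fitted PLS2 model (NIPALS).

    Arrays are stacked per component a = 1..A: ``weights`` (P x A, each
    column unit norm), ``loadings`` (P x A), ``scores`` (N x A),
    ``y_loadings`` (K x A), ``inner_coefs`` (A,) the inner-relation
    slopes b_a, and ``ssy`` (A,) = b_a^2 * t_a't_a, the y-variance
    captured per component.
    """

    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    inner_coefs: np.ndarray
    ssy: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    class_labels: list[str]
    y_classes: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"comp{a + 1}" for a in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)

    def explained_y_variance_ratio(self) -> np.ndarray:
        return self.ssy / self._total_ssy

    @property
    def _total_ssy(self) -> float:
        return float(self.__dict__.get("_ssy_total", np.sum(self.ssy)))


def one_hot(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        y[i, classes.index(lab)] = 1.0
    return y, classes


def fit_plsda(matrix: IntensityMatrix, labels: list[str],
              n_components: int = 2, max_iter: int = 500,
              tol: float = 1e-9, scale: bool = True) -> PlsdaModel:
    """Fit a PLS2 discriminant model by NIPALS.

    ``labels`` give one class per sample (matrix column); they are
    one-hot encoded and centered.  X columns (proteins) are
    mean-centered and, with ``scale=True`` (default, standard for VIP
    interpretation), scaled to unit variance.  Per component: iterate
    w ∝ X'u, t = Xw, q ∝ Y't, u = Yq to convergence, then deflate X by
    t p' and Y by the t-regression.  Deterministic given the data.
    """
    if not matrix.is_complete():
        raise ValidationError("PLS-DA requires a complete matrix")
    if len(labels) != len(matrix.sample_ids):
        raise ValidationError("one label per sample required")
    if len(set(labels)) < 2:
        raise ValidationError("need >= 2 classes")

    x = matrix.values.T.astype(float)  # samples x proteins
    y_raw, classes = one_hot(list(labels))

    x_mean = x.mean(axis=0)
    x_scale = x.std(axis=0, ddof=1) if scale else np.ones(x.shape[1])
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    xc = (x - x_mean) / x_scale
    yc = y_raw - y_raw.mean(axis=0)
    total_ssy = float(np.sum(yc ** 2))

    n, p = xc.shape
    k = yc.shape[1]
    a_max = min(n_components, n - 1, p)

    w_all = np.zeros((p, a_max))
    p_all = np.zeros((p, a_max))
    t_all = np.zeros((n, a_max))
    q_all = np.zeros((k, a_max))
    b_all = np.zeros(a_max)
    ssy_all = np.zeros(a_max)

    xd, yd = xc.copy(), yc.copy()
    for a in range(a_max):
        u = yd[:, int(np.argmax(yd.var(axis=0)))].copy()
        if np.allclose(u, 0):
            u = yd[:, 0].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = xd.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                raise ConvergenceError(
                    f"component {a + 1}: zero weight vector (X exhausted)")
            w /= norm_w
            t = xd @ w
            q = yd.T @ t
            norm_q = np.linalg.norm(q)
            if norm_q == 0:
                break  # no y-structure left; t is still defined
            q /= norm_q
            u = yd @ q
            if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), 1e-30):
                break
            t_old = t
        else:
            raise ConvergenceError(
                f"component {a + 1} did not converge in {max_iter} "
                "iterations")
        tt = float(t @ t)
        if tt == 0:
            raise ConvergenceError(f"component {a + 1}: zero score variance")
        p_vec = xd.T @ t / tt
        b = float(u @ t) / tt
        c_vec = yd.T @ t / tt  # y regression on t, used for deflation
        xd = xd - np.outer(t, p_vec)
        yd = yd - np.outer(t, c_vec)
        w_all[:, a] = w
        p_all[:, a] = p_vec
        t_all[:, a] = t
        q_all[:, a] = q
        b_all[a] = b
        ssy_all[a] = b * b * tt

    model = PlsdaModel(
        weights=w_all, loadings=p_all, scores=t_all, y_loadings=q_all,
        inner_coefs=b_all, ssy=ssy_all,
        protein_ids=matrix.protein_ids, sample_ids=matrix.sample_ids,
        class_labels=list(labels), y_classes=classes,
        x_mean=x_mean, x_scale=x_scale)
    model.__dict__["_ssy_total"] = total_ssy
    return model


def vip_scores(model: PlsdaModel) -> pd.Series:
    """Variable importance in projection per protein.

    VIP_j = sqrt( P * sum_a SSY_a w_aj^2 / sum_a SSY_a ) with unit-norm
    weight vectors, so mean(VIP^2) = 1 exactly.
    """
    total = float(np.sum(model.ssy))
    if total <= 0:
        raise ValidationError("zero explained y-variance; VIP undefined")
    p = model.weights.shape[0]
    contrib = (model.weights ** 2) @ model.ssy
    vip = np.sqrt(p * contrib / total)
    return pd.Series(vip, index=model.protein_ids,
                     name="VIP").sort_values(ascending=False)


def rand_index(labels_a, labels_b) -> float:
    """Unadjusted Rand index between two partitions."""
    from sklearn.metrics import rand_score
    return float(rand_score(list(labels_a), list(labels_b)))


def cluster_scores(model: PlsdaModel, k: int = 2, seed: int = 0
                   ) -> tuple[np.ndarray, float]:
    """k-means on the first two score dimensions; returns cluster labels
    and the Rand index against the PA / non-PA partition.

    Score dimensions are standardized and then weighted by the square
    root of each component's explained-y-variance share before
    clustering: raw PLS score variances are incommensurate (later
    components can carry large y-irrelevant variance, e.g. the fraction
    effect), so Euclidean k-means on raw scores would cluster on spread
    rather than on the class structure the model actually captured.
    """
    a = min(2, model.n_components)
    dims = model.scores[:, :a]
    sd = dims.std(axis=0, ddof=0)
    dims = dims / np.where(sd == 0, 1.0, sd)
    total = float(np.sum(model.ssy))
    if total > 0:
        dims = dims * np.sqrt(model.ssy[:a] / total)
    labels, _ = kmeans_cluster(dims, k=k, seed=seed)
    binary = ["PA" if lab == "PA" else "nonPA" for lab in model.class_labels]
    return labels, rand_index(labels, binary)


@dataclass
class ConfidenceEllipse:
    """Gaussian confidence ellipse of a 2-D point cloud."""

    center: np.ndarray
    axis_lengths: np.ndarray  # semi-axis lengths, descending
    angle: float  # radians, orientation of the major axis
    degenerate: bool


def confidence_ellipse(points: np.ndarray, level: float = 0.95
                       ) -> ConfidenceEllipse:
    """Per-class score-plot ellipse from the 2x2 sample covariance with
    the chi-square(2) quantile at ``level``.  Fewer than 3 points or a
    singular covariance yields a degenerate flag."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be n x 2")
    center = pts.mean(axis=0)
    if pts.shape[0] < 3:
        return ConfidenceEllipse(center, np.zeros(2), 0.0, True)
    cov = np.cov(pts, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) <= 1e-12 * max(np.max(evals), 1e-300):
        return ConfidenceEllipse(center, np.zeros(2), 0.0, True)
    r2 = stats.chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    lengths = np.sqrt(evals[order] * r2)
    major = evecs[:, order[0]]
    angle = float(np.arctan2(major[1], major[0]))
    return ConfidenceEllipse(center, lengths, angle, False)
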