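"""Assay-validation statistics for a candidate diagnostic biomarker.

Covers the ELISA arm of a biomarker study: relative quantitation from a
serial two-fold dilution standard curve (undiluted reference pool = 1
RU/mL), Kruskal-Wallis group testing, empirical ROC analysis with
DeLong confidence intervals, the Youden-index cutoff with positive
likelihood ratio, qualitative AUC bands, and a-priori two-sample sample
size planning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError


# ---------------------------------------------------------------------------
# plates and standard curves
# ---------------------------------------------------------------------------

@dataclass
class AssayPlate:
    """One ELISA plate.

    ``standards`` maps a dilution factor (1, 2, 4, ...) of the reference
    pool to replicate absorbances; ``samples`` maps sample ids to
    replicate absorbances; ``background`` holds uncoated-well
    absorbances used for subtraction and ``blanks`` the wells defining
    the lower detection limit (defaults to the background wells).
    """

    standards: dict[float, list[float]]
    samples: dict[str, list[float]]
    background: list[float]
    blanks: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.standards) < 4:
            raise ValidationError("need >= 4 standard dilution points")
        if not self.background:
            raise ValidationError("background wells required")
        all_vals = ([v for vs in self.standards.values() for v in vs]
                    + [v for vs in self.samples.values() for v in vs]
                    + list(self.background) + list(self.blanks or []))
        if not np.all(np.isfinite(all_vals)):
            raise ValidationError("absorbances must be finite")


@dataclass
class TiterResult:
    titers: pd.Series  # RU/mL per sample id
    slope: float
    intercept: float
    lod_absorbance: float  # mean blank + 3 SD, after background subtraction
    below_lod: list[str]
    extrapolated: list[str]


def standard_curve_titer(plate: AssayPlate) -> TiterResult:
    """Relative titers (RU/mL) from a serial two-fold dilution curve.

    The mean background absorbance is subtracted from every well; the
    standards are fit by least squares as absorbance vs log2(dilution
    factor) (a direct ELISA in its linear range); each sample's mean
    absorbance is inverted through the fit, and titer = 1/dilution, so
    the undiluted reference pool reads exactly 1 RU/mL.  Samples whose
    absorbance cannot be distinguished from blank (mean blank + 3 SD)
    are flagged, as are samples outside the standard absorbance range.
    """
    bg = float(np.mean(plate.background))
    std_x, std_y = [], []
    for d, vals in sorted(plate.standards.items()):
        if d <= 0:
            raise ValidationError("dilution factors must be > 0")
        std_x.append(math.log2(d))
        std_y.append(float(np.mean(vals)) - bg)
    if len(std_x) < 2:
        raise ValidationError("fewer than 2 usable standards")
    slope, intercept = np.polyfit(std_x, std_y, 1)
    if slope == 0:
        raise ValidationError("flat standard curve; cannot invert")

    blanks = np.asarray(plate.blanks if plate.blanks is not None
                        else plate.background, dtype=float) - bg
    lod = float(blanks.mean() + 3.0 * blanks.std(ddof=1)) \
        if blanks.size > 1 else float(blanks.mean())

    lo, hi = min(std_y), max(std_y)
    titers, below, extrap = {}, [], []
    for sid, vals in plate.samples.items():
        a = float(np.mean(vals)) - bg
        if a < lod:
            below.append(sid)
        if not (lo <= a <= hi):
            extrap.append(sid)
        log2_d = (a - intercept) / slope
        titers[sid] = float(2.0 ** (-log2_d))
    return TiterResult(titers=pd.Series(titers, name="titer_RU_per_mL"),
                       slope=float(slope), intercept=float(intercept),
                       lod_absorbance=lod, below_lod=below,
                       extrapolated=extrap)


# ---------------------------------------------------------------------------
# group testing
# ---------------------------------------------------------------------------

def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square p (g-1 df).

    ``groups`` assigns each value a group label; each group needs >= 2
    values.  Identical values across the board give H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [values[groups == g] for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("each group needs >= 2 values")
    if np.all(values == values[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Empirical ROC with DeLong inference and Youden diagnostics."""

    auc: float
    ci: tuple[float, float]
    p_value: float  # vs AUC = 0.5
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    flipped: bool  # scores negated so higher score => case
    cutoff: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    youden_j: float = float("nan")
    lr_positive: float = float("nan")
    band: str = ""


def _auc_mann_whitney(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC as the tie-corrected probability that a case outscores a
    control (equals trapezoidal area under the empirical ROC)."""
    n1, n0 = len(cases), len(controls)
    gt = (cases[:, None] > controls[None, :]).sum()
    eq = (cases[:, None] == controls[None, :]).sum()
    return float((gt + 0.5 * eq) / (n1 * n0))


def _delong_variance(cases: np.ndarray, controls: np.ndarray
                     ) -> tuple[float, float]:
    """DeLong (1988) AUC and its variance via placement values."""
    m, n = len(cases), len(controls)
    v10 = np.array([( (c > controls).sum() + 0.5 * (c == controls).sum() ) / n
                    for c in cases])
    v01 = np.array([( (cases > c).sum() + 0.5 * (cases == c).sum() ) / m
                    for c in controls])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_curve(scores, labels, ci_level: float = 0.95,
              ci_method: str = "delong", n_bootstrap: int = 2000,
              seed: int = 0) -> RocResult:
    """Empirical ROC over all observed thresholds.

    ``labels`` are truthy for cases.  AUC is computed by the
    Mann-Whitney construction (half credit for ties, identical to the
    trapezoid over the empirical curve).  The CI and the p-value
    against AUC = 0.5 use DeLong's asymptotic variance by default;
    ``ci_method="bootstrap"`` gives a stratified percentile bootstrap
    CI instead (the p-value stays DeLong).  If AUC < 0.5 the score
    orientation is flipped and recorded, so reported AUC >= 0.5 and
    "higher score implies case".
    """
    if ci_method not in ("delong", "bootstrap"):
        raise ValidationError("ci_method must be 'delong' or 'bootstrap'")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([bool(v) for v in labels])
    cases, controls = scores[y], scores[~y]
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("both classes must be present")
    auc0 = _auc_mann_whitney(cases, controls)
    flipped = auc0 < 0.5
    if flipped:
        scores = -scores
        cases, controls = -cases, -controls
    auc, var = _delong_variance(cases, controls)
    se = math.sqrt(var)
    if ci_method == "delong":
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    else:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            bc = rng.choice(cases, size=len(cases), replace=True)
            bk = rng.choice(controls, size=len(controls), replace=True)
            boots[i] = _auc_mann_whitney(bc, bk)
        lo, hi = np.quantile(boots, [(1 - ci_level) / 2,
                                     0.5 + ci_level / 2])
        ci = (float(lo), float(hi))
    p = 1.0 if se == 0 and auc == 0.5 else (
        0.0 if se == 0 else
        float(2.0 * stats.norm.sf(abs(auc - 0.5) / se)))

    # empirical curve: thresholds at observed scores, rule "positive if
    # score > threshold" (matches the ">cutoff" reporting convention)
    thr = np.unique(scores)
    thresholds = np.concatenate(([-np.inf], thr))
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])
    return RocResult(auc=auc, ci=ci, p_value=p, thresholds=thresholds,
                     sensitivities=sens, specificities=spec,
                     flipped=flipped)


def youden_cutoff(roc: RocResult) -> RocResult:
    """Select the cutoff maximizing Youden's J = sens + spec - 1.

    Ties are broken toward higher sensitivity.  LR+ = sens/(1 - spec),
    reported rounded to one decimal; infinite when specificity = 1.
    The positive call is "score > cutoff".
    """
    j = roc.sensitivities + roc.specificities - 1.0
    best = np.lexsort((-roc.sensitivities, -j))[0]
    sens = float(roc.sensitivities[best])
    spec = float(roc.specificities[best])
    roc.cutoff = float(roc.thresholds[best])
    roc.sensitivity = sens
    roc.specificity = spec
    roc.youden_j = float(j[best])
    roc.lr_positive = likelihood_ratio_positive(sens, spec)
    roc.band = auc_band(roc.auc)
    return roc


def likelihood_ratio_positive(sensitivity: float, specificity: float
                              ) -> float:
    """LR+ = sensitivity / (1 - specificity), one-decimal convention;
    infinite at perfect specificity."""
    if specificity >= 1.0:
        return float("inf")
    return round(sensitivity / (1.0 - specificity), 1)


def auc_band(auc: float) -> str:
    """Qualitative diagnostic band of an (orientation-corrected) AUC:
    exactly 0.5 not discriminant, then half-open bins [0.5,0.6) fail,
    [0.6,0.7) poor, [0.7,0.8) fair, [0.8,0.9) good, [0.9,1] excellent."""
    if not (0.0 <= auc <= 1.0):
        raise ValidationError("AUC must lie in [0, 1]")
    if auc < 0.5:
        auc = 1.0 - auc  # band after orientation flip
    if auc == 0.5:
        return "not discriminant"
    if auc < 0.6:
        return "fail"
    if auc < 0.7:
        return "poor"
    if auc < 0.8:
        return "fair"
    if auc < 0.9:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# design-time sample size
# ---------------------------------------------------------------------------

def two_sample_t_power(n_per_group: int, effect_size_sd_units: float,
                       alpha: float = 0.05) -> float:
    """Exact two-sided power of the two-sample t-test (equal n, equal
    variance) from the noncentral t distribution."""
    df = 2 * n_per_group - 2
    ncp = effect_size_sd_units * math.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, ncp)
                 + stats.nct.cdf(-tcrit, df, ncp))


def sample_size(effect_size_sd_units: float, alpha: float = 0.05,
                power: float = 0.80, n_tests: int = 1) -> int:
    """Per-group n for a two-sample comparison at a standardized effect.

    Starts from the normal approximation
    n0 = ceil( 2 * (z_{1-a'/2} + z_{power})^2 / delta^2 ), with a
    Bonferroni-adjusted a' = alpha/n_tests as the conservative
    multiplicity proxy, then increments n until the exact noncentral-t
    power reaches the target (the normal formula slightly undershoots
    t-test power at small n); floored at 2 per group so a variance is
    always estimable.
    """
    if effect_size_sd_units <= 0:
        raise ValidationError("effect size must be > 0")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValidationError("power must exceed alpha")
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    a = alpha / n_tests
    z_a = stats.norm.ppf(1.0 - a / 2.0)
    z_b = stats.norm.ppf(power)
    n0 = 2.0 * (z_a + z_b) ** 2 / effect_size_sd_units ** 2
    n = max(2, math.ceil(n0))
    while two_sample_t_power(n, effect_size_sd_units, a) < power:
        n += 1
    return n


def empirical_power(n_per_group: int, effect_size_sd_units: float,
                    alpha: float = 0.05, n_replicates: int = 2000,
                    seed: int = 0) -> float:
    """Monte-Carlo power of the Welch test at the design effect size:
    fraction of ``n_replicates`` simulated Normal(0,1) vs
    Normal(delta,1) comparisons rejected at ``alpha``."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_replicates, n_per_group))
    b = rng.normal(effect_size_sd_units, 1.0, size=(n_replicates,
                                                    n_per_group))
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return float(np.mean(res.pvalue <= alpha))
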