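"""Synthetic label-free proteomics datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: log-normal LFQ intensities (Normal on the log2 scale), a strong
fraction effect separating Tot/SEV/LEV samples, group effects confined
to a small registry of spiked marker proteins (one up-regulated and one
down-regulated in PA by default, mirroring the CPXM2/AQP4 roles), and
intensity-dependent (missing-not-at-random) dropout following a logistic
curve in log2 intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (FRACTIONS, GROUPS, IntensityMatrix, SampleSheet,
                        ValidationError)


@dataclass(frozen=True)
class SpikedMarker:
    """A protein carrying a true group effect.

    ``effect`` is the signed log2 shift applied to samples of ``group``.
    """
    protein_id: str
    group: str
    effect: float


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults reproduce the factorial design of the discovery cohort the
    pipeline targets: 3 clinical groups x 3 CSF fractions with 8 samples
    per cell, ~1000 proteins with log2 baselines Normal(25, 2) — typical
    MaxQuant LFQ magnitudes — a fraction effect drawn per fraction for a
    random 30% of background proteins, two spiked markers at +/-2 log2
    units in PA, technical noise SD 0.5, and logistic MNAR dropout well
    below the bulk of the intensity distribution, so missingness
    concentrates in genuinely low-abundance proteins.

    Spiked markers emulate validated biomarkers, which are by selection
    abundant, reliably quantified proteins: their baseline is pinned at
    ``marker_baseline`` (one SD above the bulk mean by default; set None
    to draw it like any other protein) and they are excluded from the
    fraction-offset subset, which models background biology only.
    """

    n_proteins: int = 1000
    samples_per_cell: int = 8
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    fraction_effect_sd: float = 2.0
    fraction_affected_prop: float = 0.30
    markers: Sequence[SpikedMarker] = field(default_factory=lambda: (
        SpikedMarker("CPXM2_like", "PA", +3.0),
        SpikedMarker("AQP4_like", "PA", -3.0),
    ))
    marker_baseline: float | None = 27.0
    noise_sd: float = 0.5
    mnar_midpoint: float = 20.0
    mnar_steepness: float = 1.5
    apply_missingness: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0 or self.noise_sd < 0:
            raise ValidationError("SDs must be positive")
        if self.mnar_steepness <= 0:
            raise ValidationError("mnar_steepness must be > 0")
        if len(self.markers) > self.n_proteins:
            raise ValidationError("more spiked markers than proteins")
        ids = [m.protein_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate spiked marker ids")
        for m in self.markers:
            if m.group not in GROUPS:
                raise ValidationError(f"unknown marker group {m.group!r}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    true_means: dict[tuple[str, str], pd.Series]  # (group, fraction) -> per-protein mean
    markers: tuple[SpikedMarker, ...]
    missing_mask: pd.DataFrame  # True where the emitted value was dropped

    def marker_ids(self) -> list[str]:
        return [m.protein_id for m in self.markers]


def apply_mnar(matrix: IntensityMatrix, midpoint: float, steepness: float,
               seed: int) -> IntensityMatrix:
    """Apply intensity-dependent dropout to a complete log2 matrix.

    Each entry is set missing with probability
    ``1 / (1 + exp(steepness * (x - midpoint)))`` — a logistic curve that
    approaches 1 for low-abundance values and 0 for high-abundance ones.
    """
    if not matrix.is_log2:
        raise ValidationError("apply_mnar requires a log2-scale matrix")
    if steepness <= 0:
        raise ValidationError("steepness must be > 0")
    rng = np.random.default_rng(seed)
    x = matrix.values
    p_drop = mnar_dropout_probability(x, midpoint, steepness)
    drop = rng.random(x.shape) < p_drop
    out = matrix.data.where(~drop)
    return IntensityMatrix(out, is_log2=True)


def mnar_dropout_probability(x: np.ndarray | float, midpoint: float,
                             steepness: float) -> np.ndarray | float:
    """Logistic dropout probability, monotone decreasing in intensity."""
    # expit form avoids overflow for very low intensities
    z = steepness * (np.asarray(x, dtype=float) - midpoint)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(z))


def generate_dataset(
    spec: SimulationSpec,
) -> tuple[IntensityMatrix, SampleSheet, SyntheticTruth]:
    """Draw one synthetic dataset.

    Per-protein baselines are drawn once; each sample value is
    baseline + fraction offset + group effect (markers only) +
    Normal(0, noise SD).  MNAR dropout is then applied (unless disabled)
    with a seed derived from the spec seed, so the same spec always
    yields the same matrix.
    """
    rng = np.random.default_rng(spec.seed)

    marker_ids = [m.protein_id for m in spec.markers]
    n_background = spec.n_proteins - len(marker_ids)
    protein_ids = marker_ids + [f"P{i:05d}" for i in range(n_background)]

    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd,
                           size=spec.n_proteins)
    if spec.marker_baseline is not None:
        baselines[:len(marker_ids)] = spec.marker_baseline

    # Fraction effect: a distinct random offset vector per fraction on a
    # random 30% of background proteins — separates Tot/SEV/LEV in MDS.
    n_affected = min(int(round(spec.fraction_affected_prop
                               * spec.n_proteins)), n_background)
    affected = len(marker_ids) + rng.choice(n_background, size=n_affected,
                                            replace=False)
    fraction_offset = {f: np.zeros(spec.n_proteins) for f in FRACTIONS}
    for f in FRACTIONS:
        fraction_offset[f][affected] = rng.normal(
            0.0, spec.fraction_effect_sd, size=n_affected)

    group_effect = {g: np.zeros(spec.n_proteins) for g in GROUPS}
    for m in spec.markers:
        group_effect[m.group][protein_ids.index(m.protein_id)] = m.effect

    sample_ids: list[str] = []
    sheet_rows: list[dict] = []
    cols: list[np.ndarray] = []
    true_means: dict[tuple[str, str], pd.Series] = {}
    for g in GROUPS:
        for f in FRACTIONS:
            cell_mean = baselines + fraction_offset[f] + group_effect[g]
            true_means[(g, f)] = pd.Series(cell_mean, index=protein_ids)
            for r in range(spec.samples_per_cell):
                sid = f"{g}-{f}-{r + 1}"
                sample_ids.append(sid)
                sheet_rows.append({"sample_id": sid, "group": g,
                                   "fraction": f})
                noise = rng.normal(0.0, spec.noise_sd, size=spec.n_proteins) \
                    if spec.noise_sd > 0 else 0.0
                cols.append(cell_mean + noise)

    data = pd.DataFrame(np.column_stack(cols), index=protein_ids,
                        columns=sample_ids)
    full = IntensityMatrix(data, is_log2=True)

    if spec.apply_missingness:
        mnar_seed = int(np.random.default_rng(spec.seed + 1).integers(2**31))
        matrix = apply_mnar(full, spec.mnar_midpoint, spec.mnar_steepness,
                            seed=mnar_seed)
    else:
        matrix = full

    mask = matrix.data.isna()
    sheet = SampleSheet(
        pd.DataFrame(sheet_rows).set_index("sample_id")[["group", "fraction"]])
    truth = SyntheticTruth(true_means=true_means,
                           markers=tuple(spec.markers),
                           missing_mask=mask)
    return matrix, sheet, truth
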