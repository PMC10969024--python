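"""Core domain containers for the label-free CSF/EV proteomics pipeline.

The pipeline operates on a protein x sample intensity grid (log2 scale,
NaN marks "not quantified"), a sample sheet assigning each sample to a
clinical group (CH, PA, MB) and a CSF fraction (Tot, SEV, LEV), and named
gene-set collections (GO terms, kinase substrate sets) for enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GROUPS = ("CH", "PA", "MB")
FRACTIONS = ("Tot", "SEV", "LEV")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass
class IntensityMatrix:
    """Protein x sample intensity grid.

    ``data`` is a DataFrame whose index holds unique protein identifiers
    (gene symbols) and whose columns hold unique sample ids.  Missing
    entries are NaN — never 0: an LFQ zero means "not quantified".
    ``is_log2`` records whether values are already log2-transformed.
    """

    data: pd.DataFrame
    is_log2: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate protein ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy(dtype=float)
        finite_or_nan = np.isnan(vals) | np.isfinite(vals)
        if not finite_or_nan.all():
            raise ValidationError("non-finite intensity values present")
        if not self.is_log2 and np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("raw (non-log2) intensities must be >= 0")

    # -- accessors ----------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def is_complete(self) -> bool:
        return self.n_missing == 0

    def to_log2(self) -> "IntensityMatrix":
        """Convert raw intensities to log2.  Zeros were already mapped to
        NaN at read time; any remaining zero would produce -inf and is
        rejected by validation."""
        if self.is_log2:
            return self
        return IntensityMatrix(np.log2(self.data), is_log2=True)

    def subset_proteins(self, keep: Iterable[str]) -> "IntensityMatrix":
        keep = [p for p in self.protein_ids if p in set(keep)]
        return IntensityMatrix(self.data.loc[keep], is_log2=self.is_log2)


@dataclass
class SampleSheet:
    """Per-sample clinical group and CSF fraction assignments.

    ``table`` has index sample_id and columns ``group`` in {CH, PA, MB}
    and ``fraction`` in {Tot, SEV, LEV}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids in sheet: {dups}")
        bad_g = set(t["group"]) - set(GROUPS)
        if bad_g:
            raise ValidationError(f"unknown groups: {sorted(bad_g)}")
        bad_f = set(t["fraction"]) - set(FRACTIONS)
        if bad_f:
            raise ValidationError(f"unknown fractions: {sorted(bad_f)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    def fraction_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "fraction"])

    def groups(self, samples: Iterable[str] | None = None) -> pd.Series:
        t = self.table if samples is None else self.table.loc[list(samples)]
        return t["group"]

    def fractions(self, samples: Iterable[str] | None = None) -> pd.Series:
        t = self.table if samples is None else self.table.loc[list(samples)]
        return t["fraction"]

    def cells(self) -> dict[tuple[str, str], list[str]]:
        """Map each occupied (group, fraction) cell to its sample ids."""
        out: dict[tuple[str, str], list[str]] = {}
        for sid, row in self.table.iterrows():
            out.setdefault((row["group"], row["fraction"]), []).append(str(sid))
        return out

    def samples_in(self, group: str | None = None,
                   fraction: str | None = None) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if group is not None:
            mask &= t["group"] == group
        if fraction is not None:
            mask &= t["fraction"] == fraction
        return list(t.index[mask])

    def validate_against(self, matrix: IntensityMatrix) -> None:
        """Every matrix sample must appear exactly once in the sheet."""
        missing = [s for s in matrix.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(
                f"sample ids absent from sample sheet: {missing}")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    members: frozenset[str]


@dataclass
class AnnotationCollection:
    """Named gene sets keyed by term id (GO terms, kinase substrates...)."""

    terms: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, gs in self.terms.items():
            if not gs.members:
                raise ValidationError(f"term {tid!r} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def add(self, term_id: str, description: str,
            members: Iterable[str]) -> None:
        if term_id in self.terms:
            raise ValidationError(f"duplicate term id {term_id!r}")
        self.terms[term_id] = GeneSet(term_id, description,
                                      frozenset(members))
        if not self.terms[term_id].members:
            raise ValidationError(f"term {term_id!r} has no members")


@dataclass
class PipelineConfig:
    """Tunable parameters of the end-to-end analysis.

    presence_threshold    minimum fraction of quantified samples in at
                          least one scope cell for a protein to survive
                          filtering (inclusive).
    presence_scope        "cell" (group x fraction) or "fraction".
    impute_width          imputation SD as a multiple of the sample SD.
    impute_downshift      imputation mean downshift in sample-SD units
                          (left-censored normal, Perseus convention).
    volcano_c, volcano_x0 hyperbolic significance curve y = |c/(x-x0)|
                          in (log2FC, -log10 q) coordinates.  The default
                          c makes the curve pass through (x0 +/- 1,
                          -log10 0.05).
    plsda_n_components    latent components of the PLS-DA model.
    enrichment_min_size   smallest annotation-term size scored.
    alpha                 BH-adjusted significance level.
    seed                  master seed for every stochastic step.
    """

    presence_threshold: float = 0.70
    presence_scope: str = "cell"
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    volcano_c: float = float(-np.log10(0.05))
    volcano_x0: float = 0.0
    plsda_n_components: int = 2
    plsda_scale: bool = True
    enrichment_min_size: int = 5
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.presence_threshold <= 1):
            raise ValidationError("presence_threshold must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.plsda_n_components < 1:
            raise ValidationError("plsda_n_components must be >= 1")
        if self.presence_scope not in ("cell", "fraction"):
            raise ValidationError("presence_scope must be 'cell' or 'fraction'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))
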