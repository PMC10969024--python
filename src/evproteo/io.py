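"""Readers and writers for the pipeline's plain-text formats.

Wide TSV intensity tables (protein rows x sample columns), sample sheets
(sample_id, group, fraction), GMT v1 gene-set files, and YAML/JSON
configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (AnnotationCollection, IntensityMatrix, PipelineConfig,
                        SampleSheet, ValidationError)

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "0", "0.0")


class ParseError(ValueError):
    """Raised on malformed input files (carries a line number)."""


def read_intensity_table(path: str | Path,
                         missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
                         is_log2: bool = True) -> IntensityMatrix:
    """Read a wide TSV intensity table.

    First column = protein id, header row = sample ids.  Tokens in
    ``missing_tokens`` (by default including "0", the MaxQuant
    convention for "not quantified") become NaN.  Duplicate protein ids
    are rejected; column order is preserved.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: header must name >= 1 sample")
        sample_ids = header[1:]
        n_fields = len(header)
        ids: list[str] = []
        rows: list[list[float]] = []
        miss = set(missing_tokens)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_fields} fields, "
                    f"got {len(fields)}")
            ids.append(fields[0])
            row = []
            for tok in fields[1:]:
                if tok.strip() in miss:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(tok))
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: bad value {tok!r}") from exc
            rows.append(row)
    data = pd.DataFrame(rows, index=ids, columns=sample_ids, dtype=float)
    return IntensityMatrix(data, is_log2=is_log2)


def write_intensity_table(matrix: IntensityMatrix, path: str | Path,
                          missing_token: str = "NA") -> None:
    df = matrix.data.copy()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", na_rep=missing_token)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "fraction"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: sample sheet needs columns {sorted(required)}")
    return SampleSheet(df.set_index("sample_id")[["group", "fraction"]])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT v1 file: term, description, then member symbols.

    Members are deduplicated; a line with fewer than 3 fields is a parse
    error.
    """
    coll = AnnotationCollection()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, desc = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            coll.add(term, desc, members)
    return coll


def write_gmt(coll: AnnotationCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.term_id, gs.description,
                                *sorted(gs.members)]) + "\n")


def read_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    with path.open() as fh:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(fh) or {}
        elif path.suffix == ".json":
            d = json.load(fh)
        else:
            raise ParseError(f"{path}: config must be YAML or JSON")
    if not isinstance(d, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(d)


def write_run_metadata(path: str | Path, config: PipelineConfig,
                       extra: dict | None = None) -> None:
    import evproteo
    meta = {"config": config.to_dict(), "version": evproteo.__version__}
    if extra:
        meta.update(extra)
    with Path(path).open("w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
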