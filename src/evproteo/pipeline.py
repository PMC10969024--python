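"""End-to-end driver: preprocess -> exploratory -> differential ->
multivariate -> enrichment, writing TSV result tables and run metadata.

Identical config + seed yields byte-identical numeric outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import exploratory, io, multivariate, preprocess
from .datatypes import IntensityMatrix, PipelineConfig, SampleSheet
from .differential import intersect_comparisons, run_all_comparisons
from .enrichment import kinase_enrichment, rank_score_2d

log = logging.getLogger("evproteo")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, intensity_path: str | Path,
                 sheet_path: str | Path,
                 gmt_paths: Sequence[str | Path] = (),
                 out_dir: str | Path = "results",
                 is_log2: bool = True) -> dict:
    """Execute the full analysis and write the result bundle to disk.

    Returns a dict of the in-memory results keyed by stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("read")
        matrix = io.read_intensity_table(intensity_path, is_log2=is_log2)
        if not matrix.is_log2:
            matrix = matrix.to_log2()
        sheet = io.read_sample_sheet(sheet_path)
        sheet.validate_against(matrix)
    except Exception as exc:
        raise StageError("read", exc) from exc

    try:
        stage("preprocess")
        filtered, summary = preprocess.filter_by_presence(
            matrix, sheet, threshold=config.presence_threshold,
            scope=config.presence_scope)
        imputed = preprocess.impute_missing_normal(
            filtered, width=config.impute_width,
            downshift=config.impute_downshift, seed=config.seed)
        normalized = preprocess.quantile_normalize(imputed)
        io.write_intensity_table(normalized, out / "normalized.tsv")
        summary.per_cell.to_csv(out / "presence_per_cell.tsv", sep="\t")
        results["matrix"] = normalized
        results["sheet"] = sheet
    except StageError:
        raise
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    try:
        stage("exploratory")
        screen = exploratory.spearman_outlier_screen(normalized, sheet)
        dist = 1.0 - screen.correlations
        emb = exploratory.classical_mds(dist, k=2)
        labels, _ = exploratory.kmeans_cluster(
            emb.coordinates, k=3, seed=config.seed)
        screen.correlations.to_csv(out / "spearman.tsv", sep="\t")
        emb_out = emb.coordinates.copy()
        emb_out["kmeans_label"] = labels
        emb_out.to_csv(out / "mds_embedding.tsv", sep="\t")
        results["embedding"] = emb
        results["outliers"] = screen.flagged
        results["mds_kmeans"] = labels
    except StageError:
        raise
    except Exception as exc:
        raise StageError("exploratory", exc) from exc

    try:
        stage("differential")
        tables = run_all_comparisons(
            normalized, sheet, c=config.volcano_c, x0=config.volcano_x0,
            q_max=config.alpha)
        for (comp, frac), dt in tables.items():
            dt.to_frame().to_csv(out / f"differential_{comp}_{frac}.tsv",
                                 sep="\t")
        per_fraction = {k: v for k, v in tables.items() if k[1] != "pooled"}
        panels = intersect_comparisons(per_fraction)
        panels.venn.to_csv(out / "venn_partitions.tsv", sep="\t",
                           index=False)
        pd.Series(sorted(panels.both_controls_panel)).to_csv(
            out / "panel_both_controls.tsv", sep="\t", index=False,
            header=["protein_id"])
        pd.Series(sorted(panels.all_comparisons_panel)).to_csv(
            out / "panel_all_comparisons.tsv", sep="\t", index=False,
            header=["protein_id"])
        results["differential"] = tables
        results["panels"] = panels
    except StageError:
        raise
    except Exception as exc:
        raise StageError("differential", exc) from exc

    try:
        stage("multivariate")
        binary = ["PA" if sheet.group_of(s) == "PA" else "nonPA"
                  for s in normalized.sample_ids]
        model = multivariate.fit_plsda(
            normalized, binary, n_components=config.plsda_n_components,
            scale=config.plsda_scale)
        vip = multivariate.vip_scores(model)
        _, rand = multivariate.cluster_scores(model, k=2, seed=config.seed)
        model.scores_frame().to_csv(out / "plsda_scores.tsv", sep="\t")
        vip.to_csv(out / "vip.tsv", sep="\t")
        results["plsda"] = model
        results["vip"] = vip
        results["plsda_rand_index"] = rand
    except StageError:
        raise
    except Exception as exc:
        raise StageError("multivariate", exc) from exc

    if gmt_paths:
        try:
            stage("enrichment")
            pa = [s for s in normalized.sample_ids
                  if sheet.group_of(s) == "PA"]
            non_pa = [s for s in normalized.sample_ids
                      if sheet.group_of(s) != "PA"]
            stats_x = normalized.data[pa].mean(axis=1)
            stats_y = normalized.data[non_pa].mean(axis=1)
            universe = set(normalized.protein_ids)
            sig = set().union(*(t.significant_proteins
                                for t in tables.values()))
            for gmt_path in gmt_paths:
                coll = io.read_gmt(gmt_path)
                name = Path(gmt_path).stem
                res2d = rank_score_2d(stats_x, stats_y, coll,
                                      min_size=config.enrichment_min_size)
                if len(res2d.table):
                    res2d.table.to_csv(out / f"enrichment2d_{name}.tsv",
                                       sep="\t")
                if sig:
                    kea = kinase_enrichment(sig & universe, coll, universe)
                    if len(kea.table):
                        kea.table.to_csv(out / f"kea_{name}.tsv", sep="\t")
                results.setdefault("enrichment", {})[name] = res2d
        except StageError:
            raise
        except Exception as exc:
            raise StageError("enrichment", exc) from exc

    io.write_run_metadata(out / "run_metadata.json", config)
    return results
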