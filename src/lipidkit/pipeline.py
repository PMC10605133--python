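"""End-to-end orchestration: quantify -> class profile -> multivariate ->
reaction network -> building blocks -> psychosine correlation.

A single :class:`PipelineConfig` drives every stage; all randomness flows
from one seed, so reruns with the same config produce identical outputs.
Each run writes its stage tables as CSV plus a machine-readable JSON report
(parameters, seed, per-stage record counts).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .chains import chain_abundance, chain_network, chain_profiles
from .correlate import psy_class_correlation
from .errors import LipidkitError
from .io import (
    read_feature_table,
    read_metadata,
    write_concentrations,
    write_table,
)
from .multivariate import group_ellipses, heatmap_select_cluster, normalize_median, pca, scale
from .profile import class_totals, compare_groups, profile_table
from .quantify import (
    ConcentrationMatrix,
    default_is_map,
    handle_missing,
    load_is_map,
    quantify_psy,
    semiquantify,
)
from .reactions import annotate_and_export, compute_weights, default_class_catalog, score_reactions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = (
    "quantify",
    "profile",
    "multivariate",
    "network",
    "chains",
    "correlate",
)


@dataclass
class PipelineConfig:
    feature_table: str | None = None
    metadata: str | None = None
    is_map: str | None = None
    out_dir: str = "lipidkit_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    case: str = "HOM"
    control: str = "WT"
    test: str = "welch"
    scaling: str = "pareto"
    median_normalize: bool = True
    missing_strategy: str = "none"
    significance_threshold: float = 0.05
    highlight_threshold: float = 0.02
    heatmap_k: int = 50
    correlation_method: str = "pearson"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for thr in (self.significance_threshold, self.highlight_threshold):
            if not (0.0 < thr < 1.0):
                raise ValueError(f"threshold {thr} outside (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


def _stage_enabled(config: PipelineConfig, stage: str) -> bool:
    return stage in config.stages


def run_pipeline(
    config: PipelineConfig,
    matrix: ConcentrationMatrix | None = None,
    psy=None,
) -> dict:
    """Execute the configured stages and return the run report.

    Either a feature table + metadata path pair (semi-quantification is then
    the first stage) or a ready-made :class:`ConcentrationMatrix` (and
    optionally a psychosine series) must be provided.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "lipidkit_version": __version__,
        "seed": config.seed,
        "parameters": {
            "test": config.test,
            "scaling": config.scaling,
            "median_normalize": config.median_normalize,
            "significance_threshold": config.significance_threshold,
            "highlight_threshold": config.highlight_threshold,
            "heatmap_k": config.heatmap_k,
            "correlation_method": config.correlation_method,
        },
        "stages": {},
    }

    ismap = load_is_map(config.is_map) if config.is_map else default_is_map()

    if matrix is None and _stage_enabled(config, "quantify"):
        if config.feature_table is None or config.metadata is None:
            raise LipidkitError("quantify stage needs feature_table and metadata paths")
        table = read_feature_table(config.feature_table)
        meta = read_metadata(config.metadata)
        matrix = semiquantify(table, ismap, meta)
        try:
            psy = quantify_psy(table, ismap, meta)
        except LipidkitError:
            psy = None
        matrix = handle_missing(matrix, config.missing_strategy)
        write_concentrations(matrix, out / "concentrations.csv")
        if psy is not None:
            write_table(psy.to_frame(), out / "psychosine.csv", index_label="sample_id")
        report["stages"]["quantify"] = {
            "species": int(matrix.values.shape[0]),
            "samples": int(matrix.values.shape[1]),
        }

    if matrix is None:
        report["report_path"] = str(out / "run_report.json")
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report

    totals = class_totals(matrix)

    if _stage_enabled(config, "profile"):
        table1 = profile_table(
            matrix, test=config.test, case=config.case, control=config.control
        )
        write_table(table1, out / "class_profile.csv", index_label="class")
        species_cmp = compare_groups(
            matrix.values, matrix.meta, test=config.test,
            case=config.case, control=config.control,
        )
        write_table(species_cmp, out / "species_comparison.csv", index_label="species")
        report["stages"]["profile"] = {
            "classes": int(totals.values.shape[0]),
            "significant_classes": int(
                (table1.drop(index="Total", errors="ignore")["p"]
                 < config.significance_threshold).sum()
            ),
        }

    if _stage_enabled(config, "multivariate"):
        data = matrix.values
        if config.median_normalize:
            data = normalize_median(data)
        scaled = scale(data, config.scaling)
        result = pca(scaled)
        write_table(result.scores, out / "pca_scores.csv", index_label="sample_id")
        write_table(result.loadings, out / "pca_loadings.csv", index_label="species")
        write_table(
            pd.DataFrame(
                {
                    "component": list(result.scores.columns),
                    "explained_variance_ratio": result.explained_variance_ratio,
                }
            ).set_index("component"),
            out / "pca_explained.csv",
        )
        species_cmp = compare_groups(
            matrix.values, matrix.meta, test=config.test,
            case=config.case, control=config.control,
        )
        heat = heatmap_select_cluster(data, species_cmp, k=config.heatmap_k)
        write_table(heat.values, out / "heatmap_matrix.csv", index_label="species")
        ellipses = group_ellipses(result, matrix.meta)
        report["stages"]["multivariate"] = {
            "components": int(result.n_components),
            "pc1_explained": float(result.explained_variance_ratio[0]),
            "heatmap_species": len(heat.selected),
            "ellipse_groups": sorted(ellipses),
        }

    if _stage_enabled(config, "network"):
        catalog = default_class_catalog()
        weights = compute_weights(totals, catalog)
        scores = score_reactions(
            weights, matrix.meta,
            threshold=config.significance_threshold,
            case=config.case, control=config.control, catalog=catalog,
        )
        annotate_and_export(
            scores, csv_path=out / "class_network.csv",
            graphml_path=out / "class_network.graphml",
        )
        report["stages"]["network"] = {
            "edges": int(len(scores)),
            "called": int((scores["call"] != "unchanged").sum()) if len(scores) else 0,
            "highlighted": int((scores["p"] < config.highlight_threshold).sum())
            if len(scores) else 0,
        }

    if _stage_enabled(config, "chains"):
        chain_ab = chain_abundance(matrix)
        write_table(chain_ab, out / "chain_abundance.csv", index_label="chain")
        for axis in ("length", "unsaturation"):
            prof = chain_profiles(chain_ab, matrix.meta, axis=axis,
                                  case=config.case, control=config.control)
            write_table(prof, out / f"chain_{axis}_profile.csv", index_label=axis)
        chain_scores = chain_network(
            chain_ab, matrix.meta,
            threshold=config.significance_threshold,
            case=config.case, control=config.control,
        )
        write_table(chain_scores, out / "chain_network.csv", index_label="edge")
        report["stages"]["chains"] = {
            "chains": int(chain_ab.shape[0]),
            "edges": int(len(chain_scores)),
            "called": int((chain_scores["call"] != "unchanged").sum())
            if len(chain_scores) else 0,
        }

    if _stage_enabled(config, "correlate") and psy is not None:
        corr = psy_class_correlation(
            psy, totals, method=config.correlation_method
        )
        write_table(corr, out / "psychosine_correlation.csv", index_label="class")
        report["stages"]["correlate"] = {
            "classes": int(len(corr)),
            "negative": int((corr["sign"] == "negative").sum()),
            "positive": int((corr["sign"] == "positive").sum()),
        }

    report["report_path"] = str(out / "run_report.json")
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
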