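"""End-to-end orchestration of the two analysis arms.

The ``uncorrected`` arm analyses advanced-stage raw counts directly
(after the low-count filter); the ``tissue_corrected`` arm first
normalizes advanced samples against per-site reference means (then the
zero-row filter).  Either arm then runs module detection, enrichment,
sample clustering, group statistics and — when survival data is present
— the risk-score analysis.  Every stage materializes its artifact to
the run directory, and a JSON manifest records all parameters and seeds
so a re-run reproduces byte-identical TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from stagenorm import io_formats
from stagenorm.cluster_stats import (
    compare_matched_sites,
    compare_modules_across_clusters,
    comparisons_to_frame,
)
from stagenorm.coexpr_network import NetworkParams, build_network_modules
from stagenorm.io_formats import GenomicMatrix
from stagenorm.ora_enrichment import run_ora_per_module
from stagenorm.preprocess import (
    filter_low_counts,
    filter_protein_coding,
    filter_zero_rows,
    to_raw_counts,
)
from stagenorm.sample_clustering import cluster_samples
from stagenorm.stage_normalize import build_staged_set, tissue_correct
from stagenorm.survival import run_survival_analysis

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters of one run."""

    matrix_path: str
    phenotypes_path: str
    out_dir: str
    arm: str = "tissue_corrected"  # or "uncorrected"
    divisor_stage: str = "early"  # or "normal" for matched normal tissue
    biotypes_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    survival_path: Optional[str] = None
    pseudocount: float = 1.0
    min_count: int = 10
    max_low_fraction: float = 0.90
    network: NetworkParams = field(default_factory=NetworkParams)
    k_min: int = 2
    k_max: int = 10
    alpha: float = 0.05
    min_overlap: int = 2
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("uncorrected", "tissue_corrected"):
            raise ValueError(f"unknown arm {self.arm!r}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured arm, writing artifacts stage by stage.

    Returns a name → path map of everything written.  A failing stage
    raises after all earlier artifacts are on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save_matrix(m: GenomicMatrix, name: str) -> None:
        p = out / f"{name}.tsv"
        io_formats.write_genomic_matrix(m, p)
        artifacts[name] = p

    matrix = io_formats.read_genomic_matrix(config.matrix_path)
    metadata = io_formats.read_phenotypes(config.phenotypes_path)

    counts = to_raw_counts(matrix)
    if config.biotypes_path:
        biotypes = io_formats.read_biotypes(config.biotypes_path)
        counts = filter_protein_coding(counts, biotypes)
    save_matrix(counts, "counts_filtered")

    meta_by_id = {m.sample_id: m for m in metadata}
    if config.arm == "tissue_corrected":
        staged = build_staged_set(counts, metadata, divisor_stage=config.divisor_stage)
        corrected = tissue_correct(staged, pseudocount=config.pseudocount)
        analysis_gm = filter_zero_rows(corrected.to_genomic_matrix())
        site_map = corrected.site_of_sample
        save_matrix(analysis_gm, "tissue_corrected")
        site_path = out / "site_of_sample.tsv"
        site_map.rename("primary_site").rename_axis("sample_id").to_frame().to_csv(
            site_path, sep="\t"
        )
        artifacts["site_of_sample"] = site_path
    else:
        adv_cols = [s for s in counts.sample_ids if meta_by_id[s].stage == "advanced"]
        adv = counts.with_values(counts.values[adv_cols])
        analysis_gm = filter_low_counts(
            adv, min_count=config.min_count, max_low_fraction=config.max_low_fraction
        )
        site_map = pd.Series({s: meta_by_id[s].primary_site for s in adv_cols})
        save_matrix(analysis_gm, "advanced_counts_filtered")
        corrected = None

    expr = analysis_gm.values
    assignment, beta = build_network_modules(expr, config.network)
    mod_path = out / "modules.tsv"
    assignment.labels.rename("module").rename_axis("gene_id").to_frame().to_csv(
        mod_path, sep="\t"
    )
    artifacts["modules"] = mod_path

    module_genes = {m: assignment.genes_in(m) for m in assignment.modules()}
    if config.gene_sets_path and module_genes:
        sets = io_formats.read_gmt(config.gene_sets_path)
        enrichment = run_ora_per_module(
            module_genes, expr.index, sets, min_overlap=config.min_overlap
        )
        enr_path = out / "enrichment.tsv"
        enrichment.to_csv(enr_path, sep="\t", index=False)
        artifacts["enrichment"] = enr_path

    all_module_genes = [g for genes in module_genes.values() for g in genes]
    cluster_input = all_module_genes if all_module_genes else list(expr.index)
    n_samples = expr.shape[1]
    clusters = cluster_samples(
        expr,
        module_genes=cluster_input,
        k_range=range(config.k_min, min(config.k_max, n_samples - 1) + 1),
    )
    clu_path = out / "clusters.tsv"
    clusters.labels.rename("cluster").rename_axis("sample_id").to_frame().to_csv(
        clu_path, sep="\t"
    )
    artifacts["clusters"] = clu_path

    if module_genes:
        if corrected is not None:
            stats_matrix = corrected
        else:
            # uncorrected arm: the comparison values are the filtered counts
            from stagenorm.stage_normalize import TissueCorrectedMatrix

            stats_matrix = TissueCorrectedMatrix(
                L=expr, site_of_sample=site_map, pseudocount=0.0
            )
        omnibus = compare_modules_across_clusters(
            stats_matrix, clusters, module_genes, alpha=config.alpha
        )
        matched = compare_matched_sites(
            stats_matrix, clusters, dict(site_map), module_genes, alpha=config.alpha
        )
        stats_path = out / "cluster_stats.tsv"
        comparisons_to_frame(list(omnibus.values()) + matched).to_csv(
            stats_path, sep="\t", index=False
        )
        artifacts["cluster_stats"] = stats_path

    if config.survival_path:
        surv = io_formats.read_survival(config.survival_path)
        covered = [s for s in expr.columns if s in set(surv["sample_id"])]
        if len(covered) >= 10:
            result = run_survival_analysis(
                expr[covered], surv, folds=config.cv_folds, seed=config.seed
            )
            sel_path = out / "survival_selected_genes.tsv"
            pd.Series(result.selected_genes, name="coefficient").rename_axis(
                "gene_id"
            ).to_frame().to_csv(sel_path, sep="\t")
            artifacts["survival_selected_genes"] = sel_path
            risk_path = out / "risk_scores.tsv"
            pd.DataFrame(
                {"risk_score": result.risk_score, "group": result.group}
            ).rename_axis("sample_id").to_csv(risk_path, sep="\t")
            artifacts["risk_scores"] = risk_path
            km_path = out / "km_curves.tsv"
            pd.concat(
                [c.assign(group=g) for g, c in result.km_curves.items()],
                ignore_index=True,
            ).to_csv(km_path, sep="\t", index=False)
            artifacts["km_curves"] = km_path
        else:
            logger.warning("fewer than 10 samples with survival data; stage skipped")

    manifest = {
        "config": _config_to_dict(config),
        "selected_beta": int(beta),
        "n_modules": len(module_genes),
        "selected_k": int(clusters.k),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = man_path
    return artifacts


def _config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["network"] = dataclasses.asdict(config.network)
    return d
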