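"""End-to-end orchestration of the analysis stages on one dataset."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import dynamics, latentgp, markers, ohnologs, qcnorm, synthdata, trajectory
from .config import PipelineConfig

log = logging.getLogger("thrombotraj")


def run_pipeline(
    config: PipelineConfig | None = None,
    matrix: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    pairs: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run qc -> order -> order-gplvm -> markers -> dynamics -> ohnologs.

    Without an input matrix, the default synthetic dataset is generated
    (its planted ohnolog pair list is then used).  Returns a
    machine-readable report with one section per stage; with ``outdir``
    set, per-stage tables, the report and the resolved configuration are
    written there.
    """
    config = config or PipelineConfig()
    report: dict = {"config": config.to_dict()}
    stage = "simulate"
    try:
        if matrix is None:
            matrix, meta, truth = synthdata.generate_dataset(config.generator)
            if pairs is None:
                pairs = truth.ohnolog_pairs
            report["simulate"] = {
                "n_cells": int(matrix.shape[0]),
                "n_genes": int(matrix.shape[1]),
            }

        stage = "qc"
        processed, meta_kept, qc_report = qcnorm.run_qc(
            matrix,
            meta,
            thresholds=config.qc_thresholds,
            min_tpm=config.gene_filter_min_tpm,
            min_cells=config.gene_filter_min_cells,
        )
        content = qc_report.pop("mrna_content")
        report["qc"] = {k: v for k, v in qc_report.items()}
        log.info("qc: %d cells, %d genes retained", *processed.shape)

        stage = "order"
        pseudotime, assignment, factors = trajectory.order_cells(
            processed,
            meta_kept,
            k=config.ica_k,
            n_clusters=config.n_clusters,
            seed=config.ica_seed,
        )
        report["order"] = {
            "n_ordered": int(len(pseudotime)),
            "n_outliers": int((assignment.stages == "outlier").sum()),
            "stage_sizes": assignment.stages.value_counts().to_dict(),
        }

        stage = "order-gplvm"
        latent = latentgp.fit_gplvm_1d(
            processed,
            n_genes=config.gplvm_n_genes,
            seed=config.gplvm_seed,
            restarts=config.gplvm_restarts,
        )
        latent = latentgp.align_orientation(
            latent, meta_kept.loc[latent.coords.index, "fluorescence"]
        )
        agreement = latentgp.compare_orderings(
            pseudotime, latent.coords.loc[pseudotime.index].rank()
        )
        report["order-gplvm"] = {"agreement_abs_spearman": float(agreement)}

        stage = "markers"
        rankings = markers.rank_all_markers(
            processed,
            assignment.stages,
            n_trees=config.marker_n_trees,
            seed=config.marker_seed,
        )
        report["markers"] = {
            c: r.ranking.head(5).index.tolist() for c, r in rankings.items()
        }

        stage = "dynamics"
        dyn = dynamics.detect_dynamic_genes(
            processed.loc[pseudotime.index],
            pseudotime,
            threshold=config.dynamic_threshold,
            restarts=config.dynamic_restarts,
        )
        trends = dynamics.cluster_trends(dyn, n_groups=config.trend_groups)
        report["dynamics"] = {
            "n_dynamic": int(dyn.table["dynamic"].sum()),
            "trend_sizes": trends.value_counts().to_dict(),
        }

        stage = "ohnologs"
        if pairs is not None and len(pairs):
            records, tally, skipped = ohnologs.classify_all(
                processed, pairs, thresholds=config.ohnolog_thresholds
            )
            report["ohnologs"] = {"tally": tally, "n_skipped": len(skipped)}
        else:
            report["ohnologs"] = {"tally": {}, "n_skipped": 0}
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        factors.values.to_csv(outdir / "factors.tsv", sep="\t")
        assignment.stages.to_csv(outdir / "clusters.csv")
        pseudotime.to_csv(outdir / "pseudotime.csv")
        latent.coords.to_csv(outdir / "gplvm_latent.csv")
        dyn.table.to_csv(outdir / "dynamic_genes.csv")
        trends.to_csv(outdir / "trend_groups.csv")
        content.to_csv(outdir / "mrna_content.csv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
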