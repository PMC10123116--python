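"""End-to-end orchestration: activity -> preprocess -> cluster ->
(train -> rank) x rounds -> network -> evaluate, from one validated config.

Every stage logs (stage name, wall time, shapes, seed) to stderr and the
run log; all randomness flows from the config's explicit seeds, so
re-running an identical config reproduces an identical network edge list.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
import time
from glob import glob

import numpy as np
import pandas as pd

from . import io as vio
from .config import PipelineConfig, dump_config
from .evaluation import TruthTFSet, recall
from .intervals import (
    assign_sites_to_promoters,
    compute_activity,
    compute_activity_per_cell,
    read_bed,
)
from .model import MultiTaskVelocityModel

__all__ = ["run_pipeline", "compute_activity_from_files"]

logger = logging.getLogger("velogrn")


class _Stage:
    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            logger.error("stage %s: FAILED after %.2fs: %s", self.name, dt, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", self.name, dt)


def compute_activity_from_files(
    peaks_path,
    sites_dir,
    genes_path,
    upstream: int = 3000,
    downstream: int = 3000,
    per_cell: bool = False,
    peak_cell_matrix=None,
):
    """Read BED/TSV inputs and compute (unscaled) activity matrices.

    ``sites_dir`` holds one ``<tf_id>.bed`` per TF.  In per-cell mode a
    peak x cell binary matrix (MTX prefix) attaches cell ownership to the
    peaks before scoring.
    """
    genes = vio.read_gene_annotation(genes_path)
    peaks = read_bed(peaks_path)
    site_files = sorted(glob(os.path.join(sites_dir, "*.bed")))
    if not site_files:
        raise ValueError(f"no per-TF .bed files found in {sites_dir}")
    raw_sites = {
        os.path.splitext(os.path.basename(p))[0]: read_bed(p) for p in site_files
    }
    catalog = assign_sites_to_promoters(raw_sites, genes, upstream, downstream)
    if per_cell:
        if peak_cell_matrix is None:
            raise ValueError("per-cell mode requires a peak x cell matrix")
        mat, peak_idx, cell_ids = vio.read_matrix_mtx(peak_cell_matrix)
        assignment = {
            cell: list(np.flatnonzero(mat[:, c] > 0))
            for c, cell in enumerate(cell_ids)
        }
        from .intervals import PeakSet

        owned = PeakSet(peaks.intervals, cell_assignment=assignment)
        return compute_activity_per_cell(catalog, owned)
    return compute_activity(catalog, peaks.merge())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole inference pipeline and write all artifacts under
    ``config.output_dir``.  Returns the metrics dictionary."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    if not logger.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    fh = logging.FileHandler(os.path.join(out, "run.log"))
    logger.addHandler(fh)
    config_yaml = dump_config(config)
    config_hash = hashlib.sha256(config_yaml.encode()).hexdigest()[:12]
    logger.info("config hash %s", config_hash)
    try:
        with _Stage("activity"):
            activity = compute_activity_from_files(
                config.inputs.peaks,
                config.inputs.sites_dir,
                config.inputs.genes,
                upstream=config.activity.upstream,
                downstream=config.activity.downstream,
                per_cell=config.activity.per_cell,
                peak_cell_matrix=config.inputs.peak_cell_matrix,
            )
            vio.write_matrix_mtx(
                activity.a_sum,
                activity.tf_ids,
                activity.gene_ids,
                os.path.join(out, "activity_sum"),
            )
            vio.write_matrix_mtx(
                activity.a_mean,
                activity.tf_ids,
                activity.gene_ids,
                os.path.join(out, "activity_mean"),
            )

        with _Stage("preprocess+cluster"):
            expression = vio.read_expression_tsv(config.inputs.expression)
            velocity = vio.read_velocity_tsv(config.inputs.velocity)
            # keep only TFs with activity rows, in activity order
            keep = [t for t in activity.tf_ids if t in set(expression.tf_ids)]
            idx = [expression.tf_ids.index(t) for t in keep]
            from .preprocess import ExpressionMatrix

            expression = ExpressionMatrix(
                expression.values[:, idx],
                expression.cell_ids,
                keep,
                expression.state,
            )
            model = MultiTaskVelocityModel(
                expression,
                velocity,
                activity,
                config=config.training,
                min_cells=config.filters.min_cells,
                train_frac=config.split.train_frac,
                split_seed=config.split.seed,
                cluster_seed=config.clustering.seed,
                n_clusters=config.clustering.n_clusters,
                cluster_min_size=config.clustering.min_size,
                cluster_max_size=config.clustering.max_size,
            )
            pd.DataFrame(
                sorted(model.clusters.labels.items()),
                columns=["gene_id", "cluster"],
            ).to_csv(os.path.join(out, "clusters.tsv"), sep="\t", index=False)

        with _Stage("train+rank"):
            results = model.fit(
                rounds=config.network.rounds, top_k=config.network.top_k
            )
            results.r2_frame().to_csv(os.path.join(out, "test_r2.tsv"), sep="\t")
            results.mean_importance().to_csv(
                os.path.join(out, "importance.tsv"), sep="\t", index=False
            )

        with _Stage("network"):
            assert results.network is not None
            vio.write_network(results.network, os.path.join(out, "network.tsv"))

        with _Stage("evaluate"):
            finite = [v for v in results.r2.values() if np.isfinite(v)]
            metrics = {
                "config_hash": config_hash,
                "n_genes": len(results.r2),
                "n_clusters": len(model._train_tasks),
                "n_edges": len(results.network),
                "mean_test_r2": float(np.mean(finite)) if finite else None,
                "median_test_r2": float(np.median(finite)) if finite else None,
            }
            if config.inputs.truth:
                truth_df = pd.read_csv(config.inputs.truth, sep="\t")
                truth = TruthTFSet(
                    "truth", set(truth_df.tf_id.astype(str))
                )
                metrics["network_tf_recall"] = recall(
                    results.network.tfs(), truth
                )
            with open(os.path.join(out, "metrics.json"), "w") as f:
                json.dump(metrics, f, indent=2)
        return metrics
    finally:
        logger.removeHandler(fh)
        fh.close()
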