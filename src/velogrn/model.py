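"""Model/Results front-end for the whole inference procedure.

``MultiTaskVelocityModel`` is built from the three raw inputs (cells x TFs
RPKM expression, cells x genes velocities with missing mask, TF x gene
activity matrices); construction performs the fixed preprocessing
(log10(x+1), gene filtering, 9:1 cell split, per-split standardization,
log2(x+1) activity scaling, size-constrained gene clustering, per-gene task
assembly).  ``fit()`` trains every cluster jointly under the multi-task
loss and returns a ``VelocityFitResults`` carrying per-gene test R²,
per-gene TF importances and — when ``rounds`` is requested — the consensus
regulatory network from the round-wise top-k intersections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .attribution import AttributionResult, rank_cluster, reference_example
from .clustering import ClusterAssignment, cluster_feature_matrix, constrained_kmeans
from .intervals import ActivityMatrices, scale_activity
from .network import RegulatoryNetwork, build_network, degree_ranking
from .nn import MultiTaskModel, TrainingConfig, train_cluster
from .preprocess import (
    ExpressionMatrix,
    VelocityMatrix,
    assemble_task_dataset,
    filter_genes,
    log_rpkm,
    split_cells,
    standardize_columns,
)

__all__ = ["MultiTaskVelocityModel", "VelocityFitResults"]


class MultiTaskVelocityModel:
    """Per-gene velocity regression with soft multi-task sharing.

    Parameters
    ----------
    expression : raw cells x TFs RPKM matrix.
    velocity : raw cells x genes velocities with missing mask.
    activity : TF x gene activity matrices (unscaled; scaled on entry).
    config : training hyperparameters (see :class:`TrainingConfig`).
    min_cells : drop genes observed in fewer cells (strict ``<``).
    train_frac, split_seed : 9:1 cell split by default.
    n_clusters / cluster sizes : nearly equal-sized gene clusters; when
        ``n_clusters`` is given without explicit bounds the sizes
        floor(n/k) .. ceil(n/k) are used.
    standardize_with_train_stats : apply training-set statistics to the
        test set instead of standardizing each split on its own (the
        default standardizes the splits independently).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        velocity: VelocityMatrix,
        activity: ActivityMatrices,
        config: TrainingConfig | None = None,
        min_cells: int = 0,
        train_frac: float = 0.9,
        split_seed: int = 0,
        cluster_seed: int = 0,
        n_clusters: int | None = None,
        cluster_min_size: int | None = None,
        cluster_max_size: int | None = None,
        clusters: dict[str, int] | None = None,
        standardize_with_train_stats: bool = False,
    ) -> None:
        self.config = config or TrainingConfig()
        if list(expression.tf_ids) != list(activity.tf_ids):
            raise ValueError("expression and activity TF universes differ")

        velocity = filter_genes(velocity, min_cells)
        keep = [c for c in expression.cell_ids if c in set(velocity.cell_ids)]
        if keep != list(expression.cell_ids):
            pos = {c: i for i, c in enumerate(expression.cell_ids)}
            expression = expression.subset_cells(
                np.array([pos[c] for c in velocity.cell_ids])
            )
        if expression.cell_ids != velocity.cell_ids:
            raise ValueError("expression and velocity matrices must share cells")

        logged = log_rpkm(expression) if expression.state == "raw" else expression
        self.activity = activity if activity.scaled else scale_activity(activity)

        train_cells, test_cells = split_cells(
            velocity.cell_ids, ratio=train_frac, seed=split_seed
        )
        self.train_cells, self.test_cells = train_cells, test_cells
        pos = {c: i for i, c in enumerate(velocity.cell_ids)}
        tr_idx = np.array([pos[c] for c in train_cells])
        te_idx = np.array([pos[c] for c in test_cells])

        def _standardize(xs, ys, stats_from=None):
            xv = standardize_columns(xs.values)
            yv = standardize_columns(ys.values, ys.missing_mask)
            return (
                ExpressionMatrix(xv, xs.cell_ids, xs.tf_ids, "standardized"),
                VelocityMatrix(
                    yv, ys.missing_mask, ys.cell_ids, ys.gene_ids, "standardized"
                ),
            )

        x_tr, y_tr = _standardize(
            logged.subset_cells(tr_idx), velocity.subset_cells(tr_idx)
        )
        if standardize_with_train_stats:
            # conventional alternative: reuse training statistics
            xl = logged.subset_cells(tr_idx).values
            mu, sd = xl.mean(0), xl.std(0)
            sd[sd < 1e-12] = 1.0
            xe = (logged.subset_cells(te_idx).values - mu) / sd
            yv = velocity.subset_cells(te_idx)
            ytr_raw = velocity.subset_cells(tr_idx)
            ymu = np.array(
                [
                    ytr_raw.values[~ytr_raw.missing_mask[:, j], j].mean()
                    if (~ytr_raw.missing_mask[:, j]).sum()
                    else 0.0
                    for j in range(len(ytr_raw.gene_ids))
                ]
            )
            ysd = np.array(
                [
                    ytr_raw.values[~ytr_raw.missing_mask[:, j], j].std()
                    if (~ytr_raw.missing_mask[:, j]).sum() > 1
                    else 1.0
                    for j in range(len(ytr_raw.gene_ids))
                ]
            )
            ysd[ysd < 1e-12] = 1.0
            x_te = ExpressionMatrix(
                xe, [velocity.cell_ids[i] for i in te_idx], logged.tf_ids,
                "standardized",
            )
            y_te = VelocityMatrix(
                (yv.values - ymu) / ysd,
                yv.missing_mask,
                yv.cell_ids,
                yv.gene_ids,
                "standardized",
            )
        else:
            x_te, y_te = _standardize(
                logged.subset_cells(te_idx), velocity.subset_cells(te_idx)
            )
        self.x_train, self.y_train = x_tr, y_tr
        self.x_test, self.y_test = x_te, y_te

        # genes need >=2 observed training cells to be trainable
        trainable = np.flatnonzero((~y_tr.missing_mask).sum(axis=0) >= 2)
        self.dropped_genes = [
            y_tr.gene_ids[j]
            for j in range(len(y_tr.gene_ids))
            if j not in set(trainable)
        ]
        if trainable.size < len(y_tr.gene_ids):
            y_tr = VelocityMatrix(
                y_tr.values[:, trainable],
                y_tr.missing_mask[:, trainable],
                y_tr.cell_ids,
                [y_tr.gene_ids[j] for j in trainable],
                "standardized",
            )
            self.y_train = y_tr

        n_genes = len(y_tr.gene_ids)
        if clusters is not None:
            missing = [g for g in y_tr.gene_ids if g not in clusters]
            if missing:
                raise ValueError(
                    f"preassigned clustering lacks genes {missing[:5]}"
                )
            labels_map = {g: int(clusters[g]) for g in y_tr.gene_ids}
            sizes = np.bincount(list(labels_map.values()))
            self.clusters = ClusterAssignment(
                labels_map,
                n_clusters=len(sizes),
                min_size=int(sizes.min()),
                max_size=int(sizes.max()),
            )
            k = len(sizes)
        else:
            if n_clusters is not None and cluster_min_size is None:
                cluster_min_size = n_genes // n_clusters
                cluster_max_size = -(-n_genes // n_clusters)
            cluster_min_size = 24 if cluster_min_size is None else cluster_min_size
            cluster_max_size = 25 if cluster_max_size is None else cluster_max_size
            feats = cluster_feature_matrix(y_tr)
            labels, _ = constrained_kmeans(
                feats,
                min_size=cluster_min_size,
                max_size=cluster_max_size,
                n_clusters=n_clusters,
                seed=cluster_seed,
            )
            k = int(labels.max()) + 1 if len(labels) else 0
            self.clusters = ClusterAssignment(
                {g: int(l) for g, l in zip(y_tr.gene_ids, labels)},
                n_clusters=k,
                min_size=cluster_min_size,
                max_size=cluster_max_size,
            )

        self._train_tasks: dict[int, list] = {}
        self._test_tasks: dict[int, list] = {}
        for c in range(k):
            members = self.clusters.members(c)
            tr, te = [], []
            for g in members:
                tr.append(
                    assemble_task_dataset(g, x_tr, y_tr, self.activity, train_cells)
                )
                te.append(self._test_task(g))
            self._train_tasks[c] = tr
            self._test_tasks[c] = te
        self.reference = reference_example(x_tr, len(x_tr.tf_ids))

    def _test_task(self, gene_id):
        try:
            return assemble_task_dataset(
                gene_id, self.x_test, self.y_test, self.activity, self.test_cells
            )
        except ValueError:
            return None

    @classmethod
    def from_matrices(
        cls,
        expression: np.ndarray,
        velocity: np.ndarray,
        missing_mask: np.ndarray,
        a_sum: np.ndarray,
        a_mean: np.ndarray,
        tf_ids: list[str],
        gene_ids: list[str],
        cell_ids: list[str] | None = None,
        **kwargs,
    ) -> "MultiTaskVelocityModel":
        """Construct from plain arrays (raw RPKM, raw velocities + mask,
        unscaled activity matrices)."""
        cells = cell_ids or [f"cell{i}" for i in range(expression.shape[0])]
        return cls(
            ExpressionMatrix(expression, cells, tf_ids, "raw"),
            VelocityMatrix(velocity, missing_mask, list(cells), gene_ids, "raw"),
            ActivityMatrices(a_sum, a_mean, tf_ids, gene_ids),
            **kwargs,
        )

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        rounds: int | None = None,
        top_k: int | None = None,
        rank: bool = True,
    ) -> "VelocityFitResults":
        """Train all clusters; optionally repeat for ``rounds`` seeds and
        build the consensus network from round-wise top-``top_k`` TFs.

        Without ``rounds``, training honours ``config.repeats`` (per-gene R²
        averaged over repeats) and a single attribution pass ranks TFs.
        With ``rounds``, each round is one training run (repeats=1) with a
        derived seed followed by an attribution pass.
        """
        cfg = self.config
        if rounds is None:
            cluster_models, r2 = self._fit_all(cfg)
            round_results = (
                [self._rank_all(cluster_models, run=0)] if rank else None
            )
            network = None
        else:
            top_k = top_k if top_k is not None else cfg.top_k
            round_results = []
            r2 = {}
            cluster_models = {}
            for r in range(rounds):
                cfg_r = replace(
                    cfg, seed=(cfg.seed + 104729 * (r + 1)) % (2**31 - 1), repeats=1
                )
                cluster_models, r2_r = self._fit_all(cfg_r)
                if r == 0:
                    r2 = r2_r
                round_results.append(self._rank_all(cluster_models, run=r))
            network = build_network(round_results, k=top_k)
        return VelocityFitResults(
            self, cfg, r2, cluster_models, round_results, network
        )

    def _fit_all(self, cfg: TrainingConfig):
        cluster_models: dict[int, MultiTaskModel] = {}
        r2: dict[str, float] = {}
        for c in sorted(self._train_tasks):
            tr = self._train_tasks[c]
            te = self._test_tasks[c]
            usable = [t is not None and len(t.targets) >= 2 for t in te]
            te_eval = [
                t if ok else tr[i] for i, (t, ok) in enumerate(zip(te, usable))
            ]
            model, scores = train_cluster(tr, te_eval, cfg)
            for (g, s), ok in zip(scores.items(), usable):
                r2[g] = s if ok else float("nan")
            cluster_models[c] = model
        return cluster_models, r2

    def _rank_all(
        self, cluster_models: dict[int, MultiTaskModel], run: int
    ) -> list[AttributionResult]:
        out: list[AttributionResult] = []
        for c, model in cluster_models.items():
            out.extend(
                rank_cluster(model, self._train_tasks[c], self.reference, run=run)
            )
        return out


@dataclass
class VelocityFitResults:
    """Estimates and diagnostics from a fitted multi-task velocity model."""

    model: MultiTaskVelocityModel
    config: TrainingConfig
    r2: dict[str, float]
    cluster_models: dict[int, MultiTaskModel]
    rounds: list[list[AttributionResult]] | None = None
    network: RegulatoryNetwork | None = None

    def r2_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.r2), "test_r2": list(self.r2.values())}
        ).set_index("gene_id")

    def mean_importance(self) -> pd.DataFrame:
        """Per (gene, TF) importance averaged over attribution rounds."""
        if not self.rounds:
            raise ValueError("no attribution rounds available")
        records: dict[tuple[str, str], list[float]] = {}
        for rnd in self.rounds:
            for res in rnd:
                for tf, imp in zip(res.tf_ids, res.importance):
                    records.setdefault((res.gene_id, tf), []).append(float(imp))
        rows = [
            {"gene_id": g, "tf_id": t, "importance": float(np.mean(v))}
            for (g, t), v in sorted(records.items())
        ]
        return pd.DataFrame(rows)

    def ranked_tfs(self, gene_id: str) -> list[str]:
        """TFs for one gene ordered by mean importance across rounds."""
        frame = self.mean_importance()
        sub = frame[frame.gene_id == gene_id]
        sub = sub.sort_values(["importance", "tf_id"], ascending=[False, True])
        return sub.tf_id.tolist()

    def degree_ranking(self) -> list[tuple[str, int]]:
        if self.network is None:
            raise ValueError("no network built; call fit(rounds=...)")
        return degree_ranking(self.network)

    def summary(self) -> str:
        vals = np.array([v for v in self.r2.values() if np.isfinite(v)])
        lines = [
            "Multi-task velocity regression results",
            "=" * 46,
            f"genes (tasks):        {len(self.r2)}",
            f"clusters:             {len(self.cluster_models)}",
            f"training cells:       {len(self.model.train_cells)}",
            f"test cells:           {len(self.model.test_cells)}",
            f"sharing enabled:      {self.config.sharing_enabled}"
            f" (gamma={self.config.gamma_trace})",
            f"L1 strength (lambda): {self.config.lambda_l1}",
            f"mean test R2:         {vals.mean():.4f}" if vals.size else
            "mean test R2:         n/a",
            f"median test R2:       {np.median(vals):.4f}" if vals.size else
            "median test R2:       n/a",
        ]
        if self.network is not None:
            lines.append(f"network edges:        {len(self.network)}")
            top = self.degree_ranking()[:5]
            lines.append(
                "top TFs by degree:    "
                + ", ".join(f"{t}({d})" for t, d in top)
            )
        return "\n".join(lines)
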