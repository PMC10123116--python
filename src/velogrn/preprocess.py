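"""Filtering, transformation and per-gene task assembly.

Expression is TF RPKM, log10(x+1)-transformed then column-standardized;
velocity targets are column-standardized over their observed entries only.
Because velocity is undefined in many cells, each gene defines its own task
dataset restricted to the cells where its velocity is observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import ActivityMatrices

__all__ = [
    "ExpressionMatrix",
    "VelocityMatrix",
    "ChipSampleMetadata",
    "ChipQCThresholds",
    "TaskDataset",
    "filter_chipseq_samples",
    "filter_genes",
    "log_rpkm",
    "standardize_columns",
    "split_cells",
    "assemble_task_dataset",
]


@dataclass
class ExpressionMatrix:
    """Cells x TFs expression. ``state`` tracks raw -> logged -> standardized."""

    values: np.ndarray
    cell_ids: list[str]
    tf_ids: list[str]
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.tf_ids)):
            raise ValueError("expression shape does not match index lengths")
        if self.state == "raw" and (self.values < 0).any():
            raise ValueError("raw RPKM values must be nonnegative")

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[idx],
            [self.cell_ids[i] for i in idx],
            list(self.tf_ids),
            self.state,
        )


@dataclass
class VelocityMatrix:
    """Cells x genes velocities with an explicit missing mask
    (True = velocity unavailable for that cell/gene)."""

    values: np.ndarray
    missing_mask: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("velocity shape does not match index lengths")

    def observed_counts(self) -> np.ndarray:
        """Non-missing cell count per gene."""
        return (~self.missing_mask).sum(axis=0)

    def subset_cells(self, idx: np.ndarray) -> "VelocityMatrix":
        return VelocityMatrix(
            self.values[idx],
            self.missing_mask[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
            self.state,
        )


@dataclass(frozen=True)
class ChipSampleMetadata:
    """QC metrics for one ChIP-seq sample."""

    sample_id: str
    median_quality_score: float
    uniquely_mapped_ratio: float  # percent
    pbc: float  # percent
    frip: float  # percent
    peaks_fold_change_above_10: int

    def __post_init__(self) -> None:
        for name in ("uniquely_mapped_ratio", "pbc", "frip"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"sample {self.sample_id}: missing metric {name}")
            if not 0 <= v <= 100:
                raise ValueError(
                    f"sample {self.sample_id}: {name}={v} outside [0, 100]"
                )
        if self.median_quality_score is None:
            raise ValueError(
                f"sample {self.sample_id}: missing metric median_quality_score"
            )
        if self.peaks_fold_change_above_10 < 0:
            raise ValueError(f"sample {self.sample_id}: negative peak count")


@dataclass(frozen=True)
class ChipQCThresholds:
    """Inclusive lower bounds for keeping a ChIP-seq sample."""

    min_quality: float = 25.0
    min_mapped_ratio: float = 60.0
    min_pbc: float = 80.0
    min_frip: float = 1.0
    min_peaks_fc10: int = 500


@dataclass
class TaskDataset:
    """One gene's regression task: rows are the split's cells with an
    observed velocity for the gene; inputs per row are
    (a_sum[:, gene], a_mean[:, gene], expression[cell, :]) concatenated in
    fixed TF order."""

    gene_id: str
    cell_ids: list[str]
    inputs: np.ndarray  # (n_examples, 3 * n_tfs)
    targets: np.ndarray  # (n_examples,)
    tf_ids: list[str] = field(default_factory=list)

    @property
    def n_examples(self) -> int:
        return len(self.targets)


def filter_chipseq_samples(
    meta: list[ChipSampleMetadata],
    thresholds: ChipQCThresholds | None = None,
) -> list[str]:
    """Sample ids passing all five QC criteria (inclusive thresholds):
    median sequence quality, uniquely mapped ratio, PBC, FRiP, and the
    number of peaks with fold change above 10."""
    t = thresholds or ChipQCThresholds()
    return [
        m.sample_id
        for m in meta
        if m.median_quality_score >= t.min_quality
        and m.uniquely_mapped_ratio >= t.min_mapped_ratio
        and m.pbc >= t.min_pbc
        and m.frip >= t.min_frip
        and m.peaks_fold_change_above_10 >= t.min_peaks_fc10
    ]


def filter_genes(v: VelocityMatrix, min_cells: int) -> VelocityMatrix:
    """Drop genes observed in fewer than ``min_cells`` cells (strict ``<``),
    then drop cells left with no observed gene at all."""
    if min_cells < 0:
        raise ValueError("min_cells must be nonnegative")
    keep_genes = np.flatnonzero(v.observed_counts() >= min_cells)
    if keep_genes.size == 0:
        raise ValueError(
            f"no gene has >= {min_cells} observed cells; lower the threshold"
        )
    values = v.values[:, keep_genes]
    mask = v.missing_mask[:, keep_genes]
    keep_cells = np.flatnonzero((~mask).sum(axis=1) > 0)
    return VelocityMatrix(
        values[keep_cells],
        mask[keep_cells],
        [v.cell_ids[i] for i in keep_cells],
        [v.gene_ids[j] for j in keep_genes],
        v.state,
    )


def log_rpkm(x: ExpressionMatrix) -> ExpressionMatrix:
    """log10(x + 1) transform of raw RPKM (zeros stay zero)."""
    if x.state != "raw":
        raise ValueError(f"expected raw expression, got state {x.state!r}")
    if (x.values < 0).any():
        raise ValueError("negative RPKM entry")
    return ExpressionMatrix(
        np.log10(x.values + 1.0), list(x.cell_ids), list(x.tf_ids), "logged"
    )


def standardize_columns(
    m: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Column-wise zero-mean unit-variance scaling (population sd).

    ``mask`` marks missing entries (True = missing); statistics use observed
    entries only and masked positions are passed through unchanged.  Columns
    with fewer than 2 observed values or zero variance map to all zeros.
    """
    m = np.asarray(m, dtype=float)
    out = m.copy()
    obs = ~mask if mask is not None else np.ones_like(m, dtype=bool)
    counts = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sums = np.where(obs, m, 0.0).sum(axis=0)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        sq = np.where(obs, (m - means) ** 2, 0.0).sum(axis=0)
        sds = np.sqrt(sq / np.maximum(counts, 1))
    for j in range(m.shape[1]):
        col_obs = obs[:, j]
        if counts[j] < 2 or sds[j] < 1e-12:
            out[col_obs, j] = 0.0
        else:
            out[col_obs, j] = (m[col_obs, j] - means[j]) / sds[j]
    return out


def split_cells(
    cell_ids: list[str], ratio: float = 0.9, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Uniform random train/test partition of the cells.

    ``|train| = round(ratio * n)``; deterministic for a given seed.
    """
    n = len(cell_ids)
    if n < 2:
        raise ValueError("need at least 2 cells to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    train = sorted(perm[:n_train])
    test = sorted(perm[n_train:])
    return [cell_ids[i] for i in train], [cell_ids[i] for i in test]


def assemble_task_dataset(
    gene_id: str,
    x: ExpressionMatrix,
    y: VelocityMatrix,
    a: ActivityMatrices,
    cells: list[str],
) -> TaskDataset:
    """Build one gene's task dataset from standardized expression/velocity
    and scaled activity matrices, restricted to ``cells``.

    Tissue mode broadcasts the gene's activity column to every row; per-cell
    mode substitutes each cell's own activity scores.
    """
    if x.state != "standardized":
        raise ValueError("expression must be standardized")
    if y.state != "standardized":
        raise ValueError("velocity must be standardized")
    if x.cell_ids != y.cell_ids:
        raise ValueError("expression and velocity matrices must share cell order")
    if gene_id not in y.gene_ids:
        raise ValueError(f"gene {gene_id!r} absent from velocity matrix")
    if gene_id not in a.gene_ids:
        raise ValueError(f"gene {gene_id!r} absent from activity matrices")
    if list(x.tf_ids) != list(a.tf_ids):
        raise ValueError("expression and activity matrices must share TF order")

    cell_pos = {c: i for i, c in enumerate(x.cell_ids)}
    g_col = y.gene_ids.index(gene_id)
    a_col = a.gene_ids.index(gene_id)
    rows = [
        c for c in cells if c in cell_pos and not y.missing_mask[cell_pos[c], g_col]
    ]
    if not rows:
        raise ValueError(f"gene {gene_id!r} has no observed velocity in this split")
    idx = np.array([cell_pos[c] for c in rows])
    n_tfs = len(x.tf_ids)
    inputs = np.empty((len(rows), 3 * n_tfs))
    if a.mode == "per_cell":
        if a.per_cell is None:
            raise ValueError("per-cell activity payload missing")
        for r, c in enumerate(rows):
            s, m = a.per_cell.get(c, (a.a_sum * 0.0, a.a_mean * 0.0))
            inputs[r, :n_tfs] = s[:, a_col]
            inputs[r, n_tfs : 2 * n_tfs] = m[:, a_col]
    else:
        inputs[:, :n_tfs] = a.a_sum[:, a_col]
        inputs[:, n_tfs : 2 * n_tfs] = a.a_mean[:, a_col]
    inputs[:, 2 * n_tfs :] = x.values[idx]
    targets = y.values[idx, g_col]
    return TaskDataset(gene_id, rows, inputs, targets, list(x.tf_ids))
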