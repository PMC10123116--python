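"""Per-gene TF importance by reference-based feature attribution.

Attributions are computed against a single reference input — per-TF mean of
the standardized training expressions with zero activity scores — using the
rescale rule: multipliers propagate backward through the network, and at
each nonlinearity the multiplier is scaled by
``(g(z) - g(z_ref)) / (z - z_ref)`` (the secant slope between the actual
and reference pre-activations).  For piecewise-linear networks this yields
attributions that satisfy completeness exactly: per row they sum to
``f(row) - f(reference)``.

A TF's importance for a gene is the sum over all attributed rows of the
absolute attributions of its three features (a_sum, a_mean, expression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import MultiTaskModel, forward_single
from .preprocess import ExpressionMatrix, TaskDataset

__all__ = [
    "ReferenceExample",
    "AttributionResult",
    "reference_example",
    "attribute",
    "tf_importance",
    "rank_cluster",
]

_SECANT_EPS = 1e-9


@dataclass
class ReferenceExample:
    """Reference input: training-mean expression, zero activity scores."""

    values: np.ndarray  # (3 * n_tfs,)
    n_tfs: int

    def __post_init__(self) -> None:
        if self.values.shape != (3 * self.n_tfs,):
            raise ValueError("reference length must be 3 * n_tfs")
        if np.any(self.values[: 2 * self.n_tfs] != 0.0):
            raise ValueError("activity coordinates of the reference must be 0")


@dataclass
class AttributionResult:
    """Per-gene nonnegative TF importance scores for one train+rank run."""

    gene_id: str
    tf_ids: list[str]
    importance: np.ndarray  # (n_tfs,) nonnegative
    run: int = 0
    raw_attributions: np.ndarray | None = None  # (n_rows, 3 * n_tfs)

    def __post_init__(self) -> None:
        if (self.importance < 0).any():
            raise ValueError("importances must be nonnegative")
        if len(self.importance) != len(self.tf_ids):
            raise ValueError("importance length must match tf_ids")


def reference_example(
    x_train: ExpressionMatrix | np.ndarray, n_tfs: int
) -> ReferenceExample:
    """Build the reference: expression coordinates are the column means of
    the (standardized) training expression matrix; both activity blocks are
    identically zero."""
    values = x_train.values if isinstance(x_train, ExpressionMatrix) else x_train
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("training expression matrix is empty")
    if values.shape[1] != n_tfs:
        raise ValueError("training matrix column count must equal n_tfs")
    ref = np.zeros(3 * n_tfs)
    ref[2 * n_tfs :] = values.mean(axis=0)
    return ReferenceExample(ref, n_tfs)


def _secant(z: np.ndarray, z_ref: np.ndarray, kind: str) -> np.ndarray:
    """Rescale multipliers (g(z) - g(zref)) / (z - zref), falling back to
    the derivative at z where the pre-activations coincide."""
    if kind == "relu":
        gz, gr = np.maximum(z, 0.0), np.maximum(z_ref, 0.0)
        deriv = (z > 0).astype(float)
    else:
        gz, gr = np.tanh(z), np.tanh(z_ref)
        t = np.tanh(z)
        deriv = 1.0 - t * t
    dz = z - z_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (gz - gr) / dz
    return np.where(np.abs(dz) > _SECANT_EPS, slope, deriv)


def attribute(
    model: MultiTaskModel,
    task: int,
    rows: np.ndarray,
    reference: ReferenceExample,
    completeness_tol: float = 1e-3,
    max_violations: float = 0.01,
) -> np.ndarray:
    """Per-row, per-feature attributions of one task's predictions relative
    to the reference, shape (n_rows, 3 * n_tfs).

    Completeness — sum of a row's attributions equals
    ``f(row) - f(reference)`` — is verified on every row; the call fails if
    more than ``max_violations`` of rows exceed the tolerance.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    f = model.n_tfs
    if rows.shape[1] != 3 * f:
        raise ValueError("rows must have 3 * n_tfs columns")
    p = model.task_params(task)
    kind = model.activation
    ref = reference.values

    def _preacts(x: np.ndarray) -> list[np.ndarray]:
        a_s, a_m, e = x[..., :f], x[..., f : 2 * f], x[..., 2 * f :]
        z0 = p["agg"][0] * a_s + p["agg"][1] * a_m + p["agg"][2] * e
        zs = [z0]
        h = np.maximum(z0, 0.0) if kind == "relu" else np.tanh(z0)
        for layer in (1, 2, 3):
            z = h @ p[f"W{layer}"] + p[f"b{layer}"]
            zs.append(z)
            h = np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)
        return zs

    z_rows = _preacts(rows)
    z_ref = _preacts(ref[None])

    # backward multiplier pass: start at the linear output
    mult = np.ones((rows.shape[0], 1))  # d output / d h3 chain
    mult = mult @ p["W4"].T  # (n, 16)
    for layer in (3, 2, 1):
        mult = mult * _secant(z_rows[layer], z_ref[layer], kind)
        mult = mult @ p[f"W{layer}"].T
    mult = mult * _secant(z_rows[0], z_ref[0], kind)  # (n, F) at aggregation
    attrib = np.concatenate(
        [p["agg"][0] * mult, p["agg"][1] * mult, p["agg"][2] * mult], axis=1
    ) * (rows - ref)

    delta = forward_single(model, task, rows) - float(
        forward_single(model, task, ref[None])[0]
    )
    err = np.abs(attrib.sum(axis=1) - delta) / np.maximum(1.0, np.abs(delta))
    bad = err > completeness_tol
    if bad.mean() > max_violations:
        raise ArithmeticError(
            f"attribution completeness violated on {bad.sum()} of "
            f"{len(err)} rows (max rel. err {err.max():.3g})"
        )
    return attrib


def tf_importance(
    gene_id: str,
    tf_ids: list[str],
    attributions: np.ndarray,
    run: int = 0,
    keep_raw: bool = False,
) -> AttributionResult:
    """Aggregate raw attributions to one nonnegative score per TF:
    ``sum_rows |attr(a_sum_k)| + |attr(a_mean_k)| + |attr(x_k)|``."""
    attributions = np.atleast_2d(attributions)
    n_tfs = len(tf_ids)
    if attributions.shape[1] != 3 * n_tfs:
        raise ValueError("attribution width must be 3 * n_tfs")
    absa = np.abs(attributions).sum(axis=0)
    importance = absa[:n_tfs] + absa[n_tfs : 2 * n_tfs] + absa[2 * n_tfs :]
    return AttributionResult(
        gene_id,
        list(tf_ids),
        importance,
        run=run,
        raw_attributions=attributions if keep_raw else None,
    )


def rank_cluster(
    model: MultiTaskModel,
    train: list[TaskDataset],
    reference: ReferenceExample,
    run: int = 0,
    max_rows: int | None = None,
    seed: int = 0,
) -> list[AttributionResult]:
    """Attribute every task of a trained cluster on its training rows (or a
    seeded subsample of ``max_rows``) and return per-gene TF importances."""
    results = []
    rng = np.random.default_rng(seed)
    for t, d in enumerate(train):
        rows = d.inputs
        if max_rows is not None and len(rows) > max_rows:
            rows = rows[rng.choice(len(rows), size=max_rows, replace=False)]
        attrib = attribute(model, t, rows, reference)
        results.append(tf_importance(d.gene_id, d.tf_ids, attrib, run=run))
    return results
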