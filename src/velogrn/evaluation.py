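"""Quantitative evaluation: R² of velocity prediction, recall of known
tissue TFs, and hypergeometric enrichment of set overlaps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "TruthTFSet",
    "r_squared",
    "recall",
    "hypergeom_enrichment",
    "bh_correct",
]


@dataclass
class TruthTFSet:
    """Ground-truth TFs for one tissue/context, restricted to the model's
    input TF universe."""

    label: str
    tfs: set[str]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is not None:
            outside = self.tfs - self.universe
            if outside:
                raise ValueError(
                    f"truth TFs outside the input universe: {sorted(outside)[:5]}"
                )


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (standard form)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 2:
        raise ValueError("y_true and y_pred must be equal-length vectors (n >= 2)")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("y_true is constant; R^2 undefined")
    return 1.0 - float(((y_true - y_pred) ** 2).sum()) / ss_tot


def recall(predicted: set[str], truth: TruthTFSet) -> float:
    """TP / (TP + FN): fraction of ground-truth TFs recovered."""
    if not truth.tfs:
        raise ValueError("truth TF set is empty")
    tp = len(predicted & truth.tfs)
    return tp / len(truth.tfs)


def hypergeom_enrichment(n_population: int, k_set1: int, n_set2: int, x_overlap: int) -> float:
    """Upper-tail overlap p-value P(X >= x) for
    X ~ Hypergeometric(N, K, n), evaluated in log-space.

    The standard over-representation test: from a population of
    ``n_population`` genes, how surprising is observing ``x_overlap`` common
    members between a set of size ``k_set1`` and an independent draw of size
    ``n_set2``.
    """
    if not (0 <= x_overlap <= min(k_set1, n_set2) <= n_population):
        raise ValueError(
            f"inconsistent counts: N={n_population}, K={k_set1}, "
            f"n={n_set2}, x={x_overlap}"
        )
    if x_overlap == 0:
        return 1.0
    # sf(x-1) = P(X >= x); scipy computes the tail stably in log space
    return float(
        np.exp(hypergeom.logsf(x_overlap - 1, n_population, k_set1, n_set2))
    )


def bh_correct(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return np.clip(adj, 0.0, 1.0)
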