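"""Nearly equal-sized gene clustering on velocity profiles.

Parameter sharing across per-gene models is restricted to genes within the
same cluster, so clusters must be balanced: the assignment step of k-means
is replaced by a transportation problem with per-cluster size bounds
(min-cost assignment in the Bradley-Bennett-Demiriz style).  The LP's
constraint matrix is totally unimodular, so the simplex vertex solution is
integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

__all__ = ["ClusterAssignment", "cluster_feature_matrix", "constrained_kmeans"]


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    n_clusters: int
    min_size: int
    max_size: int

    def sizes(self) -> np.ndarray:
        out = np.zeros(self.n_clusters, dtype=int)
        for lbl in self.labels.values():
            out[lbl] += 1
        return out

    def members(self, cluster: int) -> list[str]:
        return sorted(g for g, l in self.labels.items() if l == cluster)


def cluster_feature_matrix(y) -> np.ndarray:
    """Genes x cells feature matrix from a standardized velocity matrix:
    each gene's row is its standardized velocities with missing entries
    imputed as 0 (the post-standardization column mean)."""
    if y.state != "standardized":
        raise ValueError("velocity must be standardized before clustering")
    feats = np.where(y.missing_mask, 0.0, y.values)
    return feats.T.copy()


def _bounded_assignment(
    dist2: np.ndarray, min_size: int, max_size: int
) -> np.ndarray:
    """Solve min sum_ij d2[i,j] z[i,j] s.t. each point in exactly one
    cluster and min_size <= cluster size <= max_size.  Returns labels."""
    n, k = dist2.shape
    c = dist2.ravel()
    # equality: each point assigned once
    rows, cols, data = [], [], []
    for i in range(n):
        for j in range(k):
            rows.append(i)
            cols.append(i * k + j)
            data.append(1.0)
    a_eq = csr_matrix((data, (rows, cols)), shape=(n, n * k))
    b_eq = np.ones(n)
    # inequalities: size <= max ; -size <= -min
    rows, cols, data = [], [], []
    for j in range(k):
        for i in range(n):
            rows.append(j)
            cols.append(i * k + j)
            data.append(1.0)
            rows.append(k + j)
            cols.append(i * k + j)
            data.append(-1.0)
    a_ub = csr_matrix((data, (rows, cols)), shape=(2 * k, n * k))
    b_ub = np.concatenate([np.full(k, max_size), np.full(k, -min_size)])
    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=(0, 1),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"assignment LP failed: {res.message}")
    z = res.x.reshape(n, k)
    labels = np.argmax(z, axis=1)
    # guard against non-vertex solutions (should not happen with HiGHS)
    if not np.allclose(z.max(axis=1), 1.0, atol=1e-6):
        raise RuntimeError("assignment LP returned a fractional solution")
    return labels


def constrained_kmeans(
    features: np.ndarray,
    min_size: int = 24,
    max_size: int = 25,
    n_clusters: int | None = None,
    seed: int = 0,
    max_iter: int = 100,
) -> "tuple[np.ndarray, float]":
    """Size-constrained k-means on a genes x cells feature matrix.

    Alternates a bounded min-cost assignment step with the usual centroid
    update; k-means++ initialization from ``seed``; stops when the
    assignment no longer changes.  Returns (labels, within-cluster SSE).
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n_clusters is None:
        n_clusters = int(np.ceil(n / max_size))
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    if min_size * n_clusters > n:
        raise ValueError(
            f"infeasible size bounds: min_size * n_clusters = "
            f"{min_size * n_clusters} > n_genes = {n}"
        )
    if max_size * n_clusters < n:
        raise ValueError(
            f"infeasible size bounds: max_size * n_clusters = "
            f"{max_size * n_clusters} < n_genes = {n}"
        )

    rng = np.random.default_rng(seed)
    centroids = _kmeanspp(features, n_clusters, rng)
    labels = None
    sse = np.inf
    for _ in range(max_iter):
        d2 = (
            (features**2).sum(axis=1, keepdims=True)
            - 2 * features @ centroids.T
            + (centroids**2).sum(axis=1)
        )
        d2 = np.maximum(d2, 0.0)
        new_labels = _bounded_assignment(d2, min_size, max_size)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(n_clusters):
            mem = features[labels == j]
            if len(mem):
                centroids[j] = mem.mean(axis=0)
        sse = float(
            ((features - centroids[labels]) ** 2).sum()
        )
    return labels, sse


def _kmeanspp(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    d2 = ((x - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = x[rng.integers(n)]
        else:
            centroids[j] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((x - centroids[j]) ** 2).sum(axis=1))
    return centroids


def cluster_genes(
    y,
    min_size: int = 24,
    max_size: int = 25,
    n_clusters: int | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster a standardized velocity matrix's genes into nearly
    equal-sized groups; convenience wrapper returning a
    :class:`ClusterAssignment` keyed by gene id."""
    feats = cluster_feature_matrix(y)
    labels, _ = constrained_kmeans(
        feats, min_size=min_size, max_size=max_size, n_clusters=n_clusters, seed=seed
    )
    k = int(labels.max()) + 1 if len(labels) else 0
    return ClusterAssignment(
        {g: int(l) for g, l in zip(y.gene_ids, labels)},
        n_clusters=k,
        min_size=min_size,
        max_size=max_size,
    )
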