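"""Consensus regulatory network construction from repeated train+rank runs.

For each gene, the regulators are the TFs appearing in the top-k importance
list of *every* round; edge importance is the TF's mean importance across
rounds.  TFs are then ranked globally by out-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attribution import AttributionResult

__all__ = [
    "RegulatoryNetwork",
    "top_k_tfs",
    "build_network",
    "degree_ranking",
]


@dataclass
class RegulatoryNetwork:
    """Edge list of (tf_id, gene_id, mean importance, rounds supporting)."""

    edges: list[tuple[str, str, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [(tf, g) for tf, g, _, _ in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (tf, gene) edges")

    def regulators_of(self, gene_id: str) -> list[str]:
        return sorted(tf for tf, g, _, _ in self.edges if g == gene_id)

    def out_degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for tf, _, _, _ in self.edges:
            deg[tf] = deg.get(tf, 0) + 1
        return deg

    def tfs(self) -> set[str]:
        return {tf for tf, _, _, _ in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


def top_k_tfs(result: AttributionResult, k: int) -> list[str]:
    """The k TFs with largest importance, descending; ties broken by
    lexicographic TF id for reproducibility."""
    if k > len(result.tf_ids):
        raise ValueError(f"k={k} exceeds the {len(result.tf_ids)} input TFs")
    order = sorted(
        range(len(result.tf_ids)),
        key=lambda i: (-result.importance[i], result.tf_ids[i]),
    )
    return [result.tf_ids[i] for i in order[:k]]


def build_network(
    rounds: list[list[AttributionResult]],
    k: int = 50,
) -> RegulatoryNetwork:
    """Intersect each gene's per-round top-k TF sets; an edge's importance
    is the TF's mean importance for that gene across rounds."""
    if not rounds:
        raise ValueError("need at least one round of attribution results")
    universes = {tuple(sorted(r.tf_ids)) for rnd in rounds for r in rnd}
    if len(universes) > 1:
        raise ValueError("attribution rounds use differing TF universes")
    by_gene: dict[str, list[AttributionResult]] = {}
    for rnd in rounds:
        for r in rnd:
            by_gene.setdefault(r.gene_id, []).append(r)
    n_rounds = len(rounds)
    edges: list[tuple[str, str, float, int]] = []
    for gene in sorted(by_gene):
        results = by_gene[gene]
        if len(results) != n_rounds:
            raise ValueError(f"gene {gene!r} missing from some rounds")
        top_sets = [set(top_k_tfs(r, k)) for r in results]
        common = set.intersection(*top_sets)
        tf_index = {t: i for i, t in enumerate(results[0].tf_ids)}
        for tf in sorted(common):
            mean_imp = float(
                np.mean([r.importance[tf_index[tf]] for r in results])
            )
            edges.append((tf, gene, mean_imp, n_rounds))
    return RegulatoryNetwork(edges)


def degree_ranking(net: RegulatoryNetwork) -> list[tuple[str, int]]:
    """TFs ordered by out-degree descending, ties lexicographic."""
    deg = net.out_degrees()
    return sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
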