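"""Readers/writers for the pipeline's on-disk formats.

Matrices travel as MatrixMarket (.mtx) with companion row/column index TSVs,
or as dense TSV; missing velocities are NaN in TSV form.  Networks are TSV
edge lists.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .intervals import GeneAnnotation
from .network import RegulatoryNetwork
from .preprocess import ExpressionMatrix, VelocityMatrix

__all__ = [
    "read_gene_annotation",
    "write_gene_annotation",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_velocity_tsv",
    "write_velocity_tsv",
    "write_matrix_mtx",
    "read_matrix_mtx",
    "write_network",
    "read_network",
    "write_bed",
]

_NET_COLUMNS = ["tf_id", "gene_id", "importance", "n_rounds_supporting"]


def read_gene_annotation(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns {sorted(missing)}")
    return [
        GeneAnnotation(r.gene_id, r.chrom, r.strand, int(r.tss))
        for r in df.itertuples()
    ]


def write_gene_annotation(genes: list[GeneAnnotation], path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss) for g in genes],
        columns=["gene_id", "chrom", "strand", "tss"],
    ).to_csv(path, sep="\t", index=False)


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_expression_tsv(x: ExpressionMatrix, path) -> None:
    pd.DataFrame(x.values, index=x.cell_ids, columns=x.tf_ids).to_csv(
        path, sep="\t", index_label="cell_id"
    )


def read_expression_tsv(path, state: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    return ExpressionMatrix(
        df.to_numpy(float), [str(c) for c in df.index], list(df.columns), state
    )


def write_velocity_tsv(v: VelocityMatrix, path) -> None:
    vals = np.where(v.missing_mask, np.nan, v.values)
    pd.DataFrame(vals, index=v.cell_ids, columns=v.gene_ids).to_csv(
        path, sep="\t", index_label="cell_id"
    )


def read_velocity_tsv(path, state: str = "raw") -> VelocityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    vals = df.to_numpy(float)
    mask = np.isnan(vals)
    return VelocityMatrix(
        np.nan_to_num(vals),
        mask,
        [str(c) for c in df.index],
        list(df.columns),
        state,
    )


def write_matrix_mtx(values: np.ndarray, row_ids, col_ids, prefix) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.rows.tsv`` / ``.cols.tsv``."""
    mmwrite(f"{prefix}.mtx", csr_matrix(values))
    pd.Series(row_ids).to_csv(f"{prefix}.rows.tsv", sep="\t", index=False, header=False)
    pd.Series(col_ids).to_csv(f"{prefix}.cols.tsv", sep="\t", index=False, header=False)


def read_matrix_mtx(prefix) -> tuple[np.ndarray, list[str], list[str]]:
    values = np.asarray(mmread(f"{prefix}.mtx").todense())
    rows = pd.read_csv(f"{prefix}.rows.tsv", sep="\t", header=None)[0].astype(str)
    cols = pd.read_csv(f"{prefix}.cols.tsv", sep="\t", header=None)[0].astype(str)
    return values, rows.tolist(), cols.tolist()


def write_network(net: RegulatoryNetwork, path) -> None:
    """Edge-list TSV; importances serialized with 8 significant digits
    (parse-back agrees within 1e-6 relative)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_NET_COLUMNS) + "\n")
        for tf, gene, imp, n in net.edges:
            fh.write(f"{tf}\t{gene}\t{imp:.8g}\t{n}\n")


def read_network(path) -> RegulatoryNetwork:
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _NET_COLUMNS:
            raise ValueError(f"unexpected network header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 fields")
            try:
                edges.append(
                    (fields[0], fields[1], float(fields[2]), int(fields[3]))
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return RegulatoryNetwork(edges)
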