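"""Genomic intervals, promoter windows and chromatin-accessibility-weighted
TF activity scores.

A transcription factor's activity toward a gene is summarised from two
sources: (i) the TF's ChIP-seq binding sites that fall inside the gene's
promoter window, and (ii) the open-chromatin (scATAC-seq) peaks that overlap
those sites.  For each binding site the score ``S`` is the fraction of the
site's basepairs covered by open chromatin; per (TF, gene) pair these are
summed (``a_sum``) and averaged over the ``m`` sites (``a_mean``).

All coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "PeakSet",
    "BindingSiteCatalog",
    "ActivityMatrices",
    "read_bed",
    "promoter_window",
    "assign_sites_to_promoters",
    "site_overlap_fraction",
    "compute_activity",
    "compute_activity_per_cell",
    "scale_activity",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene identity plus the strand-aware transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be nonnegative")


class PeakSet:
    """A collection of genomic intervals, optionally carrying a per-cell
    assignment (cell id -> indices of the peaks whose reads came from that
    cell) for joint accessibility/expression assays.

    ``normalized`` means the intervals are sorted per chromosome and merged
    so they are mutually non-overlapping — the precondition for coverage
    computations that must not double count.
    """

    def __init__(
        self,
        intervals: list[GenomicInterval],
        cell_assignment: dict[str, list[int]] | None = None,
        normalized: bool = False,
    ) -> None:
        self.intervals = list(intervals)
        self.cell_assignment = cell_assignment
        self.normalized = normalized
        if cell_assignment is not None:
            n = len(self.intervals)
            for cell, idx in cell_assignment.items():
                bad = [i for i in idx if i < 0 or i >= n]
                if bad:
                    raise ValueError(
                        f"cell {cell!r} references unknown peak indices {bad}"
                    )
        self._by_chrom: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def merge(self) -> "PeakSet":
        """Sort per chromosome and merge overlapping/adjacent-overlap peaks.

        Idempotent.  The per-cell assignment is dropped (it refers to the
        original peak indices); subset per cell *before* merging.
        """
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        merged: list[GenomicInterval] = []
        for chrom in sorted(by_chrom):
            spans = sorted(by_chrom[chrom])
            out: list[list[int]] = []
            for s, e in spans:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged.extend(GenomicInterval(chrom, s, e) for s, e in out)
        return PeakSet(merged, normalized=True)

    def _chrom_arrays(self) -> dict[str, np.ndarray]:
        if self._by_chrom is None:
            by: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                by.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._by_chrom = {
                c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
                for c, v in by.items()
            }
        return self._by_chrom

    def subset(self, indices: list[int]) -> "PeakSet":
        return PeakSet([self.intervals[i] for i in indices])


@dataclass
class BindingSiteCatalog:
    """Binding sites of each TF assigned to gene promoters.

    ``sites[(tf_id, gene_id)]`` holds the ordered list of that TF's sites
    falling inside the gene's promoter window (``m >= 1`` per stored key).
    """

    sites: dict[tuple[str, str], list[GenomicInterval]]
    tf_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for key, sl in self.sites.items():
            if not sl:
                raise ValueError(f"empty site list stored for {key}")
        if not self.tf_ids:
            self.tf_ids = sorted({tf for tf, _ in self.sites})
        if not self.gene_ids:
            self.gene_ids = sorted({g for _, g in self.sites})


@dataclass
class ActivityMatrices:
    """TF-by-gene activity score matrices.

    ``a_sum[i, j]`` is the summed open-chromatin coverage fraction over the
    ``m`` binding sites of TF ``i`` in gene ``j``'s promoter; ``a_mean`` the
    average.  Pre-scaling, ``a_mean`` lies in [0, 1] and
    ``a_sum = m * a_mean``.  ``per_cell`` holds one (a_sum, a_mean) pair per
    cell id when computed in per-cell mode.
    """

    a_sum: np.ndarray
    a_mean: np.ndarray
    tf_ids: list[str]
    gene_ids: list[str]
    mode: str = "tissue"
    per_cell: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.mode not in {"tissue", "per_cell"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.a_sum < 0).any() or (self.a_mean < 0).any():
            raise ValueError("activity scores must be nonnegative")


def read_bed(path, dialect: str = "3-column", normalize: bool = False) -> PeakSet:
    """Read a BED3/BED6 file into a :class:`PeakSet`.

    ``normalize=True`` sorts and merges the intervals after parsing.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    intervals: list[GenomicInterval] = []
    if isinstance(path, io.StringIO):
        handle = path
        close = False
    else:
        handle = open(path)
        close = True
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            name = fields[3] if dialect == "6-column" and len(fields) > 3 else None
            strand = (
                fields[5]
                if dialect == "6-column" and len(fields) > 5 and fields[5] in "+-."
                else "."
            )
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()
    peaks = PeakSet(intervals)
    return peaks.merge() if normalize else peaks


def promoter_window(
    gene: GeneAnnotation, upstream: int = 3000, downstream: int = 3000
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clamped at coordinate 0.

    For a + strand gene the window is ``[tss - upstream, tss + downstream)``;
    for a - strand gene up/downstream swap sides.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be nonnegative")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand, gene.gene_id)


def assign_sites_to_promoters(
    raw_sites: dict[str, PeakSet],
    genes: list[GeneAnnotation],
    upstream: int = 3000,
    downstream: int = 3000,
) -> BindingSiteCatalog:
    """Assign each TF binding site to the gene whose promoter window it
    overlaps by >=1 bp; on overlap with several promoters the site goes only
    to the gene with nearest TSS (distance from the site midpoint, ties
    broken by lexicographic gene id).  Unassigned sites are dropped.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    windows = [
        (g, promoter_window(g, upstream, downstream)) for g in genes
    ]
    by_chrom: dict[str, list[tuple[GeneAnnotation, GenomicInterval]]] = {}
    for g, w in windows:
        by_chrom.setdefault(g.chrom, []).append((g, w))

    sites: dict[tuple[str, str], list[GenomicInterval]] = {}
    for tf_id in sorted(raw_sites):
        for site in raw_sites[tf_id].intervals:
            hits = [
                g
                for g, w in by_chrom.get(site.chrom, [])
                if site.start < w.end and w.start < site.end
            ]
            if not hits:
                continue
            best = min(hits, key=lambda g: (abs(site.midpoint - g.tss), g.gene_id))
            sites.setdefault((tf_id, best.gene_id), []).append(site)
    return BindingSiteCatalog(
        sites,
        tf_ids=sorted(raw_sites),
        gene_ids=sorted(g.gene_id for g in genes),
    )


def site_overlap_fraction(site: GenomicInterval, peaks: PeakSet) -> float:
    """The function S: fraction of ``site``'s basepairs covered by the merged
    open-chromatin peaks.  Requires ``peaks.normalized`` so coverage cannot be
    double counted.
    """
    if not peaks.normalized:
        raise ValueError(
            "peaks must be normalized (sorted+merged) before coverage computation"
        )
    arr = peaks._chrom_arrays().get(site.chrom)
    if arr is None or arr.size == 0:
        return 0.0
    starts, ends = arr[:, 0], arr[:, 1]
    ov = np.minimum(ends, site.end) - np.maximum(starts, site.start)
    covered = int(ov[ov > 0].sum())
    return covered / len(site)


def compute_activity(catalog: BindingSiteCatalog, peaks: PeakSet) -> ActivityMatrices:
    """Tissue-mode activity matrices from a site catalog and merged peaks.

    For each stored (TF, gene) pair with ``m`` sites:
    ``a_sum = sum_k S(site_k, peaks)`` and ``a_mean = a_sum / m``.
    Pairs absent from the catalog score 0.
    """
    if not catalog.sites:
        raise ValueError("catalog must be nonempty")
    tf_index = {t: i for i, t in enumerate(catalog.tf_ids)}
    gene_index = {g: j for j, g in enumerate(catalog.gene_ids)}
    a_sum = np.zeros((len(tf_index), len(gene_index)))
    a_mean = np.zeros_like(a_sum)
    for (tf, gene), site_list in catalog.sites.items():
        i, j = tf_index[tf], gene_index[gene]
        s = sum(site_overlap_fraction(site, peaks) for site in site_list)
        a_sum[i, j] = s
        a_mean[i, j] = s / len(site_list)
    return ActivityMatrices(a_sum, a_mean, catalog.tf_ids, catalog.gene_ids)


def compute_activity_per_cell(
    catalog: BindingSiteCatalog, peaks: PeakSet
) -> ActivityMatrices:
    """Per-cell activity: each cell's scores use only the peaks whose reads
    came from that cell (joint accessibility/expression assays).  Cells with
    no peaks score all-zero.
    """
    if peaks.cell_assignment is None:
        raise ValueError("per-cell mode requires a cell_assignment on the peak set")
    per_cell: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_tf, n_gene = len(catalog.tf_ids), len(catalog.gene_ids)
    for cell, idx in peaks.cell_assignment.items():
        if idx:
            cell_peaks = peaks.subset(idx).merge()
            am = compute_activity(catalog, cell_peaks)
            per_cell[cell] = (am.a_sum, am.a_mean)
        else:
            per_cell[cell] = (
                np.zeros((n_tf, n_gene)),
                np.zeros((n_tf, n_gene)),
            )
    # the tissue-level aggregate (all peaks) kept as the dense face
    aggregate = compute_activity(catalog, peaks.merge())
    return ActivityMatrices(
        aggregate.a_sum,
        aggregate.a_mean,
        catalog.tf_ids,
        catalog.gene_ids,
        mode="per_cell",
        per_cell=per_cell,
    )


def scale_activity(a: ActivityMatrices) -> ActivityMatrices:
    """Apply the ``log2(x + 1)`` transform to both matrices (and per-cell
    payloads).  Refuses to scale twice.
    """
    if a.scaled:
        raise ValueError("activity matrices already scaled")
    per_cell = None
    if a.per_cell is not None:
        per_cell = {
            c: (np.log2(s + 1.0), np.log2(m + 1.0))
            for c, (s, m) in a.per_cell.items()
        }
    return ActivityMatrices(
        np.log2(a.a_sum + 1.0),
        np.log2(a.a_mean + 1.0),
        list(a.tf_ids),
        list(a.gene_ids),
        mode=a.mode,
        per_cell=per_cell,
        scaled=True,
    )
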