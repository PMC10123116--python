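"""Self-contained synthetic data with a planted TF->gene network.

The generator emits every input the pipeline consumes: a planted
coefficient matrix B (exactly ``k_per_gene`` regulator TFs per gene),
cells x TFs raw expression, cells x genes velocities with per-gene
missingness, and a toy genome (gene annotation, open-chromatin peaks and
per-TF binding-site tracks) in which each true regulator's binding site
overlaps its target's promoter *and* an open peak, while non-regulators get
promoter sites without peak overlap — so the activity scores carry the same
signal as the expression.

Velocities are linear in the *transformed* (log10, standardized)
expressions plus Gaussian noise, so a noiseless, fully observed draw is
exactly linearly recoverable.  ``link='tanh'`` substitutes a saturating
response for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GeneAnnotation, GenomicInterval, PeakSet
from .preprocess import ExpressionMatrix, VelocityMatrix, log_rpkm, standardize_columns

__all__ = ["SyntheticTruth", "simulate_truth", "simulate_data", "apply_dropout"]


@dataclass
class SyntheticTruth:
    """Planted regulatory coefficients and generative noise parameters."""

    coefficients: np.ndarray  # (n_tfs, n_genes), k_per_gene nonzeros per column
    tf_ids: list[str]
    gene_ids: list[str]
    k_per_gene: int
    noise_sd: float
    missing_rate: float
    dropout_rate: float
    seed: int
    link: str = "linear"

    def __post_init__(self) -> None:
        nz = (self.coefficients != 0).sum(axis=0)
        if not np.all(nz == self.k_per_gene):
            raise ValueError("every gene column must have exactly k_per_gene nonzeros")

    def regulators_of(self, gene_id: str) -> set[str]:
        j = self.gene_ids.index(gene_id)
        return {
            self.tf_ids[i]
            for i in np.flatnonzero(self.coefficients[:, j])
        }


def simulate_truth(
    n_tfs: int = 50,
    n_genes: int = 30,
    k_per_gene: int = 5,
    effect_range: tuple[float, float] = (0.5, 2.0),
    noise_sd: float = 0.5,
    missing_rate: float = 0.3,
    dropout_rate: float = 0.0,
    seed: int = 0,
    regulator_pool: int | None = None,
    link: str = "linear",
) -> SyntheticTruth:
    """Draw a planted network: per gene, ``k_per_gene`` regulators chosen
    uniformly (from all TFs, or from a fixed pool of ``regulator_pool`` TFs
    to induce a shared low-rank structure across tasks), with effect sizes
    uniform on +/-[lo, hi]."""
    if k_per_gene > n_tfs:
        raise ValueError("k_per_gene cannot exceed n_tfs")
    if regulator_pool is not None and not (k_per_gene <= regulator_pool <= n_tfs):
        raise ValueError("regulator_pool must lie in [k_per_gene, n_tfs]")
    lo, hi = effect_range
    if not 0 <= lo <= hi:
        raise ValueError("effect_range must satisfy 0 <= lo <= hi")
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i:03d}" for i in range(n_tfs)]
    gene_ids = [f"G{j:03d}" for j in range(n_genes)]
    pool = (
        rng.choice(n_tfs, size=regulator_pool, replace=False)
        if regulator_pool is not None
        else np.arange(n_tfs)
    )
    b = np.zeros((n_tfs, n_genes))
    for j in range(n_genes):
        regs = rng.choice(pool, size=k_per_gene, replace=False)
        effects = rng.uniform(lo, hi, size=k_per_gene)
        signs = rng.choice([-1.0, 1.0], size=k_per_gene)
        b[regs, j] = signs * effects
    return SyntheticTruth(
        b,
        tf_ids,
        gene_ids,
        k_per_gene,
        noise_sd,
        missing_rate,
        dropout_rate,
        seed,
        link,
    )


def _toy_genome(
    truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[list[GeneAnnotation], PeakSet, dict[str, PeakSet]]:
    """One chromosome; genes 20 kb apart; per promoter one slot per TF.
    Regulator sites get an open peak covering 25-100% of the site."""
    n_tfs = len(truth.tf_ids)
    genes = [
        GeneAnnotation(g, "chr1", "+", 10_000 + 20_000 * j)
        for j, g in enumerate(truth.gene_ids)
    ]
    spacing = max(12, 5_700 // n_tfs)
    width = max(10, spacing - 10)
    peak_spans: list[GenomicInterval] = []
    sites: dict[str, list[GenomicInterval]] = {t: [] for t in truth.tf_ids}
    for j, gene in enumerate(genes):
        lo = gene.tss - 2_900
        for k, tf in enumerate(truth.tf_ids):
            start = lo + spacing * k
            site = GenomicInterval("chr1", start, start + width)
            sites[tf].append(site)
            if truth.coefficients[k, j] != 0:
                frac = rng.uniform(0.25, 1.0)
                cov = max(1, int(round(frac * width)))
                peak_spans.append(GenomicInterval("chr1", start, start + cov))
    peaks = PeakSet(peak_spans).merge()
    return genes, peaks, {t: PeakSet(s) for t, s in sites.items()}


def simulate_data(
    truth: SyntheticTruth, n_cells: int = 2000, seed: int = 0
) -> tuple[
    ExpressionMatrix,
    VelocityMatrix,
    PeakSet,
    dict[str, PeakSet],
    list[GeneAnnotation],
]:
    """Draw one dataset under the planted truth.

    Raw expression is log-normal-like (10**z, z standard normal), so the
    pipeline's log10(x+1) transform approximately recovers z.  Velocity for
    gene g in cell c is ``sum_k B[k, g] * e[c, k] + eps`` where ``e`` is the
    transformed-and-standardized expression and eps ~ N(0, noise_sd);
    entries go missing independently at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    n_tfs, n_genes = truth.coefficients.shape
    cell_ids = [f"cell{c:05d}" for c in range(n_cells)]
    z = rng.standard_normal((n_cells, n_tfs))
    raw = np.power(10.0, z)
    expr = ExpressionMatrix(raw, cell_ids, list(truth.tf_ids), state="raw")

    e = standardize_columns(log_rpkm(expr).values)
    signal = e @ truth.coefficients
    if truth.link == "tanh":
        signal = np.tanh(signal)
    noise = truth.noise_sd * rng.standard_normal((n_cells, n_genes))
    y = signal + noise
    mask = rng.random((n_cells, n_genes)) < truth.missing_rate
    velocity = VelocityMatrix(
        y, mask, list(cell_ids), list(truth.gene_ids), state="raw"
    )
    genes, peaks, site_tracks = _toy_genome(truth, rng)
    return expr, velocity, peaks, site_tracks, genes


def apply_dropout(
    x: ExpressionMatrix, rate: float, seed: int = 0
) -> ExpressionMatrix:
    """Zero each raw expression entry independently with probability
    ``rate`` (scRNA-seq capture drop-out), before the log transform."""
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must be in [0, 1)")
    if x.state != "raw":
        raise ValueError("dropout applies to raw expression only")
    if rate == 0:
        return ExpressionMatrix(
            x.values.copy(), list(x.cell_ids), list(x.tf_ids), "raw"
        )
    rng = np.random.default_rng(seed)
    mask = rng.random(x.values.shape) < rate
    values = np.where(mask, 0.0, x.values)
    return ExpressionMatrix(values, list(x.cell_ids), list(x.tf_ids), "raw")
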