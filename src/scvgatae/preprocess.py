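"""Quality control and feature extraction for UMI count matrices.

The fixed pipeline order is qc_filter -> normalize_log -> select_hvg ->
scale_clip -> pca_reduce, producing the preprocessed expression matrix X
(n cells x m genes) and its PCA reduction Y (n x d). All standard deviations
use the population convention (ddof=0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA

from .config import RunConfig
from .io import RawCountMatrix


@dataclass
class FeatureMatrix:
    """Preprocessed expression X (n x m) and optional PCA scores Y (n x d)."""

    X: np.ndarray
    kept_cell_ids: list
    kept_gene_ids: list
    Y: Optional[np.ndarray] = None
    d: Optional[int] = None

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]


def qc_filter(
    counts: RawCountMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
) -> RawCountMatrix:
    """Drop low-coverage cells, then genes rare among the surviving cells.

    A gene is "expressed" in a cell when its count is positive. Cells are
    filtered first; gene support is then recomputed on the remaining cells.
    """
    values = np.asarray(counts.values)
    genes_per_cell = (values > 0).sum(axis=1)
    keep_cells = genes_per_cell >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError(
            f"min_genes_per_cell={min_genes_per_cell} removed every cell"
        )
    values = values[keep_cells]
    cells_per_gene = (values > 0).sum(axis=0)
    keep_genes = cells_per_gene >= min_cells_per_gene
    if not keep_genes.any():
        raise ValueError(
            f"min_cells_per_gene={min_cells_per_gene} removed every gene"
        )
    return RawCountMatrix(
        values[:, keep_genes],
        [c for c, k in zip(counts.cell_ids, keep_cells) if k],
        [g for g, k in zip(counts.gene_ids, keep_genes) if k],
    )


def normalize_log(
    counts: RawCountMatrix,
    total_normalize: bool = True,
    target_sum: float = 1e4,
) -> FeatureMatrix:
    """Per-cell total-count normalization (optional) followed by log1p."""
    values = np.asarray(counts.values, dtype=float)
    if total_normalize:
        totals = values.sum(axis=1)
        if (totals == 0).any():
            raise ValueError(
                "cell with zero total count; run qc_filter before normalizing"
            )
        values = values * (target_sum / totals)[:, None]
    X = np.log1p(values)
    return FeatureMatrix(X, list(counts.cell_ids), list(counts.gene_ids))


def _normalized_dispersion(X: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned dispersion z-scores of log-space expression.

    Dispersion is variance/mean per gene; genes are binned by mean expression
    and the dispersion is z-scored within each bin (population std). Bins
    where the dispersion is constant score 0.
    """
    mean = X.mean(axis=0)
    var = X.var(axis=0)  # ddof=0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    # quantile bins on the means so each bin is populated
    edges = np.quantile(mean, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.digitize(mean, edges)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        idx = bins == b
        mu, sd = disp[idx].mean(), disp[idx].std()
        if sd > 0:
            z[idx] = (disp[idx] - mu) / sd
    return z


def select_hvg(fm: FeatureMatrix, n_top: int = 2000) -> FeatureMatrix:
    """Keep the n_top genes by normalized dispersion; pass through if m <= n_top."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    m = fm.X.shape[1]
    if m <= n_top:
        return fm
    z = _normalized_dispersion(fm.X)
    # rank by z-score, break z ties by raw dispersion (so zero-dispersion
    # genes in singleton bins never outrank variable ones), then by index
    mean = fm.X.mean(axis=0)
    with np.errstate(invalid="ignore"):
        disp = np.where(mean > 0, fm.X.var(axis=0) / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.lexsort((np.arange(m), -disp, -z))[:n_top]
    keep = np.sort(order)
    return FeatureMatrix(
        fm.X[:, keep],
        list(fm.kept_cell_ids),
        [fm.kept_gene_ids[i] for i in keep],
    )


def scale_clip(fm: FeatureMatrix, max_value: float = 10.0) -> FeatureMatrix:
    """Z-score each gene (population std; zero-variance genes set to 0), then
    clip values above max_value."""
    X = fm.X
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    scaled = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return FeatureMatrix(
        np.minimum(scaled, max_value), list(fm.kept_cell_ids), list(fm.kept_gene_ids)
    )


def pca_reduce(fm: FeatureMatrix, d: int = 50, seed: int = 0) -> FeatureMatrix:
    """Top-d principal-component scores of mean-centered X.

    The sign of each component is fixed by making its largest-magnitude
    loading positive, so results are deterministic across runs and solvers.
    """
    n, m = fm.X.shape
    if d > min(n, m):
        raise ValueError(f"d={d} exceeds min(n, m)={min(n, m)}")
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    Y = pca.fit_transform(fm.X)
    comps = pca.components_
    flip = np.sign(comps[np.arange(d), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Y = Y * flip
    return FeatureMatrix(
        fm.X, list(fm.kept_cell_ids), list(fm.kept_gene_ids), Y=Y, d=d
    )


def preprocess(counts: RawCountMatrix, cfg: RunConfig) -> FeatureMatrix:
    """Full preprocessing chain from raw counts to (X, Y) under a config."""
    counts = qc_filter(counts, cfg.min_genes_per_cell, cfg.min_cells_per_gene)
    fm = normalize_log(counts, cfg.total_normalize, cfg.target_sum)
    fm = select_hvg(fm, cfg.n_top_hvg)
    fm = scale_clip(fm, cfg.scale_max)
    d = min(cfg.pca_dim, min(fm.X.shape) - 1)
    return pca_reduce(fm, d=d, seed=cfg.seed)
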