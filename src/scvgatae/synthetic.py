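"""Synthetic scRNA-seq data: clustered negative-binomial counts with dropout.

The generator plants k cell clusters by up-shifting a disjoint marker-gene
set per cluster, draws counts from a gamma-Poisson (negative binomial) with
log-normal per-gene baseline means, and then masks entries to zero
independently to emulate dropout. The default spec is the study condition the
test suite and the acceptance run are measured under: 300 cells, 1000 genes,
3 equally sized clusters, 10% marker genes per cluster with a log-fold change
of 2, NB dispersion 0.3, and 30% dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import LabelVector, RawCountMatrix


@dataclass
class SimulationSpec:
    n_cells: int = 300
    n_genes: int = 1000
    k_clusters: int = 3
    cluster_proportions: Optional[Sequence[float]] = None
    baseline_mean: float = 1.0       # scale of the log-normal gene means
    de_fraction: float = 0.1         # marker genes per cluster, as a fraction
    de_log_fold: float = 2.0         # natural-log fold change of markers
    nb_dispersion: float = 0.3       # NB variance = mu + dispersion * mu^2
    dropout_rate: float = 0.3        # independent forced-zero probability
    seed: int = 0

    def __post_init__(self):
        if self.k_clusters > self.n_cells:
            raise ValueError("more clusters than cells")
        if self.cluster_proportions is None:
            self.cluster_proportions = [1.0 / self.k_clusters] * self.k_clusters
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.k_clusters or not np.isclose(props.sum(), 1.0):
            raise ValueError("cluster_proportions must sum to 1, one per cluster")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")


def generate_counts(spec: SimulationSpec) -> tuple[RawCountMatrix, LabelVector]:
    """Draw a clustered count matrix and its planted labels."""
    rng = np.random.default_rng(spec.seed)
    n, m, k = spec.n_cells, spec.n_genes, spec.k_clusters

    sizes = np.floor(np.asarray(spec.cluster_proportions) * n).astype(int)
    sizes[: n - sizes.sum()] += 1  # distribute the remainder
    labels = np.repeat(np.arange(k), sizes)
    rng.shuffle(labels)

    # heavy-tailed baseline expression, typical of UMI data
    base = spec.baseline_mean * rng.lognormal(mean=0.0, sigma=1.0, size=m)

    # disjoint marker sets, one per cluster
    n_markers = int(round(spec.de_fraction * m))
    marker_pool = rng.permutation(m)[: n_markers * k]
    mu = np.tile(base, (n, 1))
    marker_sets = {}
    for c in range(k):
        markers = marker_pool[c * n_markers : (c + 1) * n_markers]
        marker_sets[c] = markers
        mu[np.ix_(labels == c, markers)] *= np.exp(spec.de_log_fold)

    if spec.nb_dispersion > 0:
        shape = 1.0 / spec.nb_dispersion
        lam = rng.gamma(shape, mu * spec.nb_dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)

    if spec.dropout_rate > 0:
        counts = np.where(rng.random(counts.shape) < spec.dropout_rate, 0, counts)

    cell_ids = [f"cell_{i:04d}" for i in range(n)]
    gene_ids = [f"gene_{j:04d}" for j in range(m)]
    matrix = RawCountMatrix(counts, cell_ids, gene_ids)
    return matrix, LabelVector([int(l) for l in labels], cell_ids)


def generate_blobs(n_points: int, k: int, separation: float, dim: int = 2,
                   seed: int = 0) -> tuple[np.ndarray, LabelVector]:
    """Isotropic unit-variance Gaussian clusters with centers `separation`
    apart along random directions; used for metric and Leiden tests."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k, dim))
    norms = np.linalg.norm(centers, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    centers = centers / norms * separation
    labels = np.repeat(np.arange(k), int(np.ceil(n_points / k)))[:n_points]
    points = centers[labels] + rng.standard_normal((n_points, dim))
    return points, LabelVector([int(l) for l in labels])


PRESETS = {
    "easy": SimulationSpec(de_log_fold=3.0, dropout_rate=0.1),
    "medium": SimulationSpec(),
    "hard": SimulationSpec(de_log_fold=1.0, dropout_rate=0.5, k_clusters=5),
}
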