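"""Clustering quality metrics: silhouette coefficient, adjusted Rand index,
and normalized mutual information, implemented from their defining formulas.

Conventions for degenerate inputs: a zero ARI denominator (both partitions
trivial) scores 1.0; NMI with zero total entropy scores 1.0 and with zero
mutual information scores 0.0; silhouette of a singleton-cluster cell is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class ContingencyTable:
    """Shared-count table between two partitions of the same cells."""

    n_ij: np.ndarray  # k_true x k_pred
    a_i: np.ndarray   # row sums
    b_j: np.ndarray   # column sums
    n: int

    @classmethod
    def from_labels(cls, true_labels, pred_labels) -> "ContingencyTable":
        true_labels = np.asarray(true_labels)
        pred_labels = np.asarray(pred_labels)
        if true_labels.shape != pred_labels.shape:
            raise ValueError("label vectors differ in length")
        if true_labels.size == 0:
            raise ValueError("empty label vectors")
        _, ti = np.unique(true_labels, return_inverse=True)
        _, pi = np.unique(pred_labels, return_inverse=True)
        table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
        np.add.at(table, (ti, pi), 1)
        return cls(table, table.sum(axis=1), table.sum(axis=0), int(table.sum()))


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def ari(true_labels, pred_labels) -> float:
    """Adjusted Rand index via pair counting on the contingency table.

    1.0 is a perfect match; 0 is the chance expectation; negative values
    indicate worse-than-chance agreement.
    """
    ct = ContingencyTable.from_labels(true_labels, pred_labels)
    sum_ij = _comb2(ct.n_ij).sum()
    sum_a = _comb2(ct.a_i).sum()
    sum_b = _comb2(ct.b_j).sum()
    total = _comb2(np.array(ct.n)).item()
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    denom = max_index - expected
    if denom == 0:
        return 1.0
    return float((sum_ij - expected) / denom)


def nmi(true_labels, pred_labels) -> float:
    """Normalized mutual information 2*MI/(H(U)+H(V)), natural logs."""
    ct = ContingencyTable.from_labels(true_labels, pred_labels)
    n = ct.n
    pij = ct.n_ij / n
    pa = ct.a_i / n
    pb = ct.b_j / n
    outer = np.outer(pa, pb)
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / outer[nz])).sum())
    h_u = float(-(pa[pa > 0] * np.log(pa[pa > 0])).sum())
    h_v = float(-(pb[pb > 0] * np.log(pb[pb > 0])).sum())
    if h_u + h_v == 0:
        return 1.0
    if mi <= 0:
        return 0.0
    return 2.0 * mi / (h_u + h_v)


def silhouette(Z: np.ndarray, labels) -> float:
    """Mean silhouette coefficient s = (b - a) / max(a, b) over all cells.

    a is the mean Euclidean distance to the other members of the cell's own
    cluster; b is the smallest mean distance to any other cluster. Cells in
    singleton clusters score 0, as do cells where a = b = 0.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(Z, Z)
    n = Z.shape[0]
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    s = np.zeros(n)
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            continue  # singleton convention: s = 0
        a = D[i, own].sum() / (own.size - 1)
        b = min(D[i, members[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())
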