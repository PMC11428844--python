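"""Denoised cell graph construction.

Chain: Pearson similarity S -> NE transition matrix P (row-stochastic over
each cell's k nearest neighbors) -> local network matrix T -> one diffusion
step S_hat = alpha*T.S.T + (1-alpha)*T -> threshold mask giving E (original S
weights kept where S_hat clears t) -> kNN sparsification and row
normalization giving the symmetric cell graph A.

Everything here is a deterministic function of its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import RunConfig


@dataclass
class SimilarityBundle:
    """The matrices of the network-enhancement denoising chain (all n x n)."""

    S: np.ndarray
    P: np.ndarray
    T: np.ndarray
    S_hat: np.ndarray
    E: np.ndarray
    k_ne: int
    alpha: float
    t: float


@dataclass
class CellGraph:
    """Final nonnegative symmetric adjacency with zero diagonal."""

    A: np.ndarray
    k_graph: int


def pearson_similarity(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of cell rows, negatives clipped to 0,
    diagonal zeroed. Constant rows get zero similarity to everything."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to build a graph")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features for correlation")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    S = (centered @ centered.T) / np.outer(safe, safe)
    S[constant, :] = 0.0
    S[:, constant] = 0.0
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 0.0)
    return (S + S.T) / 2.0  # exact symmetry against float noise


def _topk_neighbors(row: np.ndarray, k: int, self_idx: int) -> np.ndarray:
    """Indices of the k largest entries of row, excluding self_idx; ties break
    toward the lower index."""
    order = np.lexsort((np.arange(row.size), -row))
    order = order[order != self_idx]
    return order[:k]


def ne_transition(S: np.ndarray, k_ne: int = 10) -> np.ndarray:
    """Row-stochastic transition matrix restricted to each cell's k_ne
    strongest similarities. All-zero rows fall back to uniform weights over
    the (arbitrary, lowest-index) k_ne neighbors."""
    n = S.shape[0]
    if not 1 <= k_ne < n:
        raise ValueError(f"k_ne={k_ne} must satisfy 1 <= k_ne < n={n}")
    P = np.zeros_like(S, dtype=float)
    for i in range(n):
        nbrs = _topk_neighbors(S[i], k_ne, i)
        total = S[i, nbrs].sum()
        if total > 0:
            P[i, nbrs] = S[i, nbrs] / total
        else:
            warnings.warn(f"cell {i} has an all-zero similarity row; "
                          "using uniform transition weights")
            P[i, nbrs] = 1.0 / k_ne
    return P


def ne_local_network(P: np.ndarray) -> np.ndarray:
    """Local network matrix T_ij = sum_k P_ik P_jk / colsum_k(P); columns of P
    with zero sum contribute nothing (0/0 read as 0)."""
    colsum = P.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(f"{int(zero_cols.sum())} empty transition columns skipped")
    inv = np.where(zero_cols, 0.0, 1.0 / np.where(zero_cols, 1.0, colsum))
    T = (P * inv) @ P.T
    return (T + T.T) / 2.0


def ne_diffuse(T: np.ndarray, S: np.ndarray, alpha: float = 0.5,
               iterations: int = 1) -> np.ndarray:
    """Diffusion update S_hat = alpha*T.S.T + (1-alpha)*T, applied
    `iterations` times (the published chain uses a single step)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    S_hat = S
    for _ in range(max(1, iterations)):
        S_hat = alpha * (T @ S_hat @ T) + (1.0 - alpha) * T
    return S_hat


def ne_threshold(S: np.ndarray, S_hat: np.ndarray, t: float) -> np.ndarray:
    """Keep the original similarity S_ij wherever the diffused value clears
    the threshold; symmetrize by elementwise max and zero the diagonal."""
    E = np.where(S_hat >= t, S, 0.0)
    E = np.maximum(E, E.T)
    np.fill_diagonal(E, 0.0)
    if (E.sum(axis=1) == 0).any():
        warnings.warn("threshold left isolated cells; kNN fallback to S applies")
    return E


def resolve_threshold(S_hat: np.ndarray, quantile: Optional[float] = 0.9,
                      absolute: Optional[float] = None) -> float:
    """Threshold t for the mask: an absolute value if given, otherwise a
    quantile of the off-diagonal diffused similarities."""
    if absolute is not None:
        if absolute < 0:
            raise ValueError("absolute threshold must be >= 0")
        return float(absolute)
    if not 0.0 <= quantile < 1.0:
        raise ValueError("threshold quantile must be in [0, 1)")
    off = S_hat[~np.eye(S_hat.shape[0], dtype=bool)]
    return float(np.quantile(off, quantile))


def build_cell_graph(E: np.ndarray, S: np.ndarray, k_graph: int = 15) -> CellGraph:
    """kNN sparsification of E (isolated rows rescued from S), row
    normalization, then symmetrization by averaging."""
    n = E.shape[0]
    if not 1 <= k_graph < n:
        raise ValueError(f"k_graph={k_graph} must satisfy 1 <= k_graph < n={n}")
    A = np.zeros_like(E, dtype=float)
    for i in range(n):
        row = E[i]
        if row.sum() == 0:
            row = S[i]
        nbrs = _topk_neighbors(row, k_graph, i)
        weights = row[nbrs]
        total = weights.sum()
        if total == 0:
            raise ValueError(
                f"cell {i} is disconnected even after falling back to S"
            )
        A[i, nbrs] = weights / total
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    if (A.sum(axis=1) == 0).any():
        raise ValueError("disconnected node in the final cell graph")
    return CellGraph(A, k_graph)


def build_graph(X: np.ndarray, cfg: RunConfig) -> tuple[CellGraph, SimilarityBundle]:
    """Full chain from preprocessed expression X to the cell graph A.

    With ne_enabled=False the denoising is bypassed (E = S), which is the
    no-NE ablation.
    """
    S = pearson_similarity(X)
    if cfg.ne_enabled:
        P = ne_transition(S, cfg.k_ne)
        T = ne_local_network(P)
        S_hat = ne_diffuse(T, S, cfg.ne_alpha, cfg.ne_iterations)
        t = resolve_threshold(S_hat, cfg.ne_threshold_quantile, cfg.ne_threshold_abs)
        E = ne_threshold(S, S_hat, t)
    else:
        P = np.zeros_like(S)
        T = np.zeros_like(S)
        S_hat = S
        t = 0.0
        E = S.copy()
    bundle = SimilarityBundle(S=S, P=P, T=T, S_hat=S_hat, E=E,
                              k_ne=cfg.k_ne, alpha=cfg.ne_alpha, t=t)
    graph = build_cell_graph(E, S, min(cfg.k_graph, S.shape[0] - 1))
    return graph, bundle


def export_edge_list(graph: CellGraph, path) -> None:
    """Write the upper-triangle edges of A as a TSV (i, j, weight)."""
    A = graph.A
    ii, jj = np.nonzero(np.triu(A, k=1))
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{A[i, j]:.10g}\n")
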