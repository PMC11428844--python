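"""Training with silhouette-based adaptive stopping, Leiden cluster-count
estimation, and k-means clustering of the latent embedding.

The training loop takes full-batch Adam steps on the composite loss. Every
check_interval epochs the evaluation-mode embedding (Z = mu) is clustered
with k-means and scored by the silhouette coefficient; the best-scoring
checkpoint is kept and training stops once the score has stayed more than
drop_tolerance below the best for patience_checks consecutive checks. Setting
fixed_epochs disables the checks entirely (the fixed-epoch ablation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import igraph as ig
import leidenalg
import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .autograd import Adam
from .config import RunConfig
from .graph import CellGraph
from .metrics import silhouette
from .model import VGATAE


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    source: str  # {"kmeans", "leiden"}

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)
    losses: list = field(default_factory=list)
    silhouettes: list = field(default_factory=list)  # (epoch, score) pairs
    best_epoch: Optional[int] = None
    stopped_early: bool = False

    def save_tsv(self, path) -> None:
        sil = dict(self.silhouettes)
        with open(path, "w") as fh:
            fh.write("epoch\tloss\tsilhouette\n")
            for e, l in zip(self.epochs, self.losses):
                s = sil.get(e)
                fh.write(f"{e}\t{l:.8g}\t{'' if s is None else f'{s:.8g}'}\n")


def estimate_num_clusters(Y: np.ndarray, neighbors: int = 15,
                          resolution: float = 1.0, seed: int = 0,
                          n_clusters: Optional[int] = None) -> int:
    """Cluster count from Leiden community detection on a kNN graph of Y.

    An explicit n_clusters overrides the estimate.
    """
    if n_clusters is not None:
        return int(n_clusters)
    n = Y.shape[0]
    if n < neighbors + 1:
        raise ValueError(f"need at least {neighbors + 1} cells for "
                         f"{neighbors} neighbors")
    nn = NearestNeighbors(n_neighbors=neighbors + 1).fit(Y)
    _, idx = nn.kneighbors(Y)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed,
    )
    return len(set(part.membership))


def kmeans_cluster(Z: np.ndarray, k: int, seed: int = 0,
                   restarts: int = 20) -> ClusterAssignment:
    """k-means++ with `restarts` initializations; deterministic given seed."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > Z.shape[0]:
        raise ValueError("k exceeds the number of cells")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(np.asarray(Z, dtype=float))
    return ClusterAssignment(labels, k, "kmeans")


def train(Y: np.ndarray, graph: CellGraph, model: VGATAE, cfg: RunConfig,
          k: int) -> tuple[VGATAE, np.ndarray, TrainingHistory]:
    """Optimize the model on (Y, A); returns the best-checkpoint model, its
    evaluation-mode embedding, and the loss/silhouette history."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.param_list(), lr=cfg.learning_rate)
    target = Y if model.decoder_kind == "gat" else graph.A
    history = TrainingHistory()

    n_epochs = cfg.fixed_epochs if cfg.fixed_epochs else cfg.max_epochs
    adaptive = cfg.fixed_epochs is None and k >= 2

    best_sil = -np.inf
    best_state = model.state()
    best_epoch = 0
    bad_checks = 0

    for epoch in range(1, n_epochs + 1):
        recon, mu, log_sigma, _ = model.forward(
            Y, graph, rng=rng, training=True, add_self_loops=True
        )
        total, value = model.loss(target, recon, mu, log_sigma)
        if not np.isfinite(value.total):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        opt.zero_grad()
        total.backward()
        opt.step()
        history.epochs.append(epoch)
        history.losses.append(value.total)

        if adaptive and epoch % cfg.check_interval == 0:
            _, mu_eval, _, _ = model.forward(Y, graph, training=False)
            Z = mu_eval.data
            labels = kmeans_cluster(Z, k, cfg.seed, cfg.kmeans_restarts).labels
            score = silhouette(Z, labels)
            history.silhouettes.append((epoch, score))
            if score > best_sil:
                best_sil = score
                best_state = model.state()
                best_epoch = epoch
                bad_checks = 0
            elif score < best_sil - cfg.drop_tolerance:
                bad_checks += 1
                if bad_checks >= cfg.patience_checks:
                    history.stopped_early = True
                    break
            else:
                bad_checks = 0

    if adaptive and history.silhouettes:
        model.set_state(best_state)
        history.best_epoch = best_epoch
    else:
        history.best_epoch = history.epochs[-1] if history.epochs else 0

    _, mu_eval, _, _ = model.forward(Y, graph, training=False)
    return model, mu_eval.data, history
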