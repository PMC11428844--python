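"""End-to-end pipeline: counts -> preprocess -> cell graph -> VGATAE training
-> k-means clustering -> metrics."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import graph as graph_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import preprocess as pp_mod
from . import train as train_mod
from .config import RunConfig
from .model import VGATAE


@dataclass
class PipelineResult:
    assignment: train_mod.ClusterAssignment
    metrics: dict
    feature_matrix: pp_mod.FeatureMatrix
    graph: graph_mod.CellGraph
    similarity: graph_mod.SimilarityBundle
    model: VGATAE
    Z: np.ndarray
    history: train_mod.TrainingHistory
    k: int
    config: RunConfig


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - tag and re-raise
        raise StageError(name, exc) from exc


def run_pipeline(counts: io_mod.RawCountMatrix, cfg: RunConfig,
                 true_labels: Optional[io_mod.LabelVector] = None,
                 out_dir=None) -> PipelineResult:
    """Run the full clustering pipeline under a config.

    If `true_labels` is given it is aligned to the cells that survive QC and
    ARI/NMI are reported alongside the silhouette; otherwise metrics contain
    the silhouette only. With `out_dir` set, labels, metrics, history, and the
    resolved config are written there.
    """
    cfg = cfg.resolve()
    fm = _stage("preprocess", pp_mod.preprocess, counts, cfg)
    cell_graph, bundle = _stage("cell_graph", graph_mod.build_graph, fm.X, cfg)
    k = _stage(
        "estimate_k", train_mod.estimate_num_clusters, fm.Y,
        neighbors=min(cfg.leiden_neighbors, fm.n_cells - 1),
        resolution=cfg.leiden_resolution, seed=cfg.seed,
        n_clusters=cfg.n_clusters,
    )
    rng = np.random.default_rng(cfg.seed)
    model = VGATAE(fm.Y.shape[1], cfg, rng)
    model, Z, history = _stage("train", train_mod.train, fm.Y, cell_graph,
                               model, cfg, k)
    assignment = _stage("cluster", train_mod.kmeans_cluster, Z, k,
                        cfg.seed, cfg.kmeans_restarts)

    metrics = {}
    if k >= 2:
        metrics["silhouette"] = metrics_mod.silhouette(Z, assignment.labels)
    if true_labels is not None:
        aligned = _stage("align_labels", true_labels.aligned_to, fm.kept_cell_ids)
        metrics["ari"] = metrics_mod.ari(aligned.labels, assignment.labels)
        metrics["nmi"] = metrics_mod.nmi(aligned.labels, assignment.labels)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io_mod.write_results(assignment, metrics, out_dir, fm.kept_cell_ids)
        history.save_tsv(out_dir / "history.tsv")
        cfg.save(out_dir / "config_resolved.yaml")
        model.save(out_dir / "checkpoint.npz")

    return PipelineResult(assignment, metrics, fm, cell_graph, bundle,
                          model, Z, history, k, cfg)
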