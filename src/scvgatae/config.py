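"""Run configuration: every tunable of the pipeline in one flat record.

The config round-trips through a flat YAML file so that each run can log the
fully resolved settings it used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

ABLATIONS = ("none", "no_ne", "no_attention", "all_attention", "fixed_epochs")


@dataclass
class RunConfig:
    # preprocessing
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    total_normalize: bool = True
    target_sum: float = 1e4
    n_top_hvg: int = 2000
    scale_max: float = 10.0
    pca_dim: int = 50

    # cell graph / network enhancement
    ne_enabled: bool = True
    k_ne: int = 10
    ne_alpha: float = 0.5
    ne_iterations: int = 1
    ne_threshold_quantile: float = 0.9
    ne_threshold_abs: Optional[float] = None
    k_graph: int = 15

    # model
    hidden_dim: int = 128
    latent_dim: int = 16
    add_self_loops: bool = True
    gat_heads: int = 1
    leaky_relu_slope: float = 0.2
    loss_alpha: float = 1.0
    loss_beta: float = 1.0
    decoder: str = "gat"  # {"gat", "inner_product"}
    reconstruction: str = "mse"  # {"mse", "mae"}

    # training
    max_epochs: int = 300
    fixed_epochs: Optional[int] = None
    check_interval: int = 10
    drop_tolerance: float = 0.01
    patience_checks: int = 2
    learning_rate: float = 1e-3

    # clustering
    n_clusters: Optional[int] = None
    leiden_neighbors: int = 15
    leiden_resolution: float = 1.0
    kmeans_restarts: int = 20

    # ablation switch; rewrites the fields above in resolve()
    ablation: str = "none"

    seed: int = 0

    def resolve(self) -> "RunConfig":
        """Return a copy with the ablation switch expanded into field values."""
        if self.ablation not in ABLATIONS:
            raise ValueError(
                f"unknown ablation {self.ablation!r}; choose from {ABLATIONS}"
            )
        cfg = dataclasses.replace(self)
        if cfg.ablation == "no_ne":
            cfg.ne_enabled = False
        elif cfg.ablation == "no_attention":
            cfg.decoder = "inner_product"
        elif cfg.ablation == "all_attention":
            pass  # handled by the model builder (GAT encoder)
        elif cfg.ablation == "fixed_epochs":
            if cfg.fixed_epochs is None:
                cfg.fixed_epochs = 180
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
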