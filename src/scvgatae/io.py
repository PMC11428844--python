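"""Readers and writers for count matrices, labels, and clustering results.

Counts are always surfaced cells x genes regardless of on-disk orientation.
Two dialects are covered: 10x-style Matrix Market triplet directories
(matrix.mtx + barcodes + features, conventionally stored genes x cells) and
dense CSV/TSV (assumed cells x genes with a gene-id header row and a leading
cell-id column).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class RawCountMatrix:
    """UMI counts, cells x genes, with unique cell and gene identifiers."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.gene_ids) != m:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {m} matrix columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene ids")
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative entries in count matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelVector:
    """Categorical per-cell labels, aligned to a cell-id order."""

    labels: list
    id_order: Optional[list] = None

    def __post_init__(self):
        self.labels = list(self.labels)
        if self.id_order is not None:
            self.id_order = [str(c) for c in self.id_order]
            if len(self.id_order) != len(self.labels):
                raise ValueError("id_order length differs from labels length")

    def __len__(self) -> int:
        return len(self.labels)

    def aligned_to(self, cell_ids: Sequence[str]) -> "LabelVector":
        """Reorder to the given cell ids (requires id_order); subsetting allowed."""
        cell_ids = [str(c) for c in cell_ids]
        if self.id_order is None:
            if len(self.labels) != len(cell_ids):
                raise ValueError(
                    f"{len(self.labels)} labels for {len(cell_ids)} cells and "
                    "no ids to align by"
                )
            return LabelVector(list(self.labels), list(cell_ids))
        lookup = dict(zip(self.id_order, self.labels))
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise ValueError(f"labels missing for cell ids: {missing[:5]} ...")
        return LabelVector([lookup[c] for c in cell_ids], list(cell_ids))


_MTX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.txt", "barcodes.tsv.gz")
_FEATURE_NAMES = ("features.tsv", "genes.tsv", "features.txt", "features.tsv.gz")


def _find_one(directory: Path, names) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {names} found in {directory}")


def _read_id_column(path: Path) -> list:
    # barcode/feature lists may carry extra tab-separated columns (10x style)
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path, fmt: str, orientation: Optional[str] = None) -> RawCountMatrix:
    """Read a count matrix; returns counts oriented cells x genes.

    Parameters
    ----------
    fmt : {"mtx_dir", "csv", "tsv"}
    orientation : {"cells_by_genes", "genes_by_cells"} or None
        On-disk orientation. Defaults to genes_by_cells for MTX (the 10x
        convention) and cells_by_genes for CSV/TSV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt == "mtx_dir":
        orientation = orientation or "genes_by_cells"
        mat = scipy.io.mmread(_find_one(path, _MTX_NAMES))
        values = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        barcodes = _read_id_column(_find_one(path, _BARCODE_NAMES))
        features = _read_id_column(_find_one(path, _FEATURE_NAMES))
        if orientation == "genes_by_cells":
            values = values.T
        if values.shape != (len(barcodes), len(features)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(barcodes)} barcodes x {len(features)} features"
            )
        return RawCountMatrix(values, barcodes, features)
    if fmt in ("csv", "tsv"):
        orientation = orientation or "cells_by_genes"
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if orientation == "genes_by_cells":
            df = df.T
        return RawCountMatrix(df.to_numpy(), list(df.index), list(df.columns))
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(counts: RawCountMatrix, path, fmt: str = "mtx_dir") -> None:
    """Write counts in the same dialects read_counts reads (round-trip safe)."""
    path = Path(path)
    if fmt == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(counts.values.T)  # genes x cells on disk
        scipy.io.mmwrite(path / "matrix.mtx", sparse, field="integer"
                         if np.issubdtype(counts.values.dtype, np.integer) else "real")
        (path / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
        (path / "features.tsv").write_text("\n".join(counts.gene_ids) + "\n")
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(counts.values, index=counts.cell_ids,
                          columns=counts.gene_ids)
        df.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(path) -> LabelVector:
    """Read per-cell labels: one label per line, or "cell_id,label" pairs.

    Plain labels are taken in matrix row order; keyed labels are realigned to
    the matrix cell ids by the caller via LabelVector.aligned_to.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty label file: {path}")
    # tolerate a header line such as "cell_id,label" or "cell_id,predicted_cluster"
    first = lines[0].lower().replace(" ", "")
    if first.startswith(("cell_id,", "cell,")):
        lines = lines[1:]
        if not lines:
            raise ValueError(f"label file has a header but no rows: {path}")
    if all("," in ln for ln in lines):
        ids, labels = zip(*(ln.split(",", 1) for ln in lines))
        return LabelVector(list(labels), list(ids))
    return LabelVector(lines)


def write_labels(labels: LabelVector, path) -> None:
    path = Path(path)
    if labels.id_order is not None:
        rows = [f"{c},{l}" for c, l in zip(labels.id_order, labels.labels)]
        path.write_text("cell_id,label\n" + "\n".join(rows) + "\n")
    else:
        path.write_text("\n".join(str(l) for l in labels.labels) + "\n")


def write_results(assignment, metrics: dict, out_dir, cell_ids=None) -> None:
    """Write predicted clusters as CSV and metrics as JSON.

    `assignment` is a ClusterAssignment (or any object with .labels); cell ids
    default to row indices when not given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(assignment.labels)
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(len(labels))]
    if len(cell_ids) != len(labels):
        raise ValueError("cell_ids length differs from labels length")
    pd.DataFrame({"cell_id": list(cell_ids), "predicted_cluster": labels}).to_csv(
        out_dir / "clusters.csv", index=False
    )
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump({k: float(v) for k, v in metrics.items()}, fh, indent=2)
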