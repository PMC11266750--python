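"""Cluster marker-gene selection on a cells x genes expression matrix.

A gene is a marker of a cluster when (1) its average expression in the
cluster is at least ``fold`` times its average in all remaining cells
pooled, (2) it is detectable (expression strictly above a threshold) in at
least ``min_frac`` of the cluster's cells, and (3) its per-cluster mean is
strictly highest in that cluster — so a gene can mark at most one cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ClusteredExpression", "find_markers", "load_expression"]


@dataclass
class ClusteredExpression:
    """Nonnegative expression matrix (cells x genes) with per-cell cluster labels."""

    expr: np.ndarray
    cluster: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.cluster = np.asarray(self.cluster)
        if self.expr.ndim != 2:
            raise ValueError("expr must be 2-D (cells x genes)")
        if (self.expr < 0).any():
            raise ValueError("expression values must be >= 0")
        if self.expr.shape != (len(self.cluster), len(self.gene_ids)):
            raise ValueError("expr shape does not match cluster labels / gene ids")


def find_markers(
    data: ClusteredExpression,
    cluster,
    fold: float = 2.5,
    min_frac: float = 0.10,
    detect_threshold: float = 0.0,
) -> list[str]:
    """Marker genes of ``cluster`` under the three-criteria filter.

    Genes with zero expression everywhere outside the cluster are retained
    by the fold criterion whenever their in-cluster mean is positive.
    Requires at least two clusters.
    """
    labels = np.unique(data.cluster)
    if cluster not in labels:
        raise ValueError(f"unknown cluster {cluster!r}")
    if len(labels) < 2:
        raise ValueError("need >= 2 clusters")
    in_mask = data.cluster == cluster
    expr_in = data.expr[in_mask]
    expr_rest = data.expr[~in_mask]

    mean_in = expr_in.mean(axis=0)
    mean_rest = expr_rest.mean(axis=0)
    fold_ok = np.where(mean_rest > 0, mean_in >= fold * mean_rest, mean_in > 0)

    detect_frac = (expr_in > detect_threshold).mean(axis=0)
    detect_ok = detect_frac >= min_frac

    cluster_means = np.stack([data.expr[data.cluster == lab].mean(axis=0) for lab in labels])
    others = cluster_means[[i for i, lab in enumerate(labels) if lab != cluster]]
    highest_ok = mean_in > others.max(axis=0)

    keep = fold_ok & detect_ok & highest_ok
    return [g for g, k in zip(data.gene_ids, keep) if k]


def load_expression(
    matrix_path: str | Path,
    clusters_path: str | Path,
    gene_names: str | Path | None = None,
    cell_names: str | Path | None = None,
) -> ClusteredExpression:
    """Load a dense TSV (cells x genes, header = gene ids, index = cell ids)
    or an MTX matrix with row (cell) and column (gene) name files, plus a
    two-column TSV mapping cell id -> cluster label."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        from scipy.io import mmread

        m = np.asarray(mmread(str(matrix_path)).todense())
        if gene_names is None or cell_names is None:
            raise ValueError("MTX input needs gene and cell name files")
        genes = Path(gene_names).read_text().split()
        cells = Path(cell_names).read_text().split()
        df = pd.DataFrame(m, index=cells, columns=genes)
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    clusters = pd.read_csv(clusters_path, sep="\t", index_col=0).iloc[:, 0]
    clusters = clusters.reindex(df.index)
    if clusters.isna().any():
        raise ValueError("cells missing a cluster label")
    return ClusteredExpression(df.to_numpy(float), clusters.to_numpy(), list(df.columns))
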