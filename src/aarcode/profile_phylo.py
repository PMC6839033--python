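"""From parameter feature tables to dendrograms, unrooted trees and PCA.

The clustering pipeline mirrors classic gene-expression practice: the
feature table holds parameters as rows ("genes") and species/taxa as
columns ("arrays"); rows are mean-centered and scaled, columns scaled,
distances are 1 - Spearman rank correlation, and agglomeration uses
average linkage.  Dendrograms over species are then read as unrooted
topologies and compared with a reference phylogeny by Robinson–Foulds
distance (0 = identical topology).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .seqio import TreeTopology

logger = logging.getLogger(__name__)


def adjust_table(
    ft: pd.DataFrame, tol: float = 1e-10, max_iter: int = 100
) -> pd.DataFrame:
    """Normalize a feature table for clustering.

    Constant (zero-variance) rows — e.g. the 20 RR diagonal entries, all
    exactly 1 — carry no signal and are dropped with a logged list.  The
    remaining table is adjusted by iterating, to a fixed point: (1) center
    each row by its mean, (2) scale each row to unit sum of squares,
    (3) scale each column to unit sum of squares.  Iterating makes the
    operation idempotent, which a single pass is not (column scaling
    perturbs the row means).
    """
    if ft.shape[0] < 2 or ft.shape[1] < 2:
        raise ValueError("feature table needs at least 2 rows and 2 columns")
    if ft.isna().any().any():
        raise ValueError("feature table contains missing values")
    const = ft.std(axis=1, ddof=0) == 0
    if const.any():
        logger.info("dropping %d constant row(s): %s",
                    int(const.sum()), list(ft.index[const])[:10])
    x = ft.loc[~const].to_numpy(dtype=float).copy()
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 informative rows after dropping constants")
    for _ in range(max_iter):
        prev = x.copy()
        x = x - x.mean(axis=1, keepdims=True)
        rn = np.sqrt((x**2).sum(axis=1, keepdims=True))
        rn[rn == 0] = 1.0
        x = x / rn
        cn = np.sqrt((x**2).sum(axis=0, keepdims=True))
        cn[cn == 0] = 1.0
        x = x / cn
        if np.max(np.abs(x - prev)) < tol:
            break
    return pd.DataFrame(x, index=ft.index[~const], columns=ft.columns)


def spearman_distance(ft: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """Pairwise d = 1 - Spearman rho (average ranks for ties).

    ``axis="columns"`` compares species/taxa profiles (the default for tree
    building); ``axis="rows"`` compares parameter profiles.  Constant
    vectors have undefined ranks and raise, naming the offender.
    """
    data = ft if axis == "columns" else ft.T
    if data.shape[0] < 3:
        raise ValueError("need at least 3 observations per vector")
    labels = list(data.columns)
    mat = data.to_numpy(dtype=float)
    stds = mat.std(axis=0)
    for lab, s in zip(labels, stds):
        if s == 0:
            raise ValueError(f"constant vector: {lab!r}")
    ranks = np.apply_along_axis(rankdata, 0, mat)
    rho = np.corrcoef(ranks, rowvar=False)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree over labeled items: scipy linkage matrix + labels."""

    labels: tuple[str, ...]
    merge: np.ndarray  # scipy linkage matrix, shape (n-1, 4)

    @property
    def heights(self) -> np.ndarray:
        return self.merge[:, 2]


def average_linkage_cluster(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA-style average-linkage agglomeration on a given distance matrix.

    The input need not be ultrametric; heights are the average inter-cluster
    distances at each merge.  Labels are sorted lexicographically before
    clustering so that exact ties resolve toward the lexicographically
    smallest member, deterministically across platforms.
    """
    if dist.isna().any().any():
        raise ValueError("distance matrix contains NaN")
    labels = sorted(dist.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    d = dist.loc[labels, labels].to_numpy(dtype=float)
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(labels=tuple(labels), merge=z)


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Newick string of the dendrogram topology (heights discarded)."""
    root = to_tree(dend.merge)

    def walk(node) -> str:
        if node.is_leaf():
            return dend.labels[node.id]
        return f"({walk(node.left)},{walk(node.right)})"

    return walk(root) + ";"


def dendrogram_to_unrooted(dend: Dendrogram) -> TreeTopology:
    """Unrooted topology of a dendrogram (root degree-2 node suppressed)."""
    if len(dend.labels) < 3:
        raise ValueError("need at least 3 leaves for an unrooted topology")
    return TreeTopology.from_newick(dendrogram_to_newick(dend))


def rf_distance(t1: TreeTopology, t2: TreeTopology) -> int:
    """Robinson–Foulds distance: size of the symmetric difference of the
    nontrivial bipartition sets.  0 iff the topologies are identical."""
    if t1.leaves != t2.leaves:
        only1 = sorted(t1.leaves - t2.leaves)
        only2 = sorted(t2.leaves - t1.leaves)
        raise ValueError(
            f"leaf sets differ (only in first: {only1}; only in second: {only2})"
        )
    return len(t1.splits ^ t2.splits)


# ---------------------------------------------------------------------------
# PCA with varimax rotation
# ---------------------------------------------------------------------------


def varimax(loadings: np.ndarray, max_iter: int = 25, tol: float = 1e-6) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal, kaiser-style).

    Iteratively maximizes the summed variance of squared loadings per
    component; capped at *max_iter* sweeps.
    """
    A = np.asarray(loadings, dtype=float).copy()
    p, k = A.shape
    R = np.eye(k)
    var_prev = 0.0
    for _ in range(max_iter):
        L = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (L**3 - (L * np.sum(L**2, axis=0)) / p)
        )
        R = u @ vt
        var = s.sum()
        if var_prev != 0 and var - var_prev < tol * var_prev:
            break
        var_prev = var
    return A @ R


def varimax_criterion(loadings: np.ndarray) -> float:
    """The varimax objective: summed per-column variance of squared loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame          # variables x components (unrotated)
    rotated_loadings: pd.DataFrame  # variables x components (varimax)
    scores: pd.DataFrame            # observations x components
    explained_variance_ratio: np.ndarray
    cumulative_variance: np.ndarray

    @property
    def total_variance_pct(self) -> float:
        """Percent of total variance captured by the retained components."""
        return 100.0 * float(self.explained_variance_ratio.sum())


def pca_varimax(
    table: pd.DataFrame, n_components: int = 2, max_iter: int = 25
) -> PCAResult:
    """PCA of standardized variables with varimax rotation.

    *table* has observations (taxa) as rows and variables (e.g. the 20
    m%X4 values) as columns.  Variables are z-scored; components are
    extracted by SVD of the correlation structure and the retained loading
    matrix is varimax-rotated (default iteration cap 25).
    """
    if table.shape[0] < 3 or table.shape[1] < 2:
        raise ValueError("need >= 3 observations and >= 2 variables")
    x = table.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(table.columns[sd == 0])
        raise ValueError(f"constant variable(s): {bad}")
    x = x / sd
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    ratio = eigvals[:n_components] / total
    # loadings: correlation of each variable with each component
    load = vt[:n_components].T * np.sqrt(eigvals[:n_components])
    rotated = varimax(load, max_iter=max_iter)
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    scores = u[:, :n_components] * s[:n_components]
    return PCAResult(
        loadings=pd.DataFrame(load, index=table.columns, columns=comp_names),
        rotated_loadings=pd.DataFrame(rotated, index=table.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        explained_variance_ratio=ratio,
        cumulative_variance=np.cumsum(ratio),
    )
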