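"""Tissue-panel coexpression modules.

Genes correlated with NE-DMRs are clustered across a normal-tissue
expression panel: rows are log10(RPKM+1)-transformed and mean-centered,
embedded in three dimensions by classical (Torgerson) multidimensional
scaling of Euclidean inter-gene distances, and partitioned by k-means
(K=6 by default).  Ward hierarchical clustering on the standardized matrix
serves as a consistency check (cross-tabulation and adjusted Rand index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "ModuleAssignment",
    "preprocess_tissue",
    "classical_mds",
    "kmeans_modules",
    "hclust_check",
    "TissueModuleClusterer",
]


@dataclass
class ModuleAssignment:
    """Gene -> module partition with per-module sizes."""

    labels: pd.Series  # gene id -> module in 1..K

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def total_genes(self) -> int:
        return int(self.sizes.sum())

    def genes_in(self, module: int) -> list:
        return self.labels.index[self.labels == module].tolist()


def preprocess_tissue(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """log10(x+1), duplicate resolution, zero-variance drop, row centering.

    Duplicate gene rows are resolved by keeping the entry with the highest
    standard deviation (computed on the log scale).  Returns the
    standardized matrix and a small report of dropped/deduplicated counts.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("tissue matrix must be non-negative")
    logm = np.log10(matrix + 1.0)

    n_dupes = int(logm.index.duplicated().sum())
    if n_dupes:
        sd = logm.std(axis=1, ddof=0)
        order = np.argsort(-sd.to_numpy(), kind="mergesort")
        logm = logm.iloc[order]
        logm = logm[~logm.index.duplicated(keep="first")]

    sd = logm.std(axis=1, ddof=0)
    zero_var = ~(sd > 0)
    n_zero = int(zero_var.sum())
    logm = logm.loc[~zero_var]

    centered = logm.sub(logm.mean(axis=1), axis=0)
    return centered, {"n_duplicates_resolved": n_dupes, "n_zero_variance_dropped": n_zero}


def classical_mds(X: np.ndarray | pd.DataFrame, dims: int = 3) -> np.ndarray:
    """Classical (Torgerson) MDS of the rows of X.

    Double-centers the squared Euclidean distance matrix, eigendecomposes,
    and returns coordinates for the ``dims`` largest eigenvalues (negative
    eigenvalues contribute zero coordinates).  Axes are ordered by
    decreasing eigenvalue; each axis's sign is fixed so its first nonzero
    loading is positive.
    """
    A = np.asarray(X, dtype=float)
    n = A.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} rows for a {dims}-D embedding")
    sq = (A * A).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * A @ A.T
    np.fill_diagonal(D2, 0.0)
    D2 = np.maximum(D2, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    lam = w[order]
    coords = v[:, order] * np.sqrt(np.maximum(lam, 0.0))[None, :]
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords


def kmeans_modules(
    coords: np.ndarray,
    gene_ids,
    k: int = 6,
    restarts: int = 50,
    seed: int = 0,
) -> ModuleAssignment:
    """k-means on embedded coordinates with deterministic module numbering.

    Best of ``restarts`` initializations by within-cluster sum of squares.
    Modules are renumbered 1..K by descending size; ties are broken by the
    lexicographically smallest member gene id.
    """
    coords = np.asarray(coords, dtype=float)
    if k > coords.shape[0]:
        raise ValueError("more clusters than genes")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(coords)

    gene_ids = pd.Index(gene_ids)
    keys = []
    for lbl in range(k):
        mem = gene_ids[raw == lbl]
        size = len(mem)
        first = min(mem) if size else ""
        keys.append((-size, first, lbl))
    remap = {lbl: rank + 1 for rank, (_, _, lbl) in enumerate(sorted(keys))}
    labels = pd.Series([remap[l] for l in raw], index=gene_ids, name="module")
    return ModuleAssignment(labels=labels)


def hclust_check(
    standardized: pd.DataFrame, assignment: ModuleAssignment, k: int | None = None
) -> dict:
    """Ward hierarchical clustering cut at K vs the k-means modules.

    Returns {"ari": float|None, "crosstab": DataFrame}.  ARI is None when
    K == 1 (undefined for a single cluster).
    """
    if k is None:
        k = int(assignment.labels.nunique())
    X = standardized.loc[assignment.labels.index].to_numpy()
    if k <= 1:
        return {"ari": None,
                "crosstab": pd.crosstab(assignment.labels, np.ones(len(X), dtype=int))}
    Z = linkage(X, method="ward")  # Ward.D2 on Euclidean distances
    hc = fcluster(Z, t=k, criterion="maxclust")
    ari = float(adjusted_rand_score(assignment.labels.to_numpy(), hc))
    return {"ari": ari, "crosstab": pd.crosstab(assignment.labels, hc)}


class TissueModuleClusterer(BaseEstimator):
    """Derive gene modules from a tissue-panel expression matrix.

    Parameters
    ----------
    n_modules : int
        Number of k-means clusters (K).
    n_dims : int
        MDS embedding dimensionality.
    n_restarts : int
        k-means initializations.
    random_state : int
        Seed for k-means.

    Attributes (after ``fit``)
    --------------------------
    standardized_ : preprocessed matrix
    preprocess_report_ : dict of dropped/dedup counts
    embedding_ : genes x n_dims MDS coordinates
    assignment_ : ModuleAssignment
    module_sizes_ : per-module gene counts
    hclust_ari_ : ARI between Ward and k-means partitions
    hclust_crosstab_ : cross-tabulation of the two partitions
    """

    def __init__(self, n_modules: int = 6, n_dims: int = 3,
                 n_restarts: int = 50, random_state: int = 0):
        self.n_modules = n_modules
        self.n_dims = n_dims
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, tissue: pd.DataFrame):
        self.standardized_, self.preprocess_report_ = preprocess_tissue(tissue)
        self.embedding_ = classical_mds(self.standardized_.to_numpy(), dims=self.n_dims)
        self.assignment_ = kmeans_modules(
            self.embedding_,
            self.standardized_.index,
            k=self.n_modules,
            restarts=self.n_restarts,
            seed=self.random_state,
        )
        self.module_sizes_ = self.assignment_.sizes
        chk = hclust_check(self.standardized_, self.assignment_, k=self.n_modules)
        self.hclust_ari_ = chk["ari"]
        self.hclust_crosstab_ = chk["crosstab"]
        return self

    def marker_report(self, marker_genes) -> pd.Series:
        """Which module holds each designated marker gene (manual labeling aid)."""
        lab = self.assignment_.labels
        return lab.reindex(pd.Index(marker_genes))
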