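"""QC filtering, normalization, Gini feature selection, and clustering.

Cells are kept when they carry at least ``min_umi`` transcripts, express at
least ``min_genes`` genes (>= 1 transcript each), and have a mitochondrial
UMI fraction of at most ``max_mito_frac``. Normalization divides by a
per-cell size factor (total counts over the median total) and applies
log1p. Informative features are the genes with the largest Gini coefficient
of their cluster-mean expression; clustering is Louvain on a k-nearest-
neighbor graph of PCA coordinates, with a cosine-metric UMAP embedding.
"""

from __future__ import annotations

import dataclasses
import logging
import random
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from tmecrosstalk.io import CountMatrix

log = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """A filter removed every cell."""


@dataclasses.dataclass
class QCThresholds:
    min_umi: int = 1000
    min_genes: int = 500
    max_mito_frac: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_umi <= 0 or self.min_genes <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0 < self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must be in (0, 1]")


@dataclasses.dataclass
class NormMatrix:
    """Log-normalized expression (genes x cells) with per-cell size factors."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "NormMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormMatrix(
            self.values[:, idx], self.gene_ids,
            [self.cell_ids[i] for i in idx], self.size_factors[idx])


@dataclasses.dataclass
class ClusterResult:
    labels: pd.Series  # per-cell cluster id
    features: list[str]
    pca_coords: np.ndarray
    pca_loadings: np.ndarray
    umap_coords: np.ndarray | None


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_cells(counts: CountMatrix, thr: QCThresholds | None = None
                 ) -> tuple[CountMatrix, dict]:
    """Apply the UMI / expressed-gene / mitochondrial-fraction filters.

    Returns the retained cells and a report of removal counts per criterion
    (a cell can fail several). Idempotent: running twice changes nothing.
    """
    thr = thr or QCThresholds()
    mat = counts.values.tocsc()
    totals = np.asarray(mat.sum(axis=0)).ravel()
    n_expressed = np.asarray((mat > 0).sum(axis=0)).ravel()
    mito_idx = [i for i, g in enumerate(counts.gene_ids)
                if g.startswith(thr.mito_prefix)]
    if mito_idx:
        mito = np.asarray(mat[mito_idx, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)
    else:
        mito_frac = np.zeros_like(totals, dtype=float)

    pass_umi = totals >= thr.min_umi
    pass_genes = n_expressed >= thr.min_genes
    pass_mito = mito_frac <= thr.max_mito_frac
    keep = pass_umi & pass_genes & pass_mito
    report = {
        "n_input": counts.n_cells,
        "n_retained": int(keep.sum()),
        "removed_low_umi": int((~pass_umi).sum()),
        "removed_few_genes": int((~pass_genes).sum()),
        "removed_high_mito": int((~pass_mito).sum()),
    }
    if not keep.any():
        raise EmptyResultError("QC filtering removed every cell")
    return counts.subset_cells(keep), report


def normalize(counts: CountMatrix) -> NormMatrix:
    """Size-factor correction and log1p transform.

    size_factor_c = total_c / median(total); value = log(1 + count / sf).
    """
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cell encountered; run filter_cells first")
    sf = totals / np.median(totals)
    dense = counts.values.toarray().astype(float)
    values = np.log1p(dense / sf[None, :])
    return NormMatrix(values, list(counts.gene_ids), list(counts.cell_ids), sf)


# ---------------------------------------------------------------------------
# Gini informative-feature selection
# ---------------------------------------------------------------------------

def gini_coefficients(norm: NormMatrix, clusters: pd.Series | np.ndarray
                      ) -> pd.Series:
    """Per-gene Gini coefficient of cluster-mean expression.

    G = sum_ij |m_i - m_j| / (2 K^2 mbar) over the K cluster means; genes
    with zero mean everywhere get G = 0. G lies in [0, 1 - 1/K] and is
    invariant to positive rescaling of the means.
    """
    labels = np.asarray(clusters)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters for Gini feature selection")
    means = np.stack([
        norm.values[:, labels == c].mean(axis=1) for c in uniq], axis=1)
    k = means.shape[1]
    mbar = means.mean(axis=1)
    # sorted-means identity: sum_ij |m_i - m_j| = 2 sum_i (2i - K + 1) m_(i)
    srt = np.sort(means, axis=1)
    weights = 2 * np.arange(k) - k + 1
    abs_diff_sum = 2.0 * (srt * weights[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gini = np.where(mbar > 0, abs_diff_sum / (2 * k * k * mbar), 0.0)
    return pd.Series(gini, index=norm.gene_ids)


def gini_features(norm: NormMatrix, clusters, n_features: int = 1000
                  ) -> list[str]:
    """The ``n_features`` genes with the largest Gini coefficient."""
    gini = gini_coefficients(norm, clusters)
    if n_features > len(gini):
        warnings.warn("n_features exceeds gene count; capped")
        n_features = len(gini)
    order = np.lexsort((gini.index, -gini.to_numpy()))  # stable: id asc
    return [gini.index[i] for i in order[:n_features]]


# ---------------------------------------------------------------------------
# Embedding and clustering
# ---------------------------------------------------------------------------

def _louvain(coords: np.ndarray, knn_k: int, seed: int) -> np.ndarray:
    import igraph
    from sklearn.neighbors import NearestNeighbors

    n = coords.shape[0]
    if n <= knn_k:
        raise ValueError(f"need more than knn_k={knn_k} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {(min(i, j), max(i, j))
             for i in range(n) for j in idx[i, 1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges))
    random.seed(seed)  # igraph draws from Python's random module
    part = graph.community_multilevel()
    return np.asarray(part.membership)


def embed_cluster(norm: NormMatrix, features, n_pcs: int = 30,
                  knn_k: int = 20, umap_neighbors: int = 30,
                  seed: int = 0, compute_umap: bool = True) -> ClusterResult:
    """PCA on the feature submatrix, Louvain on the k-NN graph of PC
    coordinates, and a cosine-metric UMAP embedding.
    """
    from sklearn.decomposition import PCA

    fidx = norm.gene_index(features)
    x = norm.values[fidx, :].T  # cells x features
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pca = PCA(n_components=n_pcs, random_state=seed)
    coords = pca.fit_transform(x)
    labels = _louvain(coords, knn_k, seed)
    umap_coords = None
    if compute_umap:
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_neighbors=min(umap_neighbors, norm.n_cells - 1),
                metric="cosine", random_state=seed)
            umap_coords = reducer.fit_transform(coords)
    return ClusterResult(
        labels=pd.Series(labels, index=norm.cell_ids, name="cluster"),
        features=list(features),
        pca_coords=coords,
        pca_loadings=pca.components_,
        umap_coords=umap_coords,
    )


def iff_cluster(norm: NormMatrix, n_features: int = 1000, n_pcs: int = 30,
                knn_k: int = 20, seed: int = 0, n_bootstrap_features: int = 2000,
                compute_umap: bool = False) -> ClusterResult:
    """Informative-feature clustering with a variance bootstrap.

    An initial clustering on the top ``n_bootstrap_features`` highest-
    variance genes provides labels for one Gini refinement pass, after which
    the final clustering runs on the Gini-selected features.
    """
    variances = norm.values.var(axis=1)
    order = np.lexsort((norm.gene_ids, -variances))
    boot = [norm.gene_ids[i] for i in order[:min(n_bootstrap_features,
                                                 norm.n_genes)]]
    initial = embed_cluster(norm, boot, n_pcs=n_pcs, knn_k=knn_k, seed=seed,
                            compute_umap=False)
    features = gini_features(norm, initial.labels.to_numpy(), n_features)
    return embed_cluster(norm, features, n_pcs=n_pcs, knn_k=knn_k, seed=seed,
                         compute_umap=compute_umap)
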