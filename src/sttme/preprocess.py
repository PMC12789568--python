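"""Spot QC, normalization, feature selection and clustering.

QC applies the published spot gates (UMI < 500, genes < 500, mito > 5%
removed -- strict inequalities exactly as printed, so a spot sitting on a
threshold is retained).  Normalization is median-total scaling followed by
log1p, which preserves the zero pattern.  Clustering is a contract: any
callable mapping an embedding to integer labels; the default is Leiden
community detection on a kNN graph, with a KMeans engine provided for
fixed-k use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .config import PipelineConfig
from .datasets import LOGNORM_LAYER, compute_qc_metrics, counts_matrix, lognorm_dense


@dataclass
class QCReport:
    """Removed spots with their first failing criterion (umi/genes/mito)."""

    n_input: int
    n_kept: int
    removed: pd.DataFrame  # index = barcode, column "reason"

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def qc_filter(adata: AnnData, cfg: PipelineConfig | None = None) -> tuple[AnnData, QCReport]:
    """Remove spots failing any QC gate; idempotent.

    A spot is removed when total UMI < min_umi OR detected genes <
    min_genes OR mito fraction > max_mito.  The report lists each removed
    spot with the first gate it fails, in umi -> genes -> mito order.
    """
    cfg = cfg or PipelineConfig()
    if "total_umi" not in adata.obs:
        compute_qc_metrics(adata)
    total = adata.obs["total_umi"].to_numpy()
    genes = adata.obs["n_genes_detected"].to_numpy()
    mito = adata.obs["mito_fraction"].to_numpy(dtype=float)

    fail_umi = total < cfg.min_umi
    fail_genes = genes < cfg.min_genes
    fail_mito = mito > cfg.max_mito
    removed_mask = fail_umi | fail_genes | fail_mito

    reason = np.full(adata.n_obs, "", dtype=object)
    reason[fail_mito] = "mito"
    reason[fail_genes] = "genes"
    reason[fail_umi] = "umi"  # umi wins as the first-checked gate
    removed = pd.DataFrame({"reason": reason[removed_mask]},
                           index=adata.obs_names[removed_mask])
    kept = adata[~removed_mask].copy()
    if kept.n_obs == 0:
        raise ValueError("no spots survive QC filtering")
    return kept, QCReport(n_input=adata.n_obs, n_kept=kept.n_obs, removed=removed)


def normalize(adata: AnnData) -> AnnData:
    """Median-total scaling + log1p into ``layers["lognorm"]``.

    Each spot's counts are scaled so its total equals the median
    pre-scaling total, then log1p-transformed.  Raw counts are untouched;
    zeros stay zero.
    """
    X = counts_matrix(adata).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("spot with zero total counts; run qc_filter first")
    target = float(np.median(totals))
    scaled = sparse.diags(target / totals) @ X
    scaled.data = np.log1p(scaled.data)
    adata.layers[LOGNORM_LAYER] = scaled.tocsr()
    return adata


def select_hvg(adata: AnnData, n: int) -> list[str]:
    """Top-n genes by variance-to-mean dispersion on the normalized layer.

    Ties are broken lexicographically by gene id, so selection is
    deterministic.  Constant genes have zero dispersion and are only
    selected after every non-constant gene.
    """
    if n > adata.n_vars:
        raise ValueError(f"n={n} exceeds gene count {adata.n_vars}")
    layer = lognorm_dense(adata)
    mean = layer.mean(axis=0)
    var = layer.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    order = sorted(range(adata.n_vars),
                   key=lambda i: (-dispersion[i], adata.var_names[i]))
    return [adata.var_names[i] for i in order[:n]]


class LeidenEngine:
    """Default clustering engine: kNN graph + Leiden community detection."""

    def __init__(self, n_neighbors: int = 15, resolution: float = 1.0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution

    def __call__(self, embedding: np.ndarray, seed: int = 0) -> np.ndarray:
        import igraph as ig
        import leidenalg

        k = min(self.n_neighbors, embedding.shape[0] - 1)
        knn = kneighbors_graph(embedding, n_neighbors=k, include_self=False)
        knn = knn.maximum(knn.T).tocoo()
        g = ig.Graph(n=embedding.shape[0],
                     edges=list(zip(knn.row.tolist(), knn.col.tolist())),
                     directed=False).simplify()
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=self.resolution, seed=int(seed))
        return np.asarray(part.membership, dtype=int)


class KMeansEngine:
    """Fixed-k alternative engine (useful when k is known a priori)."""

    def __init__(self, n_clusters: int):
        self.n_clusters = n_clusters

    def __call__(self, embedding: np.ndarray, seed: int = 0) -> np.ndarray:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=self.n_clusters, n_init=10, random_state=int(seed))
        return km.fit_predict(embedding).astype(int)


def embed_and_cluster(adata: AnnData, cfg: PipelineConfig | None = None,
                      engine=None, seed: int = 0,
                      embedding: np.ndarray | None = None) -> AnnData:
    """PCA on the HVG submatrix, then cluster labels from the engine.

    ``embedding`` accepts an externally batch-corrected embedding (e.g.
    Harmony output) and bypasses the internal PCA.  The engine is any
    callable ``(embedding, seed) -> labels``; a wrong-length label vector
    is a contract violation.
    """
    cfg = cfg or PipelineConfig()
    engine = engine or LeidenEngine()
    if embedding is None:
        hvg = select_hvg(adata, min(cfg.n_hvg, adata.n_vars))
        sub = lognorm_dense(adata[:, hvg])
        n_pcs = max(1, min(cfg.n_pcs, sub.shape[0] - 1, sub.shape[1]))
        embedding = PCA(n_components=n_pcs, svd_solver="full",
                        random_state=int(seed)).fit_transform(sub)
    adata.obsm["X_pca"] = np.asarray(embedding)
    labels = np.asarray(engine(np.asarray(embedding), seed))
    if labels.shape != (adata.n_obs,):
        raise ValueError(
            f"clustering engine returned {labels.shape} labels for {adata.n_obs} spots")
    adata.obs["cluster"] = pd.Categorical([str(l) for l in labels])
    return adata
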