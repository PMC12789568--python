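"""In-memory containers and per-spot QC metrics.

The spot dataset is an :class:`anndata.AnnData` (spots x genes, counts in
``.X``, size-normalized log expression in ``.layers["lognorm"]``) with the
following ``obs`` columns:

``sample_id``          tissue section the spot came from
``tissue_type``        "tumor" or "normal"
``array_row/array_col``  Visium array coordinates
``total_umi``          column sum of raw counts
``n_genes_detected``   genes with count >= 1
``mito_fraction``      share of counts on MT- genes (raw counts)
``cluster``            expression cluster label (nullable)
``compartment``        "neoplastic" / "nonneoplastic" (nullable)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

LOGNORM_LAYER = "lognorm"
MITO_PREFIX = "MT-"

OBS_REQUIRED = ("sample_id", "tissue_type")


def counts_matrix(adata: AnnData) -> sparse.csr_matrix:
    """Raw counts as CSR, whichever storage the AnnData uses."""
    X = adata.X
    if sparse.issparse(X):
        return X.tocsr()
    return sparse.csr_matrix(np.asarray(X))


def compute_qc_metrics(adata: AnnData, mito_prefix: str = MITO_PREFIX) -> AnnData:
    """Populate total_umi, n_genes_detected and mito_fraction in ``obs``.

    Mitochondrial genes are identified by name prefix (human convention);
    the fraction is computed on raw counts, before any normalization.
    """
    X = counts_matrix(adata)
    total = np.asarray(X.sum(axis=1)).ravel()
    ngenes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    mito = np.asarray(X[:, np.where(mito_mask)[0]].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    adata.obs["total_umi"] = total.astype(np.int64)
    adata.obs["n_genes_detected"] = ngenes.astype(np.int64)
    adata.obs["mito_fraction"] = mito_frac
    return adata


def validate_spot_dataset(adata: AnnData) -> None:
    """Raise if the container violates the spot-dataset contract."""
    for col in OBS_REQUIRED:
        if col not in adata.obs:
            raise ValueError(f"missing obs column: {col}")
    X = counts_matrix(adata)
    if (X.data < 0).any():
        raise ValueError("counts must be nonnegative")
    if "total_umi" in adata.obs:
        total = np.asarray(X.sum(axis=1)).ravel()
        if not np.array_equal(total.astype(np.int64), adata.obs["total_umi"].to_numpy()):
            raise ValueError("total_umi inconsistent with counts")
    if "mito_fraction" in adata.obs:
        mf = adata.obs["mito_fraction"].to_numpy(dtype=float)
        if ((mf < 0) | (mf > 1)).any():
            raise ValueError("mito_fraction outside [0, 1]")
    if LOGNORM_LAYER in adata.layers:
        layer = adata.layers[LOGNORM_LAYER]
        data = layer.data if sparse.issparse(layer) else np.asarray(layer)
        if (data < 0).any():
            raise ValueError("normalized layer must be nonnegative")


def lognorm_dense(adata: AnnData) -> np.ndarray:
    """The normalized layer as a dense array (spots x genes)."""
    if LOGNORM_LAYER not in adata.layers:
        raise ValueError("normalized layer absent; run normalize() first")
    layer = adata.layers[LOGNORM_LAYER]
    return layer.toarray() if sparse.issparse(layer) else np.asarray(layer)


@dataclass
class CellAbundanceMatrix:
    """Spots x cell-type abundances from deconvolution.

    ``raw`` holds the real-valued posterior-mean abundances; ``post`` the
    integer matrix after rounding plus the one-cell floor for empty spots
    (filled by :func:`sttme.composition.postprocess_abundance`).
    """

    raw: pd.DataFrame
    post: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("raw abundances must be nonnegative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def spot_ids(self) -> pd.Index:
        return self.raw.index

    def aligned_to(self, adata: AnnData) -> "CellAbundanceMatrix":
        """Reindex to the dataset's spots; missing spots are an error."""
        missing = adata.obs_names.difference(self.raw.index)
        if len(missing):
            raise ValueError(f"abundance matrix missing {len(missing)} spots")
        post = self.post.loc[adata.obs_names] if self.post is not None else None
        return CellAbundanceMatrix(self.raw.loc[adata.obs_names], post)
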