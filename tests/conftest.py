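"""Shared fixtures: small simulated datasets and toy-builder helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

from sttme.datasets import LOGNORM_LAYER, compute_qc_metrics
from sttme.preprocess import embed_and_cluster, normalize, qc_filter
from sttme.synthetic import STSimConfig, simulate_st_dataset


def make_adata(counts, genes=None, sample_ids=None, tissue=None, clusters=None,
               compartment=None, normalized=True) -> AnnData:
    """Toy spot dataset from a dense counts array (spots x genes)."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = genes or [f"G{j}" for j in range(g)]
    adata = AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame(index=[f"s{i}" for i in range(n)]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obs["sample_id"] = sample_ids if sample_ids is not None else "S1"
    adata.obs["tissue_type"] = tissue if tissue is not None else "tumor"
    if clusters is not None:
        adata.obs["cluster"] = pd.Categorical([str(c) for c in clusters])
    if compartment is not None:
        adata.obs["compartment"] = pd.Categorical(compartment)
    compute_qc_metrics(adata)
    if normalized:
        normalize(adata)
    return adata


@pytest.fixture(scope="session")
def small_sim():
    """A compact multi-sample simulated dataset with planted QC failures."""
    cfg = STSimConfig(seed=11, spots_per_sample=(120, 200))
    adata, truth = simulate_st_dataset(cfg)
    return adata, truth


@pytest.fixture(scope="session")
def processed(small_sim):
    """QC-filtered, normalized, clustered copy of the small simulation."""
    adata, truth = small_sim
    kept, _ = qc_filter(adata.copy())
    kept = normalize(kept)
    kept = embed_and_cluster(kept, seed=0)
    return kept, truth
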