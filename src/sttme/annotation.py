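"""Neoplastic cluster calling from sample provenance and TFH markers.

A cluster whose spots derive more than 95% (strictly) from tumor samples
is called neoplastic; more than 95% from normal samples, normal-dominant;
anything else, mixed.  The follicular-helper-T marker score (mean
normalized expression of CXCL13, MME, BCL6, PDCD1, ICOS) is reported as
supporting evidence -- provenance decides the call, and a neoplastic call
with a below-median TFH score triggers a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData

from .config import PipelineConfig
from .datasets import lognorm_dense

NEOPLASTIC = "neoplastic"
NONNEOPLASTIC = "nonneoplastic"

PROFILE_COLUMNS = ["cluster_id", "n_spots", "fraction_tumor_origin", "tfh_score", "call"]


def _tfh_scores(adata: AnnData, markers: tuple[str, ...]) -> np.ndarray:
    present = [m for m in markers if m in adata.var_names]
    if not present:
        raise ValueError(f"none of the TFH markers {markers} are in the dataset")
    if len(present) < len(markers):
        warnings.warn(
            f"TFH markers missing from dataset: {sorted(set(markers) - set(present))}; "
            "scoring over the present subset")
    sub = lognorm_dense(adata[:, present])
    return sub.mean(axis=1)


def profile_clusters(adata: AnnData, cfg: PipelineConfig | None = None,
                     on_counts: bool | None = None) -> pd.DataFrame:
    """One provenance profile per cluster.

    Returns a frame with cluster_id, n_spots, the per-sample spot
    fractions (``frac_<sample>`` columns), fraction_tumor_origin and the
    cluster-mean TFH score.  ``on_counts=True`` (default) computes
    fractions from raw spot counts; ``False`` reweights every sample to
    equal total contribution first.
    """
    cfg = cfg or PipelineConfig()
    if on_counts is None:
        on_counts = cfg.provenance_on_counts
    if "cluster" not in adata.obs:
        raise ValueError("cluster labels absent; run embed_and_cluster first")
    obs = adata.obs
    spot_scores = _tfh_scores(adata, cfg.tfh_markers)
    samples = list(pd.unique(obs["sample_id"]))
    tumor_samples = set(obs.loc[obs["tissue_type"] == "tumor", "sample_id"])

    weights = pd.Series(1.0, index=obs.index)
    if not on_counts:
        sizes = obs.groupby("sample_id", observed=True).size()
        weights = obs["sample_id"].map(1.0 / sizes).astype(float)

    rows = []
    for cl, idx in obs.groupby("cluster", observed=True).groups.items():
        sub = obs.loc[idx]
        w = weights.loc[idx]
        by_sample = w.groupby(sub["sample_id"], observed=True).sum()
        frac = (by_sample / by_sample.sum()).reindex(samples, fill_value=0.0)
        row = {
            "cluster_id": str(cl),
            "n_spots": len(idx),
            "fraction_tumor_origin": float(frac[frac.index.isin(tumor_samples)].sum()),
            "tfh_score": float(spot_scores[obs.index.get_indexer(idx)].mean()),
        }
        row.update({f"frac_{s}": float(frac[s]) for s in samples})
        rows.append(row)
    prof = pd.DataFrame(rows).sort_values("cluster_id", ignore_index=True)
    return prof


def call_neoplastic(profiles: pd.DataFrame, adata: AnnData,
                    cfg: PipelineConfig | None = None) -> tuple[pd.DataFrame, AnnData]:
    """Apply the strict >95% provenance rule and label compartments.

    call = neoplastic iff fraction_tumor_origin > threshold (strict);
    normal_dominant iff the normal-sample fraction > threshold; else
    mixed.  Every spot inherits a compartment: neoplastic for neoplastic
    clusters, nonneoplastic otherwise (the labels partition the spots).
    """
    cfg = cfg or PipelineConfig()
    thr = cfg.provenance_threshold
    profiles = profiles.copy()
    ft = profiles["fraction_tumor_origin"].to_numpy(dtype=float)
    call = np.where(ft > thr, "neoplastic",
                    np.where((1.0 - ft) > thr, "normal_dominant", "mixed"))
    profiles["call"] = call

    median_tfh = float(profiles["tfh_score"].median())
    discordant = profiles[(profiles["call"] == "neoplastic")
                          & (profiles["tfh_score"] < median_tfh)]
    if len(discordant):
        warnings.warn(
            "neoplastic-called clusters with below-median TFH score: "
            f"{discordant['cluster_id'].tolist()}")

    neo_clusters = set(profiles.loc[profiles["call"] == "neoplastic", "cluster_id"])
    comp = np.where(adata.obs["cluster"].astype(str).isin(neo_clusters),
                    NEOPLASTIC, NONNEOPLASTIC)
    adata.obs["compartment"] = pd.Categorical(comp, categories=[NEOPLASTIC, NONNEOPLASTIC])
    return profiles, adata


def composition_similarity(adata: AnnData) -> pd.DataFrame:
    """Pairwise Pearson correlation of neoplastic-cluster composition.

    For each tumor sample, the vector of its neoplastic spots' fractions
    across neoplastic clusters (summing to 1); correlations between sample
    pairs, diagonal 1.  A sample with no neoplastic spots gets a missing
    row/column with a warning.
    """
    obs = adata.obs
    if "compartment" not in obs:
        raise ValueError("compartments not called; run call_neoplastic first")
    neo = obs[obs["compartment"] == NEOPLASTIC]
    clusters = sorted(neo["cluster"].astype(str).unique())
    if len(clusters) < 2:
        raise ValueError("need at least two neoplastic clusters for composition similarity")
    samples = sorted(obs.loc[obs["tissue_type"] == "tumor", "sample_id"].unique())
    comp = pd.DataFrame(0.0, index=samples, columns=clusters)
    for s in samples:
        sub = neo[neo["sample_id"] == s]
        if len(sub) == 0:
            warnings.warn(f"sample {s} has no neoplastic spots; similarity set to NaN")
            comp.loc[s] = np.nan
            continue
        frac = sub["cluster"].astype(str).value_counts(normalize=True)
        comp.loc[s] = frac.reindex(clusters, fill_value=0.0).to_numpy()
    mat = pd.DataFrame(np.nan, index=samples, columns=samples, dtype=float)
    for a in samples:
        for b in samples:
            va, vb = comp.loc[a].to_numpy(), comp.loc[b].to_numpy()
            if np.isnan(va).any() or np.isnan(vb).any():
                continue
            if a == b:
                mat.loc[a, b] = 1.0
            else:
                mat.loc[a, b] = float(np.corrcoef(va, vb)[0, 1])
    return mat
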