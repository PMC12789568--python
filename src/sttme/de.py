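"""Differential expression by the three-part spot-level rule.

A gene is a DEG for a cluster when, comparing that cluster's spots to all
other spots with a two-sided Mann-Whitney U test on normalized
expression:

* linear fold change of mean normalized expression > 2^0.5,
* raw-count detection in at least 25% of the cluster's spots, and
* BH-adjusted q < 1e-4 (adjustment within cluster, across genes).

Fold is computed on de-logged normalized means with a 1e-9 pseudocount
guarding empty denominators.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData

from .config import PipelineConfig
from .datasets import counts_matrix, lognorm_dense
from .stats import bh_adjust, rank_sum_matrix

DEG_COLUMNS = ["gene", "cluster", "fold", "detection_fraction", "U", "p", "q", "is_deg"]


def _deg_table(linear: np.ndarray, detected: np.ndarray, layer: np.ndarray,
               mask: np.ndarray, genes, label: str, cfg: PipelineConfig) -> pd.DataFrame:
    mean_in = linear[mask].mean(axis=0)
    mean_out = linear[~mask].mean(axis=0)
    fold = (mean_in + cfg.deg_eps) / (mean_out + cfg.deg_eps)
    det = detected[mask].mean(axis=0)
    U, p = rank_sum_matrix(layer, mask)
    q = bh_adjust(p)
    return pd.DataFrame({
        "gene": genes,
        "cluster": label,
        "fold": fold,
        "detection_fraction": det,
        "U": U,
        "p": p,
        "q": q,
        "is_deg": (fold > cfg.deg_fold) & (det >= cfg.deg_detection) & (q < cfg.deg_q),
    })


def find_degs(adata: AnnData, group_by: str = "cluster",
              cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """One-vs-rest DEG table over every group of ``obs[group_by]``.

    Groups of a single spot are skipped with a warning (no rank test is
    possible).  Returns one row per gene x cluster.
    """
    cfg = cfg or PipelineConfig()
    if group_by not in adata.obs:
        raise ValueError(f"missing group label column {group_by!r}")
    groups = adata.obs[group_by].astype(str)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    layer = lognorm_dense(adata)
    linear = np.expm1(layer)
    detected = (counts_matrix(adata) > 0).toarray()
    tables = []
    for label in labels:
        mask = (groups == label).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"cluster {label} has a single spot; skipped")
            continue
        tables.append(_deg_table(linear, detected, layer, mask,
                                 list(adata.var_names), label, cfg))
    return pd.concat(tables, ignore_index=True)


def contrast_degs(adata: AnnData, group_a: list[str], group_b: list[str],
                  group_by: str = "cluster",
                  cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """The DEG rule on an explicit two-group cluster contrast.

    ``group_a`` vs ``group_b`` are disjoint cluster label sets; spots in
    neither are excluded.  Swapping the groups inverts the fold and keeps
    the p-value.
    """
    cfg = cfg or PipelineConfig()
    set_a, set_b = set(map(str, group_a)), set(map(str, group_b))
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    if not set_a or not set_b:
        raise ValueError("both groups must be non-empty")
    groups = adata.obs[group_by].astype(str)
    keep = groups.isin(set_a | set_b).to_numpy()
    sub = adata[keep]
    layer = lognorm_dense(sub)
    linear = np.expm1(layer)
    detected = (counts_matrix(sub) > 0).toarray()
    mask = groups[keep].isin(set_a).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each side of the contrast needs at least 2 spots")
    label = f"{'+'.join(sorted(set_a))}_vs_{'+'.join(sorted(set_b))}"
    return _deg_table(linear, detected, layer, mask, list(adata.var_names), label, cfg)
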