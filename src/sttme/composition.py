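"""Deconvolution abundance post-processing and compartment enrichment.

The deconvolution posterior-mean abundances are rounded to integer cell
counts; a spot whose rounded row is all zero receives exactly one cell of
its highest-abundance type (lexicographic tie-break).  Cell-type
enrichment between neoplastic and nonneoplastic spots uses the two-sided
Mann-Whitney U test per type with BH adjustment, flagged at the dual
threshold p < 0.05 and q < 0.25.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData

from .config import PipelineConfig
from .datasets import CellAbundanceMatrix
from .stats import bh_adjust, rank_sum_matrix

ENRICH_COLUMNS = ["cell_type", "median_neoplastic", "median_nonneoplastic",
                  "U", "p", "q", "direction", "significant"]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def postprocess_abundance(raw: CellAbundanceMatrix,
                          cfg: PipelineConfig | None = None) -> CellAbundanceMatrix:
    """Round abundances; give empty spots one cell of their argmax type.

    Rounding is half-to-even by default (``cfg.rounding="half_up"`` for
    the alternative).  The argmax of the *raw* row decides where the
    forced single cell goes; exact ties go to the lexicographically first
    cell-type name.
    """
    cfg = cfg or PipelineConfig()
    values = raw.raw.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("raw abundances must be nonnegative")
    rounded = np.rint(values) if cfg.rounding == "half_even" else _round_half_up(values)
    rounded = rounded.astype(np.int64)

    # type columns sorted lexicographically so np.argmax lands on the
    # first name among tied raw maxima
    order = np.argsort(np.asarray(raw.raw.columns, dtype=object))
    empty = np.where(rounded.sum(axis=1) == 0)[0]
    for i in empty:
        j = order[int(np.argmax(values[i, order]))]
        rounded[i, j] = 1
    post = pd.DataFrame(rounded, index=raw.raw.index, columns=raw.raw.columns)
    return CellAbundanceMatrix(raw.raw, post)


def enrichment_test(abundance: CellAbundanceMatrix, adata: AnnData,
                    cfg: PipelineConfig | None = None,
                    use_post: bool = True) -> pd.DataFrame:
    """Per-cell-type neoplastic vs nonneoplastic Mann-Whitney enrichment.

    Tests the post-processed integer abundances by default (``use_post=
    False`` tests the raw values).  BH adjustment across cell types;
    ``significant`` iff p < enrich_p AND q < enrich_q.
    """
    cfg = cfg or PipelineConfig()
    if "compartment" not in adata.obs:
        raise ValueError("compartments not called")
    mat = abundance.post if use_post and abundance.post is not None else abundance.raw
    mat = mat.loc[adata.obs_names]
    mask = (adata.obs["compartment"] == "neoplastic").to_numpy()
    for name, n in (("neoplastic", mask.sum()), ("nonneoplastic", (~mask).sum())):
        if n < 2:
            raise ValueError(f"{name} compartment has fewer than 2 spots")
    X = mat.to_numpy(dtype=float)
    U, p = rank_sum_matrix(X, mask)
    q = bh_adjust(p)
    med_neo = np.median(X[mask], axis=0)
    med_non = np.median(X[~mask], axis=0)
    mean_neo = X[mask].mean(axis=0)
    mean_non = X[~mask].mean(axis=0)
    direction = np.where(mean_neo >= mean_non, "up_in_neoplastic", "down_in_neoplastic")
    return pd.DataFrame({
        "cell_type": mat.columns,
        "median_neoplastic": med_neo,
        "median_nonneoplastic": med_non,
        "U": U,
        "p": p,
        "q": q,
        "direction": direction,
        "significant": (p < cfg.enrich_p) & (q < cfg.enrich_q),
    })
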