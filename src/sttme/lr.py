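"""Ligand-receptor spot-colocalization activity.

The activity of a receptor-ligand axis in a spot is the minimum of the
two genes' normalized expression values: coexpression in the same spot
quantified by the lower expression level.  A spot is "active" when the
minimum is strictly above the configured threshold (default 0, i.e. both
transcripts detected).  Active fractions are reported per
(sample, compartment) stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats as sps

from .config import PipelineConfig
from .datasets import lognorm_dense


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str

    def __post_init__(self) -> None:
        if self.ligand == self.receptor:
            raise ValueError("ligand and receptor must differ")

    @property
    def name(self) -> str:
        return f"{self.ligand}:{self.receptor}"


DEFAULT_PAIR = LRPair("CD40LG", "CD40")


@dataclass
class LRActivityResult:
    pair: LRPair
    activity: pd.Series  # per spot, >= 0
    active: pd.Series  # per spot, bool


def spot_activity(adata: AnnData, pair: LRPair = DEFAULT_PAIR,
                  cfg: PipelineConfig | None = None) -> LRActivityResult:
    """Per-spot min(ligand, receptor) normalized expression.

    Symmetric in the pair and monotone in either gene's expression;
    zero whenever either transcript is absent.
    """
    cfg = cfg or PipelineConfig()
    for g in (pair.ligand, pair.receptor):
        if g not in adata.var_names:
            raise ValueError(f"gene {g} absent from dataset")
    sub = lognorm_dense(adata[:, [pair.ligand, pair.receptor]])
    activity = np.minimum(sub[:, 0], sub[:, 1])
    return LRActivityResult(
        pair=pair,
        activity=pd.Series(activity, index=adata.obs_names, name="activity"),
        active=pd.Series(activity > cfg.activity_min, index=adata.obs_names, name="active"),
    )


def activity_fractions(result: LRActivityResult, adata: AnnData) -> pd.DataFrame:
    """Active-spot fraction per (sample, compartment) plus per-sample overall.

    Empty strata report NaN with n = 0.  Fractions are over all spots in
    the stratum (whole QC-passing sections, not only cluster-assigned
    spots).
    """
    obs = adata.obs
    if "compartment" not in obs:
        raise ValueError("compartments not called")
    active = result.active.loc[obs.index]
    rows = []
    samples = sorted(obs["sample_id"].unique())
    compartments = ["neoplastic", "nonneoplastic"]
    for s in samples:
        in_sample = obs["sample_id"] == s
        for c in compartments + ["all"]:
            m = in_sample if c == "all" else in_sample & (obs["compartment"] == c)
            n = int(m.sum())
            frac = float(active[m.to_numpy()].mean()) if n else float("nan")
            rows.append({"sample_id": s, "compartment": c, "pair": result.pair.name,
                         "n_spots": n, "active_fraction": frac})
    return pd.DataFrame(rows)


def compare_activity(result: LRActivityResult, adata: AnnData,
                     stratum_a: tuple[str, str], stratum_b: tuple[str, str]) -> pd.DataFrame:
    """Two-sided Fisher exact test of active/inactive counts between strata.

    Strata are (sample_id, compartment) pairs; ``compartment="all"``
    takes the whole sample.  A degenerate table (zero margin) reports
    p = 1 with a warning.
    """
    obs = adata.obs
    active = result.active.loc[obs.index]

    def counts(stratum: tuple[str, str]) -> tuple[int, int]:
        s, c = stratum
        m = obs["sample_id"] == s
        if c != "all":
            m = m & (obs["compartment"] == c)
        m = m.to_numpy()
        if m.sum() == 0:
            raise ValueError(f"empty stratum {stratum}")
        a = int(active[m].sum())
        return a, int(m.sum()) - a

    a1, i1 = counts(stratum_a)
    a2, i2 = counts(stratum_b)
    table = np.array([[a1, i1], [a2, i2]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn(f"degenerate 2x2 table {table.tolist()}; p set to 1")
        odds, p = float("nan"), 1.0
    else:
        odds, p = sps.fisher_exact(table, alternative="two-sided")
    return pd.DataFrame([{
        "stratum_a": "/".join(stratum_a), "stratum_b": "/".join(stratum_b),
        "active_a": a1, "inactive_a": i1, "active_b": a2, "inactive_b": i2,
        "odds_ratio": float(odds), "p": float(p),
    }])
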