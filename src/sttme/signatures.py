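"""Single-sample gene-signature scoring and dichotomy comparisons.

The score of a signature in a spot is the mean, over the signature's
present genes, of the gene's z-scored (across spots) normalized
expression -- the module-score family of single-sample statistics.  It
supports the ordinal spot-group comparisons the dichotomies (M1 vs M2
polarization, angiogenesis vs phagocytosis) require; an externally
computed score matrix (e.g. GSVA output) can be supplied wherever a
score table is accepted.

Zero-variance genes contribute 0 rather than NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData

from .datasets import lognorm_dense
from .stats import bh_adjust, mann_whitney_u

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]
    partner: str | None = None  # name of the dichotomy counterpart

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name} has duplicate genes")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sigs.append(GeneSignature(parts[0], tuple(dict.fromkeys(parts[2:]))))
    return sigs


def read_signature_tsv(path: str | Path) -> list[GeneSignature]:
    """Two-column TSV: signature <tab> gene, one gene per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["signature", "gene"])
    return [GeneSignature(name, tuple(dict.fromkeys(sub["gene"])))
            for name, sub in df.groupby("signature", sort=True)]


def score_signatures(adata: AnnData, sigs: list[GeneSignature]) -> pd.DataFrame:
    """Spots x signatures mean-z-score table."""
    layer = lognorm_dense(adata)
    mean = layer.mean(axis=0)
    sd = layer.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (layer - mean) / sd, 0.0)
    gene_pos = {g: i for i, g in enumerate(adata.var_names)}
    out = {}
    for sig in sigs:
        present = [gene_pos[g] for g in sig.genes if g in gene_pos]
        missing = [g for g in sig.genes if g not in gene_pos]
        if not present:
            raise ValueError(f"signature {sig.name}: no genes present in dataset")
        if missing:
            logger.info("signature %s: %d genes missing (%s...)",
                        sig.name, len(missing), ", ".join(missing[:3]))
        out[sig.name] = z[:, present].mean(axis=1)
    return pd.DataFrame(out, index=adata.obs_names)


def dichotomy_compare(scores: pd.DataFrame, adata: AnnData, sig_a: str, sig_b: str,
                      strata: pd.Series | str = "sample_id") -> pd.DataFrame:
    """Stratum medians of both signatures plus cross-stratum rank tests.

    ``strata`` is an obs column name or a per-spot label series (e.g.
    cluster-1 spots split by sample).  For each signature, every stratum
    is tested against all other spots with Mann-Whitney U; BH adjustment
    over the whole comparison table.  Strata of fewer than 2 spots are
    skipped with a warning.
    """
    for s in (sig_a, sig_b):
        if s not in scores.columns:
            raise ValueError(f"signature {s} not scored")
    labels = adata.obs[strata].astype(str) if isinstance(strata, str) else strata.astype(str)
    labels = labels.loc[scores.index]
    rows = []
    for name in sorted(labels.unique()):
        mask = (labels == name).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            warnings.warn(f"stratum {name} too small; skipped")
            continue
        for sig in (sig_a, sig_b):
            v = scores[sig].to_numpy()
            u, p = mann_whitney_u(v[mask], v[~mask], exact="never")
            rows.append({
                "stratum": name, "signature": sig, "n": int(mask.sum()),
                "median_in": float(np.median(v[mask])),
                "median_rest": float(np.median(v[~mask])),
                "U": u, "p": p,
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    return table
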