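"""Tumor-only variant filtering cascade with a per-step audit trail.

Without a matched normal, somatic calls are enriched by removing likely
germline or irrelevant variants in five ordered steps:

1. intronic or synonymous consequence,
2. ClinVar "benign" / "likely benign",
3. VAF strictly greater than 90% (homozygous germline),
4. population allele frequency strictly greater than 1%,
5. gene outside the frequently-mutated panel (default TET2, DNMT3A,
   IDH2, RHOA).

Order only affects the audit trail: membership of the kept set equals
the intersection of the five predicates.  Null ClinVar passes step 2;
null population AF passes step 4 (absence from the database implies
rarity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig

STEP_NAMES = ("consequence", "clinvar", "vaf", "popfreq", "panel")
_NONCODING = {"intronic", "synonymous"}
_BENIGN = {"benign", "likely benign", "benign/likely benign"}

REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "consequence",
                    "clinvar_class", "pop_af", "vaf")


@dataclass
class FilterTrace:
    """fate per variant ('kept' or 'removed@step<k>:<name>') + step counts."""

    fates: pd.Series
    steps: pd.DataFrame  # columns: step, name, n_in, n_removed, n_out


def validate_variants(variants: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    vaf = variants["vaf"].to_numpy(dtype=float)
    if np.isnan(vaf).any() or ((vaf < 0) | (vaf > 1)).any():
        raise ValueError("vaf must be within [0, 1] and non-null")
    pop = pd.to_numeric(variants["pop_af"], errors="coerce")
    if ((pop < 0) | (pop > 1)).any():
        raise ValueError("pop_af must be within [0, 1]")
    if (variants["pos"].to_numpy(dtype=int) < 1).any():
        raise ValueError("pos must be 1-based")


def _split_consequences(value: str) -> list[str]:
    return [c.strip().lower() for c in re.split(r"[&,;]", str(value)) if c.strip()]


def _fails_consequence(value, worst_wins: bool) -> bool:
    parts = _split_consequences(value)
    if not parts:
        return False
    if worst_wins:
        # a variant is only discarded when every transcript consequence is
        # intronic/synonymous (worst consequence wins)
        return all(p in _NONCODING for p in parts)
    return parts[0] in _NONCODING


def _fails_clinvar(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    norm = str(value).strip().lower().replace("_", " ")
    if "pathogenic" in norm:
        return False
    return norm in _BENIGN


def filter_cascade(variants: pd.DataFrame, panel: set[str] | None = None,
                   cfg: PipelineConfig | None = None,
                   worst_consequence_wins: bool = True) -> tuple[pd.DataFrame, FilterTrace]:
    """Apply the five rules in order; return kept variants and the trace.

    The trace records each variant's first failing step; step counts
    telescope (input of step k+1 equals output of step k).
    """
    cfg = cfg or PipelineConfig()
    panel = set(panel) if panel is not None else set(cfg.gene_panel)
    if not panel:
        raise ValueError("gene panel must be non-empty")
    validate_variants(variants)

    pop = pd.to_numeric(variants["pop_af"], errors="coerce").to_numpy()
    vaf = variants["vaf"].to_numpy(dtype=float)
    fails = [
        variants["consequence"].map(lambda v: _fails_consequence(v, worst_consequence_wins)).to_numpy(),
        variants["clinvar_class"].map(_fails_clinvar).to_numpy(),
        vaf > cfg.vaf_hom,
        np.nan_to_num(pop, nan=0.0) > cfg.pop_af,
        ~variants["gene"].astype(str).isin(panel).to_numpy(),
    ]

    fate = np.full(len(variants), "kept", dtype=object)
    alive = np.ones(len(variants), dtype=bool)
    rows = []
    for k, (name, f) in enumerate(zip(STEP_NAMES, fails), start=1):
        removed = alive & f
        fate[removed] = f"removed@step{k}:{name}"
        rows.append({"step": k, "name": name, "n_in": int(alive.sum()),
                     "n_removed": int(removed.sum()),
                     "n_out": int(alive.sum() - removed.sum())})
        alive &= ~f
    kept = variants[alive].copy()
    trace = FilterTrace(
        fates=pd.Series(fate, index=variants.index, name="fate"),
        steps=pd.DataFrame(rows),
    )
    return kept, trace


def recurrent_gene_summary(kept: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Per-gene sample incidence and VAF summary of the kept variants.

    ``incidence`` is "k/n" over the sample universe; genes whose minimum
    VAF is <= 0.20 are flagged (recurrent drivers are expected above 20%
    VAF when tumor content is adequate).
    """
    if len(kept) == 0:
        return pd.DataFrame(columns=["gene", "n_samples", "incidence",
                                     "min_vaf", "median_vaf", "low_vaf_flag"])
    if "sample_id" not in kept.columns:
        raise ValueError("kept variants must carry sample_id")
    universe = samples if samples is not None else sorted(kept["sample_id"].unique())
    rows = []
    for gene, sub in kept.groupby("gene", sort=True):
        hit = sub["sample_id"].nunique()
        vafs = sub["vaf"].to_numpy(dtype=float)
        rows.append({
            "gene": gene,
            "n_samples": int(hit),
            "incidence": f"{hit}/{len(universe)}",
            "min_vaf": float(vafs.min()),
            "median_vaf": float(np.median(vafs)),
            "low_vaf_flag": bool(vafs.min() <= 0.20),
        })
    return pd.DataFrame(rows)
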