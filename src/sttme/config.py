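"""Pipeline configuration.

Every threshold the analysis applies lives here with the published value as
its default, so a run is fully specified by one :class:`PipelineConfig` (or
the YAML file that mirrors it) plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULT_TFH_MARKERS = ("CXCL13", "MME", "BCL6", "PDCD1", "ICOS")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the spot-level TME pipeline.

    Attributes
    ----------
    min_umi, min_genes, max_mito
        Spot QC gates: a spot is kept iff total UMI >= ``min_umi`` AND
        detected genes >= ``min_genes`` AND mitochondrial fraction
        <= ``max_mito``.  The inequalities are strict on the removal side
        (a spot with exactly 500 UMIs passes).
    n_hvg, n_pcs
        Highly variable gene count and number of principal components used
        before clustering.
    provenance_threshold
        A cluster is called neoplastic iff the fraction of its spots coming
        from tumor samples is strictly greater than this value.
    tfh_markers
        Follicular-helper-T marker genes scored as supporting evidence for
        neoplastic calls.
    deg_fold, deg_detection, deg_q
        The three-part DEG rule: linear fold > deg_fold (default sqrt(2)),
        detection fraction >= deg_detection, BH-adjusted q < deg_q.
    enrich_p, enrich_q
        Dual significance gates for cell-type enrichment (p < 0.05 and
        BH q < 0.25).
    vaf_hom, pop_af
        Variant filter gates: VAF strictly greater than ``vaf_hom`` is
        removed as homozygous; population AF strictly greater than
        ``pop_af`` is removed as common.
    cells_per_spot
        Expected absolute cells per spot assumed by the deconvolution
        post-processing (and emulated by the generator).
    rounding
        ``"half_even"`` (default) or ``"half_up"`` for abundance rounding.
    activity_min
        A spot is LR-"active" when min(ligand, receptor) expression is
        strictly greater than this (default 0: both transcripts detected).
    provenance_on_counts
        Apply the neoplastic provenance rule to raw spot counts (default)
        or to per-sample-normalized fractions.
    """

    min_umi: int = 500
    min_genes: int = 500
    max_mito: float = 0.05
    n_hvg: int = 5000
    n_pcs: int = 24
    provenance_threshold: float = 0.95
    tfh_markers: tuple[str, ...] = DEFAULT_TFH_MARKERS
    deg_fold: float = 2.0 ** 0.5
    deg_detection: float = 0.25
    deg_q: float = 1e-4
    deg_eps: float = 1e-9
    enrich_p: float = 0.05
    enrich_q: float = 0.25
    vaf_hom: float = 0.90
    pop_af: float = 0.01
    cells_per_spot: float = 10.0
    rounding: str = "half_even"
    activity_min: float = 0.0
    provenance_on_counts: bool = True
    gene_panel: tuple[str, ...] = ("TET2", "DNMT3A", "IDH2", "RHOA")

    def __post_init__(self) -> None:
        if self.deg_fold <= 1:
            raise ValueError("deg_fold must exceed 1")
        for name in ("min_umi", "min_genes", "max_mito", "n_hvg", "n_pcs",
                     "deg_detection", "deg_q", "enrich_p", "enrich_q",
                     "vaf_hom", "pop_af", "cells_per_spot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rounding not in ("half_even", "half_up"):
            raise ValueError("rounding must be 'half_even' or 'half_up'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tfh_markers", "gene_panel"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tfh_markers"] = list(d["tfh_markers"])
        d["gene_panel"] = list(d["gene_panel"])
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
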