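"""End-to-end orchestration with one config, one seed and a run manifest.

Stage order mirrors the analysis: preprocess -> annotate -> composition ->
DEG -> LR activity -> signatures, with the variant and cohort branches
independent.  Every stage is a pure function of (inputs, config, seed);
all randomness flows from the root seed through named substreams.  All
outputs are plain text (CSV/TSV/JSON), so a re-run with the same config
and seed is byte-identical; only the manifest carries a timestamp.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .annotation import call_neoplastic, composition_similarity, profile_clusters
from .composition import enrichment_test, postprocess_abundance
from .config import PipelineConfig
from .datasets import CellAbundanceMatrix
from .de import find_degs
from .lr import DEFAULT_PAIR, LRPair, activity_fractions, spot_activity
from .preprocess import embed_and_cluster, normalize, qc_filter
from .signatures import GeneSignature, score_signatures
from .survival import cox_multivariate, km_logrank, relapse_test, stratify
from .synthetic import (STSimConfig, simulate_abundance_matrix, simulate_cohort,
                        simulate_st_dataset, simulate_variant_table)
from .variants import filter_cascade, recurrent_gene_summary

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "annotate", "composition", "deg",
          "lr_activity", "signatures", "variants", "cohort"]

# problem sizes for the default simulated demonstration run: small enough
# to iterate on, large enough that every stage has signal
DEFAULT_SIM_OVERRIDES = {"spots_per_sample": (150, 300), "qc_fail_rate": 0.05}
DEFAULT_VARIANTS = {"n_variants": 600}
DEFAULT_COHORT = {"n_patients": 120, "group_fraction": 0.3,
                  "hazard_ratio": 0.125, "censor_rate": 0.2}


def stage_seed(root_seed: int, stage: str) -> int:
    """Named substream: a stable child seed per stage, below 2^31."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(root_seed), idx]).generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Parsed pipeline YAML: per-stage blocks plus the analysis config."""

    seed: int = 0
    config: PipelineConfig = field(default_factory=PipelineConfig)
    sim: dict = field(default_factory=dict)
    variants: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        problems = [k for k in raw if k not in ("seed", "config", "sim", "variants",
                                                "cohort", "inputs")]
        if problems:
            raise ValueError(f"unknown top-level config keys: {problems}")
        cfg = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in (raw.get("config") or {}).items()})
        return cls(seed=int(raw.get("seed", 0)), config=cfg,
                   sim=raw.get("sim") or {}, variants=raw.get("variants") or {},
                   cohort=raw.get("cohort") or {}, inputs=raw.get("inputs") or {})


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(run_cfg: RunConfig, outdir: str | Path, simulate: bool = False) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    A stage with no available input is marked "skipped"; a stage failure
    aborts the run with the stage name while earlier outputs stay on
    disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = run_cfg.config
    manifest: dict = {
        "config_hash": cfg.content_hash(),
        "seed": run_cfg.seed,
        "stages": {},
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage: str, status: str, **info) -> None:
        manifest["stages"][stage] = {"status": status, **info}
        logger.info("stage %s: %s %s", stage, status, info)

    adata = truth = abundance = variants_df = cohort = None
    current = "simulate"
    try:
        if simulate:
            sim_kwargs = {**DEFAULT_SIM_OVERRIDES, **run_cfg.sim}
            if "spots_per_sample" in sim_kwargs:
                sim_kwargs["spots_per_sample"] = tuple(sim_kwargs["spots_per_sample"])
            sim_cfg = STSimConfig(seed=stage_seed(run_cfg.seed, "simulate"), **sim_kwargs)
            adata, truth = simulate_st_dataset(sim_cfg)
            abundance = simulate_abundance_matrix(truth)
            variants_df, fates = simulate_variant_table(
                seed=stage_seed(run_cfg.seed, "variants"),
                **{**DEFAULT_VARIANTS, **run_cfg.variants})
            cohort = simulate_cohort(seed=stage_seed(run_cfg.seed, "cohort"),
                                     **{**DEFAULT_COHORT, **run_cfg.cohort})
            record("simulate", "ok", n_spots=int(adata.n_obs), n_genes=int(adata.n_vars),
                   n_variants=len(variants_df), n_patients=len(cohort))
        else:
            if "mtx_dir" in run_cfg.inputs:
                adata = sio.read_mtx_dir(run_cfg.inputs["mtx_dir"])
            elif "h5ad" in run_cfg.inputs:
                adata = sio.read_h5ad(run_cfg.inputs["h5ad"])
            if "abundance_csv" in run_cfg.inputs:
                abundance = sio.read_abundance_csv(run_cfg.inputs["abundance_csv"])
            if "variants_tsv" in run_cfg.inputs:
                variants_df = sio.read_variants_tsv(run_cfg.inputs["variants_tsv"])
            if "cohort_csv" in run_cfg.inputs:
                cohort = sio.read_cohort_csv(run_cfg.inputs["cohort_csv"])
            record("simulate", "skipped")

        # --- ST branch -------------------------------------------------
        current = "preprocess"
        if adata is None:
            for s in ("preprocess", "annotate", "composition", "deg",
                      "lr_activity", "signatures"):
                record(s, "skipped")
        else:
            adata, report = qc_filter(adata, cfg)
            adata = normalize(adata)
            adata = embed_and_cluster(adata, cfg, seed=stage_seed(run_cfg.seed, "preprocess"))
            report.removed.rename_axis("barcode").to_csv(outdir / "qc_removed.csv")
            record("preprocess", "ok", n_in=report.n_input, n_kept=report.n_kept,
                   n_removed=report.n_removed,
                   n_clusters=int(adata.obs["cluster"].nunique()))

            current = "annotate"
            profiles = profile_clusters(adata, cfg)
            profiles, adata = call_neoplastic(profiles, adata, cfg)
            profiles.to_csv(outdir / "clusters.csv", index=False)
            n_neo = int((profiles["call"] == "neoplastic").sum())
            if n_neo >= 2:
                composition_similarity(adata).rename_axis("sample").to_csv(
                    outdir / "composition_similarity.csv")
            adata.obs.rename_axis("barcode").to_csv(outdir / "spots.csv")
            record("annotate", "ok", n_clusters=len(profiles), n_neoplastic=n_neo)

            current = "composition"
            if abundance is None:
                record("composition", "skipped")
            else:
                ab = postprocess_abundance(abundance.aligned_to(adata), cfg)
                sio.write_abundance_csv(ab, outdir / "abundance_post.csv", which="post")
                enrich = enrichment_test(ab, adata, cfg)
                enrich.to_csv(outdir / "enrichment.csv", index=False)
                record("composition", "ok", n_spots=len(ab.post),
                       n_significant=int(enrich["significant"].sum()))

            current = "deg"
            degs = find_degs(adata, "cluster", cfg)
            degs.to_csv(outdir / "degs.csv", index=False)
            record("deg", "ok", n_rows=len(degs), n_deg=int(degs["is_deg"].sum()))

            current = "lr_activity"
            pair = DEFAULT_PAIR if DEFAULT_PAIR.ligand in adata.var_names else None
            if pair is None:
                record("lr_activity", "skipped")
            else:
                res = spot_activity(adata, pair, cfg)
                frac = activity_fractions(res, adata)
                frac.to_csv(outdir / "lr_fractions.csv", index=False)
                record("lr_activity", "ok", n_strata=len(frac))

            current = "signatures"
            demo_sigs = _demo_signatures(adata)
            if not demo_sigs:
                record("signatures", "skipped")
            else:
                scores = score_signatures(adata, demo_sigs)
                scores.rename_axis("barcode").to_csv(outdir / "signature_scores.csv")
                record("signatures", "ok", n_signatures=len(demo_sigs))

        # --- variant branch --------------------------------------------
        current = "variants"
        if variants_df is None:
            record("variants", "skipped")
        else:
            kept, trace = filter_cascade(variants_df, cfg=cfg)
            sio.write_variants_tsv(kept, outdir / "variants_kept.tsv")
            trace.steps.to_csv(outdir / "variant_trace.csv", index=False)
            recurrent_gene_summary(kept).to_csv(outdir / "recurrent_genes.csv", index=False)
            record("variants", "ok", n_in=len(variants_df), n_kept=len(kept))

        # --- cohort branch ---------------------------------------------
        current = "cohort"
        if cohort is None:
            record("cohort", "skipped")
        else:
            strat = stratify(cohort.set_index("patient_id"))
            strat.groups.rename_axis("patient_id").to_csv(outdir / "stratification.csv")
            summary = {"cutpoints": strat.cutpoints}
            for endpoint in ("efs", "os"):
                _, chi2, p = km_logrank(cohort.set_index("patient_id"), strat.groups, endpoint)
                summary[endpoint] = {"logrank_chi2": round(chi2, 6), "logrank_p": round(p, 8)}
            table, fisher_p = relapse_test(cohort.set_index("patient_id"), strat.groups)
            summary["relapse"] = {"table": table.to_dict(), "fisher_p": round(fisher_p, 8)}
            cox = cox_multivariate(cohort.set_index("patient_id"), strat.groups,
                                   covariates=["age"])
            summary["cox"] = cox.to_dict(orient="records")
            _write_json(outdir / "survival_summary.json", summary)
            record("cohort", "ok", n_patients=len(cohort),
                   n_uncommon=int((strat.groups == "uncommon_TME").sum()))
    except Exception as err:
        record(current, "failed", error=str(err))
        _write_json(outdir / "manifest.json", manifest)
        raise RuntimeError(f"stage {current} failed: {err}") from err

    _write_json(outdir / "manifest.json", manifest)
    return manifest


def _demo_signatures(adata) -> list[GeneSignature]:
    """Built-in macrophage/B-cell demo signatures over present genes."""
    candidates = {
        "macrophage": ("CD68", "CD163", "C1QC", "CD14"),
        "b_cell": ("CD79A", "CD79B", "MS4A1"),
    }
    sigs = []
    for name, genes in candidates.items():
        present = tuple(g for g in genes if g in adata.var_names)
        if len(present) >= 2:
            sigs.append(GeneSignature(name, present, partner=None))
    return sigs
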