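"""Synthetic study inputs with exact ground truth.

Everything the pipeline consumes can be generated here: Visium-style spot
count matrices with planted QC failures and ligand-receptor coexpression,
deconvolution abundance matrices, annotated tumor-only variant tables with
per-rule fates, and a two-group survival cohort with a configurable hazard
ratio.  The emulation targets a six-section lymphoma study (four tumor
sections, two reactive lymph nodes, 1439-4799 spots each) in which spot
transcriptomes are cell mixtures and the tumor microenvironment is
stratified by a triple immunohistochemistry marker rule.

The generator is a first-class, tested component: a fixed config and seed
reproduce every output byte-for-byte, and every generated record has
exactly one ground-truth entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .datasets import MITO_PREFIX, CellAbundanceMatrix, compute_qc_metrics

TUMOR = "tumor"
NORMAL = "normal"
NEO = "neoplastic"
NONNEO = "nonneoplastic"

DEFAULT_CELL_TYPES = ("TFH", "B_naive", "B_GC", "Macrophage_M1", "T_CD8", "FDC")

# marker gene -> fold elevation in the owning cell type's expression profile
DEFAULT_MARKER_MAP: dict[str, dict[str, float]] = {
    "TFH": {"CXCL13": 8.0, "MME": 6.0, "BCL6": 5.0, "PDCD1": 6.0, "ICOS": 5.0},
    "B_naive": {"CD79A": 6.0, "CD79B": 6.0, "MS4A1": 6.0},
    "B_GC": {"CD40": 6.0, "AICDA": 8.0, "BCL2A1": 4.0},
    "Macrophage_M1": {"CD68": 6.0, "CD163": 5.0, "C1QC": 6.0, "CD14": 5.0},
    "T_CD8": {"CD8A": 8.0, "GZMB": 5.0},
    "FDC": {"CR2": 6.0, "FDCSP": 8.0},
}

# Dirichlet concentration per compartment over DEFAULT_CELL_TYPES: the
# neoplastic compartment is TFH- and macrophage-skewed, the nonneoplastic
# one B-cell-skewed.
DEFAULT_DIRICHLET = {
    NEO: (8.0, 0.5, 1.0, 3.0, 1.0, 0.5),
    NONNEO: (0.5, 4.0, 3.0, 1.0, 2.0, 1.0),
}

DEFAULT_LR_PAIRS = (("CD40LG", "CD40"),)

# Per-(sample, compartment) fraction of spots coexpressing each LR pair.
# AITL2 plays the uncommon, coexpression-poor section; "*" is the fallback.
DEFAULT_COEXPR_RATE = {
    ("AITL2", NEO): 0.11,
    ("AITL2", NONNEO): 0.04,
    ("*", NEO): 0.35,
    ("*", NONNEO): 0.20,
}

QC_FAIL_MODES = ("umi", "genes", "mito")


@dataclass
class STSimConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_samples_tumor: int = 4
    n_samples_normal: int = 2
    spots_per_sample: tuple[int, int] = (1439, 4799)
    n_genes: int = 1000
    nb_mean: float = 4.0
    nb_dispersion: float = 0.7
    mito_gene_fraction: float = 0.01
    qc_fail_rate: float = 0.05
    purity: float = 0.7  # fraction of tumor-sample spots that are neoplastic
    cells_per_spot: float = 10.0
    size_factor_sigma: float = 0.1
    # compartment-level expression program: genes elevated in neoplastic
    # spots, making compartments separable by clustering (as in tissue).
    # The program splits into n_neoplastic_programs disjoint sub-programs
    # (neoplastic subtypes) whose per-sample mix varies, so multiple
    # neoplastic clusters with sample-specific composition emerge.
    de_gene_count: int = 100
    de_fold: float = 3.0
    n_neoplastic_programs: int = 3
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    dirichlet_alpha: dict = field(default_factory=lambda: dict(DEFAULT_DIRICHLET))
    marker_map: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARKER_MAP.items()})
    lr_pairs: tuple[tuple[str, str], ...] = DEFAULT_LR_PAIRS
    coexpr_rate: dict = field(default_factory=lambda: dict(DEFAULT_COEXPR_RATE))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mito_gene_fraction", "qc_fail_rate", "purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("nb_mean", "nb_dispersion", "cells_per_spot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.spots_per_sample
        if not (0 < lo <= hi):
            raise ValueError("spots_per_sample range must satisfy 0 < lo <= hi")
        for comp in (NEO, NONNEO):
            if comp not in self.dirichlet_alpha:
                raise ValueError(f"dirichlet_alpha missing compartment {comp}")
            if len(self.dirichlet_alpha[comp]) != len(self.cell_types):
                raise ValueError("dirichlet_alpha length must match cell_types")
        for r in self.coexpr_rate.values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("coexpression rates must be in [0, 1]")
        unknown = set(self.marker_map) - set(self.cell_types)
        if unknown:
            raise ValueError(f"marker_map references unknown cell types: {sorted(unknown)}")

    # --- gene universe -------------------------------------------------
    def gene_names(self) -> list[str]:
        named: list[str] = []
        for genes in self.marker_map.values():
            for g in genes:
                if g not in named:
                    named.append(g)
        for lig, rec in self.lr_pairs:
            for g in (lig, rec):
                if g not in named:
                    named.append(g)
        n_mito = max(1, int(round(self.mito_gene_fraction * self.n_genes)))
        mito = [f"{MITO_PREFIX}{i+1}" for i in range(n_mito)]
        n_filler = self.n_genes - len(named) - n_mito
        if n_filler < 0:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {len(named)} named marker/LR "
                f"genes plus {n_mito} mitochondrial genes"
            )
        filler = [f"GENE{i+1:04d}" for i in range(n_filler)]
        return named + mito + filler

    def sample_names(self) -> tuple[list[str], list[str]]:
        tumor = [f"AITL{i+1}" for i in range(self.n_samples_tumor)]
        normal = [f"LN{i+1}" for i in range(self.n_samples_normal)]
        return tumor, normal

    def coexpr_rate_for(self, sample: str, compartment: str) -> float:
        key = (sample, compartment)
        if key in self.coexpr_rate:
            return self.coexpr_rate[key]
        return self.coexpr_rate.get(("*", compartment), 0.0)


@dataclass
class GroundTruth:
    """One entry per generated record.

    ``spots``: per-spot sample, tissue type, true compartment, planted QC
    failure mode (NaN = clean) and true total cell count.
    ``proportions`` / ``cell_counts``: true cell-type mixtures and the
    integer cell counts underlying the abundance matrix.
    ``coexpression``: per-spot boolean indicator per LR pair ("LIG:REC"
    columns).  Indicators of QC-corrupted spots are not meaningful.
    ``gene_fold``: analytic expected mean expression per compartment and
    their ratio, for every gene.
    """

    spots: pd.DataFrame
    proportions: pd.DataFrame
    cell_counts: pd.DataFrame
    coexpression: pd.DataFrame
    gene_fold: pd.DataFrame
    config: STSimConfig


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + m^2/dispersion (gamma-Poisson)."""
    mean = np.maximum(mean, 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _repair_qc(row: np.ndarray, mito_idx: np.ndarray, filler_idx: np.ndarray,
               min_umi: int = 500, min_genes: int = 500, max_mito: float = 0.05) -> None:
    """Lift a clean spot back over the QC gates (in place).

    Natural QC failures are vanishingly rare at the default depth, but the
    contract is that *only* planted spots fail, so the few stragglers are
    nudged over the thresholds by adding single counts on filler genes
    (which also dilutes the mitochondrial fraction).
    """
    for _ in range(200):
        total = int(row.sum())
        detected = int((row > 0).sum())
        mito = int(row[mito_idx].sum())
        ok = total >= min_umi and detected >= min_genes and mito <= max_mito * total
        if ok:
            return
        zeros = filler_idx[row[filler_idx] == 0]
        if detected < min_genes and len(zeros):
            add = zeros[: min_genes - detected]
            row[add] += 1
        else:
            row[filler_idx[:50]] += 1


def simulate_st_dataset(config: STSimConfig) -> tuple[AnnData, GroundTruth]:
    """Generate a multi-sample spot dataset plus its ground truth.

    Counts are negative-binomial around spot-level gene means that mix
    cell-type expression profiles with Dirichlet-drawn proportions; a
    configured fraction of spots is corrupted to fail exactly one QC gate;
    ligand-receptor coexpression is imposed per (sample, compartment) at
    the configured rate by forcing both transcripts detected in designated
    spots and zeroing the ligand elsewhere.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    mito_idx = np.array([i for i, g in enumerate(genes) if g.startswith(MITO_PREFIX)])
    filler_idx = np.array([i for i, g in enumerate(genes) if g.startswith("GENE")])
    types = list(config.cell_types)

    # relative expression profile per cell type (fold over baseline)
    rel = np.ones((len(types), n_genes))
    for t, markers in config.marker_map.items():
        ti = types.index(t)
        for g, fold in markers.items():
            if g not in gene_idx:
                raise ValueError(f"marker gene {g} not in gene universe")
            rel[ti, gene_idx[g]] = fold
    base_mean = np.full(n_genes, config.nb_mean)
    base_mean[mito_idx] = config.nb_mean  # MT- genes at baseline depth

    # neoplastic expression program on the last de_gene_count filler genes,
    # split into disjoint sub-programs (one per neoplastic subtype); a
    # shared core (first sub-block) is elevated in every neoplastic spot
    if config.de_gene_count > len(filler_idx):
        raise ValueError("de_gene_count exceeds available filler genes")
    de_idx = filler_idx[len(filler_idx) - config.de_gene_count:]
    n_prog = max(1, config.n_neoplastic_programs)
    prog_blocks = np.array_split(de_idx, n_prog + 1)  # block 0 = shared core
    shared_idx = prog_blocks[0]
    subtype_blocks = prog_blocks[1:]

    tumor_samples, normal_samples = config.sample_names()
    blocks, obs_rows = [], []
    prop_rows, count_rows, coex_rows = [], [], []
    pair_names = [f"{lig}:{rec}" for lig, rec in config.lr_pairs]

    for sample in tumor_samples + normal_samples:
        is_tumor = sample in tumor_samples
        lo, hi = config.spots_per_sample
        n_spots = int(rng.integers(lo, hi + 1))
        if is_tumor:
            comp = np.where(rng.random(n_spots) < config.purity, NEO, NONNEO)
        else:
            comp = np.full(n_spots, NONNEO)

        props = np.empty((n_spots, len(types)))
        for c in (NEO, NONNEO):
            m = comp == c
            if m.any():
                props[m] = rng.dirichlet(np.asarray(config.dirichlet_alpha[c], float), int(m.sum()))
        n_cells = np.maximum(rng.poisson(config.cells_per_spot, n_spots), 1)
        cell_counts = np.vstack([rng.multinomial(n, p) for n, p in zip(n_cells, props)])

        sf = np.exp(rng.normal(0.0, config.size_factor_sigma, n_spots))
        mu = sf[:, None] * (props @ rel) * base_mean[None, :]
        subtype = np.full(n_spots, -1)
        if len(de_idx):
            neo_mask = comp == NEO
            if neo_mask.any():
                # per-sample subtype mix: each section has its own blend of
                # neoplastic programs
                mix = rng.dirichlet(np.full(n_prog, 2.0))
                subtype[neo_mask] = rng.choice(n_prog, size=int(neo_mask.sum()), p=mix)
                if len(shared_idx):
                    mu[np.ix_(neo_mask, shared_idx)] *= config.de_fold
                for j, block in enumerate(subtype_blocks):
                    m = neo_mask & (subtype == j)
                    if m.any() and len(block):
                        mu[np.ix_(m, block)] *= config.de_fold
        counts = _nb_draw(rng, mu, config.nb_dispersion).astype(np.int64)

        # ligand-receptor coexpression imposed per compartment
        coex = np.zeros((n_spots, len(config.lr_pairs)), dtype=bool)
        for k, (lig, rec) in enumerate(config.lr_pairs):
            li, ri = gene_idx[lig], gene_idx[rec]
            for c in (NEO, NONNEO):
                m = comp == c
                if not m.any():
                    continue
                rate = config.coexpr_rate_for(sample, c)
                coex[m, k] = rng.random(int(m.sum())) < rate
            on = coex[:, k]
            counts[on, li] = np.maximum(counts[on, li], 1)
            counts[on, ri] = np.maximum(counts[on, ri], 1)
            counts[~on, li] = 0  # break accidental coexpression

        # planted QC failures, one mode each
        fail = rng.random(n_spots) < config.qc_fail_rate
        modes = np.full(n_spots, None, dtype=object)
        for i in np.where(fail)[0]:
            mode = QC_FAIL_MODES[int(rng.integers(len(QC_FAIL_MODES)))]
            modes[i] = mode
            row = counts[i]
            total = max(int(row.sum()), 1)
            if mode == "umi":
                t = int(rng.integers(20, 500))
                counts[i] = rng.multinomial(t, row / total)
            elif mode == "genes":
                k = int(rng.integers(50, 200))
                keep = rng.choice(n_genes, size=k, replace=False)
                newrow = np.zeros(n_genes, dtype=np.int64)
                newrow[keep] = rng.multinomial(int(rng.integers(800, 2000)), np.full(k, 1.0 / k))
                counts[i] = newrow
            else:  # mito
                extra = int(np.ceil(0.10 * total))
                boost = rng.multinomial(extra, np.full(len(mito_idx), 1.0 / len(mito_idx)))
                counts[i, mito_idx] += boost

        # guarantee clean spots clear every gate
        clean = ~fail
        tot = counts.sum(axis=1)
        det = (counts > 0).sum(axis=1)
        mito_c = counts[:, mito_idx].sum(axis=1)
        bad = clean & ((tot < 500) | (det < 500) | (mito_c > 0.05 * tot))
        for i in np.where(bad)[0]:
            _repair_qc(counts[i], mito_idx, filler_idx)

        barcodes = [f"{sample}_s{i:05d}" for i in range(n_spots)]
        blocks.append(sparse.csr_matrix(counts))
        obs_rows.append(pd.DataFrame({
            "sample_id": sample,
            "tissue_type": TUMOR if is_tumor else NORMAL,
            "array_row": np.arange(n_spots) // 64,
            "array_col": np.arange(n_spots) % 64,
        }, index=barcodes))
        prop_rows.append(pd.DataFrame(props, index=barcodes, columns=types))
        count_rows.append(pd.DataFrame(cell_counts, index=barcodes, columns=types))
        coex_rows.append(pd.DataFrame(coex, index=barcodes, columns=pair_names))
        obs_rows[-1]["compartment_true"] = comp
        obs_rows[-1]["qc_fail_mode"] = modes
        obs_rows[-1]["n_cells_true"] = n_cells
        obs_rows[-1]["neoplastic_program"] = subtype

    obs = pd.concat(obs_rows)
    adata = AnnData(
        X=sparse.vstack(blocks).tocsr(),
        obs=obs[["sample_id", "tissue_type", "array_row", "array_col"]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obs_names = obs.index
    compute_qc_metrics(adata)

    # analytic expected means per compartment (size factor averages to
    # exp(sigma^2/2); it cancels in the fold)
    gene_fold = {}
    for c in (NEO, NONNEO):
        alpha = np.asarray(config.dirichlet_alpha[c], float)
        e_props = alpha / alpha.sum()
        gene_fold[c] = (e_props @ rel) * base_mean
    de_block = np.full(n_genes, "", dtype=object)
    if len(de_idx):
        gene_fold[NEO] = gene_fold[NEO].copy()
        # shared-core genes carry the full fold in every neoplastic spot;
        # subtype genes are elevated in 1/n_prog of them in expectation
        gene_fold[NEO][shared_idx] *= config.de_fold
        de_block[shared_idx] = "shared"
        for j, block in enumerate(subtype_blocks):
            gene_fold[NEO][block] *= 1.0 + (config.de_fold - 1.0) / n_prog
            de_block[block] = f"subtype{j}"
    de_status = de_block != ""
    eps = 1e-12
    truth = GroundTruth(
        spots=obs[["sample_id", "tissue_type", "compartment_true", "qc_fail_mode",
                   "n_cells_true", "neoplastic_program"]].copy(),
        proportions=pd.concat(prop_rows),
        cell_counts=pd.concat(count_rows),
        coexpression=pd.concat(coex_rows),
        gene_fold=pd.DataFrame({
            "mean_neoplastic": gene_fold[NEO],
            "mean_nonneoplastic": gene_fold[NONNEO],
            "fold": (gene_fold[NEO] + eps) / (gene_fold[NONNEO] + eps),
            "de_program": de_status,
            "de_block": de_block,
        }, index=genes),
        config=config,
    )
    return adata, truth


def simulate_abundance_matrix(truth: GroundTruth, noise_sd: float = 0.1,
                              seed: int | None = None) -> CellAbundanceMatrix:
    """Real-valued deconvolution-style abundances around the true counts.

    Abundance = true integer cell count + Gaussian noise, floored at zero
    (the deconvolution posterior mean is nonnegative).  ``noise_sd=0``
    returns the counts exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None else seed)
    counts = truth.cell_counts.to_numpy(dtype=float)
    noisy = counts + rng.normal(0.0, noise_sd, counts.shape) if noise_sd > 0 else counts
    raw = np.maximum(noisy, 0.0)
    return CellAbundanceMatrix(pd.DataFrame(raw, index=truth.cell_counts.index,
                                            columns=truth.cell_counts.columns))


# --------------------------------------------------------------------------
# variant tables
# --------------------------------------------------------------------------

VARIANT_FATES = ("kept", "fail_consequence", "fail_clinvar", "fail_vaf",
                 "fail_popfreq", "fail_panel")

_PASS_CSQ = ("missense", "stopgain", "frameshift")
_FAIL_CSQ = ("intronic", "synonymous")
_PASS_CLNSIG = (None, "Uncertain_significance", "Pathogenic")
_FAIL_CLNSIG = ("Benign", "Likely_benign", "Benign/Likely_benign")
_OFF_PANEL_GENES = ("KRAS", "TP53", "BRAF", "NOTCH1", "MYC")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence",
                   "clinvar_class", "pop_af", "vaf", "depth", "sample_id"]


def simulate_variant_table(n_variants: int, rule_mix: dict[str, float] | None = None,
                           seed: int = 0, panel: tuple[str, ...] = ("TET2", "DNMT3A", "IDH2", "RHOA"),
                           n_samples: int = 4) -> tuple[pd.DataFrame, pd.Series]:
    """Annotated variants whose first-failing filter rule is known.

    Each variant is built to pass every rule before its assigned fate and
    fail exactly at it ("kept" passes all five); rules after the failing
    one are also satisfied, so the fate is the unique removal step.
    Returns the variant table and the per-variant true fate.
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    mix = dict.fromkeys(VARIANT_FATES, 0.0) | (rule_mix or {f: 1 / 6 for f in VARIANT_FATES})
    unknown = set(mix) - set(VARIANT_FATES)
    if unknown:
        raise ValueError(f"unknown fates in rule_mix: {sorted(unknown)}")
    probs = np.array([mix[f] for f in VARIANT_FATES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("rule_mix must sum to 1")

    rng = np.random.default_rng(seed)
    fates = np.array(VARIANT_FATES)[rng.choice(len(VARIANT_FATES), size=n_variants, p=probs)]
    bases = np.array(list("ACGT"))
    rows = []
    for i, fate in enumerate(fates):
        csq = rng.choice(_FAIL_CSQ) if fate == "fail_consequence" else rng.choice(_PASS_CSQ)
        cln = rng.choice(_FAIL_CLNSIG) if fate == "fail_clinvar" else _PASS_CLNSIG[int(rng.integers(3))]
        vaf = float(rng.uniform(0.901, 0.999)) if fate == "fail_vaf" else float(rng.uniform(0.21, 0.85))
        pop = float(rng.uniform(0.011, 0.4)) if fate == "fail_popfreq" else (
            None if rng.random() < 0.5 else float(rng.uniform(0.0, 0.009)))
        gene = rng.choice(_OFF_PANEL_GENES) if fate == "fail_panel" else rng.choice(panel)
        ref, alt = rng.choice(bases, size=2, replace=False)
        rows.append({
            "chrom": f"chr{int(rng.integers(1, 23))}",
            "pos": int(rng.integers(1, 2_000_000)),
            "ref": str(ref), "alt": str(alt),
            "gene": str(gene), "consequence": str(csq),
            "clinvar_class": cln, "pop_af": pop, "vaf": vaf,
            "depth": int(rng.integers(50, 500)),
            "sample_id": f"AITL{int(rng.integers(1, n_samples + 1))}",
        })
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    variants.index = [f"v{i:05d}" for i in range(n_variants)]
    return variants, pd.Series(fates, index=variants.index, name="true_fate")


# --------------------------------------------------------------------------
# survival cohort
# --------------------------------------------------------------------------

COHORT_COLUMNS = ["patient_id", "CD68", "CD163", "CD40LG", "efs_days", "efs_event",
                  "os_days", "os_event", "relapse", "age", "sex", "stage", "group_true"]


def simulate_cohort(n_patients: int, group_fraction: float = 0.3,
                    hazard_ratio: float = 0.125, censor_rate: float = 0.2,
                    seed: int = 0, marker_sep: float = 3.0,
                    base_efs_days: float = 500.0,
                    relapse_rates: tuple[float, float] = (0.15, 0.55)) -> pd.DataFrame:
    """Two-group survival cohort stratifiable by the triple-marker rule.

    EFS times are exponential with rate ratio ``hazard_ratio`` between the
    uncommon-TME group and the rest (0.125 reproduces an eight-fold longer
    mean EFS).  Marker scores sit ``marker_sep`` standard deviations on the
    correct side of zero (CD68/CD163 high and CD40LG low in the uncommon
    group), so the dichotomizing rule recovers the true group.  OS uses an
    attenuated rate ratio (sqrt of the EFS one); censoring is independent
    per endpoint at ``censor_rate``.
    """
    if not 0.0 < group_fraction < 1.0:
        raise ValueError("group_fraction must be in (0, 1)")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    uncommon = rng.random(n_patients) < group_fraction
    sign = np.where(uncommon, 1.0, -1.0)
    cd68 = rng.normal(sign * marker_sep, 1.0)
    cd163 = rng.normal(sign * marker_sep, 1.0)
    cd40lg = rng.normal(-sign * marker_sep, 1.0)

    base_rate = 1.0 / base_efs_days
    efs_rate = np.where(uncommon, base_rate * hazard_ratio, base_rate)
    efs = rng.exponential(1.0 / efs_rate)
    os_rate = np.where(uncommon, base_rate * np.sqrt(hazard_ratio), base_rate) / 1.5
    os_t = rng.exponential(1.0 / os_rate)

    def censor(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cens = rng.random(n_patients) < censor_rate
        obs = np.where(cens, times * rng.uniform(0.05, 0.95, n_patients), times)
        return np.maximum(obs, 1e-6), (~cens).astype(int)

    efs_obs, efs_event = censor(efs)
    os_obs, os_event = censor(os_t)
    relapse_p = np.where(uncommon, relapse_rates[0], relapse_rates[1])
    relapse = (rng.random(n_patients) < relapse_p).astype(int)

    return pd.DataFrame({
        "patient_id": [f"P{i+1:03d}" for i in range(n_patients)],
        "CD68": cd68, "CD163": cd163, "CD40LG": cd40lg,
        "efs_days": efs_obs, "efs_event": efs_event,
        "os_days": os_obs, "os_event": os_event,
        "relapse": relapse,
        "age": rng.normal(62, 10, n_patients).round(1),
        "sex": rng.choice(["M", "F"], n_patients),
        "stage": rng.integers(1, 5, n_patients),
        "group_true": np.where(uncommon, "uncommon_TME", "other"),
    })


# --------------------------------------------------------------------------
# purpose-built small datasets
# --------------------------------------------------------------------------

def planted_provenance_dataset(rates: tuple[float, ...] = (0.99, 0.96, 0.95, 0.50),
                               spots_per_cluster: int = 400, seed: int = 0) -> AnnData:
    """Clustered dataset whose per-cluster tumor-origin fractions are exact.

    Cluster k has exactly ``round(rate_k * spots_per_cluster)`` spots from
    tumor samples; counts are Poisson noise over a small gene panel that
    includes the TFH markers, normalized so downstream annotation runs.
    """
    from .preprocess import normalize  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    markers = list(DEFAULT_TFH := ("CXCL13", "MME", "BCL6", "PDCD1", "ICOS"))
    genes = markers + [f"GENE{i+1:04d}" for i in range(55)]
    rows, obs = [], []
    for k, rate in enumerate(rates):
        n_tumor = int(round(rate * spots_per_cluster))
        for i in range(spots_per_cluster):
            is_tumor = i < n_tumor
            sample = f"AITL{(i % 2) + 1}" if is_tumor else f"LN{(i % 2) + 1}"
            obs.append({
                "sample_id": sample,
                "tissue_type": TUMOR if is_tumor else NORMAL,
                "cluster": str(k),
            })
            rows.append(rng.poisson(2.0, len(genes)))
    adata = AnnData(
        X=sparse.csr_matrix(np.array(rows)),
        obs=pd.DataFrame(obs, index=[f"spot{i:05d}" for i in range(len(obs))]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obs["cluster"] = adata.obs["cluster"].astype("category")
    compute_qc_metrics(adata)
    # guard against zero-total spots before normalization
    zero = adata.obs["total_umi"] == 0
    if zero.any():
        X = adata.X.tolil()
        for i in np.where(zero)[0]:
            X[i, 0] = 1
        adata.X = X.tocsr()
        compute_qc_metrics(adata)
    return normalize(adata)
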