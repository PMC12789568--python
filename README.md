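# sttme — spatial-transcriptomics tumor-microenvironment analysis

`sttme` is a tested, reusable pipeline for spot-level (Visium-style)
analysis of lymphoma tissue sections and their tumor microenvironment
(TME), built around the analysis design used for angioimmunoblastic
T-cell lymphoma (AITL): a follicular-helper-T (TFH)-derived lymphoma
whose spots mix neoplastic cells with B cells, macrophages and stroma.
It is aimed at computational biologists who want the individual analysis
rules as well-specified, unit-tested functions rather than a notebook.

## What it implements

- **Spot QC** — a spot is removed when total UMI < 500, detected genes
  < 500, or mitochondrial fraction > 5% (strict inequalities; `MT-`
  prefix); median-total scaling + `log1p` normalization; dispersion-based
  highly-variable-gene selection; PCA plus a pluggable clustering engine
  (Leiden by default, any `(embedding, seed) -> labels` callable works).
- **Neoplastic cluster calling** — a cluster is *neoplastic* iff the
  fraction of its spots originating from tumor samples is strictly
  greater than 0.95; TFH-marker scores (*CXCL13, MME, BCL6, PDCD1,
  ICOS*) are reported as supporting evidence. Per-sample neoplastic
  composition vectors are compared by Pearson correlation.
- **Deconvolution post-processing** — cell-type abundances are rounded;
  a spot with no estimated cells receives one cell of its
  highest-abundance type. Compartment enrichment per cell type uses the
  two-sided Mann–Whitney U test with Benjamini–Hochberg correction,
  flagged at p < 0.05 and q < 0.25.
- **Differential expression** — a gene is a DEG for a cluster iff its
  linear fold change exceeds 2^0.5, it is detected in ≥ 25% of the
  cluster's spots, and BH-adjusted q < 10⁻⁴ (Mann–Whitney one-vs-rest,
  or an explicit cluster contrast).
- **Ligand–receptor activity** — the activity of an axis such as
  *CD40–CD40LG* in a spot is min(ligand, receptor) normalized
  expression; a spot is *active* when both transcripts are detected.
  Active fractions are reported per (sample, compartment) and compared
  with Fisher's exact test.
- **Signature scoring** — mean z-score module scores for gene sets
  (M1/M2 polarization, angiogenesis/phagocytosis dichotomies, ...),
  with rank tests between spot strata.
- **Tumor-only variant filtering** — five ordered rules with an audit
  trail: intronic/synonymous, ClinVar benign, VAF > 90% (homozygous
  germline), population AF > 1%, off-panel gene (default panel *TET2,
  DNMT3A, IDH2, RHOA*).
- **Survival** — patients stratified by CD68^high CD163^high CD40LG^low;
  native Kaplan–Meier and log-rank, Fisher exact relapse comparison,
  multivariate Cox (lifelines backend).
- **Synthetic data** — a first-class generator producing every input
  with exact ground truth: negative-binomial spot counts over cell-type
  mixtures, planted QC failures, per-(sample, compartment) LR
  coexpression rates, variant tables with assigned fates, and survival
  cohorts with a configurable hazard ratio.

## Worked example

```python
from sttme import STSimConfig, simulate_st_dataset, simulate_abundance_matrix
from sttme.preprocess import qc_filter, normalize, embed_and_cluster
from sttme.annotation import profile_clusters, call_neoplastic
from sttme.composition import postprocess_abundance, enrichment_test

cfg = STSimConfig(seed=0, spots_per_sample=(150, 300))
adata, truth = simulate_st_dataset(cfg)
adata, report = qc_filter(adata)
adata = normalize(adata)
adata = embed_and_cluster(adata, seed=0)
profiles, adata = call_neoplastic(profile_clusters(adata), adata)
```

prints (via `report` and `profiles`):

```
QC: kept 1316/1386 spots (70 removed)
cluster_id  n_spots  fraction_tumor_origin  tfh_score       call
         0      629                  0.456      1.309      mixed
         1      307                  0.984      2.020 neoplastic
         2      196                  0.959      2.001 neoplastic
         3      184                  0.973      1.976 neoplastic
```

The 70 removed spots are exactly the generator's planted QC failures.
Clusters 1–3 derive > 95% of their spots from tumor sections and score
highest on the TFH markers, so they are called neoplastic; cluster 0
mixes tumor and normal spots and stays `mixed`. Downstream, cell-type
enrichment recovers the planted mixture shifts:

```
    cell_type             p             q          direction  significant
          TFH 2.068843e-189 1.241306e-188   up_in_neoplastic         True
      B_naive 1.180301e-144 3.540902e-144 down_in_neoplastic         True
Macrophage_M1  1.936512e-32  2.904768e-32   up_in_neoplastic         True
```

and the *CD40–CD40LG* active fraction per sample/compartment matches the
configured coexpression rates, including the "uncommon",
coexpression-poor sample (`AITL2`: 0.096 neoplastic vs 0.35–0.38 in the
other tumor sections).

The same flow is available from the shell:

```bash
sttme run --simulate --out results/demo        # full pipeline + manifest
sttme simulate variants -n 600 --out v.tsv
sttme varfilter --tsv v.tsv --out kept.tsv --trace trace.csv
```

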