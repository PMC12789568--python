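# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the design decisions taken where the analysis
recipe left genuine choices open.

## Spot QC and normalization

A spot passes QC iff total UMI ≥ 500 AND detected genes ≥ 500 AND
mitochondrial fraction ≤ 0.05. The removal-side inequalities are strict
("less than 500", "greater than 5%"), so a spot sitting exactly on a
threshold is retained; the QC report records each removed spot's first
failing gate in the fixed order UMI → genes → mito. Mitochondrial genes
are identified by the human `MT-` name prefix, and the fraction is
computed on raw counts before any normalization.

Normalization is median-total scaling followed by `log1p`: each spot's
counts are scaled so its total equals the median pre-scaling total. The
transform preserves the zero pattern, so "detected" (count ≥ 1) is
identical on raw and normalized data. The method is the common
single-cell toolkit convention; it is a configurable choice, not a claim
of uniqueness.

Highly variable genes are the top *n* by variance-to-mean dispersion of
the normalized layer, with ties broken lexicographically by gene id so
the selection is deterministic. Clustering operates on a PCA embedding
(24 components by default) of the HVG submatrix and is a *contract*: any
callable `(embedding, seed) -> integer labels` may be supplied. The
default engine is Leiden community detection on a symmetrized kNN graph
(k = 15, resolution 1.0, seeded); a fixed-k KMeans engine ships for
cases where k is known. An externally batch-corrected embedding (e.g.
Harmony output) can be passed directly, bypassing the internal PCA —
batch correction itself is out of scope and the generator produces
batch-free data.

## Neoplastic cluster calling

Each cluster's sample-provenance profile is tallied from spot counts
(optionally from per-sample-normalized fractions; both modes exposed
because the choice is not forced by the rule itself). A cluster is
called **neoplastic** iff its tumor-sample fraction is strictly greater
than 0.95, **normal_dominant** iff its normal-sample fraction is, and
**mixed** otherwise. Provenance decides the call; the TFH marker score
(unweighted mean over *CXCL13, MME, BCL6, PDCD1, ICOS* of per-spot
normalized expression, averaged per cluster) is reported as evidence,
and a neoplastic call with a below-median TFH score triggers a warning
rather than a veto — the provenance rule is the one with a stated
numeric threshold. Spots inherit a compartment label (neoplastic /
nonneoplastic) that partitions the dataset. Sample-to-sample similarity
of the neoplastic TME is the Pearson correlation between per-sample
vectors of neoplastic-spot fractions across neoplastic clusters.

## Deconvolution post-processing and enrichment

Posterior-mean abundances are rounded half-to-even (half-up available);
any spot whose rounded row is all zero receives exactly one cell of its
argmax raw-abundance type, with exact ties going to the
lexicographically first type name — both tie-break and rounding mode are
documented choices, since neither is forced by the rounding rule.
Enrichment between compartments is a per-cell-type two-sided
Mann–Whitney U on spot-level abundances (the spot, not the cluster mean,
is the test unit), BH-adjusted across cell types, flagged at p < 0.05
AND q < 0.25. Rounded abundances are tested by default, consistent with
the stated post-processing; raw mode is available.

## Mann–Whitney U implementation

The U statistic uses the midrank convention. For group sizes ≤ 7 the
two-sided p-value is computed by full enumeration of all C(n₁+n₂, n₁)
group assignments of the pooled values — exact under ties — counting
assignments whose |U − n₁n₂/2| is at least the observed deviation.
Larger samples use the normal approximation with tie correction and
continuity correction. The approximation agrees with the exact method to
< 0.01 at moderate n on untied data and degrades gracefully under heavy
ties at very small n (which the exact path covers). `scipy`'s
implementation serves as an independent cross-check in the tests, never
as the implementation.

## Differential expression

For each (gene, cluster): two-sided Mann–Whitney of normalized
expression, cluster vs all other spots; fold change computed on the
linear (de-logged) normalized scale as (mean_in + ε)/(mean_rest + ε)
with ε = 10⁻⁹ guarding empty denominators; detection fraction is the
share of the cluster's spots with raw count ≥ 1; BH adjustment within
each cluster across genes (one-vs-rest tables are reported per cluster).
`is_deg` requires fold > 2^0.5 AND detection ≥ 0.25 AND q < 10⁻⁴.
Fold thresholds are conventionally linear-scale, hence the de-logged
means; scaling the linear normalized matrix by any positive constant
leaves folds, ranks and decisions unchanged. Explicit two-group cluster
contrasts use the same rule; swapping the groups inverts the fold and
preserves the p-value.

## Ligand–receptor activity

Activity of a pair in a spot = min(ligand, receptor) normalized
expression ("coexpression quantified by the lower expression level");
the statistic is symmetric and monotone in both genes. A spot is
*active* when the minimum is strictly positive, i.e. both transcripts
detected — the activity threshold is configurable since coloring by the
minimum does not pin down a cutoff. Active fractions are computed over
all QC-passing spots of each (sample, compartment) stratum (whole
sections, not only cluster-assigned spots); strata are compared with
Fisher's exact test on active/inactive counts. *CD40LG–CD40* is the
shipped default pair; arbitrary pair lists are accepted.

## Signature scoring

The single-sample score of a gene set in a spot is the mean over the
set's present genes of the gene's across-spot z-scored normalized
expression (the module-score family). The KS-like rank statistic of
GSVA is deliberately **not** re-implemented: the downstream claims are
ordinal comparisons between spot groups, which the mean z-score
supports, and an externally computed score matrix can be supplied
wherever a score table is accepted. Zero-variance genes contribute 0.
Shipped signature files are user-editable placeholders; curated
macrophage-polarization gene lists should be supplied by the user.

## Tumor-only variant filtering

Five rules in order, each with strict inequalities: (1) intronic or
synonymous consequence; (2) ClinVar benign / likely benign
(case-insensitive; any class containing "pathogenic" is never removed);
(3) VAF > 0.90 (homozygous germline); (4) population AF > 0.01; (5)
gene outside the panel (default *TET2, DNMT3A, IDH2, RHOA*; a file
supplied panel overrides). Null ClinVar passes step 2 and null
population AF passes step 4 (absence from the database implies rarity).
Order affects only the audit trail; kept membership equals the
intersection of the five predicates, which the tests verify by brute
force. Multi-transcript consequence strings are resolved by a
"worst-consequence wins" flag (default: a variant is only discarded when
*every* listed consequence is intronic/synonymous); this resolution is a
package choice, not asserted as canonical.

## Survival analysis

Stratification: uncommon_TME iff CD68 > cut AND CD163 > cut AND
CD40LG ≤ cut, with per-marker cohort medians as default cut points
(explicit overrides accepted; the "high/low" cuts are not canonically
defined, so the median split is a documented default). Kaplan–Meier and
the two-group log-rank test are implemented natively — they are the
module's testable core — using the product-limit estimator and the
hypergeometric-variance (Mantel–Haenszel) statistic with all tied events
sharing one risk set; `lifelines` is the independent cross-check. The
relapse comparison is a two-sided Fisher exact test (the choice of test
is a package decision; chi-square is a trivial substitution).
Multivariate Cox regression is delegated to `lifelines.CoxPHFitter`
behind a thin contract returning hazard ratios with 95% CIs;
re-deriving Newton–Raphson for the partial likelihood is out of scope.

## Synthetic-data model

The generator emulates a six-section study: 4 tumor + 2 normal samples,
spots per sample uniform in [1439, 4799]. Spot counts are negative
binomial (mean m, dispersion θ shared across genes; var = m + m²/θ)
around spot-level gene means that mix cell-type expression profiles
with Dirichlet-drawn proportions; marker genes are fold-elevated in
their owning cell type. Defaults: 1000 genes, m = 4, θ = 0.7, 1% `MT-`
genes, lognormal spot size factors (σ = 0.1) — sized so clean spots
clear every QC gate with a wide margin (a rare natural straggler is
nudged back over the gates so that *only* planted spots fail, making the
QC contract exact). Planted QC failures are corrupted to fail exactly
one gate: downsampling to < 500 UMIs, concentration onto < 500 genes,
or a mitochondrial boost past 5%.

Neoplastic spots (Bernoulli *purity* per tumor-sample spot, default
0.7 — tumor content is a free parameter, stated only to exceed 20% in
tissue) additionally express a 100-gene program at 3-fold, split into a
shared core plus three disjoint subtype blocks whose per-sample mix is
Dirichlet-drawn; this makes compartments separable by clustering and
yields several neoplastic clusters with sample-specific composition, as
in tissue. Ligand–receptor coexpression is imposed per
(sample, compartment): designated spots get both transcripts forced
detected, all other spots have the ligand zeroed, so the active-fraction
ground truth is exact. Default rates emulate the uncommon-sample
pattern (AITL2: 0.11 neoplastic / 0.04 nonneoplastic; others 0.35 /
0.20).

Cell counts per spot are Poisson(10) (floored at 1), matching the
assumed 10 cells per location; the abundance matrix adds Gaussian noise
to the true integer counts and floors at zero. Variant tables assign
each record a fate and construct it to pass every rule before that fate
and fail exactly there (later rules also pass, making the fate unique).
Survival cohorts draw exponential EFS times with the configured rate
ratio between groups (0.125 reproduces an eight-fold mean-EFS
difference), marker scores 3 SDs on the correct side of zero,
independent censoring, group-dependent relapse probabilities, and an
attenuated (square-root) rate ratio for OS.

**What the generator does not emulate:** spatial autocorrelation of
histology, batch effects, EBV status, gene–gene correlation beyond the
mixture structure, and realistic transcriptome-wide gene-mean
distributions. Passing tests therefore demonstrate correctness of the
*rules and estimators* under the stated statistical model, not
robustness to every artifact of real tissue data.

## Numerical and reproducibility choices

All randomness flows from one root seed through named per-stage
substreams (`SeedSequence` children, kept below 2³¹). Pipeline outputs
are plain text (CSV/TSV/JSON/MTX), so a rerun with the same config and
seed is byte-identical; only the manifest carries a timestamp. HDF5
(h5ad) I/O is provided for interoperability but kept off the
determinism-audited path because HDF5 embeds object-creation times.
Degenerate inputs fail loudly: empty post-QC datasets, zero-total spots
at normalization, single-spot clusters (skipped with warning),
zero-margin 2×2 tables (p = 1 with warning), constant Cox covariates,
and non-convergent fits all raise or warn explicitly.

Problem sizes in the test and acceptance runs (≈3000-spot QC datasets,
2000-spot coexpression sections, 200-patient cohorts with 200–1000
replicates, 10 000-row variant and abundance tables) were chosen as the
smallest sizes at which the binomial/Monte-Carlo tolerances of the
checks are comfortably discriminating.

## Known limitations

- The default Leiden resolution is not claimed to reproduce any
  particular cluster count on real tissue; cluster granularity is data-
  and parameter-dependent.
- The mean z-score is not GSVA; scores are comparable across spots
  within one dataset, not across datasets.
- Tumor-only filtering consumes annotations (consequence, ClinVar,
  population AF); it does not compute them.
- The Cox stage inherits lifelines' Efron tie handling; exact
  duplication invariance holds only up to tie effects.
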