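# Methods

This package re-implements, as a tested pipeline over synthetic data, a
stratification analysis of osteoarthritis (OA) knee-cartilage
transcriptomes: bulk RNA-Seq counts from OA patients and non-OA controls
are normalised and tested for differential expression; the OA patients are
partitioned into molecular subgroups by network-regularised non-negative
matrix factorisation (NMF) with consensus clustering; a compact gene panel
and margin classifier assign new patients to a subgroup; and pathway,
subnetwork and secreted-protein reports characterise the subgroups.

## Synthetic cohorts

Real cohort data are not bundled; the `synthdata` module generates cohorts
with the statistical structure the analysis assumes, so every downstream
stage is testable without downloads.

Counts are drawn per gene and sample from a negative binomial in the
mean/dispersion parameterisation Var = μ + αμ², realised as a gamma-Poisson
mixture. The default design mirrors the cohort shape the analysis targets:

| parameter | default | meaning |
|---|---|---|
| `n_control` / `n_groupA` / `n_groupB` | 10 / 24 / 18 | non-OA controls and the two OA subgroups |
| `n_shared_de` | 300 | genes DE in both subgroups vs control |
| `n_specificA`, `n_specificB` | 150, 150 | subgroup-specific DE genes |
| `lfc_magnitude` | 1.0 | planted |log2 fold change|, signs alternating |
| `dispersion` α | 0.1 | NB dispersion, a mid-range bulk RNA-Seq value |
| `baseline_mean_log_range` | (1, 3) | log10 range of baseline means (10–1000 counts) |
| `n_batches`, `batch_lfc_sd` | 2, 0.5 | additive log2-mean batch shifts on a random 20% of genes |

Library-size factors are drawn log-uniform in [0.5, 2] so the
median-of-ratios normalisation genuinely matters; batches are assigned
round-robin so they stay condition-balanced (the location-only batch
correction assumes no batch-condition confounding). No real cohort's
per-gene dispersions or depth profiles are bundled, so these defaults are
realistic stand-ins rather than fitted values; they were chosen once from
typical bulk RNA-Seq magnitudes.

What the generator does *not* emulate: gene-gene correlation beyond the
planted subgroup structure, gene-length effects, isoform structure,
outlier samples, or covariate (age/sex/BMI) effects on expression. Passing
recovery tests therefore demonstrate correctness of the machinery under the
model's own assumptions, not performance on real cartilage data.

The companion network generator plants the three DE gene sets as dense
modules (within-module edge probability `module_density`, default 0.5) over
a sparse Erdős–Rényi background (expected degree 2) and augments the graph
with a minimal spanning structure so it is connected.

## Differential expression

A deliberately simplified negative-binomial Wald test in the DESeq2 family:

1. **Size factors** — median over genes (with all-positive counts) of
   count/geometric-mean ratios.
2. **Fold change** — log2 of the ratio of group means of normalised counts,
   with a prior count of 0.5 added to both means to stabilise low-count
   genes.
3. **Dispersion** — per-gene method of moments on normalised counts
   (removing the Poisson part of the within-group variance), floored at
   1e-8, then taken as the maximum of the gene estimate and a fitted
   α = a₀ + a₁/μ mean-dispersion trend. Using the maximum rather than a
   weighted shrinkage is the conservative choice: it protects false-
   discovery calibration for genes whose moment estimate is an
   underestimate, at a negligible power cost for the effect sizes of
   interest (a 4-fold change at n = 20 + 20 has a Wald z near 20).
4. **Test** — Wald statistic log2FC / SE with a delta-method SE
   (Var(q) = μ/s + αμ² per sample), two-sided normal reference,
   Benjamini-Hochberg adjustment.
5. **DEG rule** — |fold change| ≥ 1.5 (boundary inclusive, applied as
   |log2FC| ≥ log2 1.5) and adjusted p ≤ 0.10.

No Cox-Reid adjusted profile likelihood and no fold-change shrinkage prior
are implemented: the pipeline's contract is the thresholded DEG call,
validated by simulation (null false-discovery proportion and planted-gene
power), not bit-compatibility with DESeq2. A test cross-checks fold-change
estimates against pydeseq2 on a small cohort.

Genes with fewer than 10 total counts are dropped before testing (recorded
in provenance); all-zero genes are excluded and reported, never an error.

## Stratification

**Model.** Non-negative X (gene × patient) is factorised as X ≈ WH
minimising ‖X − WH‖²_F + λ·tr(WᵀLW), where L is the degree-normalised
Laplacian of the gene interaction network restricted to the clustering
genes. The penalty pulls gene factors toward smoothness on the network, so
factors align with interaction modules. Multiplicative updates
(W ← W∘(XHᵀ+λAW)⁄(WHHᵀ+λDW), H ← H∘(WᵀX)⁄(WᵀWH), ε-guarded denominators)
keep the objective non-increasing; with λ = 0 or no network they reduce
exactly to Lee–Seung NMF, preserving the standard-NMF comparison.
λ defaults to 1.0 on the normalised Laplacian and is configurable.
Network-regularised NMF appears in the literature in more than one variant
(influence-matrix smoothing vs a Laplacian penalty); the Laplacian form is
adopted here and recorded in provenance.

**Input.** The batch-corrected log2 expression of the OA patients only,
restricted to the top-variance genes (default 2000) and min-shifted per
gene to non-negativity. Variance ranking is the standard surrogate for an
unspecified feature-selection step.

**Consensus.** 500 runs (default) of NMF from random inits on random 80%
patient subsamples; per-run hard labels are the argmax row of H (ties to
the lowest index). The co-clustering matrix divides co-labelling counts by
co-sampling counts. The number of clusters k is chosen over 2..5 by the
mean silhouette of an average-linkage cut of 1 − co-clustering, ties toward
smaller k.

**Assignment and exclusion.** Per-sample silhouettes on the consensus
dissimilarity; patients with silhouette < 0 — closer to another cluster
than their own, i.e. concordant with neither subgroup — are left
unassigned. Zero is the canonical "closer to another cluster than its own"
boundary; no sharper numeric rule is assumed.

**Covariate check.** Association of the final labels with clinical
covariates is report-only: Fisher's exact test for 2×2 contingency tables,
chi-squared for larger tables (scipy offers no r×c exact test), Wilcoxon
rank-sum for continuous covariates, BH across covariates.

## The intermediate-patient fixture

The exclusion contract ("exactly the two planted intermediates are
unassigned at threshold 0") is exercised by a constructed fixture, and its
construction is the least obvious design in the package, so it is recorded
here.

For a *homogeneous* intermediate profile the average-linkage cut almost
always assigns a sample to the cluster it co-occurs with most, making its
silhouette ≥ 0: a negative silhouette requires *chain capture* — the
intermediates must merge early with boundary-side members of the cluster
they co-occur with *less*. The generator therefore plants:

- two **intermediates**: noise-free expected-count profiles interpolating
  the *realised* (empirical) A and B group centroids on the log scale,
  placed slightly on the A side of the consensus boundary. Carrying no
  sampling noise of their own, their per-run assignment is driven entirely
  by the run-to-run wobble of the boundary (random inits and subsampling),
  which is what "concords with neither group" means operationally;
- three **outposts**: group-B patients replaced by noise-free profiles
  slightly on the B side of the boundary. Their flips track the same
  boundary wobble, so they co-occur strongly with the intermediates and
  chain them into the B consensus cluster while the intermediates'
  co-occurrence stays closer to A — the negative-silhouette configuration.

Because the realised boundary position varies with the noise realisation,
the generator self-calibrates: a probe-ladder consensus pre-run measures
co-occurrence with group A as a function of the mixing fraction θ, and the
placements are corrected iteratively (slope-based, to a tolerance of 0.025
in co-occurrence units) on the assembled cohort. The fixture is generated
batch-free, since batch shifts would displace each planted profile
differently after correction. Calibration costs a few consensus pre-runs
(~1 minute); the capture geometry has a finite tolerance window, so the
behaviour is guaranteed for the documented fixture seed, not for arbitrary
seeds.

## Marker panel and classifier

Nearest shrunken centroids in the canonical formulation:
d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀)) with m_k = √(1/n_k − 1/n), pooled
within-class s_i, and s₀ = median(s_i); soft-thresholding by Δ; the panel
is the set of genes with any surviving d′_ik, ordered by max_k |d′_ik|.
`panel_of_size` finds the smallest Δ whose panel has at most the requested
size by searching the sorted |d| magnitudes directly (the panel size is a
step function of Δ). Δ can also be tuned by stratified CV with a parsimony
tie-break (largest Δ at minimal error).

The panel feeds a linear soft-margin SVM (C = 1.0, not tuned inside the
reporting CV to avoid optimistic bias). Validation is stratified 5-fold CV
with per-gene standardisation computed on training folds only; the AUC is
rank-based (Mann–Whitney) on the pooled held-out decision scores — pooling
is more stable than per-fold averaging at cohort sizes of a few dozen.
RT-qPCR panels measured as −ΔCt are accepted as log2-scale input; the
standardisation absorbs the scale convention.

## Pathways, subnetworks, biomarkers

**ORA** — upper-tail hypergeometric test of a DEG list against a GMT
collection, BH across sets. The universe defaults to the genes actually
tested for DE, guarding against background inflation.

**Subnetworks** — a simplified active-module formulation of scoring
interaction-connected gene sets by their total differential expression:
node scores weight·|log2FC| (weights from a random walk with restart on a
seed-gene list, or uniform), greedy growth from local score maxima with the
size-normalised score Σ weight·|log2FC| / √|S| (the standard correction
against trivially large modules), Jaccard > 0.5 deduplication, and a
permutation null that re-grows under node-label permutations of the fold
changes with the same rule capped at the observed size
(p = (1 + #{perm ≥ obs})/(1 + n_perm)). Cross-species phenotype-network
variants of this module search exist; their phenotype-ontology inputs are
out of scope here, and the preserved contract is the
interaction-connected, expression-scored module search with an honest null
(verified uniform on null inputs by a KS check).

**Biomarkers** — DEGs of the A-vs-B contrast intersected with a
user-supplied secreted-protein list (the annotation is an input, not a
bundled database); fold increases are reported on the linear scale,
2^|log2FC|, sorted within the higher-expressing group. Secreted genes never
tested for DE are counted in a side channel rather than silently dropped.

## Pipeline and reproducibility

`run_pipeline` executes preprocess → DE (OA vs non-OA) → stratify (OA
patients only — controls inform DE but not the clustering) → per-group DE
(A and B vs control, B vs A) → classifier → pathways → biomarkers, writing
every intermediate artefact plus a manifest with input SHA-256 checksums,
parameters and per-stage seeds. All randomness derives from one root seed
via named per-stage substreams, so stages are independently re-runnable and
two runs of one config are byte-identical. A failed stage aborts with its
name; completed artefacts persist.

## Numerical choices and degenerate inputs

- Multiplicative updates guard denominators at 1e-10; convergence is
  declared at relative objective change < 1e-4 (consensus runs cap at 100
  iterations — at 2000×42 scale label assignments stabilise well before
  the factor values do).
- Argmax ties (cluster labels), silhouette ties at k selection (smaller k)
  and delta ties (larger delta) are all broken deterministically.
- Singleton clusters get silhouette 0; a single cluster is an error.
- Empty panels are valid results of total shrinkage; prediction then falls
  back to the majority class (prior-only discriminant).
- The BH step-up is *not* idempotent on its own output (soft-threshold
  counterexamples exist); the implementation is validated against
  statsmodels instead.
- RWR redistributes the mass lost at dangling nodes to the restart vector
  and solves to residual < 1e-10.

## Problem sizes used in tests

Simulation-heavy checks run at the default cohort scale (2000 genes,
52 samples, 500 consensus runs) where the contract demands it; unit tests
use scaled-down designs (hundreds of genes, a few dozen samples) chosen so
the whole suite completes in minutes while keeping every recovery margin
comfortably away from its threshold. `scripts/acceptance.py` runs the full
default-design analysis with 200 consensus runs over k = 2..4, 500
subnetwork permutations, and 20/40 replicate simulations for the
calibration summaries.

## Known limitations

- The DE stage's normal-reference Wald test is anti-conservative for very
  small cohorts (n < ~8 per arm); the study-scale designs used here are
  comfortably larger.
- Location-only batch correction assumes additive, condition-balanced
  batch structure — exactly what the generator produces; scale or
  confounded batch effects would need an empirical-Bayes method.
- Consensus clustering at 500 runs leaves Monte-Carlo noise of about ±0.02
  in co-clustering entries; silhouette-based decisions within that margin
  are not stable, which is precisely why borderline patients are excluded
  rather than forced into a subgroup.
- The subnetwork permutation null permutes fold changes over nodes,
  preserving the network but not any correlation between expression and
  degree.
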