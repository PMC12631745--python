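# Methods

This note records the models, parameter choices and numerical conventions
behind `phenosig`, and what the synthetic benchmark does and does not
establish about behaviour on real data.

## Phenotype definition from two IC50 sources

Each cell line contributes a point (IC50_A, IC50_B) in µM from two
independent drug-response screens. Ward agglomerative clustering
(Euclidean distance, via `scipy.cluster.hierarchy`) is applied to the raw
concentrations; a `log_scale` option ln-transforms first, as a guard when
the concentration range spans orders of magnitude. The number of clusters
k is chosen by maximal mean silhouette over k = 2..10 for both the Ward
tree (cut by cluster count) and seeded k-means (10 restarts); the
hierarchical solution is preferred whenever its best silhouette is at
least as high, because the dendrogram is the more interpretable object.
A fixed-height tree cut (`cut_distance`, default 8) is available as an
alternative to silhouette selection.

Clusters are converted to a binary phenotype by a cross-source
consistency rule. Within each source the mean rank of each cluster's
IC50 values is compared with the grand mean rank (n+1)/2: the cluster
ranked high in *both* sources (largest rank sum among qualifiers) is
resistant, the cluster low in both is sensitive, and every other cluster
is platform-discordant and excluded from supervised analysis. Ranks make
the rule invariant to any monotone transform of either source. The rule
is deliberately stricter than "argmax of mean rank": when a discordant
cluster shares one source's high-IC50 level with the resistant cluster,
their mean ranks in that source are statistically tied and an argmax
would flip on noise.

One-way ANOVA (scipy) with Tukey HSD pairwise correction (statsmodels)
reports whether the clusters differ per source; a degenerate all-constant
input returns p = 1 rather than a division error.

## Differential expression

A deliberately transparent negative-binomial Wald test in the DESeq2
family, not a reimplementation of the full estimator:

* **Size factors** — median-of-ratios over the genes positive in every
  sample, normalized to geometric mean 1.
* **Dispersion** — method of moments on normalized counts,
  phi = (s² − m)/m² averaged over the two groups, floored at 1e−8. No
  shrinkage toward a mean–dispersion trend.
* **Test** — log2(mean_resistant / mean_sensitive) with a pseudo-count of
  0.5 replacing zero group means; delta-method standard error from the NB
  variance m + phi·m²; two-sided normal p; Benjamini–Hochberg adjustment
  (step-up with cumulative-minimum enforcement, capped at 1). Genes with
  all-zero counts get log2FC 0 and p 1 by definition.
* **Gates** — strict inequalities: padj < 0.05 and |log2FC| > 1, split by
  sign. Genes with total count below 10 across samples are removed first
  (`min_total_count`, a common stability convention; exposed in config).

Omitting shrinkage, outlier replacement and independent filtering keeps
the test auditable; the full external NB-GLM estimator can be slotted in
as a comparator, and the test suite checks sign agreement with it on a
small simulated matrix. Under the null the plug-in Wald test is
approximately calibrated at the cohort sizes used here (type-I error
0.05 ± 0.02 at 50 samples/class is asserted in the suite).

## Attribution ranking

The classifier is LightGBM (binary objective, resistant = positive
class) on log10(TPM+1) features of all filtered genes — no prior feature
reduction, so weak but informative genes can surface. Defaults: max
depth 8, learning rate 0.1, L1 = L2 = 0.1, at most 300 trees with
AUC-based early stopping (50-round patience) on an internal stratified
20% slice of the training data, `min_child_samples` 10,
`colsample_bytree` 0.2, single-threaded and deterministic under the
seed. The feature subsampling matters at this shape (≈1,600 genes,
≈74 training lines): without it, boosting concentrates its splits on a
few of the mutually redundant informative genes and the rest receive
near-zero attribution; sampling 20% of features per tree spreads the
splits, which both regularizes and stabilizes the ranking.

Attributions are exact TreeSHAP values from LightGBM's `pred_contrib`
output, which satisfy the additivity identity (per-sample attributions
plus the expected-value offset equal the raw margin; asserted to 1e−6).
They are computed only for held-out-fold samples inside stratified
5-fold cross-validation repeated 12 times (repeat r uses seed
base_seed + r), so no sample is explained by a model that saw it, and
aggregated as the mean |SHAP| per gene over repeats × folds × samples.
Samples are canonicalized to id order before folding, making the summary
invariant to input column order. "Contributing" genes are those with
mean |SHAP| strictly above `epsilon` (default 0).

Holdout metrics come from a single stratified split (default 20% test,
per-class allocation by rounding); ROC and PR AUCs are trapezoidal
integrals of the sklearn curves, and the ROC AUC equals the
Mann–Whitney pair-ordering statistic (ties counted one half) — asserted
against a brute-force oracle.

## Panel selection

The candidate panel is the sign-partitioned intersection: DEG-up ∩
contributing genes and DEG-down ∩ contributing genes. Recursive
elimination then runs on standardized features: at each step the current
panel's specificity is measured by stratified 5-fold cross-validation of
an L2 logistic model (C = 1, lbfgs, 1,000 iterations; the scaler is
refitted inside every training fold to avoid leakage; prediction at
cutoff 0.5), the model is refitted on all data, and the gene with the
smallest absolute standardized coefficient is dropped (ties to the
lexicographically smallest id, for determinism). The fold partition is
drawn once per run and reused across panel sizes so the specificity
curve is comparable along the path. Specificity — true sensitive lines
predicted sensitive — is the scorer because a false "resistant" call
would wrongly deny a patient a usable drug.

The optimal panel is the size with maximal mean specificity, with ties
resolved toward the **larger** panel. With strong planted signal the CV
specificity curve saturates at exactly 1.0 over a wide range of sizes;
a parsimony tie-break would then collapse the panel to a handful of
genes and discard most true biomarkers, so under equal specificity the
panel retains them instead. Zero-variance features get coefficient 0 by
convention (with a warning) so they are eliminated first rather than
perturbing the fit.

## Signature model

`SignatureClassifier` standardizes the panel's log10(TPM+1) expression
(centers and scales learned on training data) and fits L2 logistic
regression (C = 1, lbfgs, iteration cap 1,000). The score is the
logistic of the standardized dot product; class "resistant" requires
score > cutoff, default 0.5 — the balanced region in cutoff sweeps. The
sweep reports accuracy, recall, precision, NPV, specificity and F1 at
cutoffs 0.1..0.9; undefined ratios (0/0) are reported as missing, never
silently as 0. The model serializes to a plain-text descriptor (gene,
center, scale, coefficient; intercept; cutoff) so any implementation can
rescore.

## Validation statistics

* **Kaplan–Meier / log-rank / Cox** via lifelines (median = earliest time
  the curve reaches 0.5, NaN if never; two-group log-rank with
  hypergeometric variance, asserted against a hand-tabulated oracle; Cox
  partial likelihood with Efron tie handling and Wald CIs). Covariates
  with fewer than two observed levels are flagged `estimable = False`
  and excluded rather than fabricated.
* **Landmark ROC** at a horizon h: positives died by h, negatives
  followed event-free past h, patients censored before h excluded from
  both classes — the simplest censoring-aware definition.
* **Cross-drug panel** — per drug, Welch's t-test and a 95% CI on
  natural-log IC50, exponentiated to a geometric-mean fold change
  (resistant / sensitive) whose interval cannot cover negative
  concentrations; optional BH correction across drugs (the same
  implementation as the DEG stage). Arms with fewer than 2 lines skip
  the drug with a recorded reason.
* **Fold-change concordance** — Pearson r with the t-transform p, for
  comparing log2 fold changes across platforms.

## Synthetic cohort generator

The generator emulates the structure the pipeline assumes, with defaults
mirroring a realistic two-source discovery cohort:

| parameter | default | meaning |
|---|---|---|
| n_sensitive / n_resistant / n_discordant | 60 / 55 / 35 | cohort shape |
| n_genes, planted up/down | 2,000, 15 + 15 | transcriptome size, signature |
| signature_log2fc | 1.5 | planted shift, resistant vs sensitive |
| nb_dispersion | 0.2 | NB dispersion (variance m + 0.2 m²) |
| base mean | log-normal(ln 50, 1.2) | gene expression levels |
| signature_min_base_mean | 20 counts | floor for planted genes only |
| libsize_log_sd | 0.2 | library-size factor spread |
| IC50 class means | 10 / 70 µM | boundary near 30 µM |
| ic50_log_sd / cross_source_noise_sd | 0.15 / 0.1 | shared and per-source ln-scale noise |

IC50s: each line has a shared log-normal deviate plus independent
per-source noise around its class mean; the discordant pool is split
between the two cross-platform directions, producing the four blobs a
real two-screen panel shows. Counts are NB with planted ±log2FC shifts
for truth genes in the resistant class; log10(TPM+1) is derived by
per-sample total scaling with unit gene lengths (the pipeline only uses
within-sample scaled expression, so true lengths add nothing testable).
Planted genes' base means are floored at 20 counts: a "signature gene"
drawn from the deep low-expression tail (mean below ~1 count) contains
no recoverable signal at all, which would make planted-truth recovery
checks vacuous; detectable expression is also what makes a biomarker a
biomarker. Survival is exponential with a group hazard ratio and
independent exponential censoring tuned to the requested censored
fraction; the drug panel is log-normal with per-drug class shifts. Every
generator is a pure function of (config, seed).

**What the benchmark does not emulate:** gene–gene and pathway
correlation structure, per-gene dispersion trends, graded (non-binary)
resistance phenotypes, batch effects, and any relation between
expression and survival beyond the class label. Passing tests therefore
demonstrate that the machinery recovers known structure under its own
assumptions — near-perfect holdout AUCs on synthetic cohorts say nothing
about accuracy on real screens, where class overlap is substantial.

## Problem sizes in the test suite

The acceptance-style checks run the full default cohort (150 lines ×
2,000 genes, 12 × 5-fold CV) over 10 seeds, the DEG calibration on a
2,000-gene null, the elimination benchmark on 5 + 45 genes at n = 200
over 10 seeds, and the survival recovery at n = 1,000 (Cox) and
n = 400 × 40 simulations (log-rank power). Unit tests use reduced
cohorts (≈60 lines × 250 genes). These sizes were chosen to exercise
the full default configuration while keeping the suite comfortably
runnable on a laptop.

## Known limitations

* The NB Wald test is anti-conservative for very small groups (< 10 per
  class); the suite only asserts calibration at the cohort scale.
* Silhouette-based k selection assumes compact, comparable-spread
  clusters; heavily skewed raw IC50 distributions may need `log_scale`.
* The elimination path refits the scaler per fold but draws one fold
  partition per run; a different seed can move the peak when the
  specificity curve is flat.
* Signature scores are uncalibrated probabilities (no Platt/isotonic
  step); the cutoff sweep is the intended tool for choosing an operating
  point, and clinical cutoff optimization is out of scope.
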