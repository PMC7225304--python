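# Methods

## Model and procedure

The pipeline derives a malignancy-specific expression signature from a
merged, multi-dataset microarray cohort with three comparison groups:
control spleen (CSP), the target malignancy (SMZL), and other
secondary-lymphoid-tissue B-cell lymphomas (TBCL). Expression values
are log2 intensities in a genes × samples matrix with missing values
permitted throughout; every statistic is computed over non-missing
entries.

### Preprocessing

* **log2 transform** clamps linear intensities at a positive floor
  (default 1.0) before taking log2; matrices already on the log2 scale
  skip this (the run config declares the input scale, since the
  summarisation step producing probe-set intensities is upstream of
  this package).
* **Quantile normalization** maps every sample onto the common
  distribution of cross-sample order-statistic means. Ties receive the
  mean of the rank means over the tied positions; missing values are
  excluded from ranking and columns with missing entries are mapped
  through the reference distribution by quantile interpolation. On
  tie-free complete data the transform is exactly idempotent and
  equalises sorted column vectors bitwise; ties necessarily break exact
  idempotence (tied entries share one value, which shifts the next
  round's reference slightly) — the invariants are therefore asserted
  on continuous data, where ties have probability zero.
* **Variation filter**: a gene is kept iff at least 10% of its
  non-missing values differ from the gene median by ≥ log2(1.5)
  (1.5-fold on the intensity scale) and at most 60% of its values are
  missing. "At least 10%" is inclusive, so a gene at exactly the
  threshold fraction is retained; an all-missing gene counts as 100%
  missing and is dropped, not an error.
* **Replicate averaging** and **probe collapsing**: replicate rows are
  averaged per sample; multiple probes per gene symbol reduce to the
  probe with maximal mean intensity across samples (missing ignored),
  ties keeping the earlier probe for determinism.
* **Unsupervised clustering** (reporting only): average-linkage
  agglomeration of samples under the distance 1 − Pearson r, computed
  on centered/scaled genes with pairwise-complete missing handling;
  exported as Newick text.

### Class comparison and SAM

The univariate stage uses the pooled-variance two-sample t statistic
with two-sided p-values from the t distribution (a Welch variant is
available behind a flag; the pooled form is the classical univariate
option in microarray suites). Genes with fewer than two observations
per group or zero pooled variance are flagged unevaluable and carried
through rather than dropped.

SAM moderates the t statistic with a fudge factor s₀:
d(i) = (x̄₁ − x̄₂)/(s(i) + s₀), s(i) being the pooled standard error,
so d with s₀ = 0 equals the pooled t exactly (asserted to 1e−9 in the
tests). s₀ is chosen from the candidate grid of s-percentiles
{0, 5, …, 95}: for each candidate the genes are split into ten
s-quantile windows, the median absolute deviation of d is computed per
window, and the candidate minimising the coefficient of variation of
those spreads wins, ties going to the smallest candidate — the standard
variance-stabilisation recipe.

The permutation null redraws balanced label assignments (group sizes
preserved); when the number of distinct assignments does not exceed the
requested count, all are enumerated exactly once, otherwise distinct
assignments are sampled without replacement under the run seed. For a
threshold Δ, asymmetric cutpoints are found by moving away from the
origin along sorted d until d departs from the expected null order
statistic d̄ by ≥ Δ; all genes beyond the cutpoints are called. The
FDR estimate is the median, across permutations, of null genes beyond
the cutpoints, divided by the number called, with π₀ fixed at 1
(conservative; π₀ estimation is a possible extension, off by design).
When nothing is called the FDR is reported as 0. Δ is the smallest
value on a 200-point grid spanning [0, max|d − d̄|] whose estimate
meets the target with at least one gene called; if no Δ qualifies, the
empty-call Δ is returned with a warning.

### Signature and TPIS

The signature is the intersection of the two SAM-called sets obtained
on the genes that already passed p < 10⁻⁷ in both univariate
comparisons; the subset chain (signature ⊆ SAM-called ⊆ strict-p set,
per comparison) is asserted at run time, and stage counts, s₀, Δ and
FDR estimates land in the provenance record. Any stage producing an
empty set yields an empty signature whose provenance names the stage.

TPIS is score-proportional: within each comparison and direction, a
gene's impact is |d| / |d_max| so the top-scoring probe gets exactly
1.0 — this reproduces the ratio form of the reference worked example
(7.196 / 7.852 = 0.91645), which an ordinal percent rank cannot without
knowing the list length. Down-regulated genes are ranked against the
most-negative d of their comparison. The ranking pool is the SAM-called
set of the comparison (the signature is a subset of it). TPIS is the
per-gene sum of the two impacts, and entries are ordered by TPIS
descending with ties broken by gene id; the per-gene reading of the
"sum of scores" was adopted because the score's purpose is ranking
individual markers.

### Prediction

Leave-one-out cross-validation over a designated gene list, two classes
at a time. Within each fold, genes are re-selected on the training
samples only at p < α (default 0.01) — honest nested selection; a
fixed-list mode skips re-selection for sensitivity analysis. Folds
whose selected set is empty fall back to the training majority class
and are flagged in the report. Missing entries are imputed with
training-fold gene means before classification. The method roster is
the standard six: compound covariate predictor (t-weighted sum score,
thresholded at the midpoint of class-mean scores), diagonal LDA
(per-gene pooled variances, no covariance), nearest centroid, 1-NN and
3-NN (Euclidean), and a linear SVM with cost 1. CCP and DLDA drop
zero-variance genes with a warning. Reported rates are per-method
fractions of correct held-out calls plus their mean.

### IHC scoring

SIS is the mean of available rater scores per image; OSIS the mean of
per-image SIS per sample (fewer than five images triggers a warning,
not an error). Group comparisons use the same pooled t-test as the
expression stage; prognostic association is Pearson correlation of
OSIS with ordinal clinical stage (Spearman available, stage being
ordinal; Pearson is the default because the reference analyses report
r on staged scores). No multiple-testing correction is applied across
markers by default, matching per-marker reporting; a Benjamini–
Hochberg switch exists for users.

## Synthetic data: what it emulates and what it does not

`generate_cohort` draws per-gene baseline means N(8, 2²) on the log2
scale, adds a class effect, a per-dataset batch offset N(0, batch_sd²)
per gene, and N(0, noise_sd²) noise, then masks entries completely at
random. Signature genes shift by `effect_size` × `noise_sd` in the
target class only, with random sign so both directions are exercised;
pan-lymphoma genes shift identically in both malignant classes —
differential against controls but not target-unique, which is exactly
what the dual intersection must reject. Defaults fix the study
conditions: 40/40/40 samples, 5,000 genes, 135 signature genes at a
2-SD shift, 200 pan-lymphoma genes, noise_sd 0.5 log2 units (a typical
within-gene spread for summarised expression arrays), 4 datasets with
batch_sd 0.3, 2% missingness.

Dataset membership is assigned round-robin within each class, so batch
is orthogonal to class by construction. Real multi-cohort merges are
rarely that kind — source datasets are often class-confounded, which
single-platform restriction mitigates but does not remove. Passing the
planted-recovery tests therefore shows the statistical chain works when
batch and class are unconfounded; it does not certify robustness to
confounded batch structure, probe-level artifacts, or platform mixing,
none of which the generator emulates. The IHC generator likewise models
rater noise as i.i.d. Gaussian around a shared true intensity, not
systematic rater bias.

## Numerical choices and degenerate inputs

* Sample sizes in the tests and the acceptance script follow the study
  conditions above; the pure-null calibration uses 50 cohorts of 1,000
  genes (10 + 10 samples) with 100 permutations each.
* Determinism: one run seed expands via `numpy.random.SeedSequence`
  into independent per-stage seeds (permutations per comparison,
  simulation, prediction), all below 2³¹, so stages are individually
  reproducible.
* Strict inequality at p-value thresholds (p < α); inclusive fraction
  at the variation filter; mergesort everywhere a stable order matters
  (probe ties, TPIS ties, rank computation).
* Degenerate inputs: single-sample quantile normalization warns and
  returns the input; constant genes are an error in center/scale
  (callers filter first) but an unevaluable flag in the test stages; a
  sample pair sharing fewer than three genes is a clustering error.

## Known limitations

* Two-class prediction only; no multi-class or survival variants.
* SAM here is the two-class unpaired form; π₀ is fixed at 1.
* The replication path re-evaluates a fixed signature on a new cohort
  and requires ≥ 80% gene coverage; it does no cross-platform
  harmonisation.
* Probe-set summarisation from raw array files is out of scope; the
  pipeline starts at probe-set-level matrices.
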