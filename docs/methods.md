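# Methods

This note records the models, parameter choices and numerical conventions
behind `braakstage`, and what the synthetic cohort does and does not
emulate.

## Problem setting

Each brain region is analysed independently. The unit of analysis is a
`RegionDataset`: a dense samples × genes expression matrix keyed by
ENTREZ gene IDs, aligned through a sample → subject map to a clinical
table carrying the Braak neurofibrillary-tangle score (0–VI). Braak
scores collapse to three ordinal stage groups — Early (0–II), Mid
(III–IV), Late (V–VI) — and samples whose subject lacks a parseable
Braak score are dropped at alignment (never imputed). Roman-numeral
Braak entries ("III") are accepted and mapped to integers, since both
notations circulate in clinical tables.

## Preprocessing

Order of operations: variance filter → IQR robust scaling → Z-score →
QC → duplicate-ID aggregation.

* **Variance filter**: strict `variance < threshold` on the raw values,
  ddof = 0, default threshold 0.1. The scale on which a 0.1 cutoff is
  meaningful depends on upstream normalization of the input data, so the
  threshold is configurable; no log transform is applied.
* **Robust scaling**: per gene, (x − median)/IQR with the IQR computed
  as the 75th − 25th percentile under linear interpolation. Genes with
  IQR = 0 are set to all-zero columns by default (`iqr_zero_policy =
  "zeros"`), so degenerate genes survive numerically instead of
  producing non-finite values; a `skip_gene` policy drops them instead.
* **Z-score**: per gene to mean 0 and SD 1 with ddof = 0, so the
  post-hoc SD is exactly 1; zero-variance columns pass through as zeros.
* **QC**: the mean over genes of per-gene means and of per-gene SDs is
  computed on the standardized matrix *before* duplicate aggregation,
  because averaging standardized duplicate columns changes their
  variance. The chain therefore reports mean-of-means = 0 and
  mean-of-SDs = 1 to float precision by construction; the QC is a
  verification of the implementation, not a stochastic outcome.
* **Duplicate aggregation**: columns sharing an ENTREZ ID are merged by
  element-wise mean, keeping first-occurrence order.

The chain contains no randomness.

## Staging model

* **Split**: stratified 70/30 with a largest-remainder policy, so the
  training size is exactly round(0.7·n) and per-class counts are within
  one sample of proportionality. Each class keeps at least one sample on
  both sides.
* **SMOTE**: implemented in-package (interpolation between a minority
  sample and one of its k nearest same-class neighbours, uniform
  interpolation weight, k = min(5, minority − 1), all classes raised to
  the majority count, originals preserved verbatim). Applied to the
  training part only; the test set is untouched by construction.
* **Classifier**: XGBoost `multi:softprob` with n_estimators = 100,
  max_depth = 10, learning_rate = 0.005, subsample = 0.5,
  colsample_bytree = 0.5, reg_alpha = 0.1, reg_lambda = 0.5. Training is
  single-threaded with a fixed seed so repeated fits are bit-identical;
  multithreading would trade reproducibility for speed and is not the
  default.
* **Metrics**: held-out accuracy, per-class and macro F1, and macro
  ROC AUC in the one-vs-rest variant (an OvO variant of macro AUC exists
  in the literature; OvR is the package's choice and is stated in the
  results object). If a class is absent from the test labels, AUC is
  reported as NaN with the missing classes flagged.

## Attribution

Shapley values are computed exactly from the boosted-tree structure
(path-dependent Tree SHAP, via the tree library's native implementation)
on the margin (log-odds) scale — the scale on which local accuracy
(base value + Σ attributions = margin) holds to float32 precision.
"Contribution to the predicted probability" is thus read as contribution
to the margin feeding the softmax. Importance is always stage-specific:
mean |attribution| per (gene, stage), computed over training samples for
the global rankings (configurable to test-set or pooled samples). Top-k
selection breaks ties by ascending gene ID so rankings are reproducible.
Two high-importance rules are provided — min–max-normalized importance
≥ 0.8 (default, used for regional counts) and strictly above the 90th
percentile.

## Validation framework

* **Stability** (K = 5 stratified folds): each fold reruns SMOTE,
  model fitting and attribution on its training part and records the
  per-stage top-k genes (k defaults to 20, matching the heatmap depth;
  the choice is configurable and logged). Stability = appearances / K;
  mean rank (over folds where present) and across-fold importance
  variance are kept as diagnostics. Fold importances are attributed on
  the fold's real samples, not on SMOTE-synthesized rows, so importances
  describe observed data.
* **Composite score**: 0.4·Ĩ_train + 0.3·Ĩ_test + 0.3·Stability, where
  the tilde is min–max normalization within each (region, stage)
  importance vector (constant vectors map to zero). Inputs outside
  [0, 1] are rejected.
* **Tiers**: High requires stability ≥ 0.8 *and* test importance
  strictly above the 75th percentile of the (region, stage) test-set
  importance distribution; Medium requires ≥ 0.6 and strictly above the
  median; Low requires ≥ 0.4; everything else is excluded. Stability
  comparisons use ≥, percentile comparisons use strict >, and
  percentiles use linear interpolation. Tier assignment uses the
  class-specific (per-stage) importance distribution.
* **Permutation significance**: the observed statistic per gene is the
  maximum over stages of its mean |attribution| from the real pipeline.
  For each of B permutations the stage labels are shuffled and the whole
  pipeline (SMOTE → fit → attribute) reruns — the only null that also
  nulls the model-fitting process. p = (1 + #{null ≥ observed})/(B + 1)
  (never zero), B defaults to 100 at desk scale with a minimum of 19 for
  usable resolution, q-values by Benjamini–Hochberg (statsmodels),
  significance at q < 0.005. A deterministic gene subsample (default
  200 in the orchestrated run) keeps the B full re-fits affordable; the
  statistic and the BH correction then operate within that subset.

## Regional and cross-stage aggregation

Per stage, the genes × regions importance matrix is row-normalized by
each gene's maximum (this is forced by the convention that each gene's
most responsive region scores exactly 1), averaged over genes carrying
any nonzero importance in the stage, then min–max normalized across
regions. Degenerate min–max (constant vector) maps to all zeros.
Heatmap tables take the union of per-region top-k genes, keep the
overall top-k by summed importance, sort rows and columns by summed
importance (ties by ID), and apply the same row normalization. The
cross-stage overlap statistic counts genes selected in more than one
stage over total selections (3 × k). Radar polygon area is available as
a descriptive convenience only.

Co-expression validation computes Spearman ρ between a biomarker and
each pathway-panel gene present in the region's matrix, over samples
where both are observed; pairs with fewer than 5 overlapping samples are
skipped (and not counted as tested), significance is two-sided p < 0.05.
p-values use exact permutation enumeration for n ≤ 8 (ties by average
ranks) and the t-approximation above — beyond n = 8 the enumeration cost
grows factorially while the approximation error is already negligible at
the 0.05 threshold the pipeline uses.

## Synthetic cohort

The generator emulates the structure of a multi-region post-mortem
brain-bank cohort: 11 regions (Hipp, Caud, Dors, IFG, ITG, MTG, PCC, PC,
Puta, TP, Amyg), subjects split 33/40/51 across Early/Mid/Late (the
group sizes of the emulated cohort; note they total 124), Braak scores
drawn uniformly within each group's range, and clinical covariates
matched to the cohort's summary statistics (age 84.1 ± 7.2, 72% female,
PMI 361 ± 319 min, pH 6.37 ± 0.28). Expression is lognormal by default
(positive, heavy-tailed, variance-heterogeneous; per-gene log-mean
U(0.5, 2) and log-SD U(0.3, 0.6)), with a negative-binomial option for
count realism. Per region and stage, `n_planted` genes (default 10 — a
sparse signature consistent with near-disjoint per-stage top-20 lists)
are shifted additively by `effect_size` × the gene's baseline SD in the
samples of that stage (default 1.5, the moderate-effect study
condition). A configurable fraction of genes is low-variance (default
10%, falling under the 0.1 filter) and of duplicate-ID genes (default
5%, same ID, freshly drawn values, so aggregation is non-trivial).
Optional pathway blocks plant a biomarker plus panel genes sharing a
latent factor (pairwise latent correlation 0.6 by default) for the
co-expression step. Regions are sub-seeded by CRC32 of the region name,
so adding a region never perturbs the others. At full scale the Amygdala
gene universe is larger than the other regions' (42,438 vs 36,179),
reproduced via per-region overrides.

What the generator does **not** emulate: gene–gene co-expression
networks beyond the planted pathway blocks, batch or library-size
effects, ordinal structure within stage groups (expression depends only
on group membership), region–region correlation of a subject's profiles,
or realistic per-gene effect-size distributions. Passing
parameter-recovery tests therefore demonstrates that the machinery
(preprocessing, staging, attribution, stability, tiers, FDR) behaves
correctly under controlled signal — not that real-cohort gene lists
would be recovered.

## Problem sizes and determinism

Desk-scale defaults (2,000 genes per region, 124 subjects, B = 100
permutations on a 200-gene subsample, 5-fold stability) keep a full
single-region analysis in seconds and the repository's complete test
suite in minutes, while preserving every structural property of the
full-scale analysis. Every stochastic step draws a sub-seed derived by
hashing the master seed with a purpose token (region, fold, permutation
index), so runs are bit-reproducible and independent of execution order;
reports carry a config hash and a content hash to make reruns
comparable.

## Known limitations

* Performance on real cohorts is expected to be far from the synthetic
  defaults' near-perfect separation; the synthetic effect sizes are
  chosen to exercise the machinery, and weak-signal behaviour is probed
  only by the null-cohort tests.
* The permutation test's B = 100 resolution floor (p ≥ 1/101) means
  FDR < 0.005 cannot be reached at desk scale with a 200-gene subsample;
  detecting genes at that threshold requires larger B, as in a
  full-scale run.
* Tier thresholds compare against the within-(region, stage) importance
  distribution, so tiers are relative within a region, not comparable in
  absolute terms across regions.
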