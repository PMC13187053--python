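# braakstage

Brain-region-resolved, stage-wise transcriptomic biomarker discovery for
Alzheimer's disease.

Alzheimer's pathology spreads through the brain along a stereotyped
trajectory scored by the **Braak stage** (0–VI): transentorhinal onset
(0–II), limbic spread (III–IV), neocortical involvement (V–VI).
`braakstage` implements a complete analysis pipeline that, for each brain
region separately, learns to classify post-mortem bulk RNA-seq profiles
into the three clinical stage groups — Early (Braak 0–II), Mid (III–IV),
Late (V–VI) — and then interrogates the model to find *which genes, in
which region, at which stage* drive the classification. It is aimed at
computational biologists studying stage- and region-specific expression
signatures in brain-bank cohorts (the design mirrors multi-region
resources such as the Mount Sinai Brain Bank, whose data are controlled
access; a first-class synthetic-cohort generator makes every stage of the
pipeline runnable and testable without any download).

## The method

Per region, with expression matrix X (samples × genes) and stage labels
y ∈ {0, 1, 2} derived from Braak scores:

1. **Preprocessing** — drop genes with variance < 0.1; per-gene robust
   scaling (x − median)/IQR; per-gene Z-score to mean 0, SD 1 (ddof = 0);
   QC confirms mean-of-means ≈ 0 and mean-of-SDs ≈ 1; genes sharing an
   ENTREZ ID are then averaged into one column.
2. **Staging model** — stratified 70/30 split; SMOTE oversampling of
   minority stages *on the training set only*; XGBoost multiclass
   soft-probability classifier (n_estimators = 100, max_depth = 10,
   learning_rate = 0.005, subsample = colsample_bytree = 0.5,
   reg_alpha = 0.1, reg_lambda = 0.5); held-out accuracy, macro
   one-vs-rest ROC AUC and per-class F1.
3. **Attribution** — exact Tree SHAP values φ<sub>g,i</sub><sup>(s)</sup>
   per sample i, gene g and stage s (margin scale, local accuracy
   guaranteed); global importance is the mean absolute attribution,
   e.g. TestImportance<sub>g,s</sub> = (1/N_test) Σᵢ |φ<sub>g,i</sub><sup>(s)</sup>|.
4. **Validation framework** — three evidence layers per gene and stage:
   - *Stability* = (folds in which g is in the per-stage top-k) / K over
     K = 5 stratified folds, each refitting SMOTE + model + SHAP;
   - *Test importance* as above, on the untouched test set;
   - *Composite score* = 0.4·Ĩ_train + 0.3·Ĩ_test + 0.3·Stability with
     min–max normalized importances.
   Confidence tiers: **High** (stability ≥ 0.8 and test importance above
   the 75th percentile), **Medium** (≥ 0.6 and above the median),
   **Low** (≥ 0.4), otherwise excluded. Label-permutation testing with
   full pipeline re-runs gives per-gene p-values,
   Benjamini–Hochberg-corrected; significance at FDR < 0.005.
5. **Regional aggregation** — per-gene row normalization (each gene's
   most responsive region scores 1), per-stage regional means, final
   min–max across regions (radar profiles); top-20 gene × region
   heatmaps; cross-stage overlap statistics; Spearman co-expression of
   candidate biomarkers against pathway panels (GABAergic,
   mitochondrial, inflammatory, synaptic, core-AD), counting pairs with
   ≥ 5 overlapping samples and p < 0.05 as significant.

## Worked example

```python
from braakstage import (SyntheticConfig, generate_cohort, align_region,
                        sample_subject_map, BraakStagingModel)

cfg = SyntheticConfig(regions=("Hipp",), n_genes=2000, seed=1)
matrices, clinical, truth = generate_cohort(cfg)
m = matrices["Hipp"]
dataset = align_region(m, clinical, sample_subject_map(m))
results = BraakStagingModel(dataset, seed=1).fit()
print(results.summary())
```

```
Braak staging model results
=============================================
Region:              Hipp
Samples (train/test): 87/37
Stage counts:        {'Early': 33, 'Mid': 40, 'Late': 51}
Genes after preprocessing: 1700 (filtered 200, merged 100)
QC mean of means:    -6.76e-20
QC mean of SDs:      1.000000
---------------------------------------------
Accuracy:            1.0000
ROC AUC (macro/OvR): 1.0000
F1 Early (class 0): 1.0000
F1 Mid   (class 1): 1.0000
F1 Late  (class 2): 1.0000
=============================================
```

The generator planted 10 Early-stage differential genes; the staging
model recovers them at the top of the Early-stage importance ranking:

```python
>>> results.top_genes(0, 5)
['10001', '10010', '10005', '10009', '10003']
>>> truth.planted_genes("Hipp", 0)[:5]
['10001', '10002', '10003', '10004', '10005']
>>> conf = results.validate(K=5, k_top=20)   # stability + tiers
>>> conf[conf.confidence == "High"].groupby("stage").size()
stage
0    10
1    11
2    10
```

The QC lines are the preprocessing identities (per-gene means average to
0, per-gene SDs to 1); accuracy of 1.0 reflects the strong planted
effect; the tier counts show the validation framework concentrating High
confidence on roughly the 10 planted genes per stage.

The full multi-region pipeline, including regional radar profiles,
heatmap tables, overlap statistics and co-expression validation, runs via
`run_full_pipeline(RunConfig())` or the CLI:

```sh
braakstage simulate --out cohort/
braakstage preprocess --in cohort/Hipp.tsv --out Hipp.proc.tsv --qc qc.json
braakstage run-all --seed 1 --out reports/
```

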