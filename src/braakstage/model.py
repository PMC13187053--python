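"""The region-level staging model, statsmodels-style.

:class:`BraakStagingModel` is constructed from one region's aligned data
(or raw matrices via :meth:`from_matrices`); :meth:`fit` runs
preprocessing, the stratified 70/30 split, SMOTE balancing on the
training part, XGBoost fitting, held-out evaluation and Shapley
attribution, and returns a :class:`BraakStagingResults` carrying the
estimates.  The heavier validation layers (cross-validation stability,
confidence tiers, permutation significance) hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import (
    AttributionTensor,
    ImportanceVector,
    compute_attributions,
    mean_abs_importance,
    minmax_normalize,
    top_k_genes,
)
from .io import ClinicalTable, ExpressionMatrix, RegionDataset, align_region
from .preprocess import PreprocessConfig, QCReport, run_preprocessing
from .staging import (
    N_STAGES,
    STAGE_NAMES,
    ModelHyperparams,
    PerformanceReport,
    TrainedStageModel,
    _derive_seed,
    evaluate,
    smote_balance,
    stratified_split,
    train_classifier,
)
from .validation import cv_stability, gene_confidence_table, permutation_significance

__all__ = ["BraakStagingModel", "BraakStagingResults"]


class BraakStagingModel:
    """Three-class Braak staging model for one brain region.

    Parameters
    ----------
    dataset : RegionDataset
        Expression aligned to stage labels.
    hyperparams : ModelHyperparams, optional
        Gradient-boosting settings (defaults are the staging model's
        published configuration).
    preprocess : PreprocessConfig, optional
        Variance filter / scaling settings.
    train_frac : float
        Stratified training fraction (default 0.7).
    seed : int
        Master seed; every stochastic step derives a sub-seed from it.
    """

    def __init__(self, dataset: RegionDataset, hyperparams: ModelHyperparams | None = None,
                 preprocess: PreprocessConfig | None = None, train_frac: float = 0.7,
                 smote_k: int = 5, seed: int = 0):
        self.dataset = dataset
        self.hyperparams = hyperparams or ModelHyperparams()
        self.preprocess = preprocess or PreprocessConfig()
        self.train_frac = train_frac
        self.smote_k = smote_k
        self.seed = int(seed)

    @classmethod
    def from_matrices(cls, expr: ExpressionMatrix, clinical: ClinicalTable,
                      sample_to_subject: dict, **kwargs) -> "BraakStagingModel":
        """Build the model from an unaligned matrix plus clinical table."""
        return cls(align_region(expr, clinical, sample_to_subject), **kwargs)

    def fit(self) -> "BraakStagingResults":
        expr, qc = run_preprocessing(self.dataset.expression, self.preprocess)
        X = expr.values
        y = self.dataset.labels
        train_idx, test_idx = stratified_split(y, self.train_frac, _derive_seed(self.seed, "split"))
        Xb, yb = smote_balance(X[train_idx], y[train_idx], self.smote_k,
                               seed=_derive_seed(self.seed, "smote"))
        trained = train_classifier(
            Xb, yb, self.hyperparams.with_seed(_derive_seed(self.seed, "fit")), expr.gene_ids
        )
        performance = evaluate(trained, X[test_idx], y[test_idx])
        att_train = compute_attributions(trained, X[train_idx])
        att_test = compute_attributions(trained, X[test_idx])
        train_importance = {
            s: mean_abs_importance(att_train, s, region=self.dataset.region_name)
            for s in range(N_STAGES)
        }
        test_importance = {
            s: mean_abs_importance(att_test, s, region=self.dataset.region_name)
            for s in range(N_STAGES)
        }
        return BraakStagingResults(
            model=self,
            region_name=self.dataset.region_name,
            processed=expr,
            qc=qc,
            trained=trained,
            train_idx=train_idx,
            test_idx=test_idx,
            performance=performance,
            attributions_train=att_train,
            attributions_test=att_test,
            train_importance=train_importance,
            test_importance=test_importance,
        )


@dataclass
class BraakStagingResults:
    """Fitted staging model for one region: performance, attributions and
    the validation layers."""

    model: BraakStagingModel
    region_name: str
    processed: ExpressionMatrix
    qc: QCReport
    trained: TrainedStageModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    performance: PerformanceReport
    attributions_train: AttributionTensor
    attributions_test: AttributionTensor
    train_importance: dict
    test_importance: dict
    _stability: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def gene_ids(self) -> list:
        return self.processed.gene_ids

    def top_genes(self, stage: int, k: int = 20, source: str = "train") -> list:
        """Top-k genes for one stage by mean |attribution| (train or test)."""
        imp = self.train_importance if source == "train" else self.test_importance
        return top_k_genes(imp[stage], k)

    def importance_table(self) -> pd.DataFrame:
        """Long-format importance table: region, stage, gene, raw and
        min-max normalized train importance."""
        rows = []
        for stage, iv in self.train_importance.items():
            norm = minmax_normalize(iv)
            rows.append(
                pd.DataFrame(
                    {
                        "region": self.region_name,
                        "stage": stage,
                        "gene": iv.gene_ids,
                        "importance_raw": iv.values,
                        "importance_minmax": norm.values,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def validate(self, K: int = 5, k_top: int = 20) -> pd.DataFrame:
        """Run the stability layer and assemble the gene-confidence table
        (one row per gene and stage, with the composite validation score
        and High/Medium/Low/Excluded tier)."""
        X = self.processed.values
        y = self.model.dataset.labels
        stability = cv_stability(
            X[self.train_idx], y[self.train_idx], self.gene_ids, K=K, k_top=k_top,
            hp=self.model.hyperparams, seed=_derive_seed(self.model.seed, "stability"),
        )
        self._stability = stability
        return gene_confidence_table(
            self.train_importance, self.test_importance, stability, region=self.region_name
        )

    def permutation_test(self, B: int = 100, alpha: float = 0.005,
                         gene_subsample: int | None = None) -> pd.DataFrame:
        """Label-permutation significance of per-gene importance with
        Benjamini-Hochberg FDR (``significant`` at q < ``alpha``)."""
        X = self.processed.values
        y = self.model.dataset.labels
        return permutation_significance(
            X[self.train_idx], y[self.train_idx], self.gene_ids, B=B,
            hp=self.model.hyperparams, seed=_derive_seed(self.model.seed, "perm"),
            alpha=alpha, gene_subsample=gene_subsample,
        )

    def summary(self) -> str:
        """Readable fit summary (region, cohort, QC, held-out metrics)."""
        y = self.model.dataset.labels
        counts = {STAGE_NAMES[s]: int((y == s).sum()) for s in range(N_STAGES)}
        perf = self.performance
        lines = [
            "Braak staging model results",
            "=" * 45,
            f"Region:              {self.region_name}",
            f"Samples (train/test): {len(self.train_idx)}/{len(self.test_idx)}",
            f"Stage counts:        {counts}",
            f"Genes after preprocessing: {self.processed.n_genes} "
            f"(filtered {self.qc.n_genes_filtered}, merged {self.qc.n_duplicates_merged})",
            f"QC mean of means:    {self.qc.mean_of_means:+.2e}",
            f"QC mean of SDs:      {self.qc.mean_of_sds:.6f}",
            "-" * 45,
            f"Accuracy:            {perf.accuracy:.4f}",
            f"ROC AUC (macro/OvR): {perf.auc_macro:.4f}",
        ]
        for s in range(N_STAGES):
            lines.append(f"F1 {STAGE_NAMES[s]:<5} (class {s}): {perf.f1_per_class[s]:.4f}")
        lines.append("=" * 45)
        return "\n".join(lines)
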