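"""Shapley-value gene attribution for the trained staging model.

Attributions are exact, tree-path-dependent Shapley values computed from
the boosted-tree structure (XGBoost's native Tree SHAP), expressed on the
margin (log-odds) scale: for every sample and class, the class base value
plus the per-gene attributions reconstructs the model's raw margin.  The
global per-(stage, gene) importance is the mean absolute attribution over
a sample set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xgboost as xgb

from .staging import TrainedStageModel

__all__ = [
    "AttributionTensor",
    "ImportanceVector",
    "compute_attributions",
    "mean_abs_importance",
    "top_k_genes",
    "select_high_importance",
    "minmax_normalize",
]


@dataclass
class AttributionTensor:
    """Per-sample, per-gene, per-class Shapley values (margin units).

    ``values`` has shape (n_samples, n_genes, n_classes); ``base_values``
    holds the per-class expected margins.
    """

    values: np.ndarray
    base_values: np.ndarray
    gene_ids: list
    sample_ids: list | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def margins(self) -> np.ndarray:
        """Reconstructed per-class margins (base + attribution sums)."""
        return self.base_values[None, :] + self.values.sum(axis=1)


@dataclass
class ImportanceVector:
    """Nonnegative per-gene importance for one (stage, region)."""

    gene_ids: list
    values: np.ndarray
    stage: int
    region: str | None = None
    normalization: str = "raw"  # or "minmax"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.gene_ids):
            raise ValueError("one importance per gene is required")
        if self.normalization == "raw" and np.any(self.values < 0):
            raise ValueError("raw importances must be nonnegative")

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values, index=self.gene_ids, name=f"stage{self.stage}")


def compute_attributions(model: TrainedStageModel, X, gene_ids=None,
                         sample_ids=None) -> AttributionTensor:
    """Exact Tree SHAP attributions for every sample, gene and class.

    ``gene_ids``, when given, must match the model's fit-time gene order.
    Local accuracy (base + sum of attributions = margin) holds to float32
    precision.
    """
    model._check_genes(gene_ids)
    X = np.asarray(X, dtype=np.float32)
    if X.shape[1] != len(model.gene_ids):
        raise ValueError(
            f"matrix has {X.shape[1]} genes but the model was fit with {len(model.gene_ids)}"
        )
    contribs = model.booster.predict(xgb.DMatrix(X), pred_contribs=True)
    # shape (n_samples, n_classes, n_genes + 1); last slot is the bias
    values = np.transpose(contribs[:, :, :-1], (0, 2, 1)).astype(float)
    base_values = contribs[0, :, -1].astype(float)
    return AttributionTensor(values, base_values, list(model.gene_ids), sample_ids)


def mean_abs_importance(att: AttributionTensor, class_index: int,
                        sample_subset=None, region: str | None = None) -> ImportanceVector:
    """Per-gene mean absolute attribution for one class over a sample
    subset (all samples by default).  Order of the subset is irrelevant."""
    if sample_subset is None:
        sample_subset = np.arange(att.n_samples)
    sample_subset = np.asarray(sample_subset)
    if sample_subset.size == 0:
        raise ValueError("sample subset must be non-empty")
    vals = np.abs(att.values[sample_subset, :, class_index]).mean(axis=0)
    return ImportanceVector(list(att.gene_ids), vals, stage=int(class_index), region=region)


def top_k_genes(iv: ImportanceVector, k: int = 20) -> list:
    """Genes by descending importance; ties broken by ascending gene ID.
    ``k`` larger than the gene count returns all genes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(range(len(iv.gene_ids)), key=lambda i: (-iv.values[i], iv.gene_ids[i]))
    return [iv.gene_ids[i] for i in order[:k]]


def minmax_normalize(iv: ImportanceVector) -> ImportanceVector:
    """Min-max normalize to [0, 1]; a constant vector maps to all zeros."""
    if len(iv.values) == 0:
        raise ValueError("cannot normalize an empty importance vector")
    lo, hi = iv.values.min(), iv.values.max()
    vals = np.zeros_like(iv.values) if hi == lo else (iv.values - lo) / (hi - lo)
    return ImportanceVector(list(iv.gene_ids), vals, iv.stage, iv.region, normalization="minmax")


def select_high_importance(iv: ImportanceVector, mode: str = "threshold_0.8") -> set:
    """High-importance genes from a min-max normalized vector.

    ``threshold_0.8``: normalized importance >= 0.8.  ``percentile_90``:
    strictly above the 90th percentile of the vector (linear
    interpolation).  Raw input raises ``ValueError``.
    """
    if iv.normalization != "minmax":
        raise ValueError("select_high_importance requires a min-max normalized vector")
    if len(iv.values) == 0:
        return set()
    if mode == "threshold_0.8":
        mask = iv.values >= 0.8
    elif mode == "percentile_90":
        mask = iv.values > np.percentile(iv.values, 90)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {g for g, m in zip(iv.gene_ids, mask) if m}
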