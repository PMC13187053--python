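"""Region-level preprocessing chain for expression matrices.

Order of operations: variance filter (strict ``< threshold`` on raw
values) -> per-gene robust scaling by the interquartile range -> per-gene
Z-score standardization -> QC metrics -> duplicate-ID aggregation by mean.
QC (mean of per-gene means, mean of per-gene SDs) is computed on the
standardized matrix *before* aggregation, because averaging standardized
duplicate columns changes their variance.

The chain is fully deterministic; there is no randomness in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "PreprocessConfig",
    "QCReport",
    "filter_low_variance",
    "robust_scale",
    "zscore",
    "aggregate_duplicates",
    "run_preprocessing",
]


@dataclass(frozen=True)
class PreprocessConfig:
    variance_threshold: float = 0.1
    iqr_zero_policy: str = "zeros"  # or "skip_gene"
    ddof: int = 0

    def __post_init__(self):
        if self.variance_threshold < 0:
            raise ValueError("variance_threshold must be nonnegative")
        if self.iqr_zero_policy not in ("zeros", "skip_gene"):
            raise ValueError(f"unknown iqr_zero_policy {self.iqr_zero_policy!r}")
        if self.ddof not in (0, 1):
            raise ValueError("ddof must be 0 or 1")


@dataclass
class QCReport:
    mean_of_means: float
    mean_of_sds: float
    n_genes_in: int
    n_genes_filtered: int
    n_duplicates_merged: int

    def as_dict(self) -> dict:
        return {
            "mean_of_means": self.mean_of_means,
            "mean_of_sds": self.mean_of_sds,
            "n_genes_in": self.n_genes_in,
            "n_genes_filtered": self.n_genes_filtered,
            "n_duplicates_merged": self.n_duplicates_merged,
        }


def _with_columns(m: ExpressionMatrix, keep) -> ExpressionMatrix:
    keep = np.asarray(keep)
    return ExpressionMatrix(
        region_name=m.region_name,
        gene_ids=[m.gene_ids[j] for j in keep],
        sample_ids=list(m.sample_ids),
        values=m.values[:, keep],
    )


def filter_low_variance(m: ExpressionMatrix, threshold: float = 0.1) -> ExpressionMatrix:
    """Drop genes whose sample variance (ddof=0) is strictly below
    ``threshold``; survivor order is preserved."""
    if threshold < 0:
        raise ValueError("variance threshold must be nonnegative")
    var = m.values.var(axis=0, ddof=0)
    return _with_columns(m, np.flatnonzero(var >= threshold))


def robust_scale(m: ExpressionMatrix, iqr_zero_policy: str = "zeros") -> ExpressionMatrix:
    """Per-gene ``(x - median) / IQR`` with IQR = 75th - 25th percentile
    (linear interpolation).

    Genes with IQR = 0 are set to all zeros (policy ``"zeros"``) or
    dropped (policy ``"skip_gene"``).
    """
    med = np.median(m.values, axis=0)
    q75, q25 = np.percentile(m.values, [75, 25], axis=0)
    iqr = q75 - q25
    degenerate = iqr == 0
    if iqr_zero_policy == "skip_gene" and degenerate.any():
        m = _with_columns(m, np.flatnonzero(~degenerate))
        med, iqr, degenerate = med[~degenerate], iqr[~degenerate], degenerate[~degenerate]
    safe_iqr = np.where(degenerate, 1.0, iqr)
    scaled = (m.values - med) / safe_iqr
    scaled[:, degenerate] = 0.0
    return ExpressionMatrix(m.region_name, list(m.gene_ids), list(m.sample_ids), scaled)


def zscore(m: ExpressionMatrix, ddof: int = 0) -> ExpressionMatrix:
    """Per-gene standardization to mean 0 and SD 1 (given ddof); columns
    with zero SD pass through as zeros."""
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=ddof)
    zero = sd == 0
    safe_sd = np.where(zero, 1.0, sd)
    z = (m.values - mean) / safe_sd
    z[:, zero] = 0.0
    return ExpressionMatrix(m.region_name, list(m.gene_ids), list(m.sample_ids), z)


def aggregate_duplicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Merge columns sharing a gene ID by element-wise mean; resulting IDs
    are unique in first-occurrence order."""
    if len(set(m.gene_ids)) == len(m.gene_ids):
        return m
    order: dict = {}
    for j, g in enumerate(m.gene_ids):
        order.setdefault(g, []).append(j)
    genes = list(order)
    out = np.empty((m.n_samples, len(genes)))
    for k, g in enumerate(genes):
        out[:, k] = m.values[:, order[g]].mean(axis=1)
    return ExpressionMatrix(m.region_name, genes, list(m.sample_ids), out)


def run_preprocessing(m: ExpressionMatrix,
                      cfg: PreprocessConfig | None = None) -> tuple:
    """Apply the full chain and return ``(matrix, QCReport)``.

    Raises ``ValueError`` if no genes survive the variance filter.
    """
    cfg = cfg or PreprocessConfig()
    n_in = m.n_genes
    filtered = filter_low_variance(m, cfg.variance_threshold)
    if filtered.n_genes == 0:
        raise ValueError("no genes survive the variance filter")
    scaled = robust_scale(filtered, cfg.iqr_zero_policy)
    standardized = zscore(scaled, cfg.ddof)
    means = standardized.values.mean(axis=0)
    sds = standardized.values.std(axis=0, ddof=cfg.ddof)
    aggregated = aggregate_duplicates(standardized)
    qc = QCReport(
        mean_of_means=float(means.mean()),
        mean_of_sds=float(sds.mean()),
        n_genes_in=n_in,
        n_genes_filtered=n_in - filtered.n_genes,
        n_duplicates_merged=standardized.n_genes - aggregated.n_genes,
    )
    return aggregated, qc
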