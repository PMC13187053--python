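"""Multi-layer gene-confidence validation.

Three evidence layers back every candidate gene:

* **Stability** — fraction of 5-fold cross-validation runs (each refitting
  the full SMOTE + model + attribution pipeline) in which the gene lands
  in the per-stage top-k importance list.
* **Test importance** — mean absolute attribution on the held-out test
  set, guarding against overfitting-driven selection.
* **Composite validation score** — ``0.4 * train_norm + 0.3 * test_norm +
  0.3 * stability`` with min-max normalized importances, so the score
  lives in [0, 1].

Confidence tiers (High / Medium / Low / Excluded) combine stability with
percentile cuts of the test-importance distribution; permutation testing
with Benjamini-Hochberg FDR gives per-gene significance against a null in
which stage labels are shuffled and the entire pipeline rerun.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .attribution import (
    ImportanceVector,
    compute_attributions,
    mean_abs_importance,
    minmax_normalize,
    top_k_genes,
)
from .staging import (
    N_STAGES,
    ModelHyperparams,
    _derive_seed,
    smote_balance,
    train_classifier,
)

__all__ = [
    "cv_stability",
    "stability_from_fold_lists",
    "permutation_pvalues",
    "validation_score",
    "assign_confidence",
    "gene_confidence_table",
    "permutation_significance",
    "bh_fdr",
]

#: Confidence tiers: (name, min stability, test-importance percentile cut).
TIER_RULES = (("High", 0.8, 75.0), ("Medium", 0.6, 50.0), ("Low", 0.4, None))

VALIDATION_WEIGHTS = (0.4, 0.3, 0.3)


def _pipeline_importances(X, y, gene_ids, hp: ModelHyperparams, seed: int,
                          attribute_on=None) -> np.ndarray:
    """SMOTE -> train -> attribute; returns (n_stages, n_genes) mean |SHAP|.

    Attribution is computed on the real (pre-SMOTE) rows of
    ``attribute_on`` (default: the training rows themselves).
    """
    Xb, yb = smote_balance(X, y, seed=_derive_seed(seed, "smote"))
    model = train_classifier(Xb, yb, hp.with_seed(_derive_seed(seed, "fit")), gene_ids)
    att = compute_attributions(model, X if attribute_on is None else attribute_on)
    return np.stack(
        [mean_abs_importance(att, s).values for s in range(N_STAGES)]
    )


def stability_from_fold_lists(fold_top_lists: list, gene_ids, K: int | None = None) -> pd.Series:
    """Stability = (number of folds whose top-k list contains the gene) / K.

    ``fold_top_lists`` holds one top-k gene list per fold; ``K`` defaults
    to the number of lists.  Returns a Series indexed by gene.
    """
    K = K if K is not None else len(fold_top_lists)
    if K < len(fold_top_lists):
        raise ValueError("K cannot be smaller than the number of folds supplied")
    counts = pd.Series(0.0, index=[str(g) for g in gene_ids])
    for top in fold_top_lists:
        for g in top:
            counts[str(g)] += 1
    return counts / K


def permutation_pvalues(observed, null_stats) -> np.ndarray:
    """Permutation p-values ``(1 + #{null >= observed}) / (B + 1)``.

    ``null_stats`` has shape (B, n_genes); comparison is elementwise per
    gene.
    """
    observed = np.asarray(observed, dtype=float)
    null_stats = np.atleast_2d(np.asarray(null_stats, dtype=float))
    exceed = (null_stats >= observed[None, :]).sum(axis=0)
    return (1.0 + exceed) / (null_stats.shape[0] + 1.0)


def cv_stability(X, y, gene_ids=None, K: int = 5, k_top: int = 20,
                 hp: ModelHyperparams | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-(gene, stage) stability across K stratified folds.

    Each fold reruns SMOTE, model fitting and attribution on its training
    part and records the per-stage top-``k_top`` genes.  Returns a long
    DataFrame with columns ``gene, stage, stability, mean_rank,
    importance_variance`` where stability = (folds in top-k) / K,
    mean_rank averages the 1-based rank over folds where the gene appears,
    and importance_variance is the variance of the gene's raw importance
    across all folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    hp = hp or ModelHyperparams()
    if gene_ids is None:
        gene_ids = [f"f{i}" for i in range(X.shape[1])]
    gene_ids = [str(g) for g in gene_ids]
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < K:
        raise ValueError(f"smallest class ({counts.min()}) cannot be stratified into {K} folds")
    n_genes = len(gene_ids)
    appear = np.zeros((N_STAGES, n_genes))
    rank_sum = np.zeros((N_STAGES, n_genes))
    fold_imps = np.empty((K, N_STAGES, n_genes))
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=_derive_seed(seed, "cv"))
    for fold, (tr, _) in enumerate(skf.split(X, y)):
        imps = _pipeline_importances(X[tr], y[tr], gene_ids, hp, _derive_seed(seed, "fold", fold))
        fold_imps[fold] = imps
        for stage in range(N_STAGES):
            iv = ImportanceVector(gene_ids, imps[stage], stage)
            gene_index = {g: i for i, g in enumerate(gene_ids)}
            for rank, g in enumerate(top_k_genes(iv, k_top), start=1):
                appear[stage, gene_index[g]] += 1
                rank_sum[stage, gene_index[g]] += rank
    records = []
    variance = fold_imps.var(axis=0, ddof=0)
    with np.errstate(invalid="ignore"):
        mean_rank = np.where(appear > 0, rank_sum / np.maximum(appear, 1), np.nan)
    for stage in range(N_STAGES):
        for i, g in enumerate(gene_ids):
            records.append(
                {
                    "gene": g,
                    "stage": stage,
                    "stability": appear[stage, i] / K,
                    "mean_rank": mean_rank[stage, i],
                    "importance_variance": variance[stage, i],
                }
            )
    return pd.DataFrame.from_records(records)


def validation_score(train_norm, test_norm, stability):
    """Composite score ``0.4 * train + 0.3 * test + 0.3 * stability``.

    All inputs must lie in [0, 1]; accepts scalars or arrays.
    """
    arrs = [np.asarray(v, dtype=float) for v in (train_norm, test_norm, stability)]
    for name, a in zip(("train_norm", "test_norm", "stability"), arrs):
        if np.any((a < 0) | (a > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    w = VALIDATION_WEIGHTS
    out = w[0] * arrs[0] + w[1] * arrs[1] + w[2] * arrs[2]
    return float(out) if out.ndim == 0 else out


def assign_confidence(stability, test_importance_raw, test_importance_distribution) -> str:
    """Tier a gene by stability and its place in the test-importance
    distribution.

    High: stability >= 0.8 and importance strictly above the 75th
    percentile; Medium: stability >= 0.6 and above the median; Low:
    stability >= 0.4 regardless of importance; otherwise Excluded.
    Percentiles use linear interpolation over the (region, stage)
    distribution.
    """
    dist = np.asarray(test_importance_distribution, dtype=float)
    if dist.size == 0:
        raise ValueError("test-importance distribution must be non-empty")
    for tier, min_stab, pct in TIER_RULES:
        if stability >= min_stab and (pct is None or test_importance_raw > np.percentile(dist, pct)):
            return tier
    return "Excluded"


def gene_confidence_table(train_importance: dict, test_importance: dict,
                          stability: pd.DataFrame, region: str | None = None) -> pd.DataFrame:
    """Assemble the per-(gene, stage) confidence table.

    ``train_importance`` / ``test_importance`` map stage -> raw
    :class:`ImportanceVector`; ``stability`` is :func:`cv_stability`
    output.  Returns one row per (gene, stage) with raw and min-max
    normalized importances, stability, the composite validation score and
    the confidence tier.
    """
    stab = stability.set_index(["stage", "gene"])["stability"]
    frames = []
    for stage, train_iv in train_importance.items():
        test_iv = test_importance[stage]
        if list(test_iv.gene_ids) != list(train_iv.gene_ids):
            raise ValueError("train and test importance gene orders differ")
        train_norm = minmax_normalize(train_iv).values
        test_norm = minmax_normalize(test_iv).values
        s = stab.loc[stage].reindex(train_iv.gene_ids).fillna(0.0).to_numpy()
        score = validation_score(train_norm, test_norm, s)
        tiers = [
            assign_confidence(s[i], test_iv.values[i], test_iv.values)
            for i in range(len(train_iv.gene_ids))
        ]
        frames.append(
            pd.DataFrame(
                {
                    "gene": train_iv.gene_ids,
                    "stage": stage,
                    "region": region,
                    "train_importance_raw": train_iv.values,
                    "test_importance_raw": test_iv.values,
                    "train_norm": train_norm,
                    "test_norm": test_norm,
                    "stability": s,
                    "validation_score": score,
                    "confidence": tiers,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    All p-values must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_significance(X, y, gene_ids=None, B: int = 100,
                             hp: ModelHyperparams | None = None, seed: int = 0,
                             alpha: float = 0.005,
                             gene_subsample: int | None = None) -> pd.DataFrame:
    """Label-permutation significance of per-gene importance.

    The observed statistic is each gene's maximum over stages of the mean
    absolute attribution from the real pipeline (SMOTE + fit + attribute).
    For each of ``B`` permutations the stage labels are shuffled and the
    entire pipeline rerun; ``p = (1 + #{null >= observed}) / (B + 1)``,
    q-values by Benjamini-Hochberg, significance at ``q < alpha``.

    ``gene_subsample`` restricts the analysis to a deterministic random
    subset of genes (a desk-scale economy; the statistic is computed
    within that subset).
    """
    if B < 19:
        raise ValueError("B must be at least 19 for usable p-value resolution")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    hp = hp or ModelHyperparams()
    if gene_ids is None:
        gene_ids = [f"f{i}" for i in range(X.shape[1])]
    gene_ids = [str(g) for g in gene_ids]
    if gene_subsample is not None and gene_subsample < X.shape[1]:
        rng = np.random.default_rng(_derive_seed(seed, "subsample"))
        cols = np.sort(rng.choice(X.shape[1], size=gene_subsample, replace=False))
        X = X[:, cols]
        gene_ids = [gene_ids[c] for c in cols]
    observed = _pipeline_importances(X, y, gene_ids, hp, _derive_seed(seed, "obs")).max(axis=0)
    rng = np.random.default_rng(_derive_seed(seed, "perm"))
    null_stats = np.empty((B, len(observed)))
    for b in range(B):
        y_null = rng.permutation(y)
        null_stats[b] = _pipeline_importances(
            X, y_null, gene_ids, hp, _derive_seed(seed, "perm", b)
        ).max(axis=0)
    p = permutation_pvalues(observed, null_stats)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "gene": gene_ids,
            "observed_stat": observed,
            "p_value": p,
            "q_value": q,
            "significant": q < alpha,
        }
    )
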