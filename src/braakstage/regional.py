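"""Region-resolved aggregation, cross-stage overlap and pathway
co-expression validation.

Regional importance profiles are built by row-normalizing each gene's
per-region importances by the gene's maximum (so its most responsive
region scores 1), averaging across genes, and min-max normalizing across
regions.  Cross-stage overlap quantifies how stage-specific the top gene
lists are; co-expression validation computes Spearman correlations
between a biomarker and a pathway panel within one region.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import ImportanceVector
from .io import ExpressionMatrix, PathwayPanel

__all__ = [
    "GeneRegionImportance",
    "StageRegionProfile",
    "OverlapSummary",
    "CoexpressionSummary",
    "build_gene_region_importance",
    "row_normalize",
    "stage_region_profile",
    "cross_stage_overlap",
    "heatmap_table",
    "spearman_pair",
    "coexpression_summary",
]


@dataclass
class GeneRegionImportance:
    """Genes x regions importance matrix for one stage."""

    stage: int
    frame: pd.DataFrame  # index genes, columns regions
    normalization: str = "raw"  # or "row_normalized"


@dataclass
class StageRegionProfile:
    """Stage-level regional importance (radar-plot values)."""

    stage: int
    mean_importance: pd.Series  # per-region mean of row-normalized values
    profile: pd.Series  # final min-max normalized values in [0, 1]


def build_gene_region_importance(per_region: dict, stage: int,
                                 drop_all_zero: bool = True) -> GeneRegionImportance:
    """Assemble the raw genes x regions matrix from per-region importance
    vectors for one stage (absent genes fill with 0).

    ``drop_all_zero`` removes genes with no importance anywhere, matching
    the convention that the profile averages over genes carrying any
    signal in the stage.
    """
    cols = {}
    for region, iv in per_region.items():
        if iv.stage != stage:
            raise ValueError(f"importance vector for region {region} is for stage {iv.stage}")
        cols[region] = iv.as_series()
    frame = pd.DataFrame(cols).fillna(0.0)
    if drop_all_zero:
        frame = frame.loc[frame.sum(axis=1) > 0]
    return GeneRegionImportance(stage=stage, frame=frame, normalization="raw")


def row_normalize(m: GeneRegionImportance) -> GeneRegionImportance:
    """Divide each gene's row by its maximum; all-zero rows stay zero.
    Negative entries raise ``ValueError``."""
    vals = m.frame.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("importances must be nonnegative")
    row_max = vals.max(axis=1)
    safe = np.where(row_max == 0, 1.0, row_max)
    out = vals / safe[:, None]
    return GeneRegionImportance(
        stage=m.stage,
        frame=pd.DataFrame(out, index=m.frame.index, columns=m.frame.columns),
        normalization="row_normalized",
    )


def stage_region_profile(m: GeneRegionImportance) -> StageRegionProfile:
    """Column means of the row-normalized matrix, then min-max across
    regions (constant means map to all zeros)."""
    if m.normalization != "row_normalized":
        raise ValueError("stage_region_profile requires a row-normalized matrix")
    if m.frame.shape[1] < 2:
        raise ValueError("min-max across regions needs at least 2 regions")
    means = m.frame.mean(axis=0)
    lo, hi = means.min(), means.max()
    if hi == lo:
        profile = pd.Series(0.0, index=means.index)
    else:
        profile = (means - lo) / (hi - lo)
    return StageRegionProfile(stage=m.stage, mean_importance=means, profile=profile)


@dataclass
class OverlapSummary:
    n_selected: int
    n_unique: int
    n_multi_stage: int
    overlap_fraction: float
    pairwise_shared: dict  # (stage_a, stage_b) -> sorted shared genes

    def as_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "n_unique": self.n_unique,
            "n_multi_stage": self.n_multi_stage,
            "overlap_fraction": self.overlap_fraction,
            "pairwise_shared": {f"{a}-{b}": genes for (a, b), genes in self.pairwise_shared.items()},
        }


def cross_stage_overlap(top_lists: dict) -> OverlapSummary:
    """Overlap statistics over per-stage top-gene lists.

    ``overlap_fraction`` counts genes appearing in more than one stage over
    total selections (e.g. one shared gene among three 20-lists gives
    1/60).  A duplicate within one list raises ``ValueError``.
    """
    for stage, genes in top_lists.items():
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate gene within the stage-{stage} list")
    all_genes = [g for genes in top_lists.values() for g in genes]
    n_selected = len(all_genes)
    membership: dict = {}
    for stage, genes in top_lists.items():
        for g in genes:
            membership.setdefault(g, set()).add(stage)
    multi = {g for g, stages in membership.items() if len(stages) > 1}
    pairwise = {
        (a, b): sorted(set(top_lists[a]) & set(top_lists[b]))
        for a, b in itertools.combinations(sorted(top_lists), 2)
    }
    return OverlapSummary(
        n_selected=n_selected,
        n_unique=len(membership),
        n_multi_stage=len(multi),
        overlap_fraction=len(multi) / n_selected if n_selected else 0.0,
        pairwise_shared=pairwise,
    )


def heatmap_table(per_region: dict, k: int = 20) -> pd.DataFrame:
    """Stage heatmap: overall top-k genes x regions, row-normalized.

    Candidate genes are the union of each region's top-k; of those, the
    overall top-k by summed raw importance are kept.  Rows and columns are
    sorted by summed importance descending (ties by ID/name).
    """
    from .attribution import top_k_genes

    candidates: set = set()
    for iv in per_region.values():
        candidates.update(top_k_genes(iv, k))
    stage = next(iter(per_region.values())).stage
    raw = build_gene_region_importance(per_region, stage, drop_all_zero=False)
    frame = raw.frame.loc[sorted(candidates)]
    row_tot = frame.sum(axis=1)
    keep = sorted(frame.index, key=lambda g: (-row_tot[g], g))[:k]
    frame = frame.loc[keep]
    col_tot = frame.sum(axis=0)
    cols = sorted(frame.columns, key=lambda r: (-col_tot[r], r))
    frame = frame[cols]
    normalized = row_normalize(GeneRegionImportance(stage, frame, "raw"))
    return normalized.frame


def _exact_spearman_p(x_rank: np.ndarray, y_rank: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    n = len(x_rank)
    perms = np.array(list(itertools.permutations(range(n))))
    xr = (x_rank - x_rank.mean()) / x_rank.std()
    yr = (y_rank - y_rank.mean()) / y_rank.std()
    rhos = (xr[perms] * yr[None, :]).mean(axis=1)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_pair(x, y, exact_n: int = 8):
    """Spearman rho with a two-sided p-value.

    Exact permutation enumeration for n <= ``exact_n`` (ties handled by
    average ranks); the t-approximation otherwise.  Returns (rho, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    if math.isnan(rho):
        return float("nan"), float("nan")
    if n <= exact_n:
        p = _exact_spearman_p(stats.rankdata(x), stats.rankdata(y), rho)
    return float(rho), float(p)


@dataclass
class CoexpressionSummary:
    """Spearman co-expression of one biomarker against a pathway panel."""

    gene: str
    region: str
    pathway: str
    n_tested: int
    n_significant: int
    mean_abs_rho: float
    max_rho: float
    min_rho: float
    correlations: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "region": self.region,
            "pathway": self.pathway,
            "n_tested": self.n_tested,
            "n_significant": self.n_significant,
            "mean_abs_rho": self.mean_abs_rho,
            "max_rho": self.max_rho,
            "min_rho": self.min_rho,
        }


def coexpression_summary(expr: ExpressionMatrix, biomarker: str, panel: PathwayPanel,
                         min_overlap: int = 5, alpha: float = 0.05) -> CoexpressionSummary:
    """Correlate a biomarker with each panel gene present in the matrix.

    Pairs need at least ``min_overlap`` samples where both genes are
    observed (pairs below that are skipped and not counted as tested);
    significance is a two-sided Spearman p below ``alpha``.
    """
    genes = set(expr.gene_ids)
    if biomarker not in genes:
        raise ValueError(f"biomarker {biomarker!r} absent from the expression matrix")
    frame = expr.to_frame()
    x = frame[biomarker].to_numpy()
    rows = []
    for g in panel.gene_ids:
        if g == biomarker or g not in genes:
            continue
        yv = frame[g].to_numpy()
        mask = np.isfinite(x) & np.isfinite(yv)
        if mask.sum() < min_overlap:
            continue
        rho, p = spearman_pair(x[mask], yv[mask])
        rows.append({"panel_gene": g, "rho": rho, "p_value": p, "n_overlap": int(mask.sum())})
    detail = pd.DataFrame(rows)
    if detail.empty:
        return CoexpressionSummary(biomarker, expr.region_name, panel.panel_name,
                                   0, 0, float("nan"), float("nan"), float("nan"), detail)
    sig = int((detail["p_value"] < alpha).sum())
    return CoexpressionSummary(
        gene=biomarker,
        region=expr.region_name,
        pathway=panel.panel_name,
        n_tested=len(detail),
        n_significant=sig,
        mean_abs_rho=float(detail["rho"].abs().mean()),
        max_rho=float(detail["rho"].max()),
        min_rho=float(detail["rho"].min()),
        correlations=detail,
    )
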