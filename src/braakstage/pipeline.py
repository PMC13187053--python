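"""End-to-end multi-region pipeline: preprocess, stage, attribute,
validate and aggregate across all brain regions."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import ImportanceVector
from .io import PathwayPanel, align_region
from .model import BraakStagingModel
from .preprocess import PreprocessConfig
from .regional import (
    build_gene_region_importance,
    coexpression_summary,
    cross_stage_overlap,
    heatmap_table,
    row_normalize,
    stage_region_profile,
)
from .staging import N_STAGES, STAGE_NAMES, ModelHyperparams, _derive_seed
from .synthetic import SyntheticConfig, generate_cohort, sample_subject_map

__all__ = ["RunConfig", "RunReport", "run_full_pipeline", "emit_reports"]

log = logging.getLogger("braakstage")


@dataclass
class RunConfig:
    """Full pipeline configuration (defaults are desk scale)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hyperparams: ModelHyperparams = field(default_factory=ModelHyperparams)
    train_frac: float = 0.7
    cv_folds: int = 5
    k_top: int = 20
    permutation_B: int = 100
    permutation_gene_subsample: int | None = 200
    alpha: float = 0.005
    heatmap_k: int = 20
    high_importance_mode: str = "threshold_0.8"
    run_validation: bool = True
    run_permutation: bool = False
    run_coexpression: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.synthetic.regions:
            raise ValueError("config lists no regions")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            syn = dict(kwargs["synthetic"])
            for key in ("regions", "n_per_stage"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "n_genes_overrides" in syn:
                syn["n_genes_overrides"] = tuple(
                    (k, v) for k, v in dict(syn["n_genes_overrides"]).items()
                )
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "hyperparams" in kwargs:
            kwargs["hyperparams"] = ModelHyperparams(**kwargs["hyperparams"])
        return cls(**kwargs)

    def provenance_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Aggregated pipeline outputs across regions."""

    performance: pd.DataFrame  # one row per region (Table-4 shape)
    qc: pd.DataFrame
    tier_counts: pd.DataFrame | None
    significant_counts: pd.DataFrame | None  # Table-7 shape
    gene_confidence: pd.DataFrame | None
    permutation: pd.DataFrame | None
    heatmaps: dict  # stage -> DataFrame
    profiles: dict  # stage -> StageRegionProfile
    overlap: object  # OverlapSummary
    coexpression: list  # CoexpressionSummary
    errors: dict
    provenance: dict

    def report_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.performance.round(12).to_csv().encode())
        h.update(self.qc.round(12).to_csv().encode())
        if self.gene_confidence is not None:
            h.update(self.gene_confidence.round(12).to_csv().encode())
        for stage in sorted(self.heatmaps):
            h.update(self.heatmaps[stage].round(12).to_csv().encode())
        return h.hexdigest()


def _region_models(cfg: RunConfig):
    matrices, clinical, truth = generate_cohort(cfg.synthetic)
    for region, matrix in matrices.items():
        dataset = align_region(matrix, clinical, sample_subject_map(matrix))
        yield region, BraakStagingModel(
            dataset,
            hyperparams=cfg.hyperparams,
            preprocess=cfg.preprocess,
            train_frac=cfg.train_frac,
            seed=_derive_seed(cfg.seed, "region", region),
        ), truth


def run_full_pipeline(cfg: RunConfig | None = None) -> RunReport:
    """Run every region through the full chain and aggregate.

    A failure in one region is logged and recorded; other regions
    proceed.  Fully deterministic for a fixed config.
    """
    cfg = cfg or RunConfig()
    perf_rows, qc_rows, errors = [], [], {}
    confidence_frames, perm_frames = [], []
    region_importance: dict = {s: {} for s in range(N_STAGES)}
    truth = None
    results_by_region = {}
    for region, model, truth in _region_models(cfg):
        try:
            log.info("region=%s seed=%s: fitting", region, model.seed)
            res = model.fit()
            results_by_region[region] = res
            perf_rows.append({"region": region, **res.performance.as_dict()})
            qc_rows.append({"region": region, **res.qc.as_dict()})
            for s in range(N_STAGES):
                region_importance[s][region] = res.train_importance[s]
            if cfg.run_validation:
                conf = res.validate(K=cfg.cv_folds, k_top=cfg.k_top)
                confidence_frames.append(conf)
            if cfg.run_permutation:
                perm = res.permutation_test(
                    B=cfg.permutation_B, alpha=cfg.alpha,
                    gene_subsample=cfg.permutation_gene_subsample,
                )
                perm["region"] = region
                perm_frames.append(perm)
        except Exception as exc:  # pragma: no cover - defensive per-region guard
            log.exception("region=%s failed", region)
            errors[region] = f"{type(exc).__name__}: {exc}"

    performance = pd.DataFrame(perf_rows)
    qc = pd.DataFrame(qc_rows)

    heatmaps, profiles, top_lists = {}, {}, {}
    if results_by_region:
        pooled = {}
        for s in range(N_STAGES):
            grid = build_gene_region_importance(region_importance[s], s)
            if grid.frame.shape[1] >= 2:  # cross-region min-max needs >= 2 regions
                profiles[s] = stage_region_profile(row_normalize(grid))
            heatmaps[s] = heatmap_table(region_importance[s], k=cfg.heatmap_k)
            summed = grid.frame.sum(axis=1)
            pooled[s] = ImportanceVector(list(summed.index), summed.to_numpy(), stage=s)
        from .attribution import top_k_genes

        top_lists = {s: top_k_genes(pooled[s], cfg.heatmap_k) for s in range(N_STAGES)}
    overlap = cross_stage_overlap(top_lists) if top_lists else None

    gene_confidence = pd.concat(confidence_frames, ignore_index=True) if confidence_frames else None
    tier_counts = None
    if gene_confidence is not None:
        tier_counts = (
            gene_confidence[gene_confidence["confidence"] != "Excluded"]
            .groupby(["region", "confidence"]).size().unstack(fill_value=0)
            .reindex(columns=["High", "Medium", "Low"], fill_value=0)
            .reset_index()
        )
    permutation = pd.concat(perm_frames, ignore_index=True) if perm_frames else None
    significant_counts = None
    if permutation is not None:
        significant_counts = (
            permutation.groupby("region")["significant"].sum().astype(int)
            .rename("n_significant").reset_index()
        )

    coexpr = []
    if cfg.run_coexpression and truth is not None and truth.pathway:
        for region, blocks in truth.pathway.items():
            if region not in results_by_region:
                continue
            expr = results_by_region[region].processed
            for block in blocks:
                panel = PathwayPanel(block["panel_name"], block["panel_genes"])
                try:
                    coexpr.append(coexpression_summary(expr, block["biomarker"], panel))
                except ValueError as exc:
                    errors[f"{region}/coexpression"] = str(exc)

    provenance = {
        "config_hash": cfg.provenance_hash(),
        "seed": cfg.seed,
        "package_version": __version__,
        "regions": list(cfg.synthetic.regions),
    }
    return RunReport(
        performance=performance, qc=qc, tier_counts=tier_counts,
        significant_counts=significant_counts, gene_confidence=gene_confidence,
        permutation=permutation, heatmaps=heatmaps, profiles=profiles,
        overlap=overlap, coexpression=coexpr, errors=errors, provenance=provenance,
    )


def emit_reports(report: RunReport, outdir) -> list:
    """Write the report's tables under ``outdir``; returns written paths."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    def _write(df, name):
        path = os.path.join(outdir, name)
        df.to_csv(path, index=False)
        written.append(path)

    _write(report.performance, "table4.csv")
    _write(report.qc, "qc.csv")
    if report.tier_counts is not None:
        _write(report.tier_counts, "tier_counts.csv")
    if report.significant_counts is not None:
        _write(report.significant_counts, "table7.csv")
    if report.gene_confidence is not None:
        _write(report.gene_confidence, "gene_confidence.csv")
    if report.permutation is not None:
        _write(report.permutation, "permutation.csv")
    for stage, table in report.heatmaps.items():
        path = os.path.join(outdir, f"heatmap_{STAGE_NAMES[stage].lower()}.csv")
        table.to_csv(path)
        written.append(path)
    if report.profiles:
        prof = pd.DataFrame(
            {STAGE_NAMES[s]: p.profile for s, p in report.profiles.items()}
        )
        prof.index.name = "region"
        path = os.path.join(outdir, "radar_profile.csv")
        prof.to_csv(path)
        written.append(path)
    if report.overlap is not None:
        path = os.path.join(outdir, "overlap.json")
        with open(path, "w") as fh:
            json.dump(report.overlap.as_dict(), fh, indent=1)
        written.append(path)
    if report.coexpression:
        _write(pd.DataFrame([c.as_dict() for c in report.coexpression]), "coexpression.csv")
    path = os.path.join(outdir, "summary.json")
    with open(path, "w") as fh:
        json.dump(
            {
                "provenance": report.provenance,
                "errors": report.errors,
                "report_hash": report.report_hash(),
            },
            fh, indent=1,
        )
    written.append(path)
    return written
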