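"""Synthetic multi-region cohort generator.

Emulates the structure of a post-mortem brain-bank RNA-seq cohort: 11
brain regions, 125 subjects split Early/Mid/Late (33/40/51 by Braak
score), positive heavy-tailed expression, planted stage- and
region-specific differential genes, a configurable fraction of
low-variance and duplicate-ID genes, class imbalance, and optional
pathway co-expression blocks (a biomarker and panel genes sharing a
latent factor) so the co-expression validation step is testable.

Every region draws from a sub-seeded generator (master seed + CRC32 of
the region name), so adding a region never perturbs the others and the
whole cohort is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix

__all__ = [
    "REGIONS",
    "PathwayBlock",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "null_cohort",
    "sample_subject_map",
]

#: The eleven brain regions of the emulated cohort.
REGIONS = ("Hipp", "Caud", "Dors", "IFG", "ITG", "MTG", "PCC", "PC", "Puta", "TP", "Amyg")

_BRAAK_RANGE = {0: (0, 2), 1: (3, 4), 2: (5, 6)}


@dataclass(frozen=True)
class PathwayBlock:
    """A planted co-expression block: one biomarker plus panel genes that
    share a latent factor with pairwise latent correlation ``correlation``."""

    panel_name: str = "synthetic_panel"
    n_panel_genes: int = 6
    correlation: float = 0.6

    def __post_init__(self):
        if self.n_panel_genes < 1:
            raise ValueError("pathway block needs at least one panel gene")
        if not 0 < self.correlation < 1:
            raise ValueError("correlation must be in (0, 1)")


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort generation parameters (defaults are the desk-scale study
    conditions; see docs/methods.md)."""

    n_per_stage: tuple = (33, 40, 51)
    regions: tuple = REGIONS
    n_genes: int = 2000
    n_genes_overrides: tuple = ()  # pairs (region, n_genes), e.g. Amyg at full scale
    n_planted: int = 10  # differential genes per (stage, region)
    effect_size: float = 1.5  # mean shift in baseline-SD units
    frac_low_variance: float = 0.10
    frac_duplicate_ids: float = 0.05
    noise_family: str = "lognormal"  # or "negative_binomial"
    pathway_blocks: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_stage) != 3 or any(n < 2 for n in self.n_per_stage):
            raise ValueError("n_per_stage must give >= 2 subjects for each of 3 stages")
        if not self.regions:
            raise ValueError("at least one region is required")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not (0 <= self.frac_low_variance < 1 and 0 <= self.frac_duplicate_ids < 1):
            raise ValueError("frac_low_variance and frac_duplicate_ids must lie in [0, 1)")
        if self.noise_family not in ("lognormal", "negative_binomial"):
            raise ValueError(f"unknown noise_family {self.noise_family!r}")
        for region in self.regions:
            n = self.genes_for(region)
            n_reserved = self._n_lowvar(n) + self._n_dup(n)
            n_needed = 3 * self.n_planted + sum(1 + b.n_panel_genes for b in self.pathway_blocks)
            if n_needed > n - n_reserved:
                raise ValueError(
                    f"region {region}: {n_needed} planted/block genes exceed the "
                    f"{n - n_reserved} regular genes available"
                )

    def genes_for(self, region: str) -> int:
        return dict(self.n_genes_overrides).get(region, self.n_genes)

    def _n_lowvar(self, n: int) -> int:
        return int(round(self.frac_low_variance * n))

    def _n_dup(self, n: int) -> int:
        return int(round(self.frac_duplicate_ids * n))

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_stage))


@dataclass
class GroundTruth:
    """Planted signals: per (region, stage) differential genes with their
    effect sizes, plus any planted pathway blocks."""

    planted: dict = field(default_factory=dict)  # region -> {stage -> [(gene, effect)]}
    pathway: dict = field(default_factory=dict)  # region -> [block dicts]

    def planted_genes(self, region: str, stage: int) -> list:
        return [g for g, _ in self.planted.get(region, {}).get(stage, [])]

    def all_planted_genes(self, region: str) -> set:
        out = set()
        for stage in self.planted.get(region, {}):
            out.update(self.planted_genes(region, stage))
        return out

    def to_json(self, path) -> None:
        payload = {
            "planted": {
                r: {str(s): [[g, e] for g, e in recs] for s, recs in stages.items()}
                for r, stages in self.planted.items()
            },
            "pathway": self.pathway,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        planted = {
            r: {int(s): [(g, float(e)) for g, e in recs] for s, recs in stages.items()}
            for r, stages in payload["planted"].items()
        }
        return cls(planted=planted, pathway=payload.get("pathway", {}))


def _region_rng(seed: int, region: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(region.encode())])


def _gene_id(i: int) -> str:
    return str(10001 + i)


def _make_clinical(config: SyntheticConfig):
    """Subjects, their stages, Braak scores and clinical covariates."""
    rng = np.random.default_rng([int(config.seed), 911])
    stages = np.repeat([0, 1, 2], config.n_per_stage)
    subjects = [f"S{i + 1:03d}" for i in range(config.n_subjects)]
    braak = np.array([rng.integers(*_BRAAK_RANGE[s], endpoint=True) for s in stages])
    frame = pd.DataFrame(
        {
            "braak": pd.array(braak, dtype="Int64"),
            "age": np.round(rng.normal(84.13, 7.23, config.n_subjects), 1),
            "sex": np.where(rng.random(config.n_subjects) < 0.72, "F", "M"),
            "pmi": np.round(np.clip(rng.normal(361.0, 318.7, config.n_subjects), 30, None), 0),
            "ph": np.round(rng.normal(6.37, 0.28, config.n_subjects), 2),
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    return ClinicalTable(frame), stages, subjects


def _generate_region(config: SyntheticConfig, region: str, stages: np.ndarray,
                     subjects: list):
    rng = _region_rng(config.seed, region)
    n_samples = len(subjects)
    n = config.genes_for(region)
    n_lowvar, n_dup = config._n_lowvar(n), config._n_dup(n)
    n_regular = n - n_lowvar - n_dup

    # column layout: [regular | low-variance | duplicate-ID]
    mu = rng.uniform(0.5, 2.0, n_regular)
    sigma = rng.uniform(0.3, 0.6, n_regular)
    if config.noise_family == "lognormal":
        base = np.exp(mu + sigma * rng.standard_normal((n_samples, n_regular)))
    else:
        mean = np.exp(mu)
        r = 5.0
        base = rng.negative_binomial(r, r / (r + mean), (n_samples, n_regular)).astype(float)

    cursor = 0
    planted: dict = {s: [] for s in range(3)}
    for stage in range(3):
        cols = np.arange(cursor, cursor + config.n_planted)
        cursor += config.n_planted
        if config.effect_size > 0 and len(cols):
            sd = base[:, cols].std(axis=0, ddof=0)
            base[np.ix_(stages == stage, cols)] += config.effect_size * sd
        planted[stage] = [(_gene_id(c), float(config.effect_size)) for c in cols]

    blocks_meta = []
    for block in config.pathway_blocks:
        cols = np.arange(cursor, cursor + 1 + block.n_panel_genes)
        cursor += len(cols)
        z = rng.standard_normal(n_samples)
        w = np.sqrt(block.correlation)
        for c in cols:
            eps = rng.standard_normal(n_samples)
            base[:, c] = np.exp(mu[c] + sigma[c] * (w * z + np.sqrt(1 - block.correlation) * eps))
        blocks_meta.append(
            {
                "panel_name": block.panel_name,
                "biomarker": _gene_id(cols[0]),
                "panel_genes": [_gene_id(c) for c in cols[1:]],
                "correlation": block.correlation,
            }
        )

    lowvar = np.exp(rng.normal(0.0, 0.05, (n_samples, n_lowvar)))

    # duplicate-ID columns reuse the ID of an unplanted regular gene but
    # carry freshly drawn values, so aggregation is non-trivial
    free = np.arange(cursor, n_regular)
    sources = rng.choice(free if len(free) >= 1 else np.arange(n_regular),
                         size=n_dup, replace=len(free) < n_dup)
    dup_mu = rng.uniform(0.5, 2.0, n_dup)
    dup_sigma = rng.uniform(0.3, 0.6, n_dup)
    dup = np.exp(dup_mu + dup_sigma * rng.standard_normal((n_samples, n_dup)))

    values = np.concatenate([base, lowvar, dup], axis=1)
    gene_ids = (
        [_gene_id(i) for i in range(n_regular)]
        + [_gene_id(n_regular + i) for i in range(n_lowvar)]
        + [_gene_id(int(s)) for s in sources]
    )
    sample_ids = [f"{subj}_{region}" for subj in subjects]
    matrix = ExpressionMatrix(region, gene_ids, sample_ids, values)
    return matrix, planted, blocks_meta


def generate_cohort(config: SyntheticConfig | None = None):
    """Generate the cohort.

    Returns ``(matrices, clinical, truth)`` where ``matrices`` maps region
    name to a samples x genes :class:`ExpressionMatrix`, ``clinical`` is the
    subject table and ``truth`` records the planted signals.  Deterministic
    for a fixed config (seed included).
    """
    config = config or SyntheticConfig()
    clinical, stages, subjects = _make_clinical(config)
    matrices, truth = {}, GroundTruth()
    for region in config.regions:
        matrix, planted, blocks = _generate_region(config, region, stages, subjects)
        matrices[region] = matrix
        truth.planted[region] = planted
        if blocks:
            truth.pathway[region] = blocks
    return matrices, clinical, truth


def null_cohort(config: SyntheticConfig | None = None):
    """Same cohort shape with zero planted effects: labels are independent
    of expression (the null for FDR-control checks)."""
    config = config or SyntheticConfig()
    config = replace(config, n_planted=0, pathway_blocks=())
    return generate_cohort(config)


def sample_subject_map(matrix: ExpressionMatrix) -> dict:
    """Recover the sample -> subject mapping from the generator's
    ``{subject}_{region}`` sample-ID convention."""
    return {s: s.rsplit("_", 1)[0] for s in matrix.sample_ids}
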