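"""Readers, writers and containers for expression matrices, clinical
metadata and pathway gene panels.

On-disk conventions
-------------------
* Expression: delimited text, genes as rows with the first column headed
  ``entrez_id`` and samples as columns (TSV by default; CSV accepted by
  ``.csv`` extension).  In memory the matrix is always samples x genes.
* Clinical: CSV with named columns ``subject_id, braak, age, sex, pmi, ph``
  (extra columns ignored).  Braak accepts integers 0-6 or Roman numerals
  (``III``); unparseable entries become missing and are dropped only at
  alignment time.
* Pathway panels: plain text, one gene ID per line.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .staging import EXCLUDED, braak_to_stage

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "RegionDataset",
    "PathwayPanel",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "read_pathway_panel",
    "align_region",
]

_ROMAN = {"0": 0, "O": 0, "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}


@dataclass
class ExpressionMatrix:
    """A dense samples x genes expression matrix for one brain region.

    ``gene_ids`` may contain duplicates before duplicate aggregation;
    ``sample_ids`` are always unique.  Values must be finite.
    """

    region_name: str
    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample IDs must be unique within a region")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            region_name=self.region_name,
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx],
        )


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_matrix(path, orientation: str = "genes_x_samples",
                           region_name: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression matrix; returns samples x genes.

    ``orientation`` states how the file is laid out; the returned matrix is
    transposed to samples x genes regardless.  Non-numeric cells, duplicate
    sample IDs and empty files raise ``ValueError``.
    """
    if orientation not in ("genes_x_samples", "samples_x_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n")
    if not header:
        raise ValueError(f"empty expression file: {path}")
    # parse the header ourselves: pandas would mangle duplicate column names,
    # and duplicate gene IDs are legitimate before aggregation
    columns = header.split(sep)[1:]
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         header=None, skiprows=1)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty expression file: {path}")
    if df.empty or not columns:
        raise ValueError(f"empty expression file: {path}")
    if df.shape[1] != len(columns):
        raise ValueError(f"ragged rows in {path}")
    df.columns = range(len(columns))
    values = np.empty(df.shape, dtype=float)
    for j, name in enumerate(columns):
        parsed = pd.to_numeric(df[j], errors="coerce")
        if parsed.isna().any():
            row = df.index[parsed.isna().to_numpy().argmax()]
            raise ValueError(
                f"non-numeric or missing cell at row {row!r}, column {name!r} in {path}"
            )
        values[:, j] = parsed.to_numpy()
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in columns]
    if orientation == "genes_x_samples":
        gene_ids, sample_ids, values = row_ids, col_ids, values.T
    else:
        gene_ids, sample_ids = col_ids, row_ids
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicated sample IDs in {path}: {dupes}")
    if region_name is None:
        region_name = os.path.splitext(os.path.basename(str(path)))[0]
    return ExpressionMatrix(region_name, gene_ids, sample_ids, values)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write genes-as-rows delimited text (first column ``entrez_id``).

    Values are written at full precision so a write/read round trip is
    bit-identical.
    """
    df = pd.DataFrame(m.values.T, columns=m.sample_ids)
    df.insert(0, "entrez_id", m.gene_ids)
    df.to_csv(path, sep=_sep_for(path), index=False)


def _parse_braak(raw):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip().upper()
    if not s or s in ("NA", "NAN", "NONE"):
        return None
    if s in _ROMAN:
        return _ROMAN[s]
    try:
        v = float(s)
    except ValueError:
        return None
    if v != int(v) or not 0 <= v <= 6:
        return None
    return int(v)


@dataclass
class ClinicalTable:
    """Per-subject clinical metadata (Braak score, age, sex, PMI, pH)."""

    frame: pd.DataFrame  # indexed by subject_id; column "braak" nullable Int64

    def __post_init__(self):
        if "braak" not in self.frame.columns:
            raise ValueError("clinical table requires a 'braak' column")
        if self.frame.index.has_duplicates:
            dupes = sorted(self.frame.index[self.frame.index.duplicated()].unique())
            raise ValueError(f"duplicate subject IDs: {dupes}")

    @property
    def subject_ids(self) -> list:
        return [str(s) for s in self.frame.index]

    def braak_of(self, subject_id):
        v = self.frame.loc[str(subject_id), "braak"]
        return None if pd.isna(v) else int(v)

    def write(self, path) -> None:
        self.frame.to_csv(path, index_label="subject_id")


def read_clinical_table(path) -> ClinicalTable:
    """Read the clinical CSV.  Requires ``subject_id`` and ``braak`` columns;
    rows whose Braak entry cannot be parsed keep a missing Braak (they are
    dropped at alignment, not here)."""
    df = pd.read_csv(path, dtype={0: str})
    if "subject_id" not in df.columns:
        raise ValueError(f"clinical table {path} lacks a 'subject_id' column")
    if "braak" not in df.columns:
        raise ValueError(f"clinical table {path} lacks a 'braak' column")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dupes = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"].unique())
        raise ValueError(f"duplicate subject IDs in {path}: {dupes}")
    df["braak"] = pd.array([_parse_braak(v) for v in df["braak"]], dtype="Int64")
    return ClinicalTable(df.set_index("subject_id"))


@dataclass
class PathwayPanel:
    """A named panel of pathway genes (GABAergic, mitochondrial, ...)."""

    panel_name: str
    gene_ids: list

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        if not self.gene_ids:
            raise ValueError("pathway panel must contain at least one gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"duplicate genes in panel {self.panel_name!r}")


def read_pathway_panel(path, panel_name: str | None = None) -> PathwayPanel:
    """Read a plain-text panel, one gene ID per line (blank lines and
    ``#`` comments skipped); panel name defaults to the file stem."""
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if panel_name is None:
        panel_name = os.path.splitext(os.path.basename(str(path)))[0]
    return PathwayPanel(panel_name, genes)


@dataclass
class RegionDataset:
    """One region's expression aligned to stage labels and subjects."""

    region_name: str
    expression: ExpressionMatrix
    labels: np.ndarray  # per-sample stage in {0,1,2}
    subject_map: dict = field(default_factory=dict)  # sample_id -> subject_id
    n_dropped: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != self.expression.n_samples:
            raise ValueError("one label per sample is required")
        missing = [s for s in self.expression.sample_ids if s not in self.subject_map]
        if missing:
            raise ValueError(f"samples without a subject mapping: {missing}")

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    def stage_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def align_region(expr: ExpressionMatrix, clinical: ClinicalTable,
                 sample_to_subject: dict) -> RegionDataset:
    """Link expression samples to Braak-derived stage labels.

    Samples whose subject has a missing Braak score are dropped (the count
    is recorded on the dataset); unknown subjects raise ``ValueError``.
    Gene order is untouched and sample order is preserved.
    """
    unknown = sorted(
        {str(sample_to_subject.get(s)) for s in expr.sample_ids
         if str(sample_to_subject.get(s)) not in set(clinical.subject_ids)}
    )
    missing_map = [s for s in expr.sample_ids if s not in sample_to_subject]
    if missing_map:
        raise ValueError(f"samples missing from sample-to-subject map: {missing_map}")
    if unknown:
        raise ValueError(f"samples map to subjects absent from the clinical table: {unknown}")
    keep, labels = [], []
    for i, s in enumerate(expr.sample_ids):
        stage = braak_to_stage(clinical.braak_of(sample_to_subject[s]))
        if stage == EXCLUDED:
            continue
        keep.append(i)
        labels.append(stage)
    sub = expr.subset_samples(np.asarray(keep, dtype=int)) if len(keep) < expr.n_samples else expr
    return RegionDataset(
        region_name=expr.region_name,
        expression=sub,
        labels=np.asarray(labels, dtype=int),
        subject_map={s: str(sample_to_subject[s]) for s in sub.sample_ids},
        n_dropped=expr.n_samples - len(keep),
    )
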