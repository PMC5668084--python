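"""Expression-matrix and sample-table I/O, alignment, and reference-sample batch QC.

The pipeline consumes already-normalized log2 expression (genes x samples) as
tab-delimited text or a GCT-like format, plus a per-sample annotation table.
Missing expression values are rejected rather than imputed: the upstream array
pipeline yields complete matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_RECURRENT = "recurrent"
CLASS_NON_RECURRENT = "non_recurrent"
CLASS_UNKNOWN = "unknown"
STAGES = ("IA", "IB", "IIA", "IIB", "IIIA")
ROLE_TRAIN = "train"
ROLE_VALIDATION = "validation"

SAMPLE_TABLE_COLUMNS = [
    "sample_id",
    "class",
    "stage",
    "dfs_months",
    "event",
    "batch",
    "role",
    "is_reference",
]

# printing precision for expression round-trips
_FLOAT_FMT = "%.6g"


class ExpressionParseError(ValueError):
    """Malformed expression file (duplicate IDs, ragged rows, non-numeric cells)."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with identifier lists."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Series(ids)[pd.Series(ids).duplicated()].tolist()
                raise ValueError(f"duplicate {name} IDs: {dupes[:5]}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy(float))

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        pos = pd.Index(self.sample_ids).get_indexer(list(ids))
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"sample IDs not in matrix: {missing[:5]}")
        return pos

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = self.sample_index(ids)
        return ExpressionMatrix(self.gene_ids, self.sample_ids[pos], self.values[:, pos])

    def subset_genes(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = pd.Index(self.gene_ids).get_indexer(list(ids))
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"gene IDs not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.gene_ids[pos], self.sample_ids, self.values[pos, :])


def _diagnose_lines(path: str, n_fields: int, skip: int) -> None:
    """Second pass over a file pandas rejected: name the offending line."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= skip:
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == skip + 1:
                n_fields = len(fields)
                continue
            if len(fields) != n_fields:
                raise ExpressionParseError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(fields)} fields, expected {n_fields})"
                )
            for col, cell in enumerate(fields[1:], start=2):
                try:
                    float(cell)
                except ValueError:
                    raise ExpressionParseError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno}, column {col}"
                    ) from None


def read_expression(path: str, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV (header row = sample IDs, first
    column = gene IDs; first header cell ignored) or a GCT-like file whose two
    extra header lines and Description column are skipped."""
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")
    skip = 2 if format == "gct" else 0
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, encoding="utf-8")
    except pd.errors.ParserError:
        _diagnose_lines(path, -1, skip)
        raise
    if format == "gct" and df.columns[0].lower() == "description":
        df = df.drop(columns=df.columns[0])
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ExpressionParseError(f"{path}: duplicate gene IDs: {dupes[:5]}")
    if pd.Index(df.columns).duplicated().any():
        raise ExpressionParseError(f"{path}: duplicate sample IDs in header")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        _diagnose_lines(path, -1, skip)
        raise ExpressionParseError(f"{path}: non-numeric expression values")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ExpressionParseError(f"{path}: missing value in gene {gene!r}")
    df.index = df.index.astype(str)
    return ExpressionMatrix.from_frame(df)


def write_expression(expr: ExpressionMatrix, path: str, format: str = "tsv") -> None:
    df = expr.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        if format == "gct":
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, expr.sample_ids)) + "\n")
            for gid, row in zip(expr.gene_ids, expr.values):
                fh.write(str(gid) + "\tna\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")
        elif format == "tsv":
            fh.write("gene_id\t" + "\t".join(map(str, df.columns)) + "\n")
            for gid, row in zip(expr.gene_ids, expr.values):
                fh.write(str(gid) + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")
        else:
            raise ValueError(f"unknown expression format {format!r}")


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    samples = samples.copy()
    samples["sample_id"] = samples["sample_id"].astype(str)
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in sample table")
    samples["is_reference"] = samples["is_reference"].astype(bool)
    clinical = ~samples["is_reference"]
    bad_class = clinical & ~samples.loc[:, "class"].isin(
        [CLASS_RECURRENT, CLASS_NON_RECURRENT, CLASS_UNKNOWN]
    )
    if bad_class.any():
        raise ValueError(
            f"invalid class labels: {samples.loc[bad_class, 'class'].unique().tolist()}"
        )
    unknown_train = clinical & (samples["class"] == CLASS_UNKNOWN) & (samples["role"] == ROLE_TRAIN)
    if unknown_train.any():
        raise ValueError("unknown class is only permitted for validation samples")
    dfs = pd.to_numeric(samples.loc[clinical, "dfs_months"], errors="coerce")
    if (dfs.dropna() < 0).any():
        raise ValueError("dfs_months must be non-negative")
    return samples


def read_sample_table(path: str) -> pd.DataFrame:
    samples = pd.read_csv(
        path, sep="\t", encoding="utf-8", dtype={"sample_id": str, "batch": str, "stage": str}
    )
    return validate_sample_table(samples)


def write_sample_table(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False, float_format="%.6g")


def blind_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Strip clinical outcome columns (class, dfs_months, event) so a predict
    stage provably cannot read them; bookkeeping columns are retained."""
    blinded = samples.copy()
    clinical = ~blinded["is_reference"]
    blinded.loc[clinical, "class"] = CLASS_UNKNOWN
    blinded["dfs_months"] = np.nan
    blinded["event"] = np.nan
    return blinded


def align(expr: ExpressionMatrix, samples: pd.DataFrame):
    """Restrict matrix and table to their shared sample IDs, in matrix order.

    Reference-sample rows lacking expression columns (or vice versa) are
    dropped with a logged warning; an empty intersection is an error.
    """
    table_ids = set(samples["sample_id"])
    keep = [s for s in expr.sample_ids if s in table_ids]
    if not keep:
        raise ValueError("expression matrix and sample table share no sample IDs")
    dropped_expr = [s for s in expr.sample_ids if s not in table_ids]
    dropped_tab = sorted(table_ids - set(expr.sample_ids))
    if dropped_expr:
        logger.warning("align: dropped %d expression columns without annotation: %s",
                       len(dropped_expr), dropped_expr[:5])
    if dropped_tab:
        logger.warning("align: dropped %d annotation rows without expression: %s",
                       len(dropped_tab), dropped_tab[:5])
    expr2 = expr.subset_samples(keep)
    samples2 = samples.set_index("sample_id").loc[keep].reset_index()
    return expr2, samples2


@dataclass
class BatchQCReport:
    """Pairwise agreement of the replicated reference sample across batches."""

    correlations: dict = field(default_factory=dict)  # {"b1|b2": r}
    min_correlation: float = float("nan")
    threshold: float = 0.95
    passed: bool = False
    missing_batches: list = field(default_factory=list)
    complete: bool = True

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "correlations": self.correlations,
            "min_correlation": self.min_correlation,
            "threshold": self.threshold,
            "passed": self.passed,
            "missing_batches": self.missing_batches,
            "complete": self.complete,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def batch_qc(expr: ExpressionMatrix, samples: pd.DataFrame, threshold: float = 0.95) -> BatchQCReport:
    """Pearson-correlate the reference profile of every batch pair.

    Each processing batch carries a replicate of the same reference RNA, so
    cross-batch correlation of those profiles measures batch consistency.
    Passes iff the minimum pairwise correlation reaches ``threshold``.
    """
    refs = samples[samples["is_reference"]]
    all_batches = sorted(samples["batch"].dropna().astype(str).unique())
    ref_by_batch: dict[str, np.ndarray] = {}
    for batch, grp in refs.groupby(refs["batch"].astype(str)):
        cols = expr.sample_index(grp["sample_id"])
        ref_by_batch[batch] = expr.values[:, cols].mean(axis=1)
    missing = [b for b in all_batches if b not in ref_by_batch]
    if len(ref_by_batch) < 2:
        raise ValueError("batch QC requires reference samples in at least 2 batches")
    batches = sorted(ref_by_batch)
    profiles = np.column_stack([ref_by_batch[b] for b in batches])
    corr = np.corrcoef(profiles, rowvar=False)
    pairs = {
        f"{a}|{b}": float(corr[i, j])
        for (i, a), (j, b) in combinations(enumerate(batches), 2)
    }
    min_r = min(pairs.values())
    return BatchQCReport(
        correlations=pairs,
        min_correlation=min_r,
        threshold=threshold,
        passed=min_r >= threshold,
        missing_batches=missing,
        complete=not missing,
    )
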