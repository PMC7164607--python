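"""Expression matrices, library metadata, RPM conversion and per-gene summaries.

The central container is :class:`ExpressionMatrix`, a gene-by-library table of
non-negative expression values (raw unique-read counts or reads-per-million)
together with per-library metadata (cultivar, tree, tissue, timepoint,
genotype group, total mapped reads). Summaries follow the conventional
reference-gene screening columns: mean, standard deviation, high, low,
high/low ratio and CV%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LibraryMeta",
    "ExpressionMatrix",
    "GeneSummary",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "to_rpm",
    "summarize_gene",
    "summarize_all",
    "summary_from_stats",
    "format_summary",
]

TISSUES = ("flower", "ovary", "whole_fruit", "endocarp")
GENOTYPE_GROUPS = ("normal", "stoneless")

#: Columns expected in a library metadata table, in canonical order.
META_COLUMNS = (
    "library_id",
    "cultivar",
    "tree",
    "tissue",
    "timepoint",
    "genotype_group",
    "total_mapped_reads",
)


@dataclass(frozen=True)
class LibraryMeta:
    """Metadata for one sequencing library."""

    library_id: str
    cultivar: str
    tree: str
    tissue: str
    timepoint: str
    genotype_group: str
    total_mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(
                f"unknown tissue {self.tissue!r} for library {self.library_id!r}; "
                f"expected one of {TISSUES}"
            )
        if self.genotype_group not in GENOTYPE_GROUPS:
            raise ValueError(
                f"unknown genotype_group {self.genotype_group!r} for library "
                f"{self.library_id!r}; expected one of {GENOTYPE_GROUPS}"
            )
        if self.total_mapped_reads < 0:
            raise ValueError(
                f"total_mapped_reads must be >= 0 for library {self.library_id!r}"
            )


@dataclass
class ExpressionMatrix:
    """Gene-by-library expression values plus library metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per library, all cells
        non-negative and non-missing.
    libraries
        One :class:`LibraryMeta` per column, in column order.
    layer
        ``"raw_counts"`` (integers), ``"rpm"`` or ``"normalized"``.
    """

    values: pd.DataFrame
    libraries: list[LibraryMeta] = field(default_factory=list)
    layer: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.layer not in ("raw_counts", "rpm", "normalized"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.values.isna().any().any():
            bad = self.values.stack(future_stack=True)
            bad = bad[bad.isna()].index[0]
            raise ValueError(f"missing cell at gene {bad[0]!r}, library {bad[1]!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.libraries:
            ids = [m.library_id for m in self.libraries]
            if ids != list(self.values.columns):
                raise ValueError("metadata order does not match matrix columns")
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate library_id in metadata")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta(self, library_id: str) -> LibraryMeta:
        for m in self.libraries:
            if m.library_id == library_id:
                return m
        raise KeyError(library_id)

    def libraries_where(self, **field_values: str) -> list[str]:
        """Library ids whose metadata matches all given field=value pairs."""
        out = []
        for m in self.libraries:
            if all(getattr(m, k) == v for k, v in field_values.items()):
                out.append(m.library_id)
        return out

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.libraries, self.layer)


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene summary row: mean, StDev, CV%, high, low, high/low ratio.

    ``high_low_ratio`` is NaN with ``ratio_undefined=True`` when the lowest
    value is zero (a ratio against zero is reported as undefined, not
    infinity). ``stdev_undefined`` flags single-library subsets.
    """

    gene_id: str
    mean: float
    stdev: float
    cv_percent: float
    high: float
    low: float
    high_low_ratio: float
    ratio_undefined: bool = False
    stdev_undefined: bool = False


def read_metadata(meta_path: str | Path) -> list[LibraryMeta]:
    """Read a delimited library-metadata table (columns as in META_COLUMNS)."""
    df = pd.read_csv(meta_path, sep=None, engine="python", dtype=str)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file missing columns: {missing}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            LibraryMeta(
                library_id=str(row["library_id"]),
                cultivar=str(row["cultivar"]),
                tree=str(row["tree"]),
                tissue=str(row["tissue"]),
                timepoint=str(row["timepoint"]),
                genotype_group=str(row["genotype_group"]),
                total_mapped_reads=int(row["total_mapped_reads"]),
            )
        )
    return metas


def read_matrix(
    path: str | Path,
    meta_path: str | Path | None = None,
    layer: str = "raw_counts",
) -> ExpressionMatrix:
    """Read a delimited gene-by-library matrix, first column gene ids.

    Libraries are reordered to match the metadata file; a matrix column with
    no metadata row is a hard error naming the library, as is a non-numeric
    cell (named by gene and library).
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            gene = coerced[coerced.isna()].index[0]
            raise ValueError(
                f"non-numeric value at gene {gene!r}, library {col!r}"
            )
        df[col] = coerced
    df.columns = [str(c) for c in df.columns]
    metas: list[LibraryMeta] = []
    if meta_path is not None:
        metas = read_metadata(meta_path)
        known = {m.library_id for m in metas}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ValueError(
                f"library {unknown[0]!r} in matrix has no metadata row"
            )
        order = [m.library_id for m in metas if m.library_id in df.columns]
        metas = [m for m in metas if m.library_id in df.columns]
        df = df[order]
    if layer == "raw_counts":
        arr = df.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("raw_counts layer requires integer values")
        df = df.round().astype(np.int64)
    return ExpressionMatrix(df, metas, layer)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.values.to_csv(path, sep=sep, index_label="gene_id")


def to_rpm(matrix: ExpressionMatrix, totals_source: str = "metadata") -> ExpressionMatrix:
    """Convert raw counts to reads per million mapped reads.

    ``totals_source="metadata"`` divides by each library's total mapped reads
    from its metadata; ``"column_sum"`` divides by the matrix column sums (so
    each output column sums to 1e6 exactly).
    """
    if matrix.layer != "raw_counts":
        raise ValueError(f"to_rpm expects raw_counts, got layer {matrix.layer!r}")
    if totals_source == "metadata":
        if not matrix.libraries:
            raise ValueError("metadata totals requested but matrix has no metadata")
        totals = np.array([m.total_mapped_reads for m in matrix.libraries], dtype=float)
    elif totals_source == "column_sum":
        totals = matrix.values.sum(axis=0).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown totals_source {totals_source!r}")
    if (totals <= 0).any():
        bad = matrix.library_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"library {bad!r} has zero total reads")
    rpm = matrix.values.astype(float) * (1e6 / totals)
    return ExpressionMatrix(rpm, matrix.libraries, "rpm")


def _summary(gene_id: str, x: np.ndarray, ddof: int) -> GeneSummary:
    mean = float(np.mean(x))
    high = float(np.max(x))
    low = float(np.min(x))
    stdev_undefined = x.size <= ddof
    stdev = float("nan") if stdev_undefined else float(np.std(x, ddof=ddof))
    cv = float("nan")
    if not stdev_undefined:
        cv = 0.0 if stdev == 0 else 100.0 * stdev / mean
    ratio_undefined = low == 0
    ratio = float("nan") if ratio_undefined else high / low
    return GeneSummary(
        gene_id=gene_id,
        mean=mean,
        stdev=stdev,
        cv_percent=cv,
        high=high,
        low=low,
        high_low_ratio=ratio,
        ratio_undefined=ratio_undefined,
        stdev_undefined=stdev_undefined,
    )


def summarize_gene(
    matrix: ExpressionMatrix,
    gene: str,
    library_subset: Iterable[str] | None = None,
    ddof: int = 1,
) -> GeneSummary:
    """Summary statistics for one gene across libraries.

    Uses the sample standard deviation (``ddof=1``) by default; pass
    ``ddof=0`` for the population form. A single-library subset yields an
    undefined StDev/CV (flagged), and a zero minimum yields an undefined
    high/low ratio.
    """
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    row = matrix.values.loc[gene]
    if library_subset is not None:
        subset = list(library_subset)
        if not subset:
            raise ValueError("library_subset must be non-empty")
        missing = [s for s in subset if s not in matrix.values.columns]
        if missing:
            raise KeyError(f"libraries not in matrix: {missing}")
        row = row[subset]
    return _summary(gene, row.to_numpy(dtype=float), ddof)


def summarize_all(matrix: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """One summary row per gene, in matrix gene order.

    Columns: gene_id, mean, stdev, high, low, high_low_ratio, cv_percent.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("summarize_all requires at least 2 libraries")
    rows = [_summary(g, matrix.values.loc[g].to_numpy(dtype=float), ddof)
            for g in matrix.gene_ids]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "mean": [r.mean for r in rows],
            "stdev": [r.stdev for r in rows],
            "high": [r.high for r in rows],
            "low": [r.low for r in rows],
            "high_low_ratio": [r.high_low_ratio for r in rows],
            "cv_percent": [r.cv_percent for r in rows],
        }
    ).set_index("gene_id")


def summary_from_stats(
    gene_id: str, mean: float, stdev: float, high: float, low: float
) -> GeneSummary:
    """Build a summary row from already-computed moments.

    Used when only the printed summary statistics of a study are available
    (no per-library values): recomputes the derived columns — CV% =
    100*StDev/mean and the high/low ratio — from the given inputs.
    """
    ratio_undefined = low == 0 or math.isnan(low)
    return GeneSummary(
        gene_id=gene_id,
        mean=mean,
        stdev=stdev,
        cv_percent=100.0 * stdev / mean,
        high=high,
        low=low,
        high_low_ratio=float("nan") if ratio_undefined else high / low,
        ratio_undefined=ratio_undefined,
    )


def format_summary(summary: GeneSummary) -> dict[str, object]:
    """Report-style rounding: ratios to 2 d.p., CV to integer percent.

    Full precision is kept on the :class:`GeneSummary` itself; this only
    formats for output. Exact halves round away from zero (the usual report
    convention), not half-to-even as Python's built-in round() would.
    """

    def _round_half_up(x: float, nd: int) -> float:
        if math.isnan(x):
            return x
        q = 10**nd
        return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)

    return {
        "gene_id": summary.gene_id,
        "high_low_ratio": (
            None if summary.ratio_undefined else _round_half_up(summary.high_low_ratio, 2)
        ),
        "cv_percent": (
            None if summary.stdev_undefined else int(_round_half_up(summary.cv_percent, 0))
        ),
    }
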