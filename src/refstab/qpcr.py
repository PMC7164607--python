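"""qPCR Cq processing: replicate collapsing, standard curves, quantification.

Raw quantification-cycle (Cq) values arrive as technical triplicates per
sample x gene. They are collapsed to a mean Cq with a 0.5-cycle outlier rule,
standard curves are fitted on serial (default fivefold) dilution series by
ordinary least squares of Cq on log10(input), amplification efficiency is
derived from the slope, and Cq values are converted to relative quantities
through the fitted curve.

Efficiency-corrected quantification (this module) is deliberately separate
from stability ranking, which operates on raw mean Cq values only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqRecord",
    "StandardCurve",
    "collapse_replicates",
    "collapse_table",
    "fit_standard_curve",
    "fit_curves_from_table",
    "efficiency_from_slope",
    "cq_to_quantity",
    "quantify_table",
]


@dataclass(frozen=True)
class CqRecord:
    """Technical-replicate Cq values for one sample x gene reaction."""

    sample_id: str
    gene_id: str
    replicate_cqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.replicate_cqs) <= 3:
            raise ValueError("expected 1-3 technical replicates")
        if any(not np.isfinite(c) or c <= 0 for c in self.replicate_cqs):
            raise ValueError(
                f"Cq values must be positive and finite "
                f"({self.sample_id}/{self.gene_id}: {self.replicate_cqs})"
            )


@dataclass(frozen=True)
class CollapsedCq:
    """Mean Cq after replicate collapsing, with audit flags."""

    sample_id: str
    gene_id: str
    mean_cq: float  # NaN when failed
    outlier_discarded: bool = False
    failed: bool = False
    unguarded: bool = False  # only 2 replicates: outlier rule inapplicable


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution-series line: Cq = intercept + slope * log10(input).

    A valid amplification gives slope < 0; efficiency_percent is
    100 * (10^(-1/slope) - 1), i.e. 100% for perfect per-cycle doubling
    (slope about -3.32).
    """

    gene_id: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency_percent(self) -> float:
        return efficiency_from_slope(self.slope)


def collapse_replicates(record: CqRecord, outlier_delta: float = 0.5) -> CollapsedCq:
    """Collapse technical replicates to one mean Cq.

    With three replicates: if exactly one value lies more than
    ``outlier_delta`` cycles from BOTH other values, it is discarded and the
    remaining two averaged (flagged ``outlier_discarded``); if all three are
    mutually more than ``outlier_delta`` apart the reaction is marked
    ``failed``; otherwise all three are averaged. With two replicates the
    rule is inapplicable: both are averaged and flagged ``unguarded``.
    """
    cqs = np.asarray(record.replicate_cqs, dtype=float)
    if cqs.size == 1:
        return CollapsedCq(record.sample_id, record.gene_id, float(cqs[0]))
    if cqs.size == 2:
        return CollapsedCq(
            record.sample_id, record.gene_id, float(cqs.mean()), unguarded=True
        )
    # triplicate: count, for each value, how many of the others it is far from
    far = np.abs(cqs[:, None] - cqs[None, :]) > outlier_delta
    np.fill_diagonal(far, False)
    far_counts = far.sum(axis=1)
    outliers = np.flatnonzero(far_counts == 2)
    if outliers.size == 0:
        return CollapsedCq(record.sample_id, record.gene_id, float(cqs.mean()))
    if outliers.size == 1:
        keep = np.delete(cqs, outliers[0])
        return CollapsedCq(
            record.sample_id,
            record.gene_id,
            float(keep.mean()),
            outlier_discarded=True,
        )
    return CollapsedCq(record.sample_id, record.gene_id, float("nan"), failed=True)


def collapse_table(
    cq_long: pd.DataFrame, outlier_delta: float = 0.5
) -> pd.DataFrame:
    """Collapse a long-format Cq table (sample_id, gene_id, replicate, cq).

    Returns one row per sample x gene with mean_cq and flags.
    """
    required = {"sample_id", "gene_id", "cq"}
    missing = required - set(cq_long.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    rows = []
    for (sample, gene), grp in cq_long.groupby(["sample_id", "gene_id"], sort=False):
        rec = CqRecord(str(sample), str(gene), tuple(grp["cq"].astype(float)))
        c = collapse_replicates(rec, outlier_delta)
        rows.append(
            {
                "sample_id": c.sample_id,
                "gene_id": c.gene_id,
                "mean_cq": c.mean_cq,
                "outlier_discarded": c.outlier_discarded,
                "failed": c.failed,
                "unguarded": c.unguarded,
            }
        )
    return pd.DataFrame(rows)


def fit_standard_curve(
    dilution_cqs: Sequence[tuple[float, float]], gene_id: str = ""
) -> StandardCurve:
    """Least-squares standard curve from (relative input, mean Cq) points.

    The abscissa is log10 of the relative input amount (undiluted = 1.0, a
    fivefold series then runs 1, 1/5, 1/25, ...). Requires at least three
    points with non-degenerate inputs.
    """
    pts = list(dilution_cqs)
    if len(pts) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    inputs = np.asarray([p[0] for p in pts], dtype=float)
    if (inputs <= 0).any() or not np.all(np.isfinite(inputs)):
        raise ValueError("relative inputs must be strictly positive")
    x = np.log10(inputs)
    y = np.asarray([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("dilution inputs have zero variance")
    fit = stats.linregress(x, y)
    return StandardCurve(
        gene_id=gene_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def fit_curves_from_table(dilutions: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per gene from a long dilution table.

    Expects columns gene_id, relative_input, cq (replicates at the same
    input are averaged first).
    """
    required = {"gene_id", "relative_input", "cq"}
    missing = required - set(dilutions.columns)
    if missing:
        raise ValueError(f"dilution table missing columns: {sorted(missing)}")
    curves: dict[str, StandardCurve] = {}
    for gene, grp in dilutions.groupby("gene_id", sort=False):
        pts = (
            grp.groupby("relative_input")["cq"].mean().reset_index().to_numpy()
        )
        curves[str(gene)] = fit_standard_curve(
            [(float(a), float(b)) for a, b in pts], gene_id=str(gene)
        )
    return curves


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope.

    E% = 100 * (10^(-1/slope) - 1); slope -3.3219 (i.e. -1/log10 2) gives
    100%, perfect doubling each cycle.
    """
    if not slope < 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


def cq_to_quantity(cq: float, curve: StandardCurve) -> float:
    """Relative quantity from a Cq via the curve: 10^((cq - intercept)/slope).

    Quantities are relative to the curve's undiluted reference input
    (quantity 1 at cq == intercept).
    """
    if not curve.slope < 0:
        raise ValueError("invalid standard curve (slope must be negative)")
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


def quantify_table(
    collapsed: pd.DataFrame, curves: dict[str, StandardCurve]
) -> pd.DataFrame:
    """Relative quantities for a collapsed Cq table, one row per sample x gene.

    Failed reactions propagate as NaN quantities (never dropped).
    """
    out = collapsed.copy()
    qty = []
    for _, row in out.iterrows():
        gene = row["gene_id"]
        if gene not in curves:
            raise KeyError(f"no standard curve for gene {gene!r}")
        if row.get("failed", False) or not np.isfinite(row["mean_cq"]):
            qty.append(float("nan"))
        else:
            qty.append(cq_to_quantity(float(row["mean_cq"]), curves[gene]))
    out["quantity"] = qty
    return out
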