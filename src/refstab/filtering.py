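"""Three-stage candidate reference-gene discovery cascade.

Candidate reference genes are screened from a normalized expression matrix
with three nested filters:

1. group stability + expression window — the fold change between two library
   groups (e.g. minimal-endocarp trees vs normal-stone cultivars) must lie in
   a narrow window, and the overall mean expression must sit inside a
   detectability window (high enough to quantify, low enough not to require
   extra dilution for qPCR);
2. endocarp-relative variability — the standard deviation across all
   libraries divided by the value in a designated endocarp reference library
   must fall below a first cap, biasing the screen toward genes that hold
   their level in endocarp tissue;
3. the same score below a tighter cap.

Every stage's survivors and every gene's scores are kept in a
:class:`FilterTrace` so the screen is fully auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "FilterThresholds",
    "FilterTrace",
    "group_fold_change",
    "expression_window",
    "endocarp_relative_stability",
    "run_cascade",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds and groupings for the candidate cascade.

    ``fc_mode="ratio"`` (default) keeps genes whose between-group fold change
    (always >= 1) lies in ``fc_window`` — with the default (1.0, 1.1) that is
    at most a 10% group difference. ``fc_mode="abs_log2"`` instead requires
    ``|log2 fold change|`` inside the window, the literal reading of a
    "between |1.0| and |1.1| log2 differences" screen; note that keeps
    2.0–2.14-fold changers and is provided for comparison only.

    Boundary conventions: the fold-change window is closed (a gene at
    exactly 1.1 passes), the expression window is open (strictly between
    min and max), and both stability caps are strict "less than".
    """

    reference_library: str
    group_a: frozenset[str]
    group_b: frozenset[str]
    fc_window: tuple[float, float] = (1.0, 1.1)
    fc_mode: str = "ratio"
    expr_min: float = 11.0
    expr_max: float = 450.0
    stage1_stability_max: float = 0.20
    stage2_stability_max: float = 0.11

    def __post_init__(self) -> None:
        if self.fc_mode not in ("ratio", "abs_log2"):
            raise ValueError(f"unknown fc_mode {self.fc_mode!r}")
        if not self.expr_min < self.expr_max:
            raise ValueError("expr_min must be < expr_max")
        if not 0 < self.stage2_stability_max <= self.stage1_stability_max:
            raise ValueError("need 0 < stage2_stability_max <= stage1_stability_max")
        if self.fc_window[0] > self.fc_window[1]:
            raise ValueError("fc_window bounds out of order")
        if self.group_a & self.group_b:
            raise ValueError("fold-change groups must be disjoint")
        if not self.group_a or not self.group_b:
            raise ValueError("fold-change groups must be non-empty")


@dataclass
class FilterTrace:
    """Per-gene scores and per-stage survivor lists from one cascade run.

    Survivor lists are ordered by ascending stability score and are nested:
    stage3 ⊆ stage2 ⊆ stage1.
    """

    scores: pd.DataFrame  # columns: fold_change, mean_expr, stability_score
    survivors_stage1: list[str] = field(default_factory=list)
    survivors_stage2: list[str] = field(default_factory=list)
    survivors_stage3: list[str] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (
            len(self.survivors_stage1),
            len(self.survivors_stage2),
            len(self.survivors_stage3),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long trace table: scores plus one boolean column per stage."""
        df = self.scores.copy()
        df["stage1"] = df.index.isin(self.survivors_stage1)
        df["stage2"] = df.index.isin(self.survivors_stage2)
        df["stage3"] = df.index.isin(self.survivors_stage3)
        return df


def group_fold_change(
    matrix: ExpressionMatrix,
    group_a: frozenset[str] | set[str],
    group_b: frozenset[str] | set[str],
) -> pd.Series:
    """Per-gene fold change >= 1 between two disjoint library groups.

    fc = max(mean_a, mean_b) / min(mean_a, mean_b). Genes with both group
    means zero get NaN (undefined); one zero mean gives inf (flagged
    infinite). Either way the gene cannot pass a finite window.
    """
    a = sorted(group_a)
    b = sorted(group_b)
    if set(a) & set(b):
        raise ValueError("groups overlap")
    if not a or not b:
        raise ValueError("groups must be non-empty")
    missing = [l for l in a + b if l not in matrix.values.columns]
    if missing:
        raise KeyError(f"libraries not in matrix: {missing}")
    ma = matrix.values[a].mean(axis=1).to_numpy(dtype=float)
    mb = matrix.values[b].mean(axis=1).to_numpy(dtype=float)
    hi = np.maximum(ma, mb)
    lo = np.minimum(ma, mb)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where((hi == 0) & (lo == 0), np.nan, hi / lo)
    return pd.Series(fc, index=matrix.values.index, name="fold_change")


def expression_window(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    expr_min: float = 11.0,
    expr_max: float = math.inf,
) -> list[str]:
    """Genes whose overall mean expression lies strictly inside (min, max)."""
    pool = matrix.gene_ids if genes is None else list(genes)
    means = matrix.values.loc[pool].mean(axis=1)
    return [g for g in pool if expr_min < means[g] < expr_max]


def endocarp_relative_stability(
    matrix: ExpressionMatrix, gene: str, reference_library: str, ddof: int = 1
) -> float:
    """StDev of a gene over all libraries divided by its value in one library.

    The reference library is an endocarp library from the minimal-endocarp
    genotype; dividing by it biases the screen toward genes that keep their
    expression level in endocarp tissue. A zero reference value makes the
    gene unscorable (NaN, excluded from survivors).
    """
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    if reference_library not in matrix.values.columns:
        raise KeyError(f"library {reference_library!r} not in matrix")
    row = matrix.values.loc[gene].to_numpy(dtype=float)
    ref = float(matrix.values.at[gene, reference_library])
    if ref == 0:
        return float("nan")
    return float(np.std(row, ddof=ddof)) / ref


def _stability_scores(
    matrix: ExpressionMatrix, reference_library: str, ddof: int = 1
) -> pd.Series:
    vals = matrix.values.to_numpy(dtype=float)
    ref = matrix.values[reference_library].to_numpy(dtype=float)
    sd = np.std(vals, axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(ref == 0, np.nan, sd / ref)
    return pd.Series(score, index=matrix.values.index, name="stability_score")


def run_cascade(matrix: ExpressionMatrix, thresholds: FilterThresholds) -> FilterTrace:
    """Run the full three-stage screen and return its trace.

    Stage 1: fold-change window AND expression window. Stage 2: stage 1 AND
    stability score below the first cap. Stage 3: stage 2 AND score below
    the tighter cap. Survivors within each stage are ordered by ascending
    stability score (ties by gene id).
    """
    t = thresholds
    if t.reference_library not in matrix.values.columns:
        raise KeyError(f"reference library {t.reference_library!r} not in matrix")
    fc = group_fold_change(matrix, t.group_a, t.group_b)
    mean_expr = matrix.values.mean(axis=1).astype(float)
    score = _stability_scores(matrix, t.reference_library)
    scores = pd.DataFrame(
        {"fold_change": fc, "mean_expr": mean_expr, "stability_score": score}
    )

    if t.fc_mode == "ratio":
        fc_ok = (fc >= t.fc_window[0]) & (fc <= t.fc_window[1])
    else:
        log_fc = np.abs(np.log2(fc))
        fc_ok = (log_fc >= t.fc_window[0]) & (log_fc <= t.fc_window[1])
    expr_ok = (mean_expr > t.expr_min) & (mean_expr < t.expr_max)
    stage1_mask = fc_ok.fillna(False) & expr_ok
    score_ok = score.notna()
    stage2_mask = stage1_mask & score_ok & (score < t.stage1_stability_max)
    stage3_mask = stage2_mask & (score < t.stage2_stability_max)

    def _ordered(mask: pd.Series) -> list[str]:
        kept = scores[mask].sort_index(kind="mergesort")
        return list(kept.sort_values("stability_score", kind="mergesort").index)

    trace = FilterTrace(
        scores=scores,
        survivors_stage1=_ordered(stage1_mask),
        survivors_stage2=_ordered(stage2_mask),
        survivors_stage3=_ordered(stage3_mask),
    )
    for i, n in enumerate(trace.counts, start=1):
        if n == 0:
            logger.warning("filter cascade stage %d has no survivors", i)
            break
    return trace
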