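"""Reference-gene stability ranking: four algorithms plus a comprehensive rank.

All four classical candidate-reference-gene stability measures operate here
on a genes x samples matrix of mean Cq values:

* comparative delta-Ct — mean, over all partner genes, of the StDev of the
  pairwise Cq difference across samples;
* BestKeeper — dispersion of a gene's raw Cq across samples (mean absolute
  deviation by default, StDev optional);
* NormFinder — model-based variance decomposition on log-scale expression;
* geNorm — mean pairwise variation M with iterative elimination of the least
  stable gene.

A comprehensive rank — the geometric mean of the four per-method ranks, as
popularized by the RefFinder tool — combines them. Ranking intentionally
uses raw Cq only (fixed efficiency 2.0 per cycle by default); per-gene
efficiencies are accepted for sensitivity analysis but efficiency-corrected
quantification lives in :mod:`refstab.qpcr`.

Lower is more stable for every method; rank 1 is the most stable gene and
ties receive mid-ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CqMatrix",
    "cq_to_linear",
    "delta_ct_stability",
    "bestkeeper_stability",
    "normfinder_stability",
    "genorm_stability",
    "genorm_pairwise_variation",
    "comprehensive_rank",
    "stability_report",
]


@dataclass
class CqMatrix:
    """Genes x samples mean-Cq matrix with optional groups and efficiencies.

    ``values`` is a complete DataFrame (genes as rows). ``groups`` maps
    sample id -> group label for grouped NormFinder. ``efficiencies`` maps
    gene id -> per-cycle amplification fold (default 2.0 for every gene).
    """

    values: pd.DataFrame
    groups: dict[str, str] | None = None
    efficiencies: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("Cq matrix must be complete (no missing cells)")
        if self.groups is not None:
            missing = [s for s in self.values.columns if s not in self.groups]
            if missing:
                raise ValueError(f"samples without group label: {missing}")

    def efficiency(self, gene: str) -> float:
        if self.efficiencies is None:
            return 2.0
        e = self.efficiencies.get(gene, 2.0)
        if not e > 1:
            raise ValueError(f"efficiency for {gene!r} must be > 1, got {e}")
        return e


def _as_cq(cq_matrix: CqMatrix | pd.DataFrame) -> CqMatrix:
    if isinstance(cq_matrix, pd.DataFrame):
        return CqMatrix(cq_matrix)
    return cq_matrix


def _rank(values: pd.Series) -> pd.Series:
    """Ascending ranks, ties as mid-ranks (1 = most stable)."""
    return values.rank(method="average")


def cq_to_linear(cq_matrix: CqMatrix | pd.DataFrame) -> pd.DataFrame:
    """Relative quantities from Cq: Q_gs = E_g^(min_s Cq_g - Cq_gs).

    Each gene's best (lowest-Cq) sample gets quantity 1; every extra cycle
    divides the quantity by the gene's amplification efficiency.
    """
    cm = _as_cq(cq_matrix)
    out = {}
    for gene in cm.values.index:
        row = cm.values.loc[gene].to_numpy(dtype=float)
        e = cm.efficiency(gene)
        out[gene] = e ** (row.min() - row)
    return pd.DataFrame.from_dict(out, orient="index", columns=cm.values.columns)


def delta_ct_stability(cq_matrix: CqMatrix | pd.DataFrame) -> pd.Series:
    """Comparative delta-Ct stability (cycles).

    value_g = mean over partners h != g of StDev_s(Cq_gs - Cq_hs), sample
    StDev (n-1). Invariant under per-sample shifts shared by all genes and
    under per-gene constant shifts.
    """
    cm = _as_cq(cq_matrix)
    vals = cm.values.to_numpy(dtype=float)
    g = vals.shape[0]
    if g < 2:
        raise ValueError("delta-Ct stability needs at least 2 genes")
    out = np.empty(g)
    for i in range(g):
        diffs = vals[i][None, :] - np.delete(vals, i, axis=0)
        out[i] = np.std(diffs, axis=1, ddof=1).mean()
    return pd.Series(out, index=cm.values.index, name="deltact_value")


def bestkeeper_stability(
    cq_matrix: CqMatrix | pd.DataFrame, mode: str = "mad"
) -> pd.Series:
    """BestKeeper-style raw-Cq dispersion (cycles).

    ``mad``: mean absolute deviation about the gene's mean Cq (the
    dispersion BestKeeper reports as "SD (+/- CP)"); ``sd``: sample StDev.
    Not invariant to per-sample shifts — raw-Cq dispersion deliberately
    includes input-amount variation.
    """
    cm = _as_cq(cq_matrix)
    vals = cm.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("BestKeeper needs at least 2 samples")
    if mode == "mad":
        out = np.abs(vals - vals.mean(axis=1, keepdims=True)).mean(axis=1)
    elif mode == "sd":
        out = np.std(vals, axis=1, ddof=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(out, index=cm.values.index, name="bestkeeper_value")


def _log2_expression(cm: CqMatrix) -> pd.DataFrame:
    return np.log2(cq_to_linear(cm))


def normfinder_stability(
    cq_matrix: CqMatrix | pd.DataFrame,
    grouped: bool | None = None,
    inflation: float | None = None,
) -> pd.Series:
    """Model-based (NormFinder-style) stability on log2 expression.

    Ungrouped: fit the additive model y_gs = gene effect + sample effect +
    residual by row/column means; value_g = StDev (n-1) of gene g's
    residuals, inflated by sqrt(g/(g-1)) to correct for the g-gene fit
    absorbing part of each gene's own variation (``inflation`` overrides the
    g/(g-1) variance factor).

    Grouped (``groups`` set on the matrix): an intra/intergroup
    decomposition — samples are centered (sample effects removed), then for
    each gene value_g = mean over groups of |d_gk| + sigma_gk/sqrt(n_k),
    where d_gk is the gene's group-mean deviation from its overall level and
    sigma_gk its intragroup residual StDev. Groups of one sample are an
    error.
    """
    cm = _as_cq(cq_matrix)
    if cm.values.shape[0] < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    y = _log2_expression(cm).to_numpy(dtype=float)
    g, n = y.shape
    if grouped is None:
        grouped = cm.groups is not None and len(set(cm.groups.values())) > 1
    if not grouped:
        resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
        var_factor = (g / (g - 1)) if inflation is None else inflation
        val = np.std(resid, axis=1, ddof=1) * math.sqrt(var_factor)
        return pd.Series(val, index=cm.values.index, name="normfinder_value")
    if cm.groups is None:
        raise ValueError("grouped mode requires group labels on the matrix")
    labels = np.array([cm.groups[s] for s in cm.values.columns])
    var_factor = (g / (g - 1)) if inflation is None else inflation
    # remove sample effects, then decompose per group
    z = y - y.mean(axis=0, keepdims=True)
    zbar = z.mean(axis=1, keepdims=True)  # overall per-gene level
    vals = np.zeros(g)
    uniq = sorted(set(labels))
    for lab in uniq:
        cols = labels == lab
        nk = int(cols.sum())
        if nk < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        zk = z[:, cols]
        d = zk.mean(axis=1) - zbar[:, 0]  # intergroup difference
        sigma = np.std(zk - zk.mean(axis=1, keepdims=True), axis=1, ddof=1)
        sigma = sigma * math.sqrt(var_factor)
        vals += np.abs(d) + sigma / math.sqrt(nk)
    vals /= len(uniq)
    return pd.Series(vals, index=cm.values.index, name="normfinder_value")


def _pairwise_v(logq: np.ndarray) -> np.ndarray:
    """Matrix V[g,h] = StDev_s(log2 Q_g - log2 Q_h), sample StDev."""
    g = logq.shape[0]
    v = np.zeros((g, g))
    for i in range(g):
        d = logq[i][None, :] - logq
        v[i] = np.std(d, axis=1, ddof=1)
    return v


def genorm_stability(
    quantities: pd.DataFrame,
    tie_mode: str = "shared_top",
) -> tuple[pd.Series, pd.Series]:
    """geNorm M values with iterative least-stable-gene elimination.

    ``quantities`` is a positive genes x samples relative-quantity table
    (e.g. from :func:`cq_to_linear`). Each round, every included gene's M is
    the mean StDev of its pairwise log2 ratios with the other included
    genes; the gene with the highest M is removed (ties: lexicographically
    last gene id) until two remain. A gene's reported M comes from its last
    round of inclusion.

    Returns ``(m_values, ranks)``. The final ranking is the reverse
    elimination order; the two surviving genes share rank 1.5
    (``tie_mode="shared_top"``, the default) or take ranks 1 and 2 by final
    M (``tie_mode="split"``).
    """
    if (quantities.to_numpy(dtype=float) <= 0).any():
        raise ValueError("geNorm requires strictly positive quantities")
    genes = list(quantities.index)
    if len(genes) < 3:
        raise ValueError("geNorm needs at least 3 genes")
    if tie_mode not in ("shared_top", "split"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    logq = np.log2(quantities.to_numpy(dtype=float))
    included = list(range(len(genes)))
    m_values: dict[str, float] = {}
    elimination: list[str] = []
    while len(included) > 2:
        sub = logq[included]
        v = _pairwise_v(sub)
        m = v.sum(axis=1) / (len(included) - 1)
        for idx, mi in zip(included, m):
            m_values[genes[idx]] = float(mi)
        worst_m = m.max()
        # ties at the max: drop the lexicographically last gene id
        worst = max(
            (genes[included[k]] for k in range(len(included)) if m[k] == worst_m)
        )
        elimination.append(worst)
        included = [k for k in included if genes[k] != worst]
    # final pair: M values equal their mutual pairwise variation
    survivors = [genes[k] for k in included]
    last_round_m = {s: m_values.get(s, float("nan")) for s in survivors}
    sub = logq[included]
    v_final = float(np.std(sub[0] - sub[1], ddof=1))
    for idx in included:
        m_values[genes[idx]] = v_final
    ranks: dict[str, float] = {}
    if tie_mode == "shared_top":
        for s in survivors:
            ranks[s] = 1.5
    else:
        # split by each survivor's M in its last multi-gene round, then id
        ordered_pair = sorted(survivors, key=lambda s: (last_round_m[s], s))
        for r, s in enumerate(ordered_pair, start=1):
            ranks[s] = float(r)
    for pos, gene in enumerate(reversed(elimination), start=3):
        ranks[gene] = float(pos)
    m_series = pd.Series({g: m_values[g] for g in genes}, name="genorm_m")
    rank_series = pd.Series({g: ranks[g] for g in genes}, name="genorm_rank")
    return m_series.loc[genes], rank_series.loc[genes]


def genorm_pairwise_variation(quantities: pd.DataFrame, k: int) -> float:
    """geNorm pairwise variation V(k/k+1) for choosing how many references.

    StDev over samples of the log2 ratio of geometric-mean normalization
    factors built from the top-k vs top-(k+1) geNorm-ranked genes.
    """
    genes = list(quantities.index)
    if not 2 <= k <= len(genes) - 1:
        raise ValueError(f"k must be in [2, {len(genes) - 1}], got {k}")
    _, ranks = genorm_stability(quantities)
    order = list(ranks.sort_values(kind="mergesort").index)
    logq = np.log2(quantities.to_numpy(dtype=float))
    idx = {g: i for i, g in enumerate(genes)}
    top_k = [idx[g] for g in order[:k]]
    top_k1 = [idx[g] for g in order[: k + 1]]
    nf_k = logq[top_k].mean(axis=0)
    nf_k1 = logq[top_k1].mean(axis=0)
    return float(np.std(nf_k - nf_k1, ddof=1))


def comprehensive_rank(method_ranks: pd.DataFrame, tie_break: pd.Series | None = None) -> pd.DataFrame:
    """RefFinder-style comprehensive ranking from four per-method ranks.

    ``method_ranks`` has one row per gene and one column per method. The
    comprehensive score is the geometric mean of the four ranks; the final
    rank orders genes by that score, breaking ties by ``tie_break``
    (typically the delta-Ct value) and then gene id.
    """
    if method_ranks.isna().any().any():
        bad = method_ranks.stack(future_stack=True)
        bad = bad[bad.isna()].index[0]
        raise ValueError(f"missing method rank for gene {bad[0]!r} ({bad[1]})")
    geo = np.exp(np.log(method_ranks.to_numpy(dtype=float)).mean(axis=1))
    out = pd.DataFrame(index=method_ranks.index)
    out["comprehensive_geomean"] = geo
    key = pd.DataFrame(
        {
            "geo": geo,
            "tb": tie_break.reindex(method_ranks.index) if tie_break is not None else 0.0,
            "gid": method_ranks.index.astype(str),
        },
        index=method_ranks.index,
    )
    ordered = key.sort_values(["geo", "tb", "gid"], kind="mergesort")
    final = pd.Series(range(1, len(ordered) + 1), index=ordered.index, dtype=float)
    out["comprehensive_rank"] = final.reindex(method_ranks.index)
    return out


def stability_report(
    cq_matrix: CqMatrix | pd.DataFrame,
    bestkeeper_mode: str = "mad",
    genorm_tie_mode: str = "shared_top",
) -> pd.DataFrame:
    """Full stability report: four method values + ranks + comprehensive rank.

    One row per gene with columns ``<method>_value`` / ``<method>_rank`` for
    deltact, bestkeeper, normfinder and genorm (geNorm reports its M value),
    plus the comprehensive geometric-mean score and final rank.
    """
    cm = _as_cq(cq_matrix)
    if cm.values.shape[0] < 3 or cm.values.shape[1] < 3:
        raise ValueError("stability ranking needs >= 3 genes and >= 3 samples")
    deltact = delta_ct_stability(cm)
    bk = bestkeeper_stability(cm, mode=bestkeeper_mode)
    nf = normfinder_stability(cm)
    m_values, genorm_ranks = genorm_stability(cq_to_linear(cm), tie_mode=genorm_tie_mode)
    report = pd.DataFrame(
        {
            "deltact_value": deltact,
            "deltact_rank": _rank(deltact),
            "bestkeeper_value": bk,
            "bestkeeper_rank": _rank(bk),
            "normfinder_value": nf,
            "normfinder_rank": _rank(nf),
            "genorm_m": m_values,
            "genorm_rank": genorm_ranks,
        }
    )
    ranks = report[["deltact_rank", "bestkeeper_rank", "normfinder_rank", "genorm_rank"]]
    comp = comprehensive_rank(ranks, tie_break=deltact)
    return report.join(comp)
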