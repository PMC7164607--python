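"""Multi-reference normalization of target-gene relative quantities.

A normalization scheme is a named set of reference genes; the per-sample
normalization factor is the geometric mean of the reference quantities in
that sample, and a target's normalized series is its quantity divided by the
factor. An empty scheme means "non-normalized". Scheme comparisons emit a
long-format table (target, scheme, sample, value) suitable for line plots of
one target under several schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationScheme",
    "geometric_mean_factor",
    "normalize_target",
    "run_scheme_comparison",
    "read_schemes",
]


@dataclass(frozen=True)
class NormalizationScheme:
    """Named combination of reference genes (empty = non-normalized)."""

    name: str
    reference_genes: tuple[str, ...] = ()

    @property
    def is_identity(self) -> bool:
        return len(self.reference_genes) == 0


def geometric_mean_factor(
    quantities: pd.DataFrame, reference_genes: tuple[str, ...] | list[str]
) -> pd.Series:
    """Per-sample geometric mean of the reference genes' quantities.

    ``quantities`` is a genes x samples table of positive relative
    quantities. Computed in log space for numerical robustness; a zero or
    negative reference quantity is an error naming gene and sample.
    """
    refs = list(reference_genes)
    if not refs:
        raise ValueError("reference gene set must be non-empty")
    missing = [g for g in refs if g not in quantities.index]
    if missing:
        raise KeyError(f"reference genes not in quantity table: {missing}")
    sub = quantities.loc[refs].astype(float)
    bad = (sub <= 0) | sub.isna()
    if bad.any().any():
        stacked = bad.stack(future_stack=True)
        gene, sample = stacked[stacked].index[0]
        raise ValueError(
            f"non-positive quantity for reference gene {gene!r} in sample {sample!r}"
        )
    return pd.Series(
        np.exp(np.log(sub.to_numpy()).mean(axis=0)),
        index=quantities.columns,
        name="factor",
    )


def normalize_target(
    target_quantities: pd.Series,
    scheme: NormalizationScheme,
    factors: pd.Series | None = None,
    calibrator: str | None = None,
) -> pd.Series:
    """Normalize one target's per-sample quantities under a scheme.

    An identity scheme returns the series unchanged; otherwise each sample's
    value is divided by that sample's factor (precomputed ``factors`` must
    cover the same samples). Missing target values (failed reactions)
    propagate as NaN. With ``calibrator`` the series is additionally divided
    by its value in that sample, making the calibrator read exactly 1.
    """
    values = target_quantities.astype(float)
    if scheme.is_identity:
        out = values.copy()
    else:
        if factors is None:
            raise ValueError(f"scheme {scheme.name!r} requires normalization factors")
        if set(values.index) != set(factors.index):
            raise ValueError(
                f"sample mismatch between target and factors for scheme {scheme.name!r}"
            )
        out = values / factors.reindex(values.index)
    if calibrator is not None:
        if calibrator not in out.index:
            raise KeyError(f"calibrator sample {calibrator!r} not present")
        out = out / out[calibrator]
    out.name = scheme.name
    return out


def run_scheme_comparison(
    rq_table: pd.DataFrame,
    targets: list[str],
    schemes: list[NormalizationScheme],
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Normalize each target under each scheme; long-format result.

    ``rq_table`` is genes x samples relative quantities covering targets and
    all scheme reference genes. A target may not serve as a reference in a
    scheme applied to it. Returns columns (target, scheme, sample, value)
    with one row per combination.
    """
    missing = [t for t in targets if t not in rq_table.index]
    if missing:
        raise KeyError(f"target genes not in quantity table: {missing}")
    factor_cache: dict[tuple[str, ...], pd.Series] = {}
    rows = []
    for scheme in schemes:
        factors = None
        if not scheme.is_identity:
            key = tuple(sorted(scheme.reference_genes))
            if key not in factor_cache:
                factor_cache[key] = geometric_mean_factor(rq_table, scheme.reference_genes)
            factors = factor_cache[key]
        for target in targets:
            if target in scheme.reference_genes:
                raise ValueError(
                    f"target {target!r} appears in its own reference set "
                    f"(scheme {scheme.name!r})"
                )
            series = normalize_target(
                rq_table.loc[target], scheme, factors, calibrator=calibrator
            )
            for sample, value in series.items():
                rows.append(
                    {
                        "target": target,
                        "scheme": scheme.name,
                        "sample": sample,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows, columns=["target", "scheme", "sample", "value"])


def read_schemes(path) -> list[NormalizationScheme]:
    """Read schemes from a small text file: one ``name: g1,g2,...`` per line.

    A name with no genes (``none:``) is the non-normalized scheme. Blank
    lines and ``#`` comments are ignored.
    """
    schemes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"malformed scheme line: {line!r}")
            name, _, genes = line.partition(":")
            gene_tuple = tuple(g.strip() for g in genes.split(",") if g.strip())
            schemes.append(NormalizationScheme(name.strip(), gene_tuple))
    return schemes
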