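"""Bundled worked-example tables.

Two small per-gene summary tables from a published plum early-fruit
reference-gene study ship with the package: the 13 previously published
Prunus reference genes (REF1-REF13) and the 9 RNA-seq-derived candidate
reference genes (P1-P9), each with the study's printed mean, StDev, high and
low expression (RPM) plus the printed high/low ratio and CV%. They serve as
inputs for recomputing the derived summary columns and as small realistic
fixtures; the per-library read data behind them were not released.

Note the printed inputs are themselves rounded (the candidate table to
integers), so a CV recomputed from them can differ from the printed CV by
one unit in the last printed digit.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["published_reference_summary", "candidate_reference_summary"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("refstab.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t", index_col="gene_id", na_values=["NA"])


def published_reference_summary() -> pd.DataFrame:
    """Printed summary rows for the 13 previously published reference genes."""
    return _load("published_reference_summary.tsv")


def candidate_reference_summary() -> pd.DataFrame:
    """Printed summary rows for the 9 RNA-seq-derived candidate genes."""
    return _load("candidate_reference_summary.tsv")
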