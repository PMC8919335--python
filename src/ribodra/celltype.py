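"""Percent-of-total expression across reference cell types.

For a gene list and a reference matrix of expression per cell type (e.g.
testicular somatic, mitotic, meiotic and post-meiotic cells), each gene's
expression is rescaled so its values across cell types sum to 100 — the
numbers behind per-gene heat-map rows — and a list-level profile is the
per-cell-type mean of those percentages.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["percent_expression", "summarize_list_profile"]


def percent_expression(genes, reference: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-total expression per cell type for the listed genes.

    Genes absent from the reference and genes with all-zero reference
    rows are excluded with a warning; cell-type column order is kept.
    """
    genes = pd.Index(pd.unique(pd.Index(genes)))
    present = genes.isin(reference.index)
    if not present.all():
        missing = genes[~present]
        warnings.warn(
            f"{len(missing)} gene(s) not in reference were excluded: "
            f"{list(missing[:5])}"
        )
    rows = reference.loc[genes[present]]
    if (rows.to_numpy() < 0).any():
        raise ValueError("reference expression must be nonnegative")
    totals = rows.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero gene row(s) dropped")
        rows, totals = rows[~zero], totals[~zero]
    return rows.div(totals, axis=0) * 100.0


def summarize_list_profile(profile: pd.DataFrame) -> pd.Series:
    """Mean percentage per cell type over the genes of a profile."""
    if profile.empty:
        raise ValueError("empty profile")
    return profile.mean(axis=0)
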