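"""Chromosome-level enrichment statistics for the DE/DRA gene sets.

Covers the meiotic sex chromosome inactivation (MSCI) questions: is the X
chromosome overrepresented among differentially expressed genes, are
X-linked DE genes biased towards upregulation relative to autosomal DE
genes, and how strongly does an X-linked gene list overlap an external
list (e.g. genes derepressed in another MSCI-defective mutant)?

All p-values are exact: Fisher's exact test for 2x2 contingency tables
and hypergeometric upper tails for set overrepresentation/overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyResult",
    "fisher_exact_2x2",
    "x_overrepresentation",
    "direction_bias_x_vs_autosome",
    "gene_list_overlap",
]


@dataclass
class ContingencyResult:
    table: np.ndarray
    odds_ratio: float
    p_value: float
    test: str = "fisher_exact"


def fisher_exact_2x2(table, alternative: str = "two-sided") -> ContingencyResult:
    """Fisher's exact test on a 2x2 table of nonnegative integers.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins that are as or less probable than the observed
    one.  The odds ratio is the sample estimate (a*d)/(b*c); 0/0 is
    reported as NaN, x/0 as infinity.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if t.sum() == 0:
        raise ValueError("all margins are zero")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = float(a * d) / float(b * c)
    _, p = stats.fisher_exact(t, alternative=alternative)
    return ContingencyResult(table=t, odds_ratio=odds, p_value=float(p))


def x_overrepresentation(de: pd.DataFrame, annotation: pd.DataFrame,
                         universe=None, chromosome: str = "X"):
    """Test whether a chromosome is overrepresented among DE genes.

    Hypergeometric upper-tail p for drawing >= k genes of the chromosome
    among the n DE genes from a universe of N genes of which K lie on the
    chromosome; fold enrichment is (k/n)/(K/N).

    The universe defaults to all genes in the DE table (i.e. genes that
    survived expression filtering), not the whole annotation.
    """
    de_genes = de.index[de["is_de"]] if "is_de" in de.columns else pd.Index(de)
    if universe is None:
        universe = de.index
    universe = pd.Index(pd.unique(pd.Index(universe)))
    if len(de_genes) == 0:
        raise ValueError("no DE genes: empty draw")
    missing = de_genes.difference(universe)
    if len(missing) > 0:
        raise ValueError(f"DE genes outside universe: {list(missing[:5])}")
    unannotated = universe.difference(annotation.index)
    if len(unannotated) > 0:
        raise ValueError(
            f"genes missing annotation: {list(unannotated[:5])}"
        )
    chrom = annotation.loc[universe, "chromosome"]
    N = len(universe)
    K = int((chrom == chromosome).sum())
    n = len(de_genes)
    k = int((annotation.loc[de_genes, "chromosome"] == chromosome).sum())
    if K == 0:
        raise ValueError(f"universe has no genes on chromosome {chromosome!r}")
    fold = (k / n) / (K / N)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return fold, min(p, 1.0)


def direction_bias_x_vs_autosome(de: pd.DataFrame,
                                 annotation: pd.DataFrame) -> ContingencyResult:
    """Fisher's exact test of direction bias: X vs autosomal DE genes.

    Builds the 2x2 table (X, autosome) x (up_in_mut, down_in_mut) over
    called genes and tests for association.  Y-linked genes are excluded
    from both strata (few genes, distinct regulation); undirected calls
    are dropped.
    """
    called = de[de["is_de"] & de["direction"].isin(["up_in_mut", "down_in_mut"])]
    chrom = annotation.loc[called.index, "chromosome"]
    n_y = int((chrom == "Y").sum())
    if n_y:
        warnings.warn(f"excluding {n_y} Y-linked DE genes from the contingency")
    keep = chrom != "Y"
    called, chrom = called[keep.to_numpy()], chrom[keep]
    on_x = chrom == "X"
    if on_x.sum() == 0 or (~on_x).sum() == 0:
        raise ValueError("need >=1 DE gene on X and >=1 on autosomes")
    up = (called["direction"] == "up_in_mut").to_numpy()
    table = np.array(
        [
            [int((on_x & up).sum()), int((on_x & ~up).sum())],
            [int((~on_x & up).sum()), int((~on_x & ~up).sum())],
        ]
    )
    return fisher_exact_2x2(table)


def gene_list_overlap(list_a, list_b, universe):
    """Overlap of two gene lists against a universe.

    Returns (n_overlap, jaccard, p_value) with the hypergeometric
    upper-tail p of observing at least the seen overlap.  Duplicate IDs
    are deduplicated with a warning.
    """
    a, b = pd.Index(list_a), pd.Index(list_b)
    uni = pd.Index(pd.unique(pd.Index(universe)))
    if a.has_duplicates or b.has_duplicates:
        warnings.warn("duplicate gene IDs in input lists were deduplicated")
        a, b = pd.Index(pd.unique(a)), pd.Index(pd.unique(b))
    for name, lst in (("list_a", a), ("list_b", b)):
        out = lst.difference(uni)
        if len(out) > 0:
            raise ValueError(f"{name} has genes outside universe: {list(out[:5])}")
    k = len(a.intersection(b))
    union = len(a.union(b))
    jaccard = k / union if union else 0.0
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(a), len(b)))
    return k, jaccard, min(p, 1.0)
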