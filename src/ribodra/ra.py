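"""Ribosome association (RA) ratios and the differential-RA screen.

RA for a transcript in one animal is the ratio of its IP (ribosome-bound)
TPM over its input (total RNA) TPM from the same animal.  Transcripts with
a zero input TPM in *any* input sample are removed before ratios are
formed; an IP of zero with a positive input is a valid RA of zero.
Differential ribosome association (DRA) is screened per gene with a
Welch's unpaired two-tailed t-test on the per-animal RA values of the two
genotypes at raw P < alpha, with no multiple-testing correction; a
Benjamini-Hochberg FDR column is emitted for information only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RATable",
    "DesignError",
    "compute_ra",
    "welch_t_test",
    "call_dra",
    "direction_summary",
]


class DesignError(ValueError):
    """Raised when a sample design violates the paired Input/IP layout."""


@dataclass
class RATable:
    """Per-animal ribosome-association ratios after the zero-input filter.

    Attributes
    ----------
    ra : pandas.DataFrame
        Genes x animals matrix of IP/input TPM ratios; only genes
        surviving the zero-input filter remain.
    genotype : pandas.Series
        Animal id -> {"WT", "MUT"}.
    n_filtered_genes : int
        Number of genes removed because some input sample was zero.
    """

    ra: pd.DataFrame
    genotype: pd.Series
    n_filtered_genes: int


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "animal_id", "genotype", "fraction"}
    missing = required - set(design.columns)
    if missing:
        raise DesignError(f"design lacks columns: {sorted(missing)}")
    bad_geno = set(design["genotype"]) - {"WT", "MUT"}
    if bad_geno:
        raise DesignError(f"unknown genotypes: {sorted(bad_geno)}")
    bad_frac = set(design["fraction"]) - {"input", "IP"}
    if bad_frac:
        raise DesignError(f"unknown fractions: {sorted(bad_frac)}")
    per_animal = design.groupby("animal_id")["fraction"].agg(list)
    for animal, fracs in per_animal.items():
        if sorted(fracs) != ["IP", "input"]:
            raise DesignError(
                f"animal {animal!r} must have exactly one input and one IP "
                f"sample, got {sorted(fracs)}"
            )
    geno_per_animal = design.groupby("animal_id")["genotype"].nunique()
    if (geno_per_animal > 1).any():
        raise DesignError("an animal maps to more than one genotype")
    counts = design.drop_duplicates("animal_id")["genotype"].value_counts()
    for g in ("WT", "MUT"):
        if counts.get(g, 0) < 2:
            raise DesignError(f"need >=2 animals of genotype {g}")
    return design


def compute_ra(input_matrix: pd.DataFrame, ip_matrix: pd.DataFrame,
               design: pd.DataFrame) -> RATable:
    """Pair each animal's IP and input samples and form IP/input ratios.

    Genes with a zero input value in any input sample (either genotype)
    are removed and counted in ``n_filtered_genes``.
    """
    validate_design(design)
    if not input_matrix.index.equals(ip_matrix.index):
        if set(input_matrix.index) != set(ip_matrix.index):
            raise ValueError("input and IP matrices cover different gene sets")
        ip_matrix = ip_matrix.loc[input_matrix.index]

    inp_design = design[design["fraction"] == "input"]
    ip_design = design[design["fraction"] == "IP"]
    for sid in inp_design["sample_id"]:
        if sid not in input_matrix.columns:
            raise ValueError(f"input matrix lacks design sample {sid!r}")
    for sid in ip_design["sample_id"]:
        if sid not in ip_matrix.columns:
            raise ValueError(f"IP matrix lacks design sample {sid!r}")

    inp_cols = input_matrix[list(inp_design["sample_id"])]
    keep = (inp_cols > 0).all(axis=1)
    n_filtered = int((~keep).sum())

    inp_by_animal = {r.animal_id: r.sample_id for r in inp_design.itertuples()}
    ip_by_animal = {r.animal_id: r.sample_id for r in ip_design.itertuples()}
    animals = list(inp_by_animal)
    ra = pd.DataFrame(
        {
            a: ip_matrix.loc[keep, ip_by_animal[a]]
            / input_matrix.loc[keep, inp_by_animal[a]]
            for a in animals
        }
    )
    ra.index.name = "gene_id"
    genotype = (
        design.drop_duplicates("animal_id")
        .set_index("animal_id")["genotype"]
        .loc[animals]
    )
    return RATable(ra=ra, genotype=genotype, n_filtered_genes=n_filtered)


def welch_t_test(group_a, group_b):
    """Welch's unpaired two-tailed t-test.

    Returns (t_stat, df, p_value) with the Welch-Satterthwaite degrees of
    freedom.  Degenerate conventions: both groups constant and equal gives
    t=0, p=1; both constant but unequal gives an infinite t and p=0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >=2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        df = float(na + nb - 2)
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    se2 = va / na + vb / nb
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def _welch_rowwise(a: np.ndarray, b: np.ndarray):
    """Vectorised Welch test over matrix rows (genes)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0.0
    if degenerate.any():
        df = np.where(degenerate, float(na + nb - 2), df)
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate,
                         np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return ma, mb, t, df, np.minimum(p, 1.0)


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_dra(ra_table: RATable, alpha: float = 0.05,
             log2: bool = False) -> pd.DataFrame:
    """Screen every retained gene for differential ribosome association.

    The Welch test runs on raw per-animal RA values by default; ``log2``
    tests log2-transformed ratios instead (zeros get a small offset).
    Direction ``up_in_mut`` means the mutant mean RA exceeds the wild-type
    mean; exact mean ties with p < alpha get direction ``none``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} must lie in (0, 1)")
    geno = ra_table.genotype
    wt_animals = geno.index[geno == "WT"]
    mut_animals = geno.index[geno == "MUT"]
    if len(wt_animals) < 2 or len(mut_animals) < 2:
        raise DesignError("need >=2 animals per genotype")
    wt = ra_table.ra[list(wt_animals)].to_numpy(dtype=float)
    mut = ra_table.ra[list(mut_animals)].to_numpy(dtype=float)
    if log2:
        eps = 1e-6
        wt, mut = np.log2(wt + eps), np.log2(mut + eps)
    m_mut, m_wt, t, df, p = _welch_rowwise(mut, wt)
    is_dra = p < alpha
    direction = np.where(
        ~is_dra, "none",
        np.where(m_mut > m_wt, "up_in_mut",
                 np.where(m_mut < m_wt, "up_in_wt", "none")),
    )
    return pd.DataFrame(
        {
            "mean_ra_wt": ra_table.ra[list(wt_animals)].mean(axis=1),
            "mean_ra_mut": ra_table.ra[list(mut_animals)].mean(axis=1),
            "t_stat": t,
            "df": df,
            "p_value": p,
            "bh_fdr": _bh_fdr(p),
            "is_dra": is_dra,
            "direction": direction,
        },
        index=ra_table.ra.index,
    )


def direction_summary(dra: pd.DataFrame):
    """Summarise DRA calls: count and direction percentages.

    Returns (n_dra, pct_up_in_mut, pct_up_in_wt); the percentages are NaN
    when no gene is called.  Genes called significant but with exactly
    tied means (direction "none") are excluded from the percentages.
    """
    if dra.empty:
        raise ValueError("empty DRA result table")
    called = dra[dra["is_dra"]]
    n_dra = int(len(called))
    directed = called[called["direction"] != "none"]
    if len(directed) == 0:
        return n_dra, float("nan"), float("nan")
    up_mut = float((directed["direction"] == "up_in_mut").mean() * 100.0)
    return n_dra, up_mut, 100.0 - up_mut
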