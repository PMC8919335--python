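"""Differential-expression calls on input (total RNA) samples.

The decision rule thresholds a per-gene score in [0, 1] at
``score_threshold`` (default 0.95) and additionally requires a directional
fold change different from one.  Two score sources are supported:

``welch_score``
    A stand-in scorer: 1 - p from a Welch test on log2(TPM + 1).  It is
    not an empirical-Bayes posterior; it exists so the decision rule can
    run without an external score table.
``plugin``
    A user-supplied per-gene score column (e.g. a genuine posterior
    probability of differential expression); only the decision rule is
    applied.

Fold change uses a pseudocount of 1 TPM on group means:
log2fc = log2((mean_mut + 1) / (mean_wt + 1)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ra import DesignError, _welch_rowwise

__all__ = ["call_de", "de_direction_and_magnitude_summary"]


def call_de(input_matrix: pd.DataFrame, design: pd.DataFrame,
            score_threshold: float = 0.95, method: str = "welch_score",
            scores: pd.Series | None = None) -> pd.DataFrame:
    """Call differentially expressed genes from the input fraction.

    Returns a table with columns mean_wt, mean_mut, log2fc, score, is_de,
    direction and fc_ge_2 (|log2fc| >= 1, computed for every gene).
    """
    if not 0.0 < score_threshold <= 1.0:
        raise ValueError(f"score_threshold={score_threshold} must lie in (0, 1]")
    inp = design[design["fraction"] == "input"]
    wt_ids = list(inp.loc[inp["genotype"] == "WT", "sample_id"])
    mut_ids = list(inp.loc[inp["genotype"] == "MUT", "sample_id"])
    if len(wt_ids) < 2 or len(mut_ids) < 2:
        raise DesignError("need >=2 input samples per genotype")
    missing = [s for s in wt_ids + mut_ids if s not in input_matrix.columns]
    if missing:
        raise ValueError(f"input matrix lacks design samples: {missing}")

    wt = input_matrix[wt_ids].to_numpy(dtype=float)
    mut = input_matrix[mut_ids].to_numpy(dtype=float)
    mean_wt, mean_mut = wt.mean(axis=1), mut.mean(axis=1)
    log2fc = np.log2((mean_mut + 1.0) / (mean_wt + 1.0))

    if method == "welch_score":
        _, _, _, _, p = _welch_rowwise(np.log2(mut + 1.0), np.log2(wt + 1.0))
        score = 1.0 - p
    elif method == "plugin":
        if scores is None:
            raise ValueError("method='plugin' requires a scores Series")
        score = scores.reindex(input_matrix.index).to_numpy(dtype=float)
        if np.isnan(score).any():
            missing = input_matrix.index[np.isnan(score)][:5].tolist()
            raise ValueError(f"plugin scores missing for genes: {missing}...")
    else:
        raise ValueError(f"unknown method {method!r}")

    is_de = (score >= score_threshold) & (log2fc != 0.0)
    direction = np.where(log2fc > 0, "up_in_mut",
                         np.where(log2fc < 0, "down_in_mut", "none"))
    direction = np.where(is_de, direction, "none")
    return pd.DataFrame(
        {
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "log2fc": log2fc,
            "score": score,
            "is_de": is_de,
            "direction": direction,
            "fc_ge_2": np.abs(log2fc) >= 1.0,
        },
        index=input_matrix.index,
    )


def de_direction_and_magnitude_summary(de: pd.DataFrame):
    """Summarise DE calls: count, percent down-in-mutant, percent with
    at least a two-fold change.

    Percentages are over called genes only and NaN when nothing is called.
    """
    if de.empty:
        raise ValueError("empty DE result table")
    called = de[de["is_de"]]
    n_de = int(len(called))
    if n_de == 0:
        return 0, float("nan"), float("nan")
    pct_down = float((called["direction"] == "down_in_mut").mean() * 100.0)
    pct_fc2 = float(called["fc_ge_2"].mean() * 100.0)
    return n_de, pct_down, pct_fc2
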