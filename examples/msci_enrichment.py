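"""Chromosome-level MSCI statistics on a DE gene table.

Constructs a DE result in which X-linked called genes are strongly biased
towards upregulation relative to autosomal ones (the pattern expected
when meiotic sex chromosome inactivation is leaky), then asks: is the X
overrepresented among DE genes at all, is the direction bias significant,
and how strongly does the X-linked up list overlap an external list?
"""

import numpy as np
import pandas as pd

from ribodra import (
    direction_bias_x_vs_autosome,
    gene_list_overlap,
    x_overrepresentation,
)

rng = np.random.default_rng(0)
n = 2000
genes = pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id")
chrom = np.where(rng.random(n) < 0.04, "X",
                 rng.choice([str(i) for i in range(1, 20)], n))
annotation = pd.DataFrame({"chromosome": chrom}, index=genes)

# ~5% of genes called DE; X-linked calls mostly up, autosomal mostly down
is_de = rng.random(n) < 0.05
p_up = np.where(chrom == "X", 0.85, 0.40)
direction = np.where(is_de,
                     np.where(rng.random(n) < p_up, "up_in_mut",
                              "down_in_mut"), "none")
de = pd.DataFrame({"is_de": is_de, "direction": direction}, index=genes)

fold, p = x_overrepresentation(de, annotation)
print(f"X overrepresentation: fold={fold:.2f}, p={p:.3f}")
bias = direction_bias_x_vs_autosome(de, annotation)
print(f"X vs autosome up/down table: {bias.table.tolist()}")
print(f"direction bias: odds ratio={bias.odds_ratio:.2f}, "
      f"p={bias.p_value:.2e}")

x_up = de.index[(de["direction"] == "up_in_mut") & (chrom == "X")]
external = list(x_up[: len(x_up) // 2]) + [g for g in genes[:40]
                                           if g not in set(x_up)]
k, jac, p_ov = gene_list_overlap(x_up, external, genes)
print(f"overlap with external list: {k} shared, Jaccard={jac:.2f}, "
      f"p={p_ov:.2e}")
# Fold ~1 with a large p says the X is not overrepresented among DE calls,
# while a large odds ratio with small p says X-linked DE genes are far
# more likely to be upregulated than autosomal ones.
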