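# Methods

## Ribosome association and the DRA screen

For animal *a* with paired input and IP samples, a transcript's ribosome
association is RA = IP TPM / input TPM. Ratios are only formed for
transcripts whose input TPM is strictly positive in **every** input
sample of the run, pooling both genotypes; the rule is unconditional
because a single zero denominator anywhere makes the gene's ratio set
incomparable across animals. An IP of zero over a positive input is a
genuine RA of 0 and is kept. The number of removed genes is reported in
the `RATable` and the run manifest.

The screen tests each gene's per-animal RA values, wild type vs mutant,
with Welch's unpaired two-tailed *t*-test:

    t = (m_mut − m_wt) / sqrt(s²_mut/n_mut + s²_wt/n_wt)

with Welch–Satterthwaite degrees of freedom and a two-tailed *p* from
Student's *t*. Calls use raw *p* < α (default 0.05) with no
multiple-testing correction, matching the screen this pipeline
implements; a Benjamini–Hochberg column is included for readers who want
it. Direction is by comparison of group means; the measure-zero case of
an exact mean tie at *p* < α is labeled `none` and excluded from
direction percentages. Degenerate inputs: both groups constant and equal
→ *t* = 0, *p* = 1; both constant and unequal → ±∞ sentinel and *p* = 0.

Ratios are tested **raw** by default. Whether to test raw or
log-transformed ratios is genuinely open for this kind of screen; raw
ratios are the default here because the ratio-then-row-wise-test
formulation acts on the ratios themselves, and a `log2` option is
provided for users who prefer variance stabilization.

### Small-sample size of the Welch screen

A practical caveat, measured rather than assumed: at n = 3 vs 4 the
Welch–Satterthwaite approximation is conservative. Under exact normality
the true two-sided size at nominal α = 0.05 is ≈ 0.040 (400,000-replicate
simulation), and under the simulator's log-normal multiplicative noise at
CV 0.3 the realized null call rate on raw ratios is ≈ 0.037. Users should
read "P < 0.05" at these group sizes as a slightly conservative screen,
not an exactly calibrated one. Testing log2 ratios moves the rate to
≈ 0.040 (log-normal noise becomes exactly normal on the log scale).

## DE decision rule

DE calls threshold a per-gene score at 0.95 and additionally require a
directional fold change different from one. The intended score is a
posterior probability of differential expression from an external
empirical-Bayes fit, supplied via `method="plugin"`; that model is not
reimplemented here. The bundled `welch_score` (1 − *p* from Welch on
log2(TPM+1)) is a stand-in so the rule can run self-contained — its
scores are not posteriors and should not be interpreted as such.
Fold change is log2((mean_mut + 1)/(mean_wt + 1)); the 1-TPM pseudocount
bounds the statistic under zeros and shrinks fold changes of
low-abundance genes, which is the standard trade-off. "Directional fold
change greater than one" is interpreted as any nonzero directional
change (fold ≠ 1) whose direction matches the call; no magnitude cutoff
is imposed, and the |log2fc| ≥ 1 flag is reported separately per gene so
two-fold-or-greater summaries can be formed over any call set.

## Enrichment statistics

All set statistics are exact. Overrepresentation of a chromosome among
DE genes uses the hypergeometric upper tail P(X ≥ k) with fold
enrichment (k/n)/(K/N); the universe defaults to the genes that survived
expression filtering in the run (conditioning on testability), not the
whole annotation. The X-vs-autosome direction bias builds the 2×2 table
(X, autosome) × (up, down) over directed DE calls and applies Fisher's
exact two-sided test — chosen because the counts involved are small and
no asymptotic approximation is warranted; Y-linked genes are excluded
from both strata (few genes, distinct regulation) with a logged warning.
Gene-list overlap reports the shared count, Jaccard index, and the
hypergeometric upper-tail *p* of at least that overlap.

## Cell-type profiles

For a reference of nonnegative expression per gene × cell type, a gene's
profile is 100·x/Σx (rows sum to 100 within 1e-9; all-zero rows are
dropped with a warning), and a list-level profile is the per-type mean.
Percentages are invariant to per-gene scaling of the reference, so any
abundance unit works as long as it is comparable across cell types
within a gene.

## Foci counting

Foreground is intensity ≥ threshold (inclusive, the ImageJ convention),
components are 8-connected by default (4 available), and components
smaller than `min_size` pixels are discarded — defaults threshold = 50,
min_size = 10, the published particle-analysis settings this module
reproduces. A particle is assigned to the cell containing the majority of
its pixels, ties to the lower label — a deterministic rule for the rare
straddling particle. Edge-touching particles are included by default with
an `exclude_edge` flag, since the upstream convention is not specified.
Count binning reports 0/1/2/3+ (the published bins start at 1; the 0 bin
is added because mutant-like cells may lack detected structures).
Replicate-level genotype comparisons use the pooled-variance Student's
*t*-test (not Welch), as is conventional for replicate-mean percent
comparisons; band-density normalisation is the per-sample ratio of
experimental to loading-control density.

## Synthetic-data generator

The generator emulates the study design downstream code expects: 3
wild-type and 4 mutant animals, each contributing one input and one IP
sample. Per gene:

- baseline abundance ~ log-normal(μ = 3, σ = 1.5 on the natural-log
  scale; median ≈ 20 TPM) — heavy-tailed like real RNA-seq abundance;
- a gene-specific baseline RA ~ 2^N(0, 0.25), identical across
  genotypes;
- planted effects on the log2 scale: DE genes shift input abundance in
  the mutant (direction down with probability 0.61 by default), DRA
  genes shift the IP/input ratio (direction up with probability 0.69),
  and "signature" genes jointly get a moderate abundance decrease (half
  the DE magnitude) plus a full-scale RA increase — the pattern of
  transcripts translated more while slightly depleted. Effect-magnitude
  distributions are configurable; no empirical distribution is asserted.
- multiplicative log-normal measurement noise with coefficient of
  variation `noise_cv` (unit mean), applied independently to the input
  measurement and to the IP/input ratio, so that at `noise_cv = 0`
  realized log2 fold changes and RA shifts equal the drawn true effects
  exactly;
- zero-inflation applied to input values only (probability
  `zero_input_prob`), exercising the zero-input filter;
- chromosomes multinomial over mouse-like labels 1–19, X (4%), Y (0.5%).

TPM columns are **not** renormalized after effect injection: matrices
are treated as already-normalized abundances so planted effects stay
exactly recoverable. Consequences for interpretation: the simulator has
no count-level sampling noise, no gene–gene correlation, no
library-composition coupling between genes, and no fragment/length
biases — passing recovery tests demonstrates the statistical machinery
is correct under the stated model, not that real libraries satisfy it.

The foci simulator lays cells out as disjoint rectangles in a label mask
and plants square-ish blobs of exactly `focus_size_px` pixels at
`focus_intensity` on a uniform background, separated by at least two
pixels so 8-connected counting cannot merge them; Gaussian pixel noise is
optional. With zero noise, counting at the default parameters recovers
planted counts exactly, which is the module's oracle. It does not model
PSFs, intensity gradients or touching cells.

## Problem sizes and seeds

Recovery and calibration runs use 10,000 genes (≈1,000 planted effects,
binomial s.e. on a direction percentage ≈ 1.5 points) and 100 images ×
4 cells for foci exactness — sizes at which the measured proportions are
stable to well within the tolerances tested. Every stochastic component
takes a single integer seed through `numpy.random.default_rng`;
identical configs reproduce byte-identical outputs.
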