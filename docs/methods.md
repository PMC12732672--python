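# Methods

This note documents the models, parameter choices and numerical conventions
behind `rejuvseq`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Study design and contrasts

The pipeline assumes a four-arm heterochronic-parabiosis design on the
SAMP8 (aging-accelerated) / SAMR1 (young control) mouse pair: Iso-R1 and
Iso-P8 isochronic controls, Het-R1/Het-P8 heterochronic partners. All
statistics derive from two contrasts sharing the aged arm: SEA = Iso-P8 vs
Iso-R1 (what aging changed) and REJ = Het-P8 vs Iso-P8 (what the
intervention changed). Positive avg_log2FC always means higher in the first
(numerator) group, so "SEA up" is "elevated in aged". Cells are pooled
within (organ, cell type, group) across animals; `sample_id` is carried
through for future stratification but not used as a model term.

## Quality control and normalization

Cells are kept when detected features and total counts fall inside
[500, 8000] and [500, 20000]; the bounds are read as strict
"fewer than / more than" rules, so boundary values survive. Mitochondrial
genes — identifier prefix `mt-`, matched case-insensitively, the mouse
convention — are removed *after* cell filtering, so feature counts include
them; the order is a documented choice, since nothing in the underlying
protocol fixes it. Manual curation is supported as an explicit barcode
exclusion list rather than an unstated heuristic. Normalization is
per-cell total scaling to 10⁴ followed by log1p (the default of the
standard single-cell toolkits; the scale is configurable and a zero-count
cell maps to a zero row, not NaN).

## Differential expression

The detection gate keeps genes seen in ≥ `min_pct` (0.1) of cells in at
least one group *and* in ≥ `min_cells_feature` (5) cells across both groups
combined; the combined reading follows the cited toolkit's semantics.
The test is the two-sided Mann–Whitney/Wilcoxon rank-sum test: exact
enumeration when both groups have ≤ 25 observations and the pooled sample
is tie-free, otherwise the tie-corrected normal approximation with
continuity correction; a gene whose pooled values are all identical gets
p = 1 by convention. Effect size is the Seurat avg_log2FC dialect,
log2(mean expm1(x) + 1) − log2(mean expm1(y) + 1) on log-normalized values;
a pure difference-of-mean-logs alternative is available behind
`dialect="mean_log"`. Benjamini–Hochberg adjustment is applied per contrast
per cell type over exactly the tested genes (the adjustment universe is not
fixed by the source protocol; per-scope adjustment is the toolkit default).
DEG ⇔ |avg_log2FC| > 0.25 (strict) and p_adj < 0.05. Null calibration on
unplanted NB simulations (100 + 100 cells, 1000 genes, 20 seeds) gives a
mean fraction p < 0.05 of ≈ 0.049.

## Reversed and rescued genes

For each SEA DEG, the REJ table is consulted: *reversed* ⇔ opposite-sign
REJ estimate with |avg_log2FC| > 0.1; *rescued* ⇔ opposite-sign REJ DEG
(|avg_log2FC| > 0.25 and p_adj < 0.05). The default reversed rule gates on
effect size only, which is the literal published definition; a
`require_rej_significance` flag adds the p_adj < 0.05 condition to probe
the stricter reading. Rescued is always a subset of reversed under either
flag. SEA DEGs absent from the REJ tested set are not_reversed. Reversal
ratios report exact fractions plus round-half-up integer display
percentages; a direction with zero DEGs reports an undefined marker, not
0 %. The nine published organ-level values (48/24 % brain, 65/25 % liver,
64/76 % heart; totals 1939/3488/1236) reproduce exactly from their count
pairs under this rounding.

### Known bias of the reversal estimate

On synthetic data with a planted reversal fraction of 0.6, the estimated
Rev-Up runs ≈ 60–66 % and Rev-Down ≈ 67–74 % — a systematic overcount with
two causes, both intrinsic to the published rule rather than artifacts of
this implementation:

1. **Shared-control winner's curse.** Iso-P8 appears in both contrasts with
   opposite sign. A downward noise fluctuation of the Iso-P8 mean both
   promotes a gene into the SEA-down DEG list and pushes its REJ estimate
   positive, i.e. toward apparent reversal (and symmetrically for up).
   Measured on truly unreverted genes, this contributes ≈ +0.04 mean REJ
   log2FC for SEA-down genes.
2. **Compositional shift.** Rejuvenation changes aged-cell totals, so
   total-count normalization shifts every null gene's REJ estimate slightly
   (≈ +0.02 here).

At 300 cells per arm the resulting false-reversal rate on unreverted genes
is ≈ 18 % (up) / 37 % (down). Requiring REJ significance removes the false
calls but costs enough power on partially-reverted genes that the estimate
then undershoots (≈ 43–53 %). Users comparing reversal percentages between
conditions should compare like with like (same rule, same cell numbers) and
treat the absolute level as biased upward.

## Transcriptional-noise CV

Per cell type, highly variable genes are ranked by standardized variance:
per-gene variance divided by a mean–variance trend fitted as a quadratic
polynomial in log10 space (a loess-free stand-in for the vst trend; ties
break by gene identifier, constant genes are never selected). The top 1500
are used — the same count as the standard integration step, since no
separate count is fixed for this analysis. For groups (a, b),
d_g = |mean_a − mean_b| of log-normalized expression per HVG, and
CV = sd(d)·(1/mean(d)) with the n−1 sample standard deviation; the worked
value CV((1,2,3)) = 0.5. Δ CV = CV(young vs aged) − CV(young vs intervened),
both on the same HVG set. "Differences in expression across cells in the
two groups" is deliberately realized as the difference of group means;
cell-pair constructions would measure within-group dispersion instead and
are not implemented.

Note that Δ CV has no guaranteed sign: the CV is scale-free, so it measures
the *relative* dispersion of the difference vector, not its size. When the
difference vector is a sparse mixture (a noise floor plus a minority of
genuinely changed genes, which is what the generator produces and what deep
per-group cell numbers give), removing part of the signal makes the
remaining vector *more* relatively dispersed, and Δ CV comes out near zero
or negative (measured −0.07 to +0.03 under the default generator). A
positive Δ CV requires the noise floor to dominate — few cells per group or
strong inter-animal variability. Δ CV is therefore reported as a descriptive
component alongside DEG counts and reversal ratios, and no composite
"rejuvenation impact" index is formed from the three.

## Similarity, modules, identity scores

Group similarity is the Pearson correlation of per-group mean expression
vectors over a gene set (by default the SEA ∪ REJ DEG union); zero-variance
vectors yield marked-undefined entries, and a row-scaled copy is available
for display. DEG modules assign each (gene, direction) to the subset of
subtypes calling it a SEA DEG in that direction; module ids enumerate
up-modules first and subsets in binary order (bit i = subtype i in input
order), giving a stable 1..14 numbering for three subtypes. The identity
score bins genes into 24 equal-frequency bins by dataset-wide mean
expression, draws 100 control genes per set gene with replacement from the
matching bin (seeded generator), and scores each cell as mean set
expression minus mean control expression — the standard module-score
construction, which is invariant to adding a constant to all genes of a
cell.

## Synthetic data generator

Counts are negative binomial with variance μ + μ²/θ. Per cell type,
baseline gene means are lognormal(0, 1) counts/cell (median 1; on the
2000-gene default panel this gives ≈ 3 k counts and ≈ 1 k detected features
per cell, snRNA-seq-like depth on a panel-sized gene space); θ = 2
(moderate overdispersion typical of UMI data); per-cell library-size
factors are lognormal(0, 0.35). Aged cells multiply 200 up- and 200
down-planted gene means by 2^±lfc with lfc ~ U(0.5, 1.5); effects are
planted only on genes with baseline mean ≥ 0.5 counts/cell so the truth is
recoverable in principle. In Het-P8, an exactly-drawn fraction
(`reversal_fraction`, default 0.6, per direction) of planted effects is
attenuated toward the young mean by `reversal_completeness` (default 0.6 —
real reversals are partial: the published reversal gate of 0.1 log2 units
against a DEG gate of 0.25 implies typical reversal magnitudes around half
the aged effect), so the true REJ log2FC of a reverted gene is analytically
−lfc·completeness. Het-R1 is an independent draw from the young model.
Each (cell type, group) has its own RNG stream spawned from the master
seed, so adding an arm never perturbs another, and identical configurations
are bit-identical.

What the generator does **not** model: doublets, ambient RNA, batch
effects, inter-animal (sample-level) biological variability, zero inflation
beyond NB, and spatial zonation beyond distinct cell-type labels. Passing
recovery tests therefore demonstrate the pipeline's correctness and the
estimators' sampling behaviour, not robustness to those real-data
nuisances; in particular, real inter-animal variability would widen the
noise floor of both the DE test and the CV statistic.

## Problem sizes and determinism

Default desk-scale conditions: 2000 genes, 300 cells per arm per cell type,
400 planted effects. The test suite runs the full pipeline at these sizes
(seconds per run) plus 20-seed null and noise sweeps; everything is seeded,
and two runs of the same configuration write byte-identical tables (fixed
row orders: DEG tables by (p_adj, gene), deterministic tie-breaks
everywhere, `%.10g` float formatting).
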