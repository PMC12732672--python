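# rejuvseq

Quantifying transcriptomic rejuvenation in heterochronic-parabiosis
single-nucleus RNA-seq.

## The problem

Heterochronic parabiosis — surgically joining the circulation of a young and
an aged animal — partially restores aged tissues. Studies built on the
SAMP8/SAMR1 accelerated-aging mouse model profile four arms with snRNA-seq:

| label  | animal | pairing |
|--------|--------|---------|
| Iso-R1 | young control (SAMR1) | isochronic |
| Iso-P8 | aged (SAMP8)          | isochronic |
| Het-R1 | young partner         | heterochronic |
| Het-P8 | aged, intervened      | heterochronic |

Two contrasts carry the biology: **SEA** (senescence acceleration,
Iso-P8 vs Iso-R1) captures what aging changed, and **REJ** (rejuvenation,
Het-P8 vs Iso-P8) captures what the intervention changed back. `rejuvseq`
implements the downstream statistics of this design as a tested, reusable
pipeline, exercised end-to-end on a bundled synthetic count generator with
known planted truth — no data download required.

## The statistics

Per cell type (or per organ, pooled), on log-normalized counts
(per-cell total scaled to 10⁴, then log1p):

* **Differential expression.** Genes detected in ≥ 10 % of either group and
  in ≥ 5 cells combined are tested with a two-sided Wilcoxon rank-sum test
  (exact enumeration for tie-free groups ≤ 25, tie- and continuity-corrected
  normal approximation otherwise). Effect size is the Seurat-dialect
  avg_log2FC = log2(mean expm1 + 1) difference; BH adjustment is applied per
  contrast over the tested genes. DEG ⇔ |avg_log2FC| > 0.25 and
  p_adj < 0.05.
* **Reversed / rescued genes.** A SEA DEG is *reversed* when its REJ
  estimate has the opposite sign with |avg_log2FC| > 0.1, and *rescued* when
  it is an opposite-direction REJ DEG (|avg_log2FC| > 0.25, p_adj < 0.05);
  rescued ⊆ reversed. Reversal ratios (Rev-Up %, Rev-Down %) summarize each
  scope, with exact fractions kept and round-half-up integer display.
* **Transcriptional-noise CV.** Over one highly-variable-gene set per cell
  type (vst-style standardized-variance ranking, n = 1500): per-gene
  absolute group-mean differences d_g, CV = sd(d) / mean(d), and
  Δ CV = CV(Iso-R1 vs Iso-P8) − CV(Iso-R1 vs Het-P8).
* **Group similarity.** Pearson correlation of per-group mean expression
  over the DEG union.
* **DEG modules.** Each (gene, direction) maps to the subset of subtypes
  calling it a SEA DEG — at most 2·(2³−1) = 14 modules for three subtypes.
* **Identity score.** Per-cell gene-set score: mean set expression minus the
  mean of expression-matched control genes (24 equal-frequency expression
  bins, 100 seeded control draws per set gene).

The synthetic generator plants aging effects (NB counts, lognormal baseline
means and library sizes, uniform |log2FC| ∈ [0.5, 1.5]) and reverts a known
fraction (default 0.6) of them in Het-P8, recording every planted effect in
a truth table so recovery is measurable.

## Worked example

Run the full pipeline on a fresh simulation (2000 genes, 300 cells per arm,
200 planted effects per direction, reversal fraction 0.6):

```console
$ rejuvseq report --out-dir demo_out --seed 3
    scope  n_sea_degs  rev_up_pct  rev_down_pct
liver/Hep         406          63            69
```

406 aging DEGs were found in the simulated hepatocytes; 63 % of the
upregulated and 69 % of the downregulated ones were classified reversed
after intervention. With a planted reversal fraction of 60 % the estimates
run a few points high — estimation noise around the ±0.1 log2FC gate
classifies some unreverted genes as reversed (see `docs/methods.md`).
`demo_out/` also contains the per-gene DEG tables, the reversal report with
exact fractions and rescued counts, the noise table
(`delta_cv = -0.035` for this seed), the group-similarity matrix, the
planted-truth table and a JSON manifest of every parameter.

The published organ-level arithmetic self-check:

```console
$ rejuvseq verify
             check  expected  computed   ok
  brain_rev_up_pct        48        48 True
brain_rev_down_pct        24        24 True
  liver_rev_up_pct        65        65 True
...
```

Other subcommands (`simulate`, `qc`, `de`, `reverse`, `noise`, `score`,
`run`) expose each stage standalone; `rejuvseq reverse` accepts externally
produced DEG tables. The same functionality is available as a library:

```python
from rejuvseq import SimConfig, simulate, normalize, qc_filter
from rejuvseq import ContrastSpec, find_degs, classify_reversal, reversal_ratio

adata, truth = simulate(SimConfig(seed=3))
norm = normalize(qc_filter(adata)[0])
sea = find_degs(norm, ContrastSpec.sea(cell_type="Hep"))
rej = find_degs(norm, ContrastSpec.rej(cell_type="Hep"))
report = reversal_ratio(classify_reversal(sea, rej), scope="Hep")
print(report.pct_up_reversed, report.pct_down_reversed)
```

## Data formats

Counts: Matrix-Market coordinate file (genes × cells) with one-per-line
`features`/`barcodes` sidecars. Cell metadata: TSV with columns
`barcode`, `sample_id`, `group`, `organ`, `cell_type`, groups drawn from
{Iso-R1, Iso-P8, Het-R1, Het-P8}. The simulator's `write_bundle` emits the
same layout plus `truth.tsv` (`cell_type`, `gene`, `planted`, `direction`,
`true_lfc`, `reversed`). QC follows snRNA-seq convention: cells kept with
500 ≤ features ≤ 8000 and 500 ≤ counts ≤ 20000 (bounds inclusive), then
mitochondrial genes (`mt-` prefix, case-insensitive) removed; an optional
barcode exclusion list models manual curation.
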