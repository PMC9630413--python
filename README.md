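# amplidiff

Copy-number-stratified differential expression and gene-set enrichment for
oncogene-amplified tumor cohorts.

Amplification of oncogenes such as *MYC* is associated with suppression of
interferon and inflammatory transcriptional programs in breast cancer — a
signal with direct consequences for immune infiltration and checkpoint-
inhibitor response. Quantifying it from cohort data takes a chain of
statistics: robust cross-cancer normalization, classification of samples by
copy-number status, per-gene differential scoring, and gene-set level
inference. `amplidiff` implements that chain as a tested, deterministic
Python library for computational biologists working with expression
matrices, copy-number tables, count data, ChIP-seq peaks and immune
deconvolution output.

## What it computes

* **Robust normalization** — genes with Hodges-Lehmann average expression
  below 20 are removed; each gene is standardized within each cancer type
  as (expression − robust average) / robust SD, using the Hodges-Lehmann
  location estimate (median of Walsh averages (xᵢ+xⱼ)/2) and a
  difference-based robust scale estimator (MAD available as an alternative).
* **Stratification** — samples are *amplified* when the oncogene's log2
  segment-mean copy-number ratio exceeds 0.3, *neutral* in [−0.3, 0.3],
  *excluded* below (deep loss; dropped from comparisons).
* **Differential metric** — per gene, Welch's unequal-variance t between
  amplified and neutral samples; the gene score is
  `metric = −log10(p) · sign(t)` (underflow-safe, capped at 300). A Pearson
  correlation ranking against a target gene is available for
  expression-only cohorts.
* **Enrichment, two ways** — a competitive Welch set test (in-set vs
  out-of-set metrics, size filter 10–500, BH FDR) and preranked GSEA
  (weighted Kolmogorov–Smirnov running sum, gene-permutation null,
  ES/NES/p/FDR, size filter 15–3000).
* **DEG calling** — median-of-ratios size factors, Welch on log2 normalized
  counts, BH; DEG ⇔ padj < 0.05 and linear |fold change| > 1.5; directional
  unions across experiments.
* **ChIP integration** — replicate peak merging and ≥k-sample recurrence
  filtering by interval overlap, nearest-gene (TSS) target assignment with
  strand-aware promoter windows, factor co-occupancy, intersection with DEG
  unions, and one-sided Fisher's-exact over-representation (FDR < 0.1).
* **Immune fractions** — per-cell-type Welch test on deconvolved fraction
  matrices with the same signed log-p metric.
* **Synthetic cohorts** — a first-class generator that produces every input
  with planted truth (amplified subpopulation, suppressed IFN set,
  low-expression decoys, promoter peaks with non-recurring background,
  Dirichlet fractions), fully deterministic under a seed.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Generate a cohort with planted effects, run the core chain, and test
enrichment both ways (`examples/03_gene_set_enrichment.py`):

```python
from amplidiff import (SimulationDesign, generate_cohort, filter_low_expression,
                       robust_standardize, stratify_cohort, differential_profile,
                       enrich_all, preranked_gsea)

design = SimulationDesign(n_genes=2000, n_samples=80, seed=7)
cohort = generate_cohort(design)
standardized = robust_standardize(filter_low_expression(cohort.expression, 20.0))
strat = stratify_cohort(cohort.copy_number, design.oncogene)
profile = differential_profile(standardized, strat.amplified, strat.neutral)
set_table, _ = enrich_all(profile, cohort.gene_sets, min_size=10, max_size=500)
gsea_table = preranked_gsea(profile, cohort.gene_sets, n_perm=2000,
                            min_size=15, max_size=3000, seed=design.seed)
```

Output:

```
competitive Welch set test, top rows:
         set_name  n_in  direction  neglog10p           fdr
0     MYC_TARGETS    50          1  22.070498  4.250811e-21
1   IFN_SIGNALING    50         -1  19.188223  1.620753e-18
2  RANDOM_SET_007    25         -1   1.594913  3.474513e-01
3  RANDOM_SET_002    50         -1   1.538859  3.474513e-01

preranked GSEA, top rows:
         set_name  n_in        es       nes         p       fdr
0     MYC_TARGETS    50  0.963376  2.818263  0.000860  0.029797
1   IFN_SIGNALING    50 -0.935753 -2.953277  0.001192  0.029797
2  RANDOM_SET_002    50 -0.415164 -1.310276  0.092968  1.000000
3  RANDOM_SET_007    25 -0.480647 -1.302165  0.151047  1.000000
```

Both procedures put the two planted sets on top with the planted
directions: the oncogene-target set is up-regulated in amplified samples
(direction +1, positive NES) and the interferon set is suppressed
(direction −1, negative NES), at FDR far below 0.05, while the 48 random
decoy sets stay non-significant. The other scripts in `examples/` walk
through simulation, stratification and ranking, ChIP target recovery, and
immune-fraction testing, each printing and interpreting its numbers.

A thin CLI mirrors the stages (`amplidiff simulate | normalize | stratify |
diff | set-test | gsea | deg | chip-integrate | fractions | run`); given
identical inputs, config and seed, `run` produces byte-identical outputs.

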