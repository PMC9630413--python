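# Methods

`amplidiff` implements the downstream statistics of a cohort analysis that
asks how amplification of an oncogene (the motivating case is *MYC* in
breast cancer) reshapes transcriptional programs — in particular whether
interferon/inflammatory gene sets are suppressed in amplified tumors. This
note records the models, the defaults and why, the numerical choices, and
what the synthetic data does and does not establish.

## Robust normalization

Pan-cancer expression cohorts mix cancer types with different location and
scale, and contain outliers that make moment-based standardization
unreliable. Two robust estimators drive preprocessing:

* **Location — Hodges-Lehmann.** The median of all Walsh averages
  (x_i + x_j)/2 over pairs i ≤ j (i = j included). Computed by direct
  O(n²) enumeration, which is exact and cheap at cohort scale (n ≤ a few
  hundred samples per stratum); the row-wise variant is chunked to bound
  temporary memory.

* **Scale — difference-based estimator.** The order-2 difference estimator
  of Hall, Kay & Titterington with the optimal weight sequence
  (d₀, d₁, d₂) = ((1+√5)/4, −1/2, −(√5−1)/4):

      σ̂² = (1/(n−2)) Σᵢ (d₀ xᵢ + d₁ xᵢ₊₁ + d₂ xᵢ₊₂)²,

  applied to the values in their **observed sample order**. Because
  Σd = 0 and Σd² = 1, σ̂² is unbiased for the variance of exchangeable data
  and immune to any smooth trend across the sample ordering. Applying the
  same formula to *sorted* values is not an option: order statistics are
  locally nearly deterministic, the squared differences shrink like O(1/n²),
  and the estimate collapses to zero as n grows — it cannot recover σ. The
  estimator is implemented in exact difference form
  (d₀(xᵢ−xᵢ₊₁) + d₂(xᵢ₊₂−xᵢ₊₁)) so constant input yields exactly 0.
  A normal-consistent MAD (×1.4826) is available via
  `scale_method="mad"` so sensitivity to the scale-estimator choice can be
  probed; both recover σ within 5% on 10⁴ Normal draws (tested).

Genes whose cohort-wide Hodges-Lehmann average falls strictly below the
filter threshold (default 20 expression units) are removed; a value exactly
at the threshold is retained. Standardization —
(expression − robust location)/robust scale — is done per gene within each
cancer-type stratum independently; strata need ≥ 3 samples, and a zero
robust scale (constant gene) is a hard error naming the gene. The procedure
is idempotent to ≈ 1e-9 because both estimators are exactly
translation/scale-equivariant.

The scale on which the filter threshold of 20 lives is taken to be the
expression scale of the input matrix as given; the package does not
log-transform.

## Copy-number stratification

Samples are classified by the oncogene's log2 segment-mean copy-number
ratio: **amplified** strictly above 0.3, **neutral** inside the closed band
[−0.3, 0.3], **excluded** below −0.3 (deep loss). Excluded samples are
dropped from all group comparisons, never folded into neutral. Input is a
per-sample-per-gene table of final log ratios; a helper maps segment tables
onto genes (segment covering the TSS wins, ties to the longer gene-body
overlap) for callers starting from segmentation output. Either group
smaller than 2 aborts, since the downstream Welch test is undefined.

## Per-gene differential metric

For each gene, Welch's unequal-variance t between amplified and neutral
samples, with Welch–Satterthwaite degrees of freedom and a two-sided p. The
gene score is the signed log p-value

    metric = −log10(p) · sign(t),

two-sided because direction is carried entirely by sign(t). The metric is
computed from the t-distribution's log survival function, so it degrades
gracefully when p underflows double precision; its magnitude is capped at
300 and capped genes are flagged (`capped` column). Genes constant and
equal in both groups would be 0/0; in a genome-wide scan they receive
metric 0 with a `degenerate` flag rather than aborting the run — one
degenerate gene must not kill a cohort analysis. The scalar `welch_t` on
such input raises instead. A single Welch implementation backs the gene
scan, the scalar test, the gene-set test and the immune-fraction test.

For correlation-driven rankings (e.g. ranking all genes by co-expression
with the oncogene in an expression-only cohort), `correlation_profile`
returns the Pearson r of every other gene against a target gene; the target
itself is excluded and a zero-variance target is an error.

## Competitive gene-set test

For a per-gene metric vector, each set is tested by Welch's t between the
metrics of measured in-set genes and the metrics of all other measured
genes (competitive null: "is this set shifted relative to the rest of the
genome"). Membership is intersected with the measured universe *before* the
size filter (default 10–500 measured members); filtered sets are reported
separately, never silently dropped. Scores are −log10(p) with direction
sign(t); BH FDR is computed across surviving sets and both raw and adjusted
values are emitted (the procedure is meaningful with or without the
correction; emitting both keeps either reading available).

## Preranked GSEA

Genes are sorted by metric descending (ties broken by gene id, stable).
The enrichment score is the extremum of the weighted Kolmogorov–Smirnov
running sum with weight |metric| and exponent 1: the sum gains
|metricᵢ|/Σ_set|metric| at members and loses 1/(N − n_in) elsewhere. The
implementation evaluates only the 2·n_in candidate extrema (immediately
after each hit for the maximum, immediately before for the minimum), which
is algebraically identical to walking all N positions; when the positive
and negative extrema tie exactly in magnitude the one attained earlier in
the ranking wins, matching a literal left-to-right walk. Exhaustive
brute-force enumeration on small universes and an independent external
implementation are both used as test oracles.

The null is gene-label permutation: random same-size gene subsets re-scored
against the same ranking. Because this null depends on the set only through
its size, the null ES distribution is drawn once per distinct set size
within a call — statistically identical to per-set draws and much cheaper.
NES divides ES by the mean |null ES| of matching sign; sets whose same-sign
null is empty get NaN NES with a `no_same_sign_null` flag and are excluded
from the BH adjustment. The permutation p is the finite-sample estimator

    p = (1 + #{same-sign null ES at least as extreme}) / (1 + #{same-sign null ES}),

which cannot be 0 and therefore composes with BH (raw fractions can be 0,
which BH rejects). Size filter default 15–3000 measured members;
`n_permutations` defaults to 1000 and the seed is mandatory configuration.

**Permutation resolution and BH.** The attainable p floor is
1/(1 + n_same-sign) ≈ 2/n_perm. For a set at BH rank r among m sets to
reach FDR < α its p must be ≤ α·r/m, so the permutation count must satisfy
n_perm ≳ 2m/(α·r). With m ≈ 50 sets and two true positives (r = 2) at
α = 0.05 this requires n_perm comfortably above 1000; the replicated
effect-recovery analyses therefore use n_perm = 2000. This is a resolution
requirement, not a power issue — with insufficient permutations a maximally
extreme set sits exactly at the floor and can never clear the threshold.

## DEG calling on counts

A deliberately simple stand-in for a full negative-binomial GLM pipeline:
median-of-ratios size factors (reference = per-gene geometric mean over
samples, restricted to genes nonzero everywhere; factor = median of
count/reference, the linear median, making the brute-force definition the
test oracle), then per-gene Welch on log2(normalized + 1), BH adjustment,
and the double threshold: DEG ⇔ padj < 0.05 and linear |fold change| > 1.5
(|log2FC| > log2 1.5 ≈ 0.585, applied to raw, unshrunken fold changes).
Fold change uses mean pseudo-count 0.5; both pseudo-counts are recorded in
the output attrs. No dispersion shrinkage, independent filtering or outlier
handling — downstream logic depends only on the DEG table schema, so output
from a full NB pipeline can be substituted via TSV. Size factors are
defined up to a common constant (the geometric-mean reference renormalizes
when a sample is rescaled); fold changes are invariant to that constant.
DEG unions across experiments are kept separate by direction; a gene up in
one experiment and down in another lands in both unions and in a conflict
set.

## ChIP peak integration

Intervals are BED-convention half-open, 0-based throughout. Peak clustering
is single-linkage by genomic overlap (≥ 1 bp by default; configurable):
replicate merging emits the union interval of clusters supported by both
replicates, and the recurrence filter generalizes this to ≥ k distinct
samples (default 2). Both operators are idempotent and order-independent.

Target assignment: a locus overlapping a gene's promoter window — strand-
aware TSS −2000/+500 bp by default, a common annotation-package default
since no single standard exists — gets that gene at distance 0, class
`promoter`; otherwise the gene with the minimal peak-edge-to-TSS gap on the
chromosome wins, ties to the lexicographically smaller gene id. TSS
distance (not gene-body distance) is used throughout. Co-occupancy between
two factors reports the intervals of one set overlapping the other, with
counts in both directions.

Over-representation of a gene list (e.g. down-regulated direct targets)
within a set collection uses the one-sided Fisher's exact test — the
hypergeometric upper tail of the observed overlap against the stated
universe — with BH FDR across sets and a significance flag at FDR < 0.1.
A two-sided variant is available behind a flag.

## Immune fractions

Per cell type, the same Welch test and signed log-p metric (amplified minus
neutral) on the raw proportion scale, with BH across cell types. A logit
transform is available but off by default. Compositional dependence between
cell types (rows sum to 1) is acknowledged and deliberately not corrected;
a strong shift in one abundant type necessarily leaks small opposite shifts
into others, which the differential table will show.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with planted truth: expression
with per-cancer-type location/scale shifts and Normal noise; an amplified
subpopulation carrying a +1.0 SD shift on a 50-gene target set and a
−0.8 SD shift on a 50-gene IFN set (shifts are `effect × noise_sd` in raw
units); ~5% low-expression decoy genes placed below the filter threshold;
copy-number ratios drawn from disjoint ranges (amplified U(0.4, 1.2),
neutral U(−0.25, 0.25), excluded U(−1.0, −0.35)) so stratification recovers
truth exactly; negative-binomial counts (dispersion 0.05, mean tied to the
expression baseline) with group fold change 2^effect on the planted sets;
replicate ChIP peak sets with one jittered promoter peak per target plus
non-recurring background (each replicate's background sits on a grid with a
replicate-specific phase offset, so cross-replicate background overlap is
impossible by construction — recurrence filtering removes it exactly); and
Dirichlet immune fractions with a multiplicative concentration effect in
the amplified group. Decoy gene sets are drawn from unperturbed,
well-expressed genes with sizes from the palette {25, 50, 100}; the small
palette keeps set-size-matched permutation nulls shared and the power
scenarios affordable without changing any statistic. Each artifact uses its
own RNG stream (seed + fixed offset), so regenerating one never perturbs
another; everything is deterministic under the design seed.

Deliberately absent: read-level data, batch effects, tumor purity, gene–
gene correlation, heavy-tailed noise, segmentation noise in copy number,
and deconvolution uncertainty in fractions. Passing tests therefore
demonstrate that the *statistics and plumbing* are correct and calibrated
under the assumed generative structure — not that the biological
conclusions transfer to any real cohort.

## Scenario sizes

The replicated analyses use 5000 genes × 80 samples (≈ 40 vs 40) with 100
seeded replicates for effect recovery, 200 random sets for set-test
calibration, and a 2000-gene, 20-sample, 4-replicate-ChIP bundle with
six-fold repression of a 100-gene target set for the end-to-end recovery
scenario — sizes at which every planted signal is comfortably detectable
and the whole suite runs in minutes on one CPU.

## Known limitations

* The competitive set test treats genes as independent; inter-gene
  correlation in real data inflates its type-I error (a known property of
  competitive tests), which the independence-based synthetic null does not
  exercise.
* The DEG stand-in will be anti-conservative at very low counts relative to
  an NB-GLM with dispersion shrinkage; it is intended for well-expressed
  genes and moderate group sizes.
* Nearest-gene target assignment ignores topological domains and enhancer
  skipping; it is exactly the "closest TSS" rule, no more.
* The immune-fraction test inherits all caveats of testing compositions
  marginally.
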