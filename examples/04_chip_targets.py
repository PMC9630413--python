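"""ChIP peak integration: from replicate peaks to repressed direct targets.

Replicate peak sets covering the promoters of a repressed 100-gene set (plus
50% background peaks per replicate) are recurrence-filtered (support >= 2),
assigned to their nearest gene by TSS distance, intersected with the
down-regulated DEG union from count data, and the resulting gene list is
tested for gene-set over-representation with Fisher's exact test.
"""

import math

from amplidiff import (
    SimulationDesign,
    assign_nearest_gene,
    deg_test,
    fisher_overrepresentation,
    generate_annotation,
    generate_cohort,
    generate_peaks,
    intersect_targets_degs,
    median_ratio_size_factors,
    recurrent_peaks,
    stratify_cohort,
    union_degs,
)

design = SimulationDesign(
    n_genes=2000,
    n_samples=20,
    excluded_fraction=0.0,
    ifn_set_size=100,
    ifn_set_effect=-math.log2(6.0),  # six-fold repression in amplified samples
    seed=9,
)
cohort = generate_cohort(design)
annotation = generate_annotation(design)
replicates = generate_peaks(cohort.truth.ifn_set, annotation, n_samples=4, fpr=0.5, seed=9)
print(f"peaks per replicate: {[len(r) for r in replicates]} "
      f"({len(cohort.truth.ifn_set)} promoter peaks + background)")

loci = recurrent_peaks(replicates, min_support=2)
assignments = assign_nearest_gene(loci, annotation)
targets = set(assignments["gene_id"])
print(f"recurrent loci: {len(loci)}; distinct target genes: {len(targets)}")

strat = stratify_cohort(cohort.copy_number, design.oncogene)
degs = deg_test(cohort.counts, median_ratio_size_factors(cohort.counts),
                strat.amplified, strat.neutral)
up, down, _ = union_degs([degs])
up_targets, down_targets = intersect_targets_degs(targets, up, down)
print(f"DEGs: {len(up)} up, {len(down)} down; "
      f"targets down-regulated: {len(down_targets)}")

over = fisher_overrepresentation(down_targets, set(degs.index), cohort.gene_sets, 0.1)
top = over.iloc[0]
print(f"top over-represented set: {top['set_name']} "
      f"(overlap {top['n_overlap']}/{top['n_set']}, fdr {top['fdr']:.3g})")

# Background peaks never recur across replicates, so the recurrence filter
# leaves exactly the planted promoter loci; the repressed set is recovered
# in full and dominates the over-representation table.
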