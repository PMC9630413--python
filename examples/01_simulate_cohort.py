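"""Generate a synthetic tumor cohort and inspect its structure.

The generator plants an amplified subpopulation (oncogene copy-number log2
ratio > 0.3) in which a designated target gene set is shifted up and a
designated interferon-response set is shifted down, plus low-expression
decoy genes that the robust filter should remove.
"""

from amplidiff import SimulationDesign, generate_cohort

design = SimulationDesign(n_genes=2000, n_samples=80, seed=7)
cohort = generate_cohort(design)

groups = cohort.truth.groups.value_counts()
print(f"expression matrix: {cohort.expression.values.shape[0]} genes x "
      f"{cohort.expression.values.shape[1]} samples")
print(f"sample groups: {groups.to_dict()}")
print(f"planted sets: {len(cohort.truth.target_set)} up-regulated targets, "
      f"{len(cohort.truth.ifn_set)} suppressed IFN genes")
print(f"low-expression decoys: {len(cohort.truth.low_expression_genes)}")
print(f"gene-set collection: {len(cohort.gene_sets)} sets "
      f"({cohort.gene_sets.total_members()} memberships)")

# The amplified/neutral/excluded counts reflect the design fractions (0.5 /
# 0.45 / 0.05 here); the planted sets are what downstream enrichment must
# recover from the expression and count matrices.
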