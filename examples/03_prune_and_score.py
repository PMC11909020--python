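"""LD pruning and clumping-and-thresholding scores.

Pruning slides a 200-SNP window in 50-SNP steps along each chromosome
and, inside every window, repeatedly removes one member of the
highest-r² pair above 0.25 (the one with the larger GWAS p-value) until
no pair violates the threshold.  Scores are then weighted dosage sums
over the surviving SNPs at seven nested p-value cutoffs.
"""

from prsdiff import PruneConfig, SimulationConfig, ThresholdSet, simulate_cohort
from prsdiff.prune import prune
from prsdiff.qc import filter_variants, harmonize_alleles, variant_stats
from prsdiff.score import build_prs_matrix

cohort = simulate_cohort(SimulationConfig(seed=7, n_target=200,
                                          n_blocks=10, snps_per_block=40))
stats = variant_stats(cohort["genotypes"], cohort["variants"])
stats["chrom"] = stats["chrom"].astype(str)
kept, _ = filter_variants(stats, cohort["sumstats"])
weights, _ = harmonize_alleles(cohort["sumstats"], kept)

g_kept = cohort["genotypes"].subset_variants(list(kept["variant_id"]))
keep_ids, log = prune(g_kept, kept, weights, PruneConfig())
print(f"pruning: {len(kept)} -> {len(keep_ids)} variants "
      f"({len(log)} removals)")
if len(log):
    print(f"largest removed-pair r² = {log['r2'].max():.3f}")
# Blocks are simulated with within-block correlation 0.8, so roughly
# half to two-thirds of each block collapses onto its tag SNPs.

g_pruned = g_kept.subset_variants(keep_ids)
w_pruned = weights[weights["variant_id"].isin(keep_ids)]
prs = build_prs_matrix(g_pruned, w_pruned, ThresholdSet())
snp_counts = {c: int(prs[c].iloc[0]) for c in prs.columns
              if c.startswith("n_")}
print("SNPs per cutoff:", snp_counts)
# The cutoffs are nested (p < 1e-3 ⊂ p < 0.01 ⊂ ... ⊆ p ≤ 1), so the
# SNP counts increase monotonically and the final column uses every
# pruned-in variant.
print(f"z_1 score: mean {prs['z_1'].mean():+.2e}, sd {prs['z_1'].std():.3f}")
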