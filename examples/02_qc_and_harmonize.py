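"""Variant QC and allele harmonization.

Filters mirror a standard imputed-GWAS cleaning pass: duplicates,
strand-ambiguous pairs, non-autosomal variants, indels, low INFO,
low call rate, Hardy-Weinberg failures, rare alleles and poorly
imputed sites.  Harmonization then aligns discovery effect sizes to
the target's alt allele, recognizing swapped and strand-flipped
records and discarding what cannot be resolved.
"""

from prsdiff import SimulationConfig, simulate_cohort
from prsdiff.qc import filter_variants, harmonize_alleles, variant_stats

cohort = simulate_cohort(SimulationConfig(seed=7, n_target=200,
                                          n_blocks=10, snps_per_block=40))
stats = variant_stats(cohort["genotypes"], cohort["variants"])
stats["chrom"] = stats["chrom"].astype(str)

kept, report = filter_variants(stats, cohort["sumstats"])
print(report.to_text())
# Exactly the 25 planted violators fall: 5 per class, each attributed
# to the first filter (in documented order) that catches it.

weights, counts = harmonize_alleles(cohort["sumstats"], kept)
print("\nharmonization:")
for k, v in counts.items():
    print(f"  {k}: {v}")
# The generator swaps allele order in ~30% of discovery rows and strand-
# flips ~15%; every safe (non-ambiguous) pair is still recovered, so the
# four 'matched_*' counts sum to the number of kept variants.
print(f"\naligned weights: {len(weights)} rows; "
      f"mean |logOR| = {weights['weight'].abs().mean():.4f}")
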