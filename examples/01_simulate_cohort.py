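"""Simulate a discovery-plus-target study and inspect what was planted.

The generator produces a target cohort genotyped on LD-blocked SNPs, a
noisy case-case discovery GWAS summary table, phenotypes (four cognitive
domains and 68 x 2 cortical outcomes) and covariates.  A handful of
variants deliberately violate each QC rule so downstream filters can be
checked exactly.
"""

from prsdiff import SimulationConfig, simulate_cohort

config = SimulationConfig(seed=7, n_target=200, n_blocks=10,
                          snps_per_block=40, prs_effect=0.21,
                          affected_regions=("WM",))
cohort = simulate_cohort(config)

g = cohort["genotypes"]
variants = cohort["variants"]
print(f"target cohort: {g.n_samples} samples x {g.n_variants} variants")

planted = variants[variants["planted_class"] != ""]
print("planted QC violators by class:")
print(planted["planted_class"].value_counts().to_string())
# Five per class: these 25 variants are the ones QC must remove.

ss = cohort["sumstats"]
print(f"\ndiscovery summary rows: {len(ss)}; "
      f"median p = {ss['p_value'].median():.3f}")
# Effects are mostly null (10% causal), so the p-value distribution is
# close to uniform and the median sits near 0.5.

ph = cohort["phenotypes"]
print(f"phenotype columns: {ph.shape[1] - 1} "
      "(4 cognitive domains + 34 regions x 2 hemispheres x 2 measures)")
print(f"WM mean {ph['WM'].mean():+.3f}, sd {ph['WM'].std():.3f}")
# Outcomes are built on a unit-variance budget, so each column has
# roughly zero mean and unit spread before any model is fitted.
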