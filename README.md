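# prsdiff

Clumping-and-thresholding polygenic risk scores (PRS) from a case–case
discovery GWAS, associated with cognition and cortical structure in a
small target cohort — with a fully seeded synthetic data generator, so
every stage can be validated against planted ground truth.

## The science

A case–case GWAS contrasts two diagnostic groups (here: two
neurodevelopmental-condition cohorts of 9,315 and 11,964 cases) and
yields per-SNP log odds ratios that discriminate one condition from the
other. A *differentiation PRS* built from those effects can then be
computed in an independent target cohort (n = 168, with cognition
assessed in 145 and neuroimaging in 126) and regressed on
neurocognitive measures — four cognitive domain scores — and on
FreeSurfer-style cortical measures: surface area and thickness for each
of 34 Desikan–Killiany regions in both hemispheres.

The package implements the full pipeline:

1. **Simulation** — LD-blocked dosage genotypes (Gaussian-copula AR(1)
   haplotypes), a noisy discovery summary table with planted allele
   swaps and strand flips, phenotypes with a planted standardized PRS
   effect, and exactly five planted violators of each QC rule.
2. **QC + harmonization** — duplicate, strand-ambiguous, non-autosomal
   and indel removal; INFO < 0.6, call rate < 60 %, Hardy–Weinberg
   exact p < 1e-5, MAF < 0.001 and imputation quality ≤ 0.9 filters;
   alignment of discovery effects to the target's alt allele across all
   four allele orientations.
3. **LD pruning** — sliding 200-SNP window, 50-SNP step, removing one
   member of every dosage-r² > 0.25 pair (the one with the larger GWAS
   p-value).
4. **Scoring** — weighted dosage sums at seven nested p-value cutoffs
   (p < 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5 and p ≤ 1), z-transformed.
5. **Association** — per outcome and cutoff, OLS of the standardized
   outcome on the z-scored PRS with age and sex as covariates (plus
   age², age × sex and intracranial volume for surface areas),
   reporting the standardized beta, its p-value and the adjusted-R²
   increment over the covariate-only model, Bonferroni-corrected for
   the 34 regions per measure family (0.05 / 34 ≈ 1.47 × 10⁻³).

## The core model

For sample *i* with harmonized per-SNP weights
*ŵⱼ* (discovery log odds ratios aligned to the target alt allele) and
mean-imputed dosages *gᵢⱼ*, the score at cutoff *T* is

```
PRS_i(T) = Σ_{j : p_j < T} ŵ_j · g_ij        (p_j ≤ T at T = 1)
```

over the LD-pruned SNP set. Each association is the OLS fit

```
z(y) = β · z(PRS(T)) + γᵀ·covariates + ε
```

on listwise-complete rows, so β is the standardized effect and
ΔadjR² = adjR²(full) − adjR²(covariates-only) is the variance uniquely
attributable to the score.

## Worked example

`examples/05_full_pipeline.py` runs the five-stage pipeline on the
built-in fixture configuration (seed 1, 168 samples, 100 LD blocks × 50
SNPs, a standardized effect of 0.21 planted on working memory and the
left medial orbitofrontal surface area):

```
{'name': 'simulate', 'samples': 168, 'variants_out': 5025}
{'name': 'qc', 'variants_in': 5025, 'variants_out': 5000}
{'name': 'prune', 'variants_in': 5000, 'variants_out': 2904}
{'name': 'score', 'samples': 168, 'thresholds': [0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0]}
{'name': 'associate', 'cognitive_tests': 28, 'cortical_tests': 952,
 'bonferroni_significant': 0, 'nominal_significant': 39}

WM at p ≤ 1: beta = +0.126, p = 0.129, n = 145
```

QC removes exactly the 25 planted violators; pruning collapses the LD
blocks from 5,000 to 2,904 SNPs; the estimated score recovers an
attenuated, same-signed working-memory beta (the discovery weights are
noisy, so attenuation relative to the planted 0.21 is expected — when
the regression is run against the noise-free true score instead, the
mean recovered beta over 500 replicates is 0.212; see
`scripts/acceptance.py`). The other examples cover each stage in
isolation: `01_simulate_cohort.py`, `02_qc_and_harmonize.py`,
`03_prune_and_score.py`, `04_association_scan.py`.

A thin CLI wraps the same API:

```sh
prsdiff simulate --seed 3 --out sim/
prsdiff run --config run.yaml        # or qc / prune / score / associate
```

## Layout

```
src/prsdiff/   library (simulate, qc, prune, score, associate, pipeline, cli, io, plotting)
tests/         pytest suite, oracles first; tests/test_acceptance.py holds the acceptance criteria
examples/      short narrative scripts, one per capability
scripts/       acceptance.py
docs/          methods.md — model, parameter rationale, numerical choices, limitations
```
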