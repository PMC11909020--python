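# Methods

## Study design being modeled

A discovery case–case GWAS (two diagnostic cohorts, defaults 9,315 and
11,964 cases) supplies per-SNP log odds ratios that differentiate the
two conditions. A differentiation polygenic risk score (PRS) built from
those weights is evaluated in a small independent target cohort
(default n = 168; cognition assessed in a 145-sample subset and
neuroimaging in a 126-sample subset) against four cognitive domain
scores (VC, PO, WM, PS) and against cortical surface area and thickness
for 34 Desikan–Killiany regions per hemisphere — 140 outcomes in all.

## Synthetic data generator

**Genotypes.** Variants come in LD blocks. A block of *m* SNPs is drawn
from a Gaussian copula with AR(1) correlation ρ^|i−j| (default
within-block ρ = 0.8); each latent Gaussian is thresholded at the
variant's allele frequency (MAF drawn uniformly from [0.05, 0.5]) to
yield a haplotype allele, and two independent haplotypes sum to a
dosage in {0, 1, 2}. Missingness is injected completely at random
(default rate 0.02). This reproduces the two properties downstream
stages actually exercise — blockwise LD with decay, and allele-frequency
spread — without coalescent realism: there is no recombination-rate
variation, no allele-frequency/LD coupling, no population structure or
relatedness.

**Planted QC violators.** Five variants per class (configurable) are
appended: strand-ambiguous (A/T or C/G), duplicated (sharing IDs and
positions pairwise among themselves, so removing all copies removes
exactly the planted set; a count of one is rejected at configuration
time), indels (A/AT), low-INFO (summary INFO drawn U(0.1, 0.55) against
U(0.65, 1.0) for the rest), and Hardy–Weinberg failures (homozygote
excess generated with inbreeding-style F = 0.7 at MAF 0.3). These make
the QC stage exactly checkable: the filter must remove precisely the
planted 5 per class and nothing else.

**Discovery summary statistics.** A fraction of variants (default 0.1)
is causal with true log odds ratios N(0, 0.1²). The reported estimate
adds noise with the standard case–case Wald standard error
SE² = 2/(n_A·2p(1−p)) + 2/(n_B·2p(1−p)), and the p-value is the
two-sided Wald test. To exercise harmonization, ~30 % of rows have
their allele order swapped and ~15 % are strand-flipped; both are
recoverable except for ambiguous pairs, which the generator never
assigns to non-planted variants.

**Phenotypes.** Outcomes are built on a unit-variance budget:
y = β·z(s) + Σ γ_k·z(c_k) + σ·ε with σ chosen so Var(y) = 1, where s is
the *true* polygenic score (noise-free weights, z-transformed) and β is
`prs_effect` applied only to the outcomes named in `affected_regions`.
β is therefore a standardized effect by construction, which is what the
association stage estimates. Cognitive outcomes take no age effect
(modeling age-adjusted test scores) but age remains a covariate
downstream; imaging outcomes get γ_age = −0.3 (age-related decline), all
outcomes γ_sex = 0.1, and surface areas additionally γ_icv = 0.3
(head-size scaling). `n_cognition` / `n_imaging` plant block
missingness in the respective outcome sets.

**Determinism.** Every stage draws from
`default_rng(SeedSequence((seed, salt)))` with a distinct salt per
stage, so changing one stage's inputs never perturbs another's stream,
and an entire run is a pure function of the configuration.

## Parameter defaults and rationale

| Parameter | Default | Why |
|---|---|---|
| INFO minimum | 0.6 | standard imputation-quality floor for summary rows |
| call-rate minimum | 0.6 | permissive floor suited to dosage data |
| HWE exact p minimum | 1e-5 | conventional genotyping-error screen |
| MAF minimum | 0.001 | drop near-monomorphic sites with unstable weights |
| imputation quality | > 0.9 (strict) | target-side dosage reliability |
| prune window / step | 200 / 50 SNPs | standard C+T window with 4× overlap |
| prune r² threshold | 0.25 | keeps at most weakly correlated predictors |
| P-value cutoffs | 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1 | nested C+T grid; strict `<` except inclusive at 1.0 so the final score uses every SNP |
| Bonferroni family | 34 regions | one family per measure (area, thickness), α = 0.05/34 ≈ 1.47e-3 |
| covariates | age, sex (+ age², age×sex, ICV for areas) | allometric and quadratic-age confounds matter for area, not for pre-adjusted cognition |

## Numerical choices

- **Hardy–Weinberg exact test** conditions on the observed allele totals
  and sums P(h) over attainable heterozygote counts with
  P(h) ≤ P(observed). Weights are exact integers
  (n! / (AA!·h!·aa!) · 2^h), so tie comparisons are exact and the test
  agrees with naive enumeration to < 1e-12 at any count configuration.
- **Pairwise r²** uses pairwise-complete observations; a pair with < 2
  complete rows or a constant vector is *degenerate* and treated as
  r² = 0 (never pruned on). The windowed matrix is computed vectorized
  with mask products.
- **Pruning order.** Within a window the highest-r² violating pair is
  processed first, removing its larger-GWAS-p member (ties: larger
  position, then lexicographic ID). This rule makes the kept set
  deterministic and threshold-monotone: the kept set at a higher r²
  threshold contains the kept set at any lower one (the lower-threshold
  removal sequence is an extension of the higher-threshold one).
- **Scoring** mean-imputes missing dosages per variant (keeping scores
  comparable across samples with different missingness) and z-scores
  with the n−1 SD; constant scores z-transform to zeros with a warning
  rather than dividing by zero.
- **Association** z-scores the outcome and the PRS *within the
  listwise-complete subset*, so β is a standardized effect on exactly
  the analyzed rows; ΔadjR² is the difference of adjusted R² between
  the full and covariate-only fits on the identical subset. OLS is
  delegated to statsmodels behind `fit_ols`, which first runs a pivoted
  QR rank check and raises an error naming the collinear columns. The
  suite verifies `fit_ols` against an independent normal-equations
  implementation.

## Familywise error across both hemispheres and measures

The Bonferroni correction is per measure family of 34 regions
(α = 0.05/34), while one full scan at a single cutoff runs
34 × 2 hemispheres × 2 measures = 136 tests. Under a global null with
independent outcomes the chance that a scan yields *zero*
Bonferroni-significant results is (1 − 0.05/34)^136 ≈ 0.819, i.e. about
one scan in five shows at least one significant region even when
nothing is real — the correction controls each 34-region family at
0.05, not the 136-test union. `scripts/acceptance.py` measures this
zero-hit fraction over 100 all-null scans, and the corresponding
acceptance test asserts a ≥ 0.95 zero-hit rate, which this design
cannot attain; that test is left failing deliberately, as the honest
statement of the scan's familywise behavior.

## Open design decisions

- The pipeline exposes both a library API and a `prsdiff` CLI; the CLI
  is a thin wrapper and every subcommand is reproducible from the API.
- Duplicate handling removes *all* copies of a duplicated ID/position
  rather than keeping the best copy — conservative, and exactly
  verifiable against the planted set.
- Filter attribution is first-match in a documented order (duplicate →
  ambiguous → non-autosomal → indel → low INFO → call rate → HWE → MAF
  → imputation quality); a variant failing several rules is counted
  once.
- The generator's "true score" uses noise-free weights; associations
  against the estimated C+T score are attenuated by discovery noise.
  Recovery of the planted β is therefore validated against the true
  score, while the end-to-end pipeline reports the realistic attenuated
  estimate.

## Limitations

- No population stratification, relatedness, or ancestry mismatch
  between discovery and target; no principal-component covariates.
- LD is blockwise AR(1); no inter-block LD, no MAF-dependent LD.
- Case–case effect sizes are drawn i.i.d. normal with no genomic
  architecture (no MAF–effect coupling, no functional enrichment).
- Phenotypes are linear-Gaussian with homoscedastic noise; cortical
  outcomes are mutually independent given the score, with no spatial
  correlation between neighboring regions.
- Clumping is LD *pruning* (p-value-informed removal), not
  index-SNP clumping with window-in-kb semantics; positions enter only
  through per-chromosome ordering and tie-breaking.
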