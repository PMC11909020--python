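"""Synthetic cohort generator.

Produces everything the downstream stages consume, with known ground truth:

* LD-structured target genotypes (block-wise Gaussian copula haplotypes),
* a case-case discovery GWAS summary table (Wald statistics per variant),
* phenotype and covariate tables with a configurable standardized
  polygenic effect planted on designated outcomes.

Deliberately QC-violating variants (strand-ambiguous, duplicated, indel,
low-INFO, Hardy-Weinberg-violating) are planted and tagged so filter
behaviour can be asserted exactly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .containers import GenotypeMatrix
from .errors import ValidationError
from .regions import (
    COGNITIVE_DOMAINS,
    all_outcomes,
    outcome_class,
)

# salts for per-stage random streams derived from the one config seed
_GENO_SALT, _TRUTH_SALT, _SUMSTATS_SALT, _PHENO_SALT = 11, 13, 17, 19

#: Non-complementary allele pairs (strand-resolvable SNPs).
_SAFE_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, salt)))


def _block_haplotypes(rng, n_hap: int, k: int, rho: float) -> np.ndarray:
    """Latent AR(1) Gaussian haplotypes: corr(z_i, z_j) = rho^|i-j|."""
    z = np.empty((n_hap, k))
    z[:, 0] = rng.standard_normal(n_hap)
    if k > 1:
        innov = rng.standard_normal((n_hap, k - 1)) * np.sqrt(1.0 - rho * rho)
        for j in range(1, k):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return z


def simulate_genotypes(config: SimulationConfig):
    """Draw the target-cohort dosage matrix and its variant table.

    Haplotypes within a block come from a Gaussian copula with AR(1)
    correlation ``within_block_corr`` thresholded at each variant's allele
    frequency; two haplotypes per sample are summed into a 0/1/2 dosage.
    Blocks are mutually independent.  Planted QC-violating variants are
    appended after the core variants and tagged in ``planted_class``.

    Returns
    -------
    (GenotypeMatrix, pandas.DataFrame)
        The dosage matrix (``nan`` marks missing calls) and the variant
        table with columns ``variant_id, chrom, pos, ref_allele,
        alt_allele, block_id, maf_true, imputation_quality, planted_class``.
    """
    rng = _rng(config, _GENO_SALT)
    n = config.n_target
    plants = config.qc_plant_counts
    if plants.duplicate == 1:
        raise ValidationError("qc_plant_counts.duplicate must be 0 or >= 2 "
                              "(a single variant cannot be its own duplicate)")

    lo, hi = config.maf_range
    dosage_cols: list[np.ndarray] = []
    rows: list[dict] = []
    pos_counter: dict[int, int] = {}

    def next_pos(chrom: int) -> int:
        pos_counter[chrom] = pos_counter.get(chrom, 0) + 5000
        return pos_counter[chrom]

    vid = 0
    for b in range(config.n_blocks):
        k = config.snps_per_block
        chrom = (b % 22) + 1
        mafs = rng.uniform(lo, hi, size=k)
        z = _block_haplotypes(rng, 2 * n, k, config.within_block_corr)
        # per-variant threshold so that P(alt) = maf
        thresh = stats.norm.ppf(mafs)
        hap = (z < thresh[None, :]).astype(float)
        dos = hap[0::2] + hap[1::2]
        for j in range(k):
            vid += 1
            ref, alt = _SAFE_ALLELE_PAIRS[rng.integers(len(_SAFE_ALLELE_PAIRS))]
            rows.append(dict(
                variant_id=f"rs{vid}", chrom=chrom, pos=next_pos(chrom),
                ref_allele=ref, alt_allele=alt, block_id=b,
                maf_true=float(mafs[j]), planted_class="",
            ))
            dosage_cols.append(dos[:, j])

    def binom_dosage(p: float) -> np.ndarray:
        return rng.binomial(1, p, size=n) + rng.binomial(1, p, size=n).astype(float)

    plant_chrom = 0

    def plant_row(klass: str, ref: str, alt: str, p: float,
                  variant_id: str | None = None,
                  pos: int | None = None, chrom: int | None = None) -> dict:
        nonlocal vid, plant_chrom
        vid += 1
        if chrom is None:
            plant_chrom = plant_chrom % 22 + 1
            chrom = plant_chrom
        if pos is None:
            pos = next_pos(chrom)
        return dict(
            variant_id=variant_id or f"rs{vid}", chrom=chrom, pos=pos,
            ref_allele=ref, alt_allele=alt, block_id=-1,
            maf_true=p, planted_class=klass,
        )

    for i in range(plants.ambiguous):
        ref, alt = _AMBIGUOUS_PAIRS[rng.integers(len(_AMBIGUOUS_PAIRS))]
        rows.append(plant_row("ambiguous", ref, alt, 0.3))
        dosage_cols.append(binom_dosage(0.3))

    # duplicates share an ID and position within the planted group only, so
    # conservative remove-all-copies removes exactly the planted variants
    dup_ids = [f"dup{i // 2}" for i in range(plants.duplicate)]
    if plants.duplicate % 2 == 1:
        dup_ids[-1] = dup_ids[-2]
    dup_anchor: dict[str, tuple[int, int]] = {}
    for dup_id in dup_ids:
        ref, alt = _SAFE_ALLELE_PAIRS[rng.integers(len(_SAFE_ALLELE_PAIRS))]
        if dup_id in dup_anchor:
            chrom, pos = dup_anchor[dup_id]
        else:
            plant_chrom = plant_chrom % 22 + 1
            chrom, pos = plant_chrom, next_pos(plant_chrom)
            dup_anchor[dup_id] = (chrom, pos)
        rows.append(plant_row("duplicate", ref, alt, 0.3,
                              variant_id=dup_id, pos=pos, chrom=chrom))
        dosage_cols.append(binom_dosage(0.3))

    for i in range(plants.indel):
        rows.append(plant_row("indel", "A", "AT", 0.3))
        dosage_cols.append(binom_dosage(0.3))

    for i in range(plants.low_info):
        ref, alt = _SAFE_ALLELE_PAIRS[rng.integers(len(_SAFE_ALLELE_PAIRS))]
        rows.append(plant_row("low_info", ref, alt, float(rng.uniform(lo, hi))))
        dosage_cols.append(binom_dosage(rows[-1]["maf_true"]))

    # Hardy-Weinberg violators: strong homozygote excess (inbreeding-style
    # mixture, F = 0.7) so the exact test flags them at modest sample sizes
    for i in range(plants.hwe_fail):
        ref, alt = _SAFE_ALLELE_PAIRS[rng.integers(len(_SAFE_ALLELE_PAIRS))]
        rows.append(plant_row("hwe_fail", ref, alt, 0.3))
        a1 = rng.binomial(1, 0.3, size=n)
        copy = rng.random(n) < 0.7
        a2 = np.where(copy, a1, rng.binomial(1, 0.3, size=n))
        dosage_cols.append((a1 + a2).astype(float))

    dosages = np.column_stack(dosage_cols)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    variants = pd.DataFrame(rows)
    variants["imputation_quality"] = rng.uniform(0.92, 1.0, size=len(variants))
    samples = [f"S{i + 1:04d}" for i in range(n)]
    genotypes = GenotypeMatrix(dosages, samples, list(variants["variant_id"]))
    return genotypes, variants


def simulate_truth(variants: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Assign true per-variant log odds ratios.

    ``round(causal_fraction * m)`` variants are causal with effects drawn
    ``Normal(0, effect_sd)``; all others have a true logOR of exactly zero.
    """
    rng = _rng(config, _TRUTH_SALT)
    m = len(variants)
    n_causal = int(round(config.causal_fraction * m))
    causal_idx = rng.choice(m, size=n_causal, replace=False)
    true_logor = np.zeros(m)
    true_logor[causal_idx] = rng.normal(0.0, config.effect_sd, size=n_causal)
    is_causal = np.zeros(m, dtype=bool)
    is_causal[causal_idx] = True
    return pd.DataFrame({
        "variant_id": variants["variant_id"].to_numpy(),
        "true_logOR": true_logor,
        "is_causal": is_causal,
        "block_id": variants["block_id"].to_numpy(),
    })


def wald_p(logor, se):
    """Two-sided Wald p-value for logOR / SE under a standard normal."""
    z = np.asarray(logor, dtype=float) / np.asarray(se, dtype=float)
    return 2.0 * stats.norm.sf(np.abs(z))


def simulate_discovery_sumstats(truth: pd.DataFrame, variants: pd.DataFrame,
                                config: SimulationConfig) -> pd.DataFrame:
    """Emulate the case-case discovery GWAS summary table.

    Each variant's estimated logOR is its true effect plus Gaussian noise
    with the two-cohort Wald standard error
    ``SE = sqrt(2/(nA*2p(1-p)) + 2/(nB*2p(1-p)))`` at allele frequency
    ``p``; the p-value is the two-sided normal tail of logOR/SE.  A random
    subset of rows is written with swapped effect/other alleles and/or on
    the opposite strand, exercising downstream harmonization.
    """
    if not np.array_equal(truth["variant_id"].to_numpy(),
                          variants["variant_id"].to_numpy()):
        raise ValidationError("truth and variants must be aligned on variant_id")
    rng = _rng(config, _SUMSTATS_SALT)
    p = variants["maf_true"].to_numpy(dtype=float)
    mono = (p <= 0.0) | (p >= 1.0)
    het = np.where(mono, np.nan, 2.0 * p * (1.0 - p))
    se = np.sqrt(2.0 / (config.n_cases_a * het) + 2.0 / (config.n_cases_b * het))
    logor = truth["true_logOR"].to_numpy() + rng.normal(0.0, 1.0, size=len(p)) * se
    pval = wald_p(logor, se)
    pval = np.clip(pval, np.nextafter(0.0, 1.0), 1.0)
    logor = np.where(mono, np.nan, logor)
    pval = np.where(mono, np.nan, pval)

    info = rng.uniform(0.65, 1.0, size=len(p))
    low = (variants["planted_class"] == "low_info").to_numpy()
    info[low] = rng.uniform(0.10, 0.55, size=int(low.sum()))

    effect = variants["alt_allele"].astype(str).to_numpy().copy()
    other = variants["ref_allele"].astype(str).to_numpy().copy()
    out_logor = logor.copy()
    # allele-order swap: effect allele reported as the target's ref
    swap = rng.random(len(p)) < 0.3
    effect[swap], other[swap] = other[swap].copy(), effect[swap].copy()
    out_logor[swap] = -out_logor[swap]
    # opposite-strand report (only meaningful for single-base alleles)
    flip = rng.random(len(p)) < 0.15

    def comp(a: str) -> str:
        return "".join(_COMPLEMENT.get(c, c) for c in a)

    effect = np.array([comp(a) if f else a for a, f in zip(effect, flip)])
    other = np.array([comp(a) if f else a for a, f in zip(other, flip)])

    return pd.DataFrame({
        "variant_id": variants["variant_id"].to_numpy(),
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": effect,
        "other_allele": other,
        "logOR": out_logor,
        "OR": np.exp(out_logor),
        "se": se,
        "p_value": pval,
        "info": info,
        "monomorphic": mono,
    })


def true_score(genotypes: GenotypeMatrix, truth: pd.DataFrame) -> np.ndarray:
    """Ground-truth polygenic score (mean-imputed dosages), z-transformed."""
    d = genotypes.dosages
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(np.isnan(d), col_mean[None, :], d)
    s = filled @ truth["true_logOR"].to_numpy()
    sd = s.std(ddof=1)
    if sd == 0:
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def _zcol(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd


def simulate_phenotypes(genotypes: GenotypeMatrix, truth: pd.DataFrame,
                        config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None):
    """Generate phenotype and covariate tables with planted effects.

    Outcomes named in ``affected_regions`` receive a standardized effect of
    ``prs_effect`` from the z-scored true polygenic score; every other
    outcome gets zero.  Covariate effects act on standardized covariates
    (imaging outcomes: age and sex; surface areas additionally head size)
    and residual noise is scaled so each outcome has unit variance in
    expectation.  Cognitive domains are generated age-adjusted: no age
    effect enters them, although age is still carried as a covariate for
    the downstream models.

    Passing an explicit ``rng`` redraws covariates and noise while keeping
    the genotypes fixed — the cheap way to run replicate cohorts.
    """
    if rng is None:
        rng = _rng(config, _PHENO_SALT)
    n = genotypes.n_samples
    s_z = true_score(genotypes, truth)

    age = rng.uniform(*config.age_range, size=n)
    sex = np.zeros(n, dtype=int)
    sex[rng.permutation(n)[: n // 2]] = 1
    icv = np.abs(rng.normal(config.icv_mean, config.icv_sd, size=n))
    z_age, z_sex, z_icv = _zcol(age), _zcol(sex.astype(float)), _zcol(icv)

    affected = set(config.affected_regions)
    data: dict[str, np.ndarray] = {}
    for outcome in all_outcomes():
        klass = outcome_class(outcome)
        beta = config.prs_effect if outcome in affected else 0.0
        g_age = -config.gamma_age if klass in ("thickness", "surface_area") else 0.0
        g_sex = config.gamma_sex
        g_icv = config.gamma_icv if klass == "surface_area" else 0.0
        explained = beta ** 2 + g_age ** 2 + g_sex ** 2 + g_icv ** 2
        if explained > 1.0 + 1e-12:
            raise ValidationError(
                f"effects for outcome {outcome!r} explain more than unit variance "
                f"({explained:.3f}); reduce prs_effect or covariate gammas"
            )
        sigma = np.sqrt(max(0.0, 1.0 - explained))
        data[outcome] = (beta * s_z + g_age * z_age + g_sex * z_sex
                         + g_icv * z_icv + sigma * rng.standard_normal(n))

    phenotypes = pd.DataFrame({"sample_id": genotypes.samples, **data})
    if config.n_cognition is not None and config.n_cognition < n:
        drop = rng.choice(n, size=n - config.n_cognition, replace=False)
        phenotypes.loc[drop, list(COGNITIVE_DOMAINS)] = np.nan
    if config.n_imaging is not None and config.n_imaging < n:
        drop = rng.choice(n, size=n - config.n_imaging, replace=False)
        imaging_cols = [c for c in phenotypes.columns
                        if c not in COGNITIVE_DOMAINS and c != "sample_id"]
        phenotypes.loc[drop, imaging_cols] = np.nan

    covariates = pd.DataFrame({
        "sample_id": genotypes.samples,
        "age": age,
        "sex": sex,
        "icv": icv,
    })
    return phenotypes, covariates


def simulate_cohort(config: SimulationConfig) -> dict:
    """Run the whole generator; returns all tables keyed by name."""
    genotypes, variants = simulate_genotypes(config)
    truth = simulate_truth(variants, config)
    sumstats = simulate_discovery_sumstats(truth, variants, config)
    phenotypes, covariates = simulate_phenotypes(genotypes, truth, config)
    return dict(genotypes=genotypes, variants=variants, truth=truth,
                sumstats=sumstats, phenotypes=phenotypes, covariates=covariates)
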