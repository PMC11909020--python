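"""Configuration dataclasses shared by all pipeline stages.

Every config validates itself eagerly (``__post_init__``) and raises
:class:`~prsdiff.errors.ValidationError` on out-of-range values, so stage
code can assume well-formed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .errors import ValidationError
from .regions import validate_outcome

#: The seven nested p-value cutoffs used to admit discovery variants into
#: the score.  All cutoffs are strict (p < c) except the final 1.0, which is
#: inclusive so that every scored variant enters the broadest set.
DEFAULT_THRESHOLDS: tuple[float, ...] = (1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


def _check_prob(name: str, value: float, open_low: bool = False) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    low_ok = value > 0 if open_low else value >= 0
    if not (low_ok and value <= 1):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class QCPlantCounts:
    """Counts of deliberately QC-violating variants planted by the simulator."""

    ambiguous: int = 5
    duplicate: int = 5
    indel: int = 5
    low_info: int = 5
    hwe_fail: int = 5

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"qc_plant_counts.{name} must be a non-negative int")

    @property
    def total(self) -> int:
        return self.ambiguous + self.duplicate + self.indel + self.low_info + self.hwe_fail


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic cohort generator.

    The discovery-cohort sizes default to the case-case GWAS this pipeline
    is designed around (9,315 vs 11,964 patients); the target cohort
    defaults to 168 samples, the size of the intended target study.
    """

    seed: int = 0
    n_target: int = 168
    n_cases_a: int = 9315
    n_cases_b: int = 11964
    n_blocks: int = 20
    snps_per_block: int = 50
    within_block_corr: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_fraction: float = 0.1
    effect_sd: float = 0.1
    prs_effect: float = 0.0
    affected_regions: tuple[str, ...] = ()
    missing_rate: float = 0.02
    qc_plant_counts: QCPlantCounts = field(default_factory=QCPlantCounts)
    # covariate effects on standardized covariates; residual noise absorbs
    # the rest so each outcome has unit variance in expectation
    gamma_age: float = 0.3        # imaging outcomes only (cognition is pre-adjusted)
    gamma_sex: float = 0.1
    gamma_icv: float = 0.3        # surface areas only
    age_range: tuple[float, float] = (18.0, 80.0)
    icv_mean: float = 1.5e6       # mm^3
    icv_sd: float = 1.5e5
    # planted phenotype missingness (None = fully observed)
    n_cognition: Optional[int] = None
    n_imaging: Optional[int] = None

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        for name in ("n_target", "n_cases_a", "n_cases_b"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 2:
                raise ValidationError(f"{name} must be an integer >= 2, got {v!r}")
        for name in ("n_blocks", "snps_per_block"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        if not (0 <= self.within_block_corr < 1):
            raise ValidationError("within_block_corr must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < low <= high <= 0.5")
        _check_prob("causal_fraction", self.causal_fraction)
        _check_prob("missing_rate", self.missing_rate)
        if self.missing_rate >= 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        for name in ("effect_sd", "icv_mean", "icv_sd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and non-negative")
        if not math.isfinite(self.prs_effect):
            raise ValidationError("prs_effect must be finite")
        if self.age_range[0] >= self.age_range[1]:
            raise ValidationError("age_range must be (low, high) with low < high")
        object.__setattr__(
            self, "affected_regions",
            tuple(validate_outcome(o) for o in self.affected_regions),
        )
        for n in (self.n_cognition, self.n_imaging):
            if n is not None and not (isinstance(n, int) and 1 <= n <= self.n_target):
                raise ValidationError("n_cognition/n_imaging must be in [1, n_target]")

    @property
    def n_core_variants(self) -> int:
        return self.n_blocks * self.snps_per_block

    @property
    def n_variants(self) -> int:
        return self.n_core_variants + self.qc_plant_counts.total


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered p-value cutoffs defining the nested SNP sets for scoring."""

    cutoffs: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self):
        object.__setattr__(self, "cutoffs", tuple(float(c) for c in self.cutoffs))
        if not self.cutoffs:
            raise ValidationError("ThresholdSet needs at least one cutoff")
        for c in self.cutoffs:
            if not (0 < c <= 1):
                raise ValidationError(f"cutoffs must lie in (0, 1], got {c!r}")
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValidationError("cutoffs must be strictly increasing")

    def labels(self) -> list[str]:
        return [f"{c:g}" for c in self.cutoffs]


@dataclass(frozen=True)
class PruneConfig:
    """Sliding-window pairwise-r² pruning parameters."""

    window_snps: int = 200
    step_snps: int = 50
    r2_threshold: float = 0.25
    order_by: str = "gwas_p"   # which member of a violating pair is removed

    def __post_init__(self):
        if not (isinstance(self.window_snps, int) and self.window_snps >= 2):
            raise ValidationError("window_snps must be an integer >= 2")
        if not (isinstance(self.step_snps, int) and 1 <= self.step_snps <= self.window_snps):
            raise ValidationError("step_snps must satisfy 1 <= step_snps <= window_snps")
        if not (0 < self.r2_threshold <= 1):
            raise ValidationError("r2_threshold must lie in (0, 1]")
        if self.order_by not in ("gwas_p", "position"):
            raise ValidationError("order_by must be 'gwas_p' or 'position'")


@dataclass(frozen=True)
class QCThresholds:
    """Variant-level filter thresholds.

    Defaults mirror the standard published filter set: discovery INFO >= 0.6,
    call rate >= 0.6, HWE exact p >= 1e-5, MAF >= 0.001, target imputation
    quality > 0.9, autosomes only, no indels, no strand-ambiguous pairs, no
    duplicated IDs or positions.
    """

    info_min: float = 0.6
    call_rate_min: float = 0.6
    hwe_p_min: float = 1e-5
    maf_min: float = 0.001
    imputation_quality_min: float = 0.9  # exclusive bound (quality must exceed it)
    autosomes_only: bool = True
    exclude_indels: bool = True
    exclude_ambiguous: bool = True
    exclude_duplicates: bool = True
    subject_call_rate_min: float = 0.6

    def __post_init__(self):
        for name in ("info_min", "call_rate_min", "maf_min",
                     "imputation_quality_min", "subject_call_rate_min"):
            _check_prob(name, getattr(self, name))
        if not (0 < self.hwe_p_min <= 1):
            raise ValidationError("hwe_p_min must lie in (0, 1]")


#: Covariate sets per outcome family.  Surface-area models additionally
#: adjust for quadratic age, the age-by-sex interaction, and head size.
COVARIATES_BY_CLASS = {
    "cognition": ("age", "sex"),
    "thickness": ("age", "sex"),
    "surface_area": ("age", "sex", "age2", "age_x_sex", "icv"),
}


@dataclass(frozen=True)
class RegressionSpec:
    """Covariate set and multiplicity control for one outcome family."""

    outcome_class: str = "cognition"
    n_regions_for_correction: int = 34
    alpha: float = 0.05

    def __post_init__(self):
        if self.outcome_class not in COVARIATES_BY_CLASS:
            raise ValidationError(
                f"outcome_class must be one of {sorted(COVARIATES_BY_CLASS)}"
            )
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (isinstance(self.n_regions_for_correction, int)
                and self.n_regions_for_correction >= 1):
            raise ValidationError("n_regions_for_correction must be a positive integer")

    @property
    def covariates(self) -> tuple[str, ...]:
        return COVARIATES_BY_CLASS[self.outcome_class]
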