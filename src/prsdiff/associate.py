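"""Covariate-adjusted association of the PRS with each outcome.

For each outcome the full model (covariates + PRS) and the covariate-only
model are fitted by OLS on the identical listwise-complete subset; the
variance uniquely attributable to the score is the difference of adjusted
R² values (ΔadjR²).  The outcome and the PRS are z-scored within the
analysis subset, so the reported beta is a standardized coefficient.
Cognitive and thickness models adjust for age and sex; surface-area
models additionally adjust for age², age×sex (age centered first) and
intracranial volume.  Multiple testing over the cortical grid uses a
Bonferroni threshold of alpha divided by the 34 regions, shared by both
hemispheres within a measure family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .config import RegressionSpec, ThresholdSet
from .errors import RankDeficientError, ValidationError
from .regions import (
    COGNITIVE_DOMAINS,
    cortical_outcomes,
    outcome_class,
    parse_cortical_outcome,
)


@dataclass(frozen=True)
class OLSFit:
    params: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    adj_r2: float
    n: int
    names: tuple[str, ...]


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    threshold: float
    beta: float
    se: float
    t: float
    p: float
    adj_r2_full: float
    adj_r2_cov: float
    delta_adj_r2: float
    n: int
    significant_bonferroni: bool
    significant_nominal: bool


def _check_rank(X: np.ndarray, names) -> None:
    """Name the collinear columns via pivoted QR before fitting."""
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"need n > number of design columns ({n} <= {k})")
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    bad = [names[piv[i]] for i in range(k) if diag[i] <= tol]
    if bad:
        raise RankDeficientError(bad)


def fit_ols(y, X, names=None) -> OLSFit:
    """Least-squares fit with per-coefficient two-sided t-tests.

    ``X`` must already contain the intercept column.  Raises
    :class:`RankDeficientError` naming collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or len(y) != X.shape[0]:
        raise ValidationError("y must be a vector aligned with the rows of X")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValidationError("fit_ols requires complete data; drop missing rows first")
    names = tuple(names) if names is not None else tuple(
        f"x{i}" for i in range(X.shape[1]))
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    return OLSFit(
        params=res.params, se=res.bse, t=res.tvalues, p=res.pvalues,
        r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
        n=int(res.nobs), names=names,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-test significance level alpha / m."""
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValidationError("m must be a positive integer")
    return alpha / m


def _zscore_subset(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant vector cannot be z-scored")
    return (x - x.mean()) / sd


def build_design(covariates: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    """Covariate design for one outcome family (no intercept column).

    Surface-area models use centered age for the quadratic and interaction
    terms to curb collinearity; the PRS coefficient is unaffected.
    """
    cols = {}
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)  # reference level: sex == 0
    for name in spec.covariates:
        if name == "age":
            cols["age"] = age
        elif name == "sex":
            cols["sex"] = sex
        elif name == "age2":
            ac = age - np.nanmean(age)
            cols["age2"] = ac * ac
        elif name == "age_x_sex":
            ac = age - np.nanmean(age)
            cols["age_x_sex"] = ac * sex
        elif name == "icv":
            cols["icv"] = covariates["icv"].to_numpy(dtype=float)
        else:  # pragma: no cover - spec validates covariate names
            raise ValidationError(f"unknown covariate {name!r}")
    return pd.DataFrame(cols, index=covariates.index)


def prs_association(outcome: pd.Series, prs_z: pd.Series,
                    covariates: pd.DataFrame, spec: RegressionSpec,
                    outcome_name: str = "outcome",
                    threshold: float = np.nan) -> AssociationResult:
    """Standardized PRS effect and ΔadjR² for one outcome.

    All inputs must share an index (sample alignment).  Rows missing any
    of outcome, PRS or covariates are dropped listwise; both models use
    the identical subset.
    """
    design = build_design(covariates, spec)
    df = pd.concat(
        {"y": outcome.astype(float), "prs": prs_z.astype(float)}, axis=1
    ).join(design)
    df = df.dropna()
    k_cov = design.shape[1]
    if len(df) < k_cov + 3:
        raise ValidationError(
            f"only {len(df)} complete rows for {outcome_name!r}; "
            f"need at least {k_cov + 3}"
        )
    y = _zscore_subset(df["y"].to_numpy())
    prs = _zscore_subset(df["prs"].to_numpy())
    cov = df[design.columns].to_numpy()
    ones = np.ones((len(df), 1))

    X_cov = np.hstack([ones, cov])
    X_full = np.hstack([X_cov, prs[:, None]])
    names_cov = ("const", *design.columns)
    fit_cov = fit_ols(y, X_cov, names_cov)
    fit_full = fit_ols(y, X_full, (*names_cov, "prs"))

    beta = float(fit_full.params[-1])
    p = float(fit_full.p[-1])
    bonf = bonferroni_threshold(spec.alpha, spec.n_regions_for_correction)
    return AssociationResult(
        outcome=outcome_name,
        threshold=float(threshold),
        beta=beta,
        se=float(fit_full.se[-1]),
        t=float(fit_full.t[-1]),
        p=p,
        adj_r2_full=fit_full.adj_r2,
        adj_r2_cov=fit_cov.adj_r2,
        delta_adj_r2=fit_full.adj_r2 - fit_cov.adj_r2,
        n=fit_full.n,
        significant_bonferroni=bool(p < bonf),
        significant_nominal=bool(p < spec.alpha),
    )


def _results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def run_cognitive_scan(phenotypes: pd.DataFrame, prs: pd.DataFrame,
                       covariates: pd.DataFrame,
                       thresholds: ThresholdSet | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Associate the PRS with the four cognitive domains at each cutoff."""
    thresholds = thresholds or ThresholdSet()
    spec = RegressionSpec(outcome_class="cognition", alpha=alpha,
                          n_regions_for_correction=34)
    ph = phenotypes.set_index("sample_id")
    pr = prs.set_index("sample_id")
    cv = covariates.set_index("sample_id")
    results = []
    for cutoff, label in zip(thresholds.cutoffs, thresholds.labels()):
        for domain in COGNITIVE_DOMAINS:
            results.append(prs_association(
                ph[domain], pr[f"z_{label}"], cv, spec,
                outcome_name=domain, threshold=cutoff))
    return _results_frame(results)


def run_cortical_scan(phenotypes: pd.DataFrame, prs: pd.DataFrame,
                      covariates: pd.DataFrame,
                      thresholds: ThresholdSet | None = None,
                      alpha: float = 0.05,
                      n_regions_for_correction: int = 34) -> pd.DataFrame:
    """Full 34-region x hemisphere x measure x threshold association scan.

    Returns a long-format table with one row per cell; ``region``,
    ``hemisphere`` and ``measure`` columns index the grid.  Use
    :func:`heatmap_table` / :func:`threshold_profile` for the wide views.
    """
    thresholds = thresholds or ThresholdSet()
    ph = phenotypes.set_index("sample_id")
    pr = prs.set_index("sample_id")
    cv = covariates.set_index("sample_id")
    results = []
    meta = []
    for measure in ("area", "thickness"):
        spec = RegressionSpec(
            outcome_class="surface_area" if measure == "area" else "thickness",
            alpha=alpha, n_regions_for_correction=n_regions_for_correction)
        for outcome in cortical_outcomes(measure):
            if outcome not in ph.columns:
                raise ValidationError(f"phenotype table lacks region column "
                                      f"{outcome!r}")
            region, hemi, _ = parse_cortical_outcome(outcome)
            for cutoff, label in zip(thresholds.cutoffs, thresholds.labels()):
                results.append(prs_association(
                    ph[outcome], pr[f"z_{label}"], cv, spec,
                    outcome_name=outcome, threshold=cutoff))
                meta.append((region, hemi, measure))
    out = _results_frame(results)
    out[["region", "hemisphere", "measure"]] = pd.DataFrame(meta, index=out.index)
    return out


def heatmap_table(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Wide beta table at one cutoff: rows = region, columns = hemi x measure."""
    sub = results[np.isclose(results["threshold"], threshold)]
    return sub.pivot_table(index="region", columns=["measure", "hemisphere"],
                           values="beta")


def threshold_profile(results: pd.DataFrame,
                      outcomes: list[str] | None = None) -> pd.DataFrame:
    """ΔadjR² per outcome across cutoffs (rows = outcome, cols = threshold)."""
    sub = results if outcomes is None else results[results["outcome"].isin(outcomes)]
    return sub.pivot_table(index="outcome", columns="threshold",
                           values="delta_adj_r2")
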