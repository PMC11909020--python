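"""Polygenic score construction over nested p-value thresholds.

A sample's raw score is the sum over scored variants of the aligned-allele
dosage (0, 1 or 2; fractional for imputed data) times the harmonized
logOR weight.  Scores are built for each p-value cutoff of a
:class:`~prsdiff.config.ThresholdSet` — the SNP sets are nested, so raw
scores decompose additively across threshold strata — and z-transformed
across samples for association analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import ThresholdSet
from .containers import GenotypeMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)


def select_snps(weights: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Weights admitted at one cutoff: p < cutoff, inclusive at 1.0."""
    if not (0 < cutoff <= 1):
        raise ValidationError(f"cutoff must lie in (0, 1], got {cutoff!r}")
    p = weights["p_value"]
    mask = p <= cutoff if cutoff == 1.0 else p < cutoff
    return weights[mask]


def compute_prs(genotypes: GenotypeMatrix, weights: pd.DataFrame,
                missing: str = "mean",
                max_dropped_fraction: float = 0.1) -> np.ndarray:
    """Per-sample raw weighted-sum score.

    Missing dosages are replaced by the variant's mean dosage over
    non-missing samples (``missing='mean'``, keeping scores comparable
    across samples) or contribute nothing (``missing='omit'``).  Weight
    rows absent from the genotypes are dropped with a warning once more
    than ``max_dropped_fraction`` of them are missing.  An empty weight
    set scores everyone 0.
    """
    if missing not in ("mean", "omit"):
        raise ValidationError("missing must be 'mean' or 'omit'")
    n = genotypes.n_samples
    if len(weights) == 0:
        logger.warning("empty weight set; all scores set to 0")
        return np.zeros(n)
    idx = genotypes.column_index()
    present = weights["variant_id"].isin(idx)
    dropped = int((~present).sum())
    if dropped:
        msg = f"{dropped}/{len(weights)} weight rows absent from genotypes"
        if dropped / len(weights) > max_dropped_fraction:
            logger.warning(msg)
        else:
            logger.debug(msg)
    w_used = weights[present]
    if len(w_used) == 0:
        return np.zeros(n)
    cols = [idx[v] for v in w_used["variant_id"]]
    d = genotypes.dosages[:, cols]
    w = w_used["weight"].to_numpy(dtype=float)
    if missing == "mean":
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        d = np.where(np.isnan(d), col_mean[None, :], d)
    else:
        d = np.where(np.isnan(d), 0.0, d)
    return d @ w


def zscore(raw: np.ndarray) -> np.ndarray:
    """(x - mean) / SD with the n-1 sample SD; constant input -> zeros."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValidationError("zscore needs at least two samples")
    sd = raw.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate scores (zero variance); z set to 0")
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def build_prs_matrix(genotypes: GenotypeMatrix, weights: pd.DataFrame,
                     thresholds: ThresholdSet | None = None,
                     missing: str = "mean") -> pd.DataFrame:
    """Raw, z-transformed and SNP-count columns per threshold.

    Columns are ``raw_{c}``, ``z_{c}`` and ``n_{c}`` per cutoff label; the
    SNP sets are nested so ``n_`` is non-decreasing across cutoffs.
    """
    thresholds = thresholds or ThresholdSet()
    out = {"sample_id": genotypes.samples}
    for cutoff, label in zip(thresholds.cutoffs, thresholds.labels()):
        sub = select_snps(weights, cutoff)
        raw = compute_prs(genotypes, sub, missing=missing)
        out[f"raw_{label}"] = raw
        out[f"z_{label}"] = zscore(raw)
        out[f"n_{label}"] = int(sub["variant_id"].isin(genotypes.column_index()).sum())
    return pd.DataFrame(out)
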