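"""Summary-statistic parsing, variant-level QC and allele harmonization.

The filter set mirrors the standard pre-scoring pipeline: discovery rows
with INFO < 0.6 or variant call rate < 60% are dropped; target variants
that are duplicated, strand-ambiguous, non-autosomal, indels, out of
Hardy-Weinberg equilibrium (exact p < 1e-5), rare (MAF < 0.001) or poorly
imputed (quality <= 0.9) are excluded.  Removal is attributed
first-filter-wins in a fixed, documented order so QC reports are
reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCThresholds
from .containers import GenotypeMatrix
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Fixed filter order; removal is attributed to the first filter that fires.
FILTER_ORDER = (
    "duplicate",
    "ambiguous",
    "non_autosomal",
    "indel",
    "low_info",
    "low_call_rate",
    "hwe_fail",
    "low_maf",
    "low_imputation_quality",
)

_AUTOSOMES = {str(i) for i in range(1, 23)}


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(c, c) for c in allele)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele totals and sums the probabilities of
    every attainable heterozygote count whose probability does not exceed
    that of the observed count.  Weights are computed with exact integer
    arithmetic (``P(h) ∝ n!/(AA! h! aa!) · 2^h``), so ties are compared
    exactly and the result is reproducible to machine precision.
    """
    for name, v in (("n_AA", n_AA), ("n_Aa", n_Aa), ("n_aa", n_aa)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
    n = int(n_AA + n_Aa + n_aa)
    if n < 1:
        raise ValidationError("at least one genotype count must be positive")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)

    def weight(h: int) -> int:
        aa_major = (max(n_A, n_a) - h) // 2
        return math.comb(n, h) * math.comb(n - h, aa_major) * (2 ** h)

    w_obs = weight(n_Aa)
    total = 0
    extreme = 0
    for h in range(rare % 2, rare + 1, 2):
        w = weight(h)
        total += w
        if w <= w_obs:
            extreme += w
    return min(1.0, extreme / total)


# ---------------------------------------------------------------------------
# Summary-statistic parsing
# ---------------------------------------------------------------------------

#: Canonical column names understood downstream.
MANDATORY_COLUMNS = ("variant_id", "chrom", "pos", "effect_allele",
                     "other_allele", "p_value", "info")


def parse_sumstats(path, column_map: dict | None = None,
                   max_bad_fraction: float = 0.05) -> pd.DataFrame:
    """Read and validate a tab-delimited discovery summary table.

    ``column_map`` maps canonical names (``variant_id, chrom, pos,
    effect_allele, other_allele, logOR`` or ``OR``, ``p_value, info``) to
    the file's column headers.  If only an ``OR`` column is declared, the
    natural log is taken.  Rows failing validation are dropped and listed
    (1-based data line numbers) in ``df.attrs['bad_rows']``; the run aborts
    if more than ``max_bad_fraction`` of rows fail.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep="\t", dtype=str)

    def col(name):
        return column_map.get(name, name)

    for name in MANDATORY_COLUMNS:
        if col(name) not in raw.columns:
            raise ConfigurationError(
                f"mandatory column {name!r} (file column {col(name)!r}) "
                f"missing from {path}"
            )
    has_logor = col("logOR") in raw.columns
    has_or = col("OR") in raw.columns
    if not (has_logor or has_or):
        raise ConfigurationError(
            f"need a 'logOR' or 'OR' column (via column_map) in {path}"
        )

    df = pd.DataFrame({
        "variant_id": raw[col("variant_id")].astype(str),
        "chrom": raw[col("chrom")].astype(str),
        "pos": pd.to_numeric(raw[col("pos")], errors="coerce"),
        "effect_allele": raw[col("effect_allele")].astype(str).str.upper(),
        "other_allele": raw[col("other_allele")].astype(str).str.upper(),
        "p_value": pd.to_numeric(raw[col("p_value")], errors="coerce"),
        "info": pd.to_numeric(raw[col("info")], errors="coerce"),
    })
    if has_logor:
        df["logOR"] = pd.to_numeric(raw[col("logOR")], errors="coerce")
    else:
        orv = pd.to_numeric(raw[col("OR")], errors="coerce")
        with np.errstate(invalid="ignore", divide="ignore"):
            df["logOR"] = np.log(orv.where(orv > 0))

    allele_ok = (df["effect_allele"].str.fullmatch(r"[ACGT]+")
                 & df["other_allele"].str.fullmatch(r"[ACGT]+")
                 & (df["effect_allele"] != df["other_allele"]))
    valid = (
        allele_ok.fillna(False)
        & df["pos"].notna() & (df["pos"] >= 1)
        & df["p_value"].notna() & (df["p_value"] > 0) & (df["p_value"] <= 1)
        & df["info"].notna() & (df["info"] >= 0) & (df["info"] <= 1)
        & np.isfinite(df["logOR"].to_numpy(dtype=float))
    )
    bad_rows = [int(i) + 1 for i in np.flatnonzero(~valid.to_numpy())]
    if len(df) and len(bad_rows) / len(df) > max_bad_fraction:
        raise ValidationError(
            f"{len(bad_rows)}/{len(df)} summary rows failed validation "
            f"(first bad data lines: {bad_rows[:10]})"
        )
    if bad_rows:
        logger.warning("dropped %d invalid summary rows (data lines %s...)",
                       len(bad_rows), bad_rows[:10])
    out = df[valid].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    out.attrs["bad_rows"] = bad_rows
    return out


# ---------------------------------------------------------------------------
# Per-variant statistics from genotypes
# ---------------------------------------------------------------------------

def variant_stats(genotypes: GenotypeMatrix, variants: pd.DataFrame) -> pd.DataFrame:
    """Attach call_rate, empirical MAF, HWE exact p and indel flag.

    Dosages are rounded to hard calls for the genotype-count-based HWE
    test; the MAF is min(freq, 1-freq) of the alt allele over non-missing
    calls.
    """
    if list(variants["variant_id"]) != list(genotypes.variant_ids):
        raise ValidationError("variant table and genotype columns must align")
    d = genotypes.dosages
    observed = ~np.isnan(d)
    call_rate = observed.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / (2.0 * np.maximum(observed.sum(axis=0), 1))
    maf = np.minimum(freq, 1.0 - freq)

    hard = np.where(observed, np.rint(np.clip(d, 0, 2)), np.nan)
    hwe_p = np.ones(d.shape[1])
    for j in range(d.shape[1]):
        col = hard[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[j] = 1.0
            continue
        n_aa0 = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_alt2 = int((col == 2).sum())
        hwe_p[j] = hwe_exact_test(n_alt2, n_het, n_aa0)

    out = variants.copy()
    out["call_rate"] = call_rate
    out["maf"] = maf
    out["hwe_p"] = hwe_p
    out["is_indel"] = (out["ref_allele"].astype(str).str.len() != 1) | \
                      (out["alt_allele"].astype(str).str.len() != 1)
    return out


def filter_samples(genotypes: GenotypeMatrix,
                   min_call_rate: float = 0.6):
    """Optional subject-level missingness filter (returns kept, removed ids)."""
    rate = (~np.isnan(genotypes.dosages)).mean(axis=1)
    keep = rate >= min_call_rate
    removed = [s for s, k in zip(genotypes.samples, keep) if not k]
    kept = GenotypeMatrix(genotypes.dosages[keep],
                          [s for s, k in zip(genotypes.samples, keep) if k],
                          list(genotypes.variant_ids))
    return kept, removed


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-filter removal counts (first-filter-wins attribution)."""

    variants_in: int = 0
    variants_out: int = 0
    counts: dict = field(default_factory=dict)
    reasons: pd.DataFrame | None = None  # variant_id, reason for removed rows

    def to_text(self) -> str:
        lines = [f"variants in:  {self.variants_in}",
                 f"variants out: {self.variants_out}"]
        lines += [f"removed[{k}]: {self.counts.get(k, 0)}" for k in FILTER_ORDER]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"key": "variants_in", "value": self.variants_in},
                {"key": "variants_out", "value": self.variants_out}]
        rows += [{"key": f"removed_{k}", "value": self.counts.get(k, 0)}
                 for k in FILTER_ORDER]
        return pd.DataFrame(rows)


def filter_variants(variants: pd.DataFrame, sumstats: pd.DataFrame | None = None,
                    thresholds: QCThresholds | None = None):
    """Apply every variant-level filter; returns (kept table, QCReport).

    Filter order (first hit is charged): duplicate, ambiguous,
    non-autosomal, indel, low discovery INFO, low call rate, HWE failure,
    low MAF, low imputation quality.  All copies of a duplicated ID or
    position are removed.  Variants without a matching summary row skip
    the INFO filter (INFO is a discovery-side quantity).
    """
    thresholds = thresholds or QCThresholds()
    v = variants.reset_index(drop=True)
    m = len(v)
    reason = np.full(m, "", dtype=object)

    def mark(mask: np.ndarray, klass: str) -> None:
        mask = np.asarray(mask, dtype=bool) & (reason == "")
        reason[mask] = klass

    if thresholds.exclude_duplicates:
        dup_id = v["variant_id"].duplicated(keep=False)
        dup_pos = v.duplicated(subset=["chrom", "pos"], keep=False)
        mark((dup_id | dup_pos).to_numpy(), "duplicate")

    ref = v["ref_allele"].astype(str).str.upper()
    alt = v["alt_allele"].astype(str).str.upper()
    if thresholds.exclude_ambiguous:
        pair_ambig = ((ref.str.len() == 1) & (alt.str.len() == 1)
                      & (alt == ref.map(lambda a: _COMPLEMENT.get(a, ""))))
        mark(pair_ambig.to_numpy(), "ambiguous")

    if thresholds.autosomes_only:
        mark(~v["chrom"].astype(str).isin(_AUTOSOMES).to_numpy(), "non_autosomal")

    if thresholds.exclude_indels:
        if "is_indel" in v.columns:
            indel = v["is_indel"].astype(bool)
        else:
            indel = (ref.str.len() != 1) | (alt.str.len() != 1)
        mark(indel.to_numpy(), "indel")

    if sumstats is not None and "info" in sumstats.columns:
        info_map = (sumstats.drop_duplicates("variant_id")
                    .set_index("variant_id")["info"])
        info = v["variant_id"].map(info_map)
        mark((info < thresholds.info_min).fillna(False).to_numpy(), "low_info")

    if "call_rate" in v.columns:
        mark((v["call_rate"] < thresholds.call_rate_min).to_numpy(), "low_call_rate")
    if "hwe_p" in v.columns:
        mark((v["hwe_p"] < thresholds.hwe_p_min).to_numpy(), "hwe_fail")
    if "maf" in v.columns:
        mark((v["maf"] < thresholds.maf_min).to_numpy(), "low_maf")
    if "imputation_quality" in v.columns:
        mark((v["imputation_quality"] <= thresholds.imputation_quality_min)
             .to_numpy(), "low_imputation_quality")

    removed = reason != ""
    kept = v[~removed].reset_index(drop=True)
    counts = {k: int((reason == k).sum()) for k in FILTER_ORDER if (reason == k).any()}
    report = QCReport(
        variants_in=m,
        variants_out=len(kept),
        counts=counts,
        reasons=pd.DataFrame({
            "variant_id": v.loc[removed, "variant_id"].to_numpy(),
            "reason": reason[removed],
        }),
    )
    return kept, report


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(sumstats: pd.DataFrame, variants: pd.DataFrame):
    """Align discovery effect sizes to the target's alt allele.

    Per variant (matched on ``variant_id``): if the discovery effect allele
    is the target alt, the weight is +logOR; if it is the target ref, the
    sign flips; if alleles only match after complementing both (opposite
    strand report), they are complemented first and the same sign rule
    applies.  Strand-ambiguous pairs are unresolvable from alleles alone
    and are dropped, as are pairs that match under no orientation.

    Returns (weights, counts): a table with ``variant_id, aligned_allele,
    weight, p_value`` and a dict of per-orientation match/drop counts.
    """
    merged = sumstats.merge(
        variants[["variant_id", "ref_allele", "alt_allele"]],
        on="variant_id", how="inner",
    )
    ea = merged["effect_allele"].astype(str).str.upper()
    oa = merged["other_allele"].astype(str).str.upper()
    ref = merged["ref_allele"].astype(str).str.upper()
    alt = merged["alt_allele"].astype(str).str.upper()
    cea, coa = ea.map(_complement), oa.map(_complement)

    ambiguous = ea == coa  # e.g. A/T or C/G: strand unresolvable
    direct = (ea == alt) & (oa == ref) & ~ambiguous
    swap = (ea == ref) & (oa == alt) & ~ambiguous
    flip = (cea == alt) & (coa == ref) & ~ambiguous
    flip_swap = (cea == ref) & (coa == alt) & ~ambiguous

    logor = merged["logOR"].to_numpy(dtype=float)
    weight = np.full(len(merged), np.nan)
    weight[direct | flip] = logor[direct | flip]
    weight[swap | flip_swap] = -logor[swap | flip_swap]
    matched = direct | swap | flip | flip_swap

    counts = {
        "matched_direct": int(direct.sum()),
        "matched_swap": int(swap.sum()),
        "matched_strand_flip": int(flip.sum()),
        "matched_strand_flip_swap": int(flip_swap.sum()),
        "dropped_ambiguous": int(ambiguous.sum()),
        "dropped_unmatched": int((~matched & ~ambiguous).sum()),
    }
    weights = pd.DataFrame({
        "variant_id": merged.loc[matched, "variant_id"].to_numpy(),
        "aligned_allele": alt[matched].to_numpy(),
        "weight": weight[matched],
        "p_value": merged.loc[matched, "p_value"].to_numpy(),
    })
    return weights, counts
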