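"""Windowed pairwise-r² LD pruning.

Variants are scanned per chromosome in position order with a sliding
window (default 200 SNPs, step 50).  Within a window, while any surviving
pair has dosage r² above the threshold (default 0.25), the pair with the
highest r² is resolved first and one member is removed — by default the
one with the larger discovery-GWAS p-value, so the more strongly
associated variant of each LD pair survives.  Processing violating pairs
in decreasing-r² order makes the kept set monotone in the threshold: the
run at a higher threshold is a prefix of the run at a lower one.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import PruneConfig
from .containers import GenotypeMatrix
from .errors import ValidationError


class R2Result(NamedTuple):
    r2: float
    degenerate: bool


def pairwise_r2(g1, g2) -> R2Result:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples; returns ``(0.0, True)`` if
    fewer than two complete pairs exist or either vector is constant on
    the complete subset.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1 or g1.size < 2:
        raise ValidationError("pairwise_r2 needs two equal-length vectors (n >= 2)")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if ok.sum() < 2:
        return R2Result(0.0, True)
    x, y = g1[ok], g2[ok]
    vx = x - x.mean()
    vy = y - y.mean()
    sx = float(vx @ vx)
    sy = float(vy @ vy)
    if sx == 0.0 or sy == 0.0:
        return R2Result(0.0, True)
    r = float(vx @ vy) / np.sqrt(sx * sy)
    return R2Result(min(1.0, r * r), False)


def r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise-complete r² between all columns of a dosage matrix.

    Vectorized over the observation masks; degenerate pairs (fewer than
    two complete observations, or a constant column on the complete
    subset) get r² = 0.
    """
    x = np.asarray(dosages, dtype=float)
    mask = (~np.isnan(x)).astype(float)
    xz = np.where(np.isnan(x), 0.0, x)
    n = mask.T @ mask
    sx = xz.T @ mask          # sum of x over pairs complete with each j
    sy = sx.T
    sxy = xz.T @ xz
    sxx = (xz * xz).T @ mask
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        r2 = cov * cov / (varx * vary)
    r2[(n < 2) | ~np.isfinite(r2)] = 0.0
    return np.clip(r2, 0.0, 1.0)


def _removal_choice(i: int, j: int, pvals: np.ndarray, pos: np.ndarray,
                    ids: list[str], order_by: str) -> int:
    """Index of the pair member to remove under the configured rule."""
    if order_by == "gwas_p":
        pi, pj = pvals[i], pvals[j]
        if pi != pj and not (np.isnan(pi) or np.isnan(pj)):
            return i if pi > pj else j
    # position mode, equal p, or missing p: drop the later variant
    if pos[i] != pos[j]:
        return i if pos[i] > pos[j] else j
    return i if ids[i] > ids[j] else j


def prune(genotypes: GenotypeMatrix, variants: pd.DataFrame,
          weights: pd.DataFrame | None, config: PruneConfig | None = None):
    """Greedy sliding-window pruning; returns (kept ids, removal log).

    ``variants`` must be sorted by (chrom, pos) and aligned with the
    genotype columns; ``weights`` supplies the discovery p-value per
    variant for the default removal rule.  The removal log is a DataFrame
    with columns ``removed, kept, r2``.
    """
    config = config or PruneConfig()
    if list(variants["variant_id"]) != list(genotypes.variant_ids):
        raise ValidationError("variant table and genotype columns must align")
    chrom = variants["chrom"].astype(str).to_numpy()
    pos = variants["pos"].to_numpy(dtype=float)
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValidationError(f"variants on chromosome {c} are not "
                                  "position-sorted")

    ids = list(variants["variant_id"])
    pvals = np.full(len(ids), np.nan)
    if config.order_by == "gwas_p":
        if weights is None or "p_value" not in getattr(weights, "columns", []):
            raise ValidationError("order_by='gwas_p' requires a weight table "
                                  "with a p_value column")
        pmap = (weights.drop_duplicates("variant_id")
                .set_index("variant_id")["p_value"])
        pvals = variants["variant_id"].map(pmap).to_numpy(dtype=float)

    alive = np.ones(len(ids), dtype=bool)
    log_rows = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while True:
            win = idx[start:start + config.window_snps]
            if len(win) >= 2:
                _prune_window(genotypes.dosages, win, alive, pvals, pos, ids,
                              config, log_rows)
            if start + config.window_snps >= len(idx):
                break
            start += config.step_snps
    kept = [ids[i] for i in np.flatnonzero(alive)]
    log = pd.DataFrame(log_rows, columns=["removed", "kept", "r2"])
    return kept, log


def _prune_window(dosages, win, alive, pvals, pos, ids, config, log_rows):
    live = win[alive[win]]
    if len(live) < 2:
        return
    r2 = r2_matrix(dosages[:, live])
    np.fill_diagonal(r2, 0.0)
    local_alive = np.ones(len(live), dtype=bool)
    while True:
        masked = np.where(np.outer(local_alive, local_alive), r2, 0.0)
        k = int(np.argmax(masked))
        a, b = divmod(k, len(live))
        if masked[a, b] <= config.r2_threshold:
            break
        if a > b:  # canonical pair order for deterministic tie handling
            a, b = b, a
        gi, gj = int(live[a]), int(live[b])
        drop = _removal_choice(gi, gj, pvals, pos, ids, config.order_by)
        keep = gj if drop == gi else gi
        alive[drop] = False
        local_alive[a if drop == gi else b] = False
        log_rows.append((ids[drop], ids[keep], float(masked[a, b])))


def prune_global_reference(dosages: np.ndarray, ids: list[str],
                           pvals: np.ndarray, pos: np.ndarray,
                           r2_threshold: float,
                           order_by: str = "gwas_p") -> list[str]:
    """Single-window pruning over the whole instance (no window sliding).

    Equivalent to :func:`prune` with ``window_snps >= m`` on one
    chromosome; exposed for small exact comparisons.
    """
    m = len(ids)
    alive = np.ones(m, dtype=bool)
    r2 = r2_matrix(dosages)
    np.fill_diagonal(r2, 0.0)
    while True:
        masked = np.where(np.outer(alive, alive), r2, 0.0)
        k = int(np.argmax(masked))
        a, b = divmod(k, m)
        if masked[a, b] <= r2_threshold:
            break
        if a > b:
            a, b = b, a
        drop = _removal_choice(a, b, pvals, pos, ids, order_by)
        alive[drop] = False
    return [ids[i] for i in np.flatnonzero(alive)]
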