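"""Arrayed-validation statistics for knockdown editing experiments.

Implements the statistics used to call knockdown effects on editing
efficiencies against non-targeting controls:

* z-scores, z = (x - mu) / sigma, with mu and sigma from the
  negative-control efficiency distribution; |z| > 3 flags a strong effect;
* adjusted z-scores over replicates, |mean(z)| - sd(z), with significance
  tiers * / ** / *** at 1.5 / 2 / 3 (boundaries go to the higher tier);
* fold changes of mean efficiencies (ratio of the larger to the smaller,
  rounded half-up, with a direction flag) and the unrounded log2 fold
  change;
* relative outcome percentages (percent of edited reads);
* rescue fractions, (rescue - kd) / (nc - kd), 1 = full rescue;
* Livak relative expression from qPCR Ct values, 2^(-ddCt).

The standard-deviation convention is the sample SD (ddof=1) throughout,
exposed as a flag; the printed worked examples are insensitive to the
choice at one-decimal precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ZScoreResult",
    "FoldChangeResult",
    "ExpressionResult",
    "zscore",
    "adjusted_zscore",
    "tier_for",
    "fold_change",
    "relative_outcomes",
    "rescue_delta",
    "delta_delta_ct",
]

STRONG_Z = 3.0
TIER_THRESHOLDS = (1.5, 2.0, 3.0)   # *, **, ***


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ZScoreResult:
    x: float
    mu: float
    sigma: float
    z: float
    strong: bool        # |z| > 3
    direction: str      # up | down


def zscore(x: float, nc_values, ddof: int = 1) -> ZScoreResult:
    """z-score of an observed efficiency against negative-control values.

    Requires at least 3 negative-control values with positive spread.
    """
    nc = np.asarray(nc_values, dtype=float)
    if nc.size < 3:
        raise ValueError("need at least 3 negative-control values")
    mu = float(nc.mean())
    sigma = float(nc.std(ddof=ddof))
    if sigma <= 0:
        raise ValueError("negative controls have zero spread; "
                         "add more NC replicates")
    z = (x - mu) / sigma
    return ZScoreResult(x=float(x), mu=mu, sigma=sigma, z=z,
                        strong=abs(z) > STRONG_Z,
                        direction="up" if z >= 0 else "down")


def tier_for(adjusted: float) -> str:
    """Significance tier for an adjusted z-score (boundaries to higher tier)."""
    lo, mid, hi = TIER_THRESHOLDS
    if adjusted >= hi:
        return "***"
    if adjusted >= mid:
        return "**"
    if adjusted >= lo:
        return "*"
    return "ns"


def adjusted_zscore(zs, ddof: int = 1) -> tuple[float, str]:
    """Adjusted z-score over replicates: |mean(z)| - sd(z), with tier.

    A single replicate cannot support the adjustment; the plain |z| is
    returned with a warning.
    """
    zs = np.asarray(zs, dtype=float)
    if zs.size == 0:
        raise ValueError("no z-scores supplied")
    if zs.size == 1:
        warnings.warn("adjusted z-score undefined for a single replicate; "
                      "falling back to |z|", stacklevel=2)
        adj = abs(float(zs[0]))
    else:
        adj = abs(float(zs.mean())) - float(zs.std(ddof=ddof))
    return adj, tier_for(adj)


@dataclass(frozen=True)
class FoldChangeResult:
    nc_mean: float
    kd_mean: float
    fold: float         # ratio of larger to smaller, rounded
    direction: str      # up | down | none
    lfc: float          # log2(kd / nc), unrounded


def fold_change(nc_mean: float, kd_mean: float, decimals: int = 1) -> FoldChangeResult:
    """Fold change of a knockdown mean efficiency versus the NC mean.

    The fold is the ratio of the larger to the smaller mean, rounded
    half-up to ``decimals``; the direction records which way the knockdown
    moved the efficiency.  The log2 fold change is left unrounded.
    """
    if nc_mean <= 0 or kd_mean <= 0:
        raise ValueError("fold change needs positive mean efficiencies")
    fold = round_half_up(max(nc_mean / kd_mean, kd_mean / nc_mean), decimals)
    if kd_mean > nc_mean:
        direction = "up"
    elif kd_mean < nc_mean:
        direction = "down"
    else:
        direction = "none"
    return FoldChangeResult(nc_mean=nc_mean, kd_mean=kd_mean, fold=fold,
                            direction=direction, lfc=math.log2(kd_mean / nc_mean))


def relative_outcomes(absolute: dict[str, float],
                      wt_key: str = "WT") -> dict[str, float] | None:
    """Per-category percent of edited reads from absolute percentages.

    ``absolute`` maps outcome categories (including WT) to percent of all
    reads.  Returns ``None`` with a warning when nothing is edited.
    """
    edited = {k: v for k, v in absolute.items() if k != wt_key}
    total = sum(edited.values())
    if total <= 0:
        warnings.warn("no edited reads; relative outcomes undefined",
                      stacklevel=2)
        return None
    return {k: 100.0 * v / total for k, v in edited.items()}


def rescue_delta(kd: dict[str, float], rescue: dict[str, float],
                 nc: dict[str, float]) -> dict[str, float]:
    """Per-category rescue fraction: (rescue - kd) / (nc - kd).

    1 means the re-expression fully restored the NC level, 0 means no
    rescue; movement toward NC is positive regardless of the direction of
    the knockdown effect.  Categories where nc == kd are undefined and
    reported as NaN.
    """
    out = {}
    for cat in kd:
        denom = nc[cat] - kd[cat]
        out[cat] = (rescue[cat] - kd[cat]) / denom if denom != 0 else float("nan")
    return out


@dataclass(frozen=True)
class ExpressionResult:
    delta_ct_kd: float
    delta_ct_nc: float
    ddct: float
    relative_expression: float   # fold of control; control maps to 1.0


def delta_delta_ct(ct_target_kd: float, ct_ref_kd: float,
                   ct_target_nc: float, ct_ref_nc: float) -> ExpressionResult:
    """Livak relative expression from qPCR Ct values.

    ddCt = (Ct_target - Ct_reference)_kd - (Ct_target - Ct_reference)_nc;
    relative expression = 2^(-ddCt), so the control sample maps to 1.0.
    """
    cts = (ct_target_kd, ct_ref_kd, ct_target_nc, ct_ref_nc)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("non-finite Ct value")
    d_kd = ct_target_kd - ct_ref_kd
    d_nc = ct_target_nc - ct_ref_nc
    ddct = d_kd - d_nc
    return ExpressionResult(delta_ct_kd=d_kd, delta_ct_nc=d_nc, ddct=ddct,
                            relative_expression=2.0 ** (-ddct))
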