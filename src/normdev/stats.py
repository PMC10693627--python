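"""Nonparametric group comparison: Mann-Whitney U, BH-FDR, 2x2 chi-square.

The exact Mann-Whitney p-value is computed from the full permutation
distribution of the rank sum (tie-aware, via a subset-sum count over
doubled midranks), used by default whenever min(n1, n2) <= 8; larger
samples use the normal approximation with tie-corrected variance and
continuity correction.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import chi2, norm, rankdata

from .errors import ValidationError
from .normative import DeviationMatrix

__all__ = [
    "MWUResult",
    "ChisqResult",
    "mannwhitney_u",
    "bh_adjust",
    "compare_regions",
    "proportion_chisq",
    "two_sided_normal_tail",
]

EXACT_MAX_MIN_N = 8


class MWUResult(NamedTuple):
    statistic: float  # U for x: pairs with x > y, plus half-ties
    pvalue: float
    method: str
    degenerate: bool = False


class ChisqResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def two_sided_normal_tail(threshold: float) -> float:
    """Two-sided standard-normal tail mass beyond +/- threshold."""
    return float(2.0 * norm.sf(threshold))


def _exact_u_pvalue(u_obs: float, doubled_ranks: np.ndarray, n1: int, n2: int) -> float:
    """Two-sided permutation p-value of U via subset-sum counting.

    ``doubled_ranks`` are 2x the pooled midranks (integers even with ties).
    Counts, for every achievable doubled rank-sum s of a size-n1 subset,
    the number of subsets achieving it; U maps linearly to s.
    """
    N = n1 + n2
    total = comb(N, n1, exact=True)
    if total > 4 * 10**18:  # int64 overflow guard
        raise OverflowError("exact Mann-Whitney distribution too large")
    max_s = int(np.sort(doubled_ranks)[-n1:].sum())
    dp = np.zeros((n1 + 1, max_s + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in doubled_ranks.astype(int):
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : max_s + 1 - r]
    counts = dp[n1]
    s_vals = np.flatnonzero(counts)
    # U = R1 - n1(n1+1)/2 with R1 = s/2
    u_vals = s_vals / 2.0 - n1 * (n1 + 1) / 2.0
    center = n1 * n2 / 2.0
    dev_obs = abs(u_obs - center)
    keep = np.abs(u_vals - center) >= dev_obs - 1e-9
    return float(counts[s_vals[keep]].sum() / total)


def mannwhitney_u(x, y, method: str = "auto") -> MWUResult:
    """Mann-Whitney U test; U counts pairs with x > y plus half-ties.

    ``method`` is one of "exact", "approximate", "auto"; "auto" uses the
    exact permutation distribution when min(n1, n2) <= 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if method not in ("exact", "approximate", "auto"):
        raise ValidationError(f"unknown method {method!r}")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = float(r1 - n1 * (n1 + 1) / 2.0)

    if np.ptp(pooled) == 0:
        return MWUResult(statistic=u, pvalue=1.0, method="degenerate", degenerate=True)

    use_exact = method == "exact" or (method == "auto" and min(n1, n2) <= EXACT_MAX_MIN_N)
    if use_exact:
        doubled = np.round(2 * ranks).astype(np.int64)
        try:
            p = _exact_u_pvalue(u, doubled, n1, n2)
            return MWUResult(statistic=u, pvalue=p, method="exact")
        except OverflowError:
            warnings.warn("exact distribution too large; using normal approximation",
                          stacklevel=2)

    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
    var = n1 * n2 / 12.0 * (N + 1 - tie_term)
    if var <= 0:
        return MWUResult(statistic=u, pvalue=1.0, method="degenerate", degenerate=True)
    center = n1 * n2 / 2.0
    zstat = (abs(u - center) - 0.5) / np.sqrt(var)
    p = float(min(2.0 * norm.sf(max(zstat, 0.0)), 1.0))
    return MWUResult(statistic=u, pvalue=p, method="approximate")


def bh_adjust(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted p, rejection flags)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted <= alpha
    return adjusted, reject


def compare_regions(z: DeviationMatrix, alpha: float = 0.05, method: str = "auto") -> pd.DataFrame:
    """Region-wise Mann-Whitney tests of patient vs control z-scores.

    BH correction is applied jointly across all regions.  Effect size is
    the rank-biserial correlation 1 - 2U/(n1*n2) with U computed for the
    patient sample; positive values mean patients rank lower.
    """
    patients = z.subjects("patient")
    controls = z.subjects("control")
    if len(patients) == 0 or len(controls) == 0:
        raise ValidationError("both patient and control groups must be present")
    if z.z.isna().any().any():
        bad = z.z.columns[z.z.isna().any()].tolist()
        raise ValidationError(f"missing z-scores in regions {bad} (complete cases required)")
    zp = z.z.loc[patients]
    zc = z.z.loc[controls]
    n1, n2 = len(patients), len(controls)
    rows = []
    for region in z.z.columns:
        res = mannwhitney_u(zp[region].to_numpy(), zc[region].to_numpy(), method=method)
        rows.append(
            {
                "region_id": region,
                "U": res.statistic,
                "p": res.pvalue,
                "effect_size": 1.0 - 2.0 * res.statistic / (n1 * n2),
                "median_patient": float(zp[region].median()),
                "median_control": float(zc[region].median()),
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    adjusted, reject = bh_adjust(out["p"].to_numpy(), alpha=alpha)
    out["p_adj"] = adjusted
    out["significant"] = reject
    return out[
        ["region_id", "U", "p", "p_adj", "significant", "effect_size",
         "median_patient", "median_control", "method"]
    ]


def proportion_chisq(k1: int, n1: int, k2: int, n2: int) -> ChisqResult:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    for name, val in (("k1", k1), ("n1", n1), ("k2", k2), ("n2", n2)):
        if val < 0:
            raise ValidationError(f"{name} must be >= 0")
    if n1 == 0 or n2 == 0:
        raise ValidationError("group sizes must be > 0")
    if k1 > n1 or k2 > n2:
        raise ValidationError("counts cannot exceed group sizes")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    N = n1 + n2
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(mrg == 0 for mrg in margins):
        return ChisqResult(statistic=0.0, pvalue=1.0, degenerate=True)
    x2 = N * (a * d - b * c) ** 2 / np.prod([float(mrg) for mrg in margins])
    return ChisqResult(statistic=float(x2), pvalue=float(chi2.sf(x2, df=1)))
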