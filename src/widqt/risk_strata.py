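"""Median-split risk groups and exact conditional 2x2 inference.

Subjects are split at the median of each score ("high" strictly above the
median, computed over all subjects in the set at hand), the two binary
labels are crossed into four risk groups, and each non-reference group is
compared with the low/low reference by a median-unbiased odds ratio.

The odds-ratio machinery is conditional-exact: given the margins of a 2x2
table, the exposed-case count follows Fisher's noncentral hypergeometric
distribution with noncentrality psi (the odds ratio). The median-unbiased
estimate is the psi at which the mid-p tail probability of the observed
count equals one half; 95% limits invert the mid-p tails at 0.025 per side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import nchypergeom_fisher

__all__ = [
    "median_split",
    "combine_groups",
    "median_unbiased_or",
    "risk_table",
    "quantile_or_curve",
    "OddsRatioResult",
    "GROUP_LABELS",
    "REFERENCE_GROUP",
]

GROUP_LABELS = ["low/low", "high/low", "low/high", "high/high"]
REFERENCE_GROUP = "low/low"


@dataclass(frozen=True)
class OddsRatioResult:
    """Median-unbiased odds ratio with mid-p 95% CI and two-sided p."""

    or_hat: float
    ci_low: float
    ci_high: float
    p: float

    def __iter__(self):
        return iter((self.or_hat, self.ci_low, self.ci_high, self.p))


def median_split(scores) -> pd.Series:
    """Label each subject 'high' iff its score is strictly above the median.

    The median is taken over all provided subjects; ties at the median go
    to the low group.
    """
    scores = pd.Series(scores, dtype=float)
    if scores.empty:
        raise ValueError("median_split requires at least one score")
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"),
                     index=scores.index, name="risk_group")


def combine_groups(prs_labels, index_labels) -> pd.Series:
    """Cross PRS and methylation-index high/low labels into four groups.

    Returned labels are '<prs>/<index>'; 'low/low' is the reference.
    """
    prs_labels = pd.Series(prs_labels)
    index_labels = pd.Series(index_labels)
    if not prs_labels.index.equals(index_labels.index):
        if set(prs_labels.index) != set(index_labels.index):
            raise ValueError("PRS and index labels cover different subjects")
        index_labels = index_labels.reindex(prs_labels.index)
    combined = prs_labels.astype(str) + "/" + index_labels.astype(str)
    combined.name = "combined_group"
    return combined


def _midp_tails(a: int, psi: float, total: int, n_exposed: int, n_cases: int):
    """Mid-p upper and lower tail probabilities of the exposed-case count."""
    dist = nchypergeom_fisher(total, n_exposed, n_cases, psi)
    pmf_a = dist.pmf(a)
    upper = dist.sf(a) + 0.5 * pmf_a       # P(X > a) + P(X = a)/2
    lower = dist.cdf(a) - 0.5 * pmf_a      # P(X < a) + P(X = a)/2
    return upper, lower


def _solve_psi(a, total, n_exposed, n_cases, tail: str, target: float,
               log_center: float) -> float:
    """Find psi with mid-p tail == target by bisection on log-psi.

    `tail` selects the upper (increasing in psi) or lower (decreasing)
    mid-p tail. Returns 0 or inf when the equation has no finite root.
    """
    def f(log_psi):
        upper, lower = _midp_tails(a, math.exp(log_psi), total,
                                   n_exposed, n_cases)
        return (upper if tail == "upper" else lower) - target

    sign = 1.0 if tail == "upper" else -1.0
    lo, hi = log_center - 5.0, log_center + 5.0
    for _ in range(60):
        if sign * f(lo) < 0:
            break
        lo -= 5.0
        if lo < -700:
            return 0.0
    else:
        return 0.0
    for _ in range(60):
        if sign * f(hi) > 0:
            break
        hi += 5.0
        if hi > 700:
            return math.inf
    else:
        return math.inf
    root = brentq(f, lo, hi, xtol=1e-8)
    return math.exp(root)


def median_unbiased_or(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Median-unbiased odds ratio for a 2x2 table with mid-p CI and p.

    Parameters are the table cells: ``a`` exposed cases, ``b`` exposed
    controls, ``c`` reference cases, ``d`` reference controls. The estimate
    solves mid-p tail = 1/2 under the noncentral hypergeometric law
    conditioned on the margins (the upper- and lower-tail equations
    coincide under the mid-p correction, so the two roots are averaged
    trivially); the 95% interval inverts each mid-p tail at 0.025, and the
    two-sided p-value is twice the smaller mid-p tail at psi = 1.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    total = a + b + c + d
    n_exposed, n_cases = a + b, a + c
    if n_exposed == 0 or c + d == 0 or n_cases == 0 or b + d == 0:
        raise ValueError("both margins of the 2x2 table must be positive")

    support_lo = max(0, n_cases - (c + d))
    support_hi = min(n_exposed, n_cases)
    # crude cross-product (Haldane-corrected) centres the root bracket
    crude = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    log_crude = math.log(crude)

    if support_lo == support_hi:
        # margins fix the table completely; no information about psi
        or_hat, ci_low, ci_high, p = 1.0, 0.0, math.inf, 1.0
        return OddsRatioResult(or_hat, ci_low, ci_high, p)

    if a == support_lo:
        or_hat = 0.0
    elif a == support_hi:
        or_hat = math.inf
    else:
        lo_root = _solve_psi(a, total, n_exposed, n_cases, "upper", 0.5, log_crude)
        hi_root = _solve_psi(a, total, n_exposed, n_cases, "lower", 0.5, log_crude)
        or_hat = math.sqrt(lo_root * hi_root) if np.isfinite(lo_root + hi_root) \
            else (lo_root + hi_root) / 2

    ci_low = 0.0 if a == support_lo else _solve_psi(
        a, total, n_exposed, n_cases, "upper", 0.025, log_crude)
    ci_high = math.inf if a == support_hi else _solve_psi(
        a, total, n_exposed, n_cases, "lower", 0.025, log_crude)

    upper1, lower1 = _midp_tails(a, 1.0, total, n_exposed, n_cases)
    p = min(1.0, 2.0 * min(upper1, lower1))
    return OddsRatioResult(or_hat, ci_low, ci_high, p)


def risk_table(groups, case_status, group_order=None) -> pd.DataFrame:
    """Per-group case/control counts with ORs versus the low/low reference.

    Returns a DataFrame indexed by group label with columns cases,
    controls, or_hat, ci_low, ci_high, p. The reference row carries
    or_hat = 1 and no p-value.
    """
    groups = pd.Series(groups)
    case_status = pd.Series(case_status).reindex(groups.index).astype(int)
    order = group_order or [g for g in GROUP_LABELS if g in set(groups)]
    if not order:
        order = sorted(set(groups))
    if REFERENCE_GROUP not in set(groups):
        raise ValueError(f"reference group {REFERENCE_GROUP!r} is empty")
    if len(set(groups)) < 2:
        raise ValueError("risk_table needs at least two groups")

    ref_mask = groups == REFERENCE_GROUP
    c = int(case_status[ref_mask].sum())
    d = int((1 - case_status[ref_mask]).sum())
    if c == 0 or d == 0:
        raise ValueError("reference group must contain both cases and controls")

    rows = []
    for g in order:
        mask = groups == g
        a = int(case_status[mask].sum())
        b = int((1 - case_status[mask]).sum())
        if g == REFERENCE_GROUP:
            rows.append((g, a, b, 1.0, np.nan, np.nan, np.nan))
        else:
            res = median_unbiased_or(a, b, c, d)
            rows.append((g, a, b, res.or_hat, res.ci_low, res.ci_high, res.p))
    return pd.DataFrame(
        rows, columns=["group", "cases", "controls", "or_hat",
                       "ci_low", "ci_high", "p"]).set_index("group")


def quantile_or_curve(scores_a, scores_b=None, case_status=None,
                      cut_points=(25, 50, 75)) -> pd.DataFrame:
    """Odds ratios of percentile bins of a score (or combined score) vs the bottom bin.

    With two scores, each is standardized (z-scored) and summed before
    binning. ``cut_points`` are interior percentiles in (0, 100); bins are
    compared with the bottom bin by :func:`median_unbiased_or`. Bins with
    neither cases nor controls are dropped with a warning.
    """
    cut_points = list(cut_points)
    if any(not 0 < q < 100 for q in cut_points) or cut_points != sorted(set(cut_points)):
        raise ValueError("cut_points must be strictly increasing within (0, 100)")
    scores_a = pd.Series(scores_a, dtype=float)
    if scores_b is not None:
        scores_b = pd.Series(scores_b, dtype=float).reindex(scores_a.index)
        za = (scores_a - scores_a.mean()) / scores_a.std(ddof=1)
        zb = (scores_b - scores_b.mean()) / scores_b.std(ddof=1)
        combined = za + zb
    else:
        combined = scores_a
    case_status = pd.Series(case_status).reindex(combined.index).astype(int)

    edges = np.percentile(combined, [0] + cut_points + [100])
    edges[0], edges[-1] = -np.inf, np.inf
    bins = np.digitize(combined, edges[1:-1], right=True)

    ref_mask = bins == 0
    c = int(case_status[ref_mask].sum())
    d = int((1 - case_status[ref_mask]).sum())
    rows = [("bin_0", c, d, 1.0, np.nan, np.nan, np.nan)]
    for k in range(1, len(edges) - 1):
        mask = bins == k
        a = int(case_status[mask].sum())
        b = int((1 - case_status[mask]).sum())
        if a == 0 and b == 0:
            warnings.warn(f"percentile bin {k} has no subjects; omitted")
            continue
        res = median_unbiased_or(a, b, c, d)
        rows.append((f"bin_{k}", a, b, res.or_hat, res.ci_low, res.ci_high, res.p))
    return pd.DataFrame(
        rows, columns=["stratum", "cases", "controls", "or_hat",
                       "ci_low", "ci_high", "p"]).set_index("stratum")
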