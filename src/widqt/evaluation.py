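"""ROC/AUC with DeLong intervals, paired reductions, and association tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult", "roc_auc", "stratified_auc", "paired_reduction_rate",
    "covariate_association", "group_difference_test",
]

_WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class ROCResult:
    """AUC with a 95% confidence interval and an optional stratum label."""

    auc: float
    ci_low: float
    ci_high: float
    stratum: str | None = None
    n_cases: int = 0
    n_controls: int = 0


def _placements(scores: np.ndarray, labels: np.ndarray):
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    # midrank placements: V10[i] = P(case_i beats a random control)
    v10 = np.array([np.mean((c > controls) + 0.5 * (c == controls))
                    for c in cases])
    v01 = np.array([np.mean((cases > c) + 0.5 * (cases == c))
                    for c in controls])
    return v10, v01


def roc_auc(scores, labels, stratum: str | None = None) -> ROCResult:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2).

    The 95% CI uses the DeLong variance of the case and control placement
    values, truncated to [0, 1].
    """
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels).reindex(scores.index).to_numpy(int)
    s = scores.to_numpy()
    m, n = int((labels == 1).sum()), int((labels == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present for ROC analysis")
    v10, v01 = _placements(s, labels)
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(var)
    return ROCResult(auc=auc, ci_low=float(max(0.0, auc - half)),
                     ci_high=float(min(1.0, auc + half)), stratum=stratum,
                     n_cases=m, n_controls=n)


def stratified_auc(scores, labels, strata) -> list[ROCResult]:
    """Per-stratum ROC analysis; one-class strata are skipped with a warning."""
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels).reindex(scores.index)
    strata = pd.Series(strata).reindex(scores.index)
    out = []
    for name in pd.unique(strata.dropna()):
        mask = strata == name
        sub_labels = labels[mask]
        if mask.sum() == 0 or sub_labels.nunique() < 2:
            warnings.warn(f"stratum {name!r} lacks both classes; skipped")
            continue
        out.append(roc_auc(scores[mask], sub_labels, stratum=str(name)))
    return out


def paired_reduction_rate(before, after) -> tuple[int, int, float]:
    """Count paired observations where the score decreased.

    Exact ties count as non-reduced. Returns (n_reduced, n_total, fraction).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be equal-length 1-D vectors")
    n_reduced = int(np.sum(after < before))
    n_total = int(len(before))
    frac = n_reduced / n_total if n_total else 0.0
    return n_reduced, n_total, frac


def covariate_association(scores, covariate, group_labels=None) -> pd.DataFrame:
    """Pearson correlation of a score with a covariate, per group.

    Returns a DataFrame indexed by group with columns r, p, n. With no
    groups, a single row labelled 'all' is returned.
    """
    scores = pd.Series(scores, dtype=float)
    covariate = pd.Series(covariate, dtype=float).reindex(scores.index)
    groups = (pd.Series(group_labels).reindex(scores.index)
              if group_labels is not None
              else pd.Series("all", index=scores.index))
    rows = []
    for name in pd.unique(groups.dropna()):
        mask = groups == name
        x, y = scores[mask], covariate[mask]
        ok = x.notna() & y.notna()
        x, y = x[ok], y[ok]
        if len(x) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 paired values")
        if np.isclose(y.std(ddof=1), 0) or np.isclose(x.std(ddof=1), 0):
            raise ValueError(f"correlation undefined in group {name!r}: "
                             "constant input")
        r, p = stats.pearsonr(x, y)
        rows.append((name, float(r), float(p), int(len(x))))
    return pd.DataFrame(rows, columns=["group", "r", "p", "n"]).set_index("group")


def group_difference_test(scores_a, scores_b, paired: bool = False) -> float:
    """Two-tailed p-value for a difference between two score groups.

    Unpaired comparisons use Welch's t-test. Paired comparisons use the
    Wilcoxon signed-rank test, with the exact null distribution for
    n <= 25 non-zero differences and a continuity-corrected normal
    approximation above.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not paired:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least two observations per group")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(p) if np.isfinite(p) else 1.0
    if a.shape != b.shape:
        raise ValueError("paired comparison requires equal-length vectors")
    diffs = a - b
    nz = np.count_nonzero(diffs)
    if nz == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if nz <= _WILCOXON_EXACT_MAX_N else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=(method == "approx"),
                         method=method)
    return float(res.pvalue)
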