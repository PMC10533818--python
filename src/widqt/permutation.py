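"""Permutation null for index specificity.

Retrains the lasso classifier on randomly drawn sets of non-mQTL CpGs and
collects the resulting held-out AUCs. If methylation at mQTL CpGs carries
risk information beyond what arbitrary CpGs provide, the true index's AUC
should exceed the upper band of this null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import roc_auc
from .qt_index import compute_index, fit_penalized_classifier

__all__ = ["PermutationResult", "permutation_null"]


@dataclass
class PermutationResult:
    aucs: np.ndarray
    median_auc: float
    band_low: float           # central 95% band of the null AUCs
    band_high: float
    n_perm: int
    n_cpgs_per_perm: int
    seed: int

    def __post_init__(self):
        self.aucs = np.asarray(self.aucs, dtype=float)
        if np.any((self.aucs < 0) | (self.aucs > 1)):
            raise ValueError("AUCs must lie in [0, 1]")

    def summary(self) -> dict:
        return {
            "median_auc": self.median_auc,
            "band_low": self.band_low,
            "band_high": self.band_high,
            "n_perm": self.n_perm,
            "n_cpgs_per_perm": self.n_cpgs_per_perm,
            "seed": self.seed,
        }


def permutation_null(all_betas: pd.DataFrame, mqtl_cpgs, labels,
                     train_samples, eval_samples, n_perm: int = 100,
                     n_cpgs: int = 120, k_folds: int = 10,
                     seed: int = 0, cv_tol: float = 3e-4,
                     fit_tol: float = 1e-4) -> PermutationResult:
    """Null AUC distribution from lasso classifiers on random non-mQTL CpGs.

    Per permutation, ``n_cpgs`` CpGs are sampled without replacement from
    the CpGs of ``all_betas`` NOT in ``mqtl_cpgs``; a lasso classifier is
    trained on ``train_samples`` (CV folds re-randomized from the
    permutation's child seed) and its AUC recorded on ``eval_samples``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    mqtl_set = set(mqtl_cpgs)
    pool = np.array([c for c in all_betas.index if c not in mqtl_set])
    if len(pool) < n_cpgs:
        raise ValueError(
            f"non-mQTL pool has {len(pool)} CpGs, fewer than n_cpgs={n_cpgs}")
    labels = pd.Series(labels)
    train_labels = labels.loc[train_samples]
    eval_labels = labels.loc[eval_samples]

    children = np.random.SeedSequence(seed).spawn(n_perm)
    aucs = np.empty(n_perm)
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        chosen = rng.choice(pool, size=n_cpgs, replace=False)
        fold_seed = int(rng.integers(2**31 - 1))
        model, _ = fit_penalized_classifier(
            all_betas.loc[chosen, train_samples], train_labels,
            penalty="l1", k_folds=k_folds, seed=fold_seed,
            cv_tol=cv_tol, fit_tol=fit_tol)
        scores = compute_index(all_betas.loc[chosen, eval_samples], model)
        aucs[k] = roc_auc(scores, eval_labels).auc

    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return PermutationResult(
        aucs=aucs, median_auc=float(np.median(aucs)), band_low=float(lo),
        band_high=float(hi), n_perm=n_perm, n_cpgs_per_perm=n_cpgs,
        seed=seed)
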