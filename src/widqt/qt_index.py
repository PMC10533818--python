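"""Training, selection, and scoring of the mQTL methylation risk index.

The index is a linear combination of methylation beta values at mQTL CpGs,
fit by L1- or L2-penalized logistic regression over a descending lambda
path with stratified k-fold cross-validation on binomial deviance. After
model selection on an internal validation set, the chosen penalty is refit
on the full discovery set and the raw weighted sum sum_i w_i * beta_ij is
centred and scaled by its discovery-set mean mu and standard deviation
sigma, so the finalized index scores the discovery set with zero mean and
unit SD:

    score_j = (sum_i w_i * beta_ij - mu) / sigma

Weights act directly on the beta scale; the logistic intercept is dropped
from scoring since centring by mu removes location anyway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._solver import lambda_max, logistic_path
from .evaluation import roc_auc

__all__ = [
    "IndexModel", "TrainReport", "fit_penalized_classifier", "select_model",
    "finalize_index", "compute_index", "save_index", "load_index",
]

N_LAMBDA = 30
LAMBDA_MIN_RATIO = 1e-2
_ALPHA = {"l1": 1.0, "l2": 0.0}


@dataclass
class IndexModel:
    """CpG weights plus the scaling constants defining the risk index."""

    cpg_ids: list[str]
    weights: np.ndarray
    intercept: float
    mu: float
    sigma: float
    penalty: str            # "l1" | "l2"
    lam: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.cpg_ids):
            raise ValueError("one weight per CpG required")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def nonzero_cpgs(self) -> list[str]:
        return [c for c, w in zip(self.cpg_ids, self.weights) if w != 0]


@dataclass
class TrainReport:
    cv_curve: dict[float, float]          # lambda -> mean CV deviance
    chosen_lambda: float
    n_nonzero: int
    internal_validation_auc: float | None = None


def _as_xy(betas: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels = pd.Series(labels).reindex(betas.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = labels.to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = betas.to_numpy(float).T            # samples x CpGs
    if np.isnan(X).any():
        raise ValueError("beta matrix contains missing values")
    return X, y, list(betas.index)


def _deviance(coefs, intercepts, X, y) -> np.ndarray:
    """Mean binomial deviance of each lambda's model on (X, y)."""
    eta = X @ coefs.T + intercepts
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = y[:, None] * np.log(p) + (1 - y[:, None]) * np.log(1 - p)
    return -2.0 * ll.mean(axis=0)


def fit_penalized_classifier(train_betas: pd.DataFrame, labels,
                             penalty: str = "l1", k_folds: int = 10,
                             seed: int = 0, cv_tol: float = 1e-4,
                             fit_tol: float = 1e-6
                             ) -> tuple[IndexModel, TrainReport]:
    """Fit a penalized logistic classifier over a CV-tuned lambda path.

    ``train_betas`` is CpGs x samples; lambda is chosen to minimize the
    mean cross-validated binomial deviance over class-stratified folds.
    The returned model has placeholder scaling (mu=0, sigma=1); use
    :func:`finalize_index` to set the scaling on the discovery set.
    """
    if penalty not in _ALPHA:
        raise ValueError("penalty must be 'l1' or 'l2'")
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    X, y, cpgs = _as_xy(train_betas, labels)
    if k_folds > len(y):
        raise ValueError("k_folds cannot exceed the number of samples")
    alpha = _ALPHA[penalty]

    lam_hi = lambda_max(X, y, alpha=max(alpha, 1.0))  # L1 zero-threshold anchor
    path = np.geomspace(lam_hi, lam_hi * LAMBDA_MIN_RATIO, N_LAMBDA)
    folds = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    cv_loss = np.zeros(len(path))
    for train_idx, test_idx in folds.split(X, y):
        coefs, intercepts = logistic_path(X[train_idx], y[train_idx], path,
                                          alpha, tol=cv_tol)
        cv_loss += _deviance(coefs, intercepts, X[test_idx], y[test_idx])
    cv_loss /= k_folds
    best = int(np.argmin(cv_loss))
    chosen = float(path[best])

    coefs, intercepts = logistic_path(X, y, path[: best + 1], alpha,
                                      tol=fit_tol)
    model = IndexModel(cpg_ids=cpgs, weights=coefs[best],
                       intercept=float(intercepts[best]), mu=0.0, sigma=1.0,
                       penalty=penalty, lam=chosen)
    report = TrainReport(cv_curve={float(l): float(v)
                                   for l, v in zip(path, cv_loss)},
                         chosen_lambda=chosen, n_nonzero=model.n_nonzero)
    return model, report


def select_model(candidates, internal_betas: pd.DataFrame,
                 internal_labels) -> IndexModel:
    """Pick the candidate with the highest internal-validation AUC.

    Ties break toward the sparser model (fewer non-zero weights).
    ``candidates`` is a list of (IndexModel, TrainReport); each report's
    ``internal_validation_auc`` is filled in as a side effect.
    """
    if not candidates:
        raise ValueError("at least one candidate model is required")
    scored = []
    for model, report in candidates:
        auc = roc_auc(compute_index(internal_betas, model),
                      internal_labels).auc
        report.internal_validation_auc = auc
        scored.append((auc, -model.n_nonzero, model))
    scored.sort(key=lambda t: (t[0], t[1]), reverse=True)
    return scored[0][2]


def finalize_index(penalty: str, discovery_betas: pd.DataFrame,
                   discovery_labels, k_folds: int = 10,
                   seed: int = 0) -> tuple[IndexModel, TrainReport]:
    """Refit on the full discovery set and fix the index scaling.

    mu and sigma are the mean and (sample) standard deviation of the raw
    weighted sum over discovery subjects, so the finalized index has zero
    mean and unit SD on the discovery set by construction.
    """
    model, report = fit_penalized_classifier(
        discovery_betas, discovery_labels, penalty=penalty,
        k_folds=k_folds, seed=seed)
    raw = discovery_betas.to_numpy(float).T @ model.weights
    sigma = float(np.std(raw, ddof=1))
    if sigma == 0:
        raise ValueError("index is degenerate: all weights zero or constant "
                         "weighted sum on the discovery set")
    model.mu = float(np.mean(raw))
    model.sigma = sigma
    return model, report


def compute_index(betas: pd.DataFrame, model: IndexModel) -> pd.Series:
    """Score subjects: (sum_i w_i * beta_ij - mu) / sigma."""
    missing = [c for c in model.cpg_ids if c not in betas.index]
    if missing:
        raise KeyError(f"beta matrix is missing model CpGs: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    sub = betas.loc[model.cpg_ids]
    raw = sub.to_numpy(float).T @ model.weights
    return pd.Series((raw - model.mu) / model.sigma, index=betas.columns,
                     name="qt_index")


def save_index(model: IndexModel, weights_path, sidecar_path) -> None:
    """Serialize as a (cpg_id, weight) TSV plus a JSON scaling sidecar."""
    pd.DataFrame({"cpg_id": model.cpg_ids, "weight": model.weights}).to_csv(
        weights_path, sep="\t", index=False)
    Path(sidecar_path).write_text(json.dumps({
        "mu": model.mu, "sigma": model.sigma, "penalty": model.penalty,
        "lambda": model.lam, "intercept": model.intercept}, indent=2))


def load_index(weights_path, sidecar_path) -> IndexModel:
    tab = pd.read_csv(weights_path, sep="\t")
    meta = json.loads(Path(sidecar_path).read_text())
    return IndexModel(cpg_ids=tab["cpg_id"].tolist(),
                      weights=tab["weight"].to_numpy(float),
                      intercept=float(meta.get("intercept", 0.0)),
                      mu=float(meta["mu"]), sigma=float(meta["sigma"]),
                      penalty=meta["penalty"], lam=float(meta["lambda"]))
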