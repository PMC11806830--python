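"""Informative (MAR) structured missingness: core variables and their model.

Structured missingness is assumed to be driven by a set of fully observed
baseline ("core") variables through a logistic model.  This module selects
core variables with L1-penalised logistic regression, estimates the
predictability of missingness (AUC_c) by stratified cross-validation, and
estimates the correlation matrix of the core variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._stats import rank_auc

# Penalty convention: ``lam`` is the per-sample L1 weight in
#   (1/n) sum_i logloss_i + lam * ||w||_1,
# mapped onto scikit-learn's C = 1 / (n * lam).
_MAX_C = 1e8


def _l1_logistic(lam: float, n: int) -> LogisticRegression:
    c = _MAX_C if lam <= 0 else min(1.0 / (n * lam), _MAX_C)
    return LogisticRegression(
        penalty="l1", C=c, solver="liblinear", max_iter=2000, tol=1e-6
    )


def _standardize(x: NDArray) -> tuple[NDArray, NDArray, NDArray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (x - mu) / sd, mu, sd


def _prepare_x0(x0: NDArray) -> NDArray:
    x0 = np.asarray(x0, dtype=float)
    if np.isnan(x0).any():
        warnings.warn(
            "baseline data contains missing entries; mean-filling before the fit",
            RuntimeWarning,
            stacklevel=3,
        )
        mu = np.nanmean(x0, axis=0)
        idx = np.where(np.isnan(x0))
        x0 = x0.copy()
        x0[idx] = np.take(mu, idx[1])
    return x0


@dataclass
class SMPredictor:
    """Fitted penalised logistic model for one cluster's SM indicator."""

    lam: float
    intercept: float
    coef: NDArray[np.float64]          # on the standardized scale
    core_idx: NDArray[np.int64]        # columns of X0 with nonzero coefficients
    mean: NDArray[np.float64]
    scale: NDArray[np.float64]
    auc: float | None = None

    def decision(self, x0: NDArray) -> NDArray[np.float64]:
        z = (np.asarray(x0, dtype=float) - self.mean) / self.scale
        return self.intercept + z @ self.coef


@dataclass
class CoreVariableModel:
    """Per-cluster SM predictors plus the global core-variable correlation."""

    predictors: dict[int, SMPredictor]
    core_union: NDArray[np.int64] = field(default_factory=lambda: np.empty(0, np.int64))
    sigma_core: NDArray[np.float64] | None = None


def fit_sm_predictor(x0: NDArray, b: NDArray, lam: float) -> SMPredictor:
    """L1-penalised logistic regression of an SM indicator on baseline data.

    Predictors are standardized before fitting; core variables are the
    columns with nonzero coefficients at penalty ``lam``.
    """
    x0 = _prepare_x0(x0)
    b = np.asarray(b).astype(int)
    if len(np.unique(b)) < 2:
        raise ValueError("SM indicator has a single class; cannot fit a predictor")
    z, mu, sd = _standardize(x0)
    model = _l1_logistic(lam, len(b)).fit(z, b)
    coef = model.coef_.ravel()
    core = np.flatnonzero(coef != 0.0)
    if core.size == 0:
        warnings.warn(
            f"no core variables selected at lambda={lam:g}; intercept-only model",
            RuntimeWarning,
            stacklevel=2,
        )
    return SMPredictor(
        lam=float(lam),
        intercept=float(model.intercept_[0]),
        coef=coef,
        core_idx=core,
        mean=mu,
        scale=sd,
    )


def cv_auc(
    x0: NDArray, b: NDArray, lam: float, folds: int = 5, seed: int = 0
) -> float:
    """Mean out-of-fold AUC of the penalised logistic score (stratified folds)."""
    x0 = _prepare_x0(x0)
    b = np.asarray(b).astype(int)
    n_pos = int(b.sum())
    if min(n_pos, len(b) - n_pos) < folds:
        raise ValueError(
            f"fewer minority-class samples ({min(n_pos, len(b) - n_pos)}) than folds "
            f"({folds}); reduce the number of folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(x0, b):
        z, mu, sd = _standardize(x0[train])
        model = _l1_logistic(lam, len(train)).fit(z, b[train])
        score = model.decision_function((x0[test] - mu) / sd)
        aucs.append(rank_auc(score, b[test]))
    return float(np.mean(aucs))


def lambda_report(
    x0: NDArray,
    b: NDArray,
    lambda_grid,
    folds: int = 5,
    seed: int = 0,
    var_types: NDArray | None = None,
) -> pd.DataFrame:
    """Cross-validated trade-off table over an L1 penalty grid.

    One row per lambda with validation log-loss, out-of-fold AUC and the
    number of selected core variables (and how many of them are binary),
    supporting the manual choice of a penalty that keeps only strongly
    predictive core variables.
    """
    grid = np.asarray(list(lambda_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    x0 = _prepare_x0(x0)
    b = np.asarray(b).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x0, b))
    rows = []
    for lam in grid:
        losses, aucs = [], []
        for train, test in splits:
            z, mu, sd = _standardize(x0[train])
            model = _l1_logistic(lam, len(train)).fit(z, b[train])
            p = model.predict_proba((x0[test] - mu) / sd)[:, 1]
            p = np.clip(p, 1e-12, 1 - 1e-12)
            losses.append(-np.mean(b[test] * np.log(p) + (1 - b[test]) * np.log(1 - p)))
            aucs.append(rank_auc(p, b[test]))
        fit = fit_sm_predictor(x0, b, lam)
        n_core = int(fit.core_idx.size)
        n_binary = (
            int(np.sum(np.asarray(var_types, dtype=object)[fit.core_idx] == "binary"))
            if var_types is not None and n_core
            else 0
        )
        rows.append(
            {
                "lambda": lam,
                "val_loss": float(np.mean(losses)),
                "auc": float(np.mean(aucs)),
                "n_core": n_core,
                "n_binary_core": n_binary,
            }
        )
    return pd.DataFrame(rows)


def estimate_sigma_core(x0_core: NDArray, delta: float = 1e-8) -> NDArray[np.float64]:
    """Correlation matrix of the core variables, projected to PD if needed."""
    from .correlation import nearest_correlation

    x = np.asarray(x0_core, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least two core variables")
    sd = x.std(axis=0)
    for j in np.flatnonzero(sd == 0.0):
        raise ValueError(f"core variable at column {j} is constant")
    sigma = np.corrcoef(x, rowvar=False)
    if np.linalg.eigvalsh(sigma).min() < delta:
        sigma = nearest_correlation(sigma, delta=delta)
    return sigma
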