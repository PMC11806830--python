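"""Mixed-type predictor-selection scores for chained-equation imputation.

For a target variable j and a candidate predictor j', the score S_jj' is
proportional to the maximum expected reduction in imputation error (MSE for
continuous targets, misclassification rate for binary ones) obtainable from
j', weighted by the co-observation count V_jj' — the number of rows where j
is missing but j' is observed.  Binary variables are modelled as thresholded
latent Gaussians; the biserial correlation recovers the latent-scale
association from the observed Pearson correlation.

S is directional: rows index the imputation target, columns the predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.integrate import quad
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from ._stats import bvn_cdf
from .correlation import pairwise_complete_corr

__all__ = [
    "co_observation",
    "BiserialParams",
    "biserial_from_pearson",
    "score_continuous",
    "score_binary_target",
    "score_binary_binary",
    "score_matrix",
    "select_predictors",
]


def co_observation(mask: NDArray) -> NDArray[np.int64]:
    """V = M^T (1 - M): V[j, j'] counts rows where j is missing and j' observed."""
    m = np.asarray(mask, dtype=float)
    v = m.T @ (1.0 - m)
    return np.rint(v).astype(np.int64)


@dataclass
class BiserialParams:
    """Latent-threshold view of a binary variable paired with a continuous one."""

    p: float          # positive-case rate
    D: float          # latent threshold Phi^-1(p)
    rho_b: float      # latent-scale (biserial) correlation


def biserial_from_pearson(rho: float, p: float) -> BiserialParams:
    """Biserial correlation from the observed Pearson correlation.

    rho_b = rho * sqrt(p(1-p)) / phi(D) with D = Phi^-1(p); values outside
    [-1, 1] (possible for extreme rho/p combinations) are clipped with a
    warning.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("positive rate p must lie in (0, 1)")
    d = float(ndtri(p))
    rho_b = float(rho) * np.sqrt(p * (1.0 - p)) / norm.pdf(d)
    if abs(rho_b) > 1.0:
        warnings.warn(
            f"biserial conversion gave {rho_b:.4f}; clipping to [-1, 1]",
            RuntimeWarning,
            stacklevel=2,
        )
        rho_b = float(np.clip(rho_b, -1.0, 1.0))
    return BiserialParams(p=float(p), D=d, rho_b=rho_b)


def score_continuous(v: float, rho: float) -> float:
    """S = V * rho^2 (continuous target; also continuous target with binary
    predictor): the relative MSE reduction of the best linear predictor."""
    if abs(rho) > 1.0 + 1e-12:
        raise ValueError("|rho| must not exceed 1")
    return float(v) * float(rho) ** 2


def _binary_accuracy(rho_b, d):
    """Classification accuracy of the conditional-median rule, vectorised.

    The target's latent Gaussian z determines x = 1 on one side of the
    threshold; x is predicted from a continuous predictor x' (latent-scale
    correlation rho_b) by whether the conditional median of z clears the
    threshold.  The two semi-infinite integrals of the accuracy reduce to
    bivariate-normal orthant probabilities: with a = D / rho_b,

      rho_b > 0: acc = 1 - Phi(a) - Phi(D) + 2 * Phi2(a, D; rho_b)
      rho_b < 0: acc = Phi(a) + Phi(D) - 2 * Phi2(a, D; rho_b)
    """
    rho_b = np.asarray(rho_b, dtype=float)
    d = np.asarray(d, dtype=float)
    rho_b, d = np.broadcast_arrays(rho_b, d)
    out = np.empty(rho_b.shape)
    pos = rho_b > 0
    neg = rho_b < 0
    zero = ~(pos | neg)
    with np.errstate(divide="ignore"):
        a = np.where(zero, np.inf, d / rho_b)
    phi2 = bvn_cdf(a, d, np.abs(np.clip(rho_b, -1.0, 1.0)) * np.sign(rho_b))
    out[pos] = (1.0 - ndtr(a) - ndtr(d) + 2.0 * phi2)[pos]
    out[neg] = (ndtr(a) + ndtr(d) - 2.0 * phi2)[neg]
    p = ndtr(d)
    out[zero] = np.maximum(p, 1.0 - p)[zero]
    return out


def _binary_accuracy_quad(rho_b: float, d: float, epsabs: float = 1e-8) -> float:
    """Direct quadrature of the printed two-regime accuracy integrals."""
    s = np.sqrt(max(1.0 - rho_b * rho_b, 0.0))
    if s == 0.0:  # |rho_b| = 1: prediction is exact
        return 1.0

    def inner(x):
        return norm.cdf((d - rho_b * x) / s)

    a = d / rho_b
    if rho_b > 0:
        t1, _ = quad(lambda x: norm.pdf(x) * inner(x), -np.inf, a, epsabs=epsabs)
        t2, _ = quad(lambda x: norm.pdf(x) * (1.0 - inner(x)), a, np.inf, epsabs=epsabs)
    else:
        t1, _ = quad(lambda x: norm.pdf(x) * (1.0 - inner(x)), -np.inf, a, epsabs=epsabs)
        t2, _ = quad(lambda x: norm.pdf(x) * inner(x), a, np.inf, epsabs=epsabs)
    return t1 + t2


def score_binary_target(
    v: float, rho: float, p: float, method: str = "bvn"
) -> float:
    """Score for a binary target j with a continuous predictor j'.

    S = V * [accuracy of the conditional-median rule - max(p, 1-p)], where
    the accuracy integral is evaluated either in closed form via
    bivariate-normal CDFs (``method="bvn"``, default) or by adaptive
    quadrature of the printed integrals (``method="quad"``).
    """
    bp = biserial_from_pearson(rho, p)
    if bp.rho_b == 0.0:
        return 0.0
    if abs(bp.rho_b) >= 1.0 - 1e-9:
        acc = 1.0
    elif method == "bvn":
        acc = float(_binary_accuracy(bp.rho_b, bp.D))
    elif method == "quad":
        acc = _binary_accuracy_quad(bp.rho_b, bp.D)
    else:
        raise ValueError("method must be 'bvn' or 'quad'")
    return float(v) * max(acc - max(p, 1.0 - p), 0.0)


def _binary_binary_gain(rho, p, p2, clip_tol: float = 1e-6):
    """Accuracy gain for a binary target given a binary predictor, vectorised.

    The 2x2 joint table follows from the phi-coefficient identity
    P(x=1, x'=1) = p p' + rho sqrt(p(1-p) p'(1-p')).
    """
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p11 = p * p2 + rho * np.sqrt(p * (1 - p) * p2 * (1 - p2))
    lo = np.maximum(0.0, p + p2 - 1.0)
    hi = np.minimum(p, p2)
    infeasible = (p11 < lo - clip_tol) | (p11 > hi + clip_tol)
    p11 = np.clip(p11, lo, hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = p11 / p2
        c0 = (p - p11) / (1.0 - p2)
    gain = (
        p2 * np.maximum(c1, 1.0 - c1)
        + (1.0 - p2) * np.maximum(c0, 1.0 - c0)
        - np.maximum(p, 1.0 - p)
    )
    return np.maximum(gain, 0.0), infeasible


def score_binary_binary(v: float, rho: float, p: float, p2: float) -> float:
    """Score for a binary target j with a binary predictor j'."""
    for name, val in (("p", p), ("p'", p2)):
        if not 0.0 < val < 1.0:
            raise ValueError(f"positive rate {name} must lie in (0, 1)")
    gain, infeasible = _binary_binary_gain(rho, p, p2)
    if bool(infeasible):
        raise ValueError(
            f"rho={rho} is infeasible for marginals (p={p}, p'={p2})"
        )
    return float(v) * float(gain)


def score_matrix(
    values: NDArray,
    var_types: NDArray,
    mask: NDArray | None = None,
    min_overlap: int = 2,
) -> NDArray[np.float64]:
    """Full d x d score matrix S (rows: target, columns: predictor).

    Correlations and positive rates are computed on (pairwise-complete)
    observed values; unavailable correlations score 0.
    """
    x = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(x).astype(np.int8)
    else:
        x = np.where(np.asarray(mask) == 1, np.nan, x)
    var_types = np.asarray(var_types, dtype=object)
    d = x.shape[1]
    v = co_observation(mask).astype(float)
    corr, _ = pairwise_complete_corr(x, min_overlap=min_overlap)
    rho = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(rho, 0.0)

    is_bin = var_types == "binary"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    p = np.clip(np.where(np.isnan(p), 0.5, p), 1e-6, 1 - 1e-6)

    s = v * rho**2  # continuous-target default (either predictor type)

    bt = np.flatnonzero(is_bin)
    if bt.size:
        # binary target, continuous predictor
        cont = np.flatnonzero(~is_bin)
        if cont.size:
            d_thr = ndtri(p[bt])
            rho_blk = rho[np.ix_(bt, cont)]
            rho_b = rho_blk * (np.sqrt(p[bt] * (1 - p[bt])) / norm.pdf(d_thr))[:, None]
            rho_b = np.clip(rho_b, -1.0, 1.0)
            acc = _binary_accuracy(rho_b, d_thr[:, None])
            near_one = np.abs(rho_b) >= 1.0 - 1e-9
            acc = np.where(near_one, 1.0, acc)
            gain = np.maximum(acc - np.maximum(p[bt], 1 - p[bt])[:, None], 0.0)
            gain = np.where(rho_blk == 0.0, 0.0, gain)
            s[np.ix_(bt, cont)] = v[np.ix_(bt, cont)] * gain
        # binary target, binary predictor
        gain_bb, _ = _binary_binary_gain(
            rho[np.ix_(bt, bt)], p[bt][:, None], p[bt][None, :]
        )
        gain_bb = np.where(rho[np.ix_(bt, bt)] == 0.0, 0.0, gain_bb)
        s[np.ix_(bt, bt)] = v[np.ix_(bt, bt)] * gain_bb

    np.fill_diagonal(s, 0.0)
    return s


def select_predictors(
    values: NDArray,
    var_types: NDArray,
    strategy: str,
    k: int,
    mask: NDArray | None = None,
    var_ids: NDArray | None = None,
    min_overlap: int = 2,
    warn_short: bool = True,
) -> dict[int, NDArray[np.int64]]:
    """Top-k predictor lists per variable with missing entries.

    ``strategy`` is one of ``correlation`` (highest |r|), ``co_observation``
    (largest V) or ``mixed_score`` (largest S).  Candidates with a zero
    criterion are dropped; ties break by ascending variable index so the
    selection is deterministic.
    """
    x = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(x).astype(np.int8)
    else:
        x = np.where(np.asarray(mask) == 1, np.nan, x)
    d = x.shape[1]
    if not 0 < k < d:
        raise ValueError("k must satisfy 0 < k < d")
    if strategy == "correlation":
        corr, _ = pairwise_complete_corr(x, min_overlap=min_overlap)
        crit = np.abs(np.where(np.isnan(corr), 0.0, corr))
    elif strategy == "co_observation":
        crit = co_observation(mask).astype(float)
    elif strategy == "mixed_score":
        crit = score_matrix(x, var_types, min_overlap=min_overlap)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    np.fill_diagonal(crit, 0.0)

    out: dict[int, NDArray[np.int64]] = {}
    n_short = 0
    miss_cols = np.flatnonzero(np.asarray(mask).sum(axis=0) > 0)
    for j in miss_cols:
        row = crit[j]
        nonzero = np.flatnonzero(row > 0.0)
        order = nonzero[np.lexsort((nonzero, -row[nonzero]))]
        if order.size < k:
            n_short += 1
        out[int(j)] = order[:k]
    if n_short and warn_short:
        warnings.warn(
            f"{n_short} variables had fewer than k={k} candidates with a "
            "nonzero criterion; shorter predictor lists returned",
            RuntimeWarning,
            stacklevel=2,
        )
    return out
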