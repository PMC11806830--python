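"""Shared statistical primitives: rank AUC, bivariate-normal CDF, seeded substreams."""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import ndtr, owens_t
from scipy.stats import rankdata

__all__ = ["rank_auc", "soft_rank_auc", "bvn_cdf", "substream"]

# fixed name -> entropy word table so substreams are stable across runs
_STREAMS = (
    "core", "calibration", "sm", "um", "sigma", "thresholds",
    "mcar", "replicates", "folds", "misc",
)


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named, independent random substream derived from one master seed.

    All randomness in the generation pipeline flows through these so that
    individual stages are reproducible in isolation.
    """
    if name not in _STREAMS:
        raise ValueError(f"unknown stream name {name!r}; expected one of {_STREAMS}")
    word = _STREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, word, int(index)]))


def rank_auc(scores: ArrayLike, labels: ArrayLike) -> float:
    """Area under the ROC curve via the Mann-Whitney rank-sum statistic.

    Ties among scores receive half credit.  Exact, O(n log n).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)  # average ranks: ties -> half credit
    rank_sum = ranks[np.asarray(labels) == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def soft_rank_auc(scores: NDArray[np.floating], pos_prob: NDArray[np.floating]) -> float:
    """Population AUC of a score against Bernoulli(pos_prob) outcomes.

    Conditions on the score sample (Rao-Blackwellised over the label draws):
    AUC = sum_{s_i > s_j} p_i (1 - p_j) / (sum p)(sum (1-p)), ties half credit.
    Used by the generator's binary-search calibration, where it makes the
    target function deterministic given the Monte-Carlo score draw.
    """
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    p = pos_prob[order]
    q = 1.0 - p
    # group ties
    new_group = np.empty(s.size, dtype=bool)
    new_group[0] = True
    np.not_equal(s[1:], s[:-1], out=new_group[1:])
    group_id = np.cumsum(new_group) - 1
    n_groups = group_id[-1] + 1
    p_g = np.bincount(group_id, weights=p, minlength=n_groups)
    q_g = np.bincount(group_id, weights=q, minlength=n_groups)
    q_below = np.concatenate(([0.0], np.cumsum(q_g)[:-1]))
    num = np.sum(p_g * (q_below + 0.5 * q_g))
    den = p.sum() * q.sum()
    return float(num / den)


def bvn_cdf(h: ArrayLike, k: ArrayLike, rho: ArrayLike) -> NDArray[np.float64]:
    """P(X <= h, Y <= k) for standard bivariate normal (X, Y) with correlation rho.

    Closed form in terms of Owen's T function; vectorised over all arguments.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, dtype=float), np.asarray(k, dtype=float), np.asarray(rho, dtype=float)
    )
    # the CDF is continuous, so nudging exact zeros off the axis is exact in the limit
    h = np.where(h == 0.0, 1e-15, h).astype(float)
    k = np.where(k == 0.0, 1e-15, k).astype(float)
    rho = np.asarray(rho, dtype=float)
    out = np.empty(h.shape, dtype=float)

    hi = rho >= 1.0 - 1e-12
    lo = rho <= -1.0 + 1e-12
    mid = ~(hi | lo)
    if hi.any():
        out[hi] = ndtr(np.minimum(h[hi], k[hi]))
    if lo.any():
        out[lo] = np.clip(ndtr(h[lo]) + ndtr(k[lo]) - 1.0, 0.0, None)
    if mid.any():
        hm, km, rm = h[mid], k[mid], rho[mid]
        s = np.sqrt(1.0 - rm * rm)
        t1 = owens_t(hm, (km - rm * hm) / (hm * s))
        t2 = owens_t(km, (hm - rm * km) / (km * s))
        # correction term: 1/2 when h and k lie on opposite sides of the origin
        beta = np.where(hm * km < 0, 0.5, 0.0)
        out[mid] = 0.5 * (ndtr(hm) + ndtr(km)) - t1 - t2 - beta
    return np.clip(out, 0.0, 1.0)
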