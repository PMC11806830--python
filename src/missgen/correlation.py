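"""Cluster-pair correlation distributions and the synthetic correlation matrix.

Between-variable correlations are summarised per cluster pair as histograms
over [-1, 1] (estimated on pairwise-complete observations).  A full d x d
synthetic correlation matrix is drawn entry-wise from those histograms, the
core block is overwritten with the estimated core correlation, and the
result is projected to the nearest positive-definite correlation matrix by
alternating projections (Higham's algorithm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .structure import ClusterAssignment, DataMatrix, compute_mask

logger = logging.getLogger(__name__)


def pairwise_complete_corr(
    values: NDArray, min_overlap: int = 2
) -> tuple[NDArray[np.float64], NDArray[np.int64]]:
    """Pearson correlations on pairwise-complete observations, via mask algebra.

    Returns (corr, counts); entries with fewer than ``min_overlap``
    co-observed rows, or with a degenerate marginal, are NaN.
    """
    x = np.asarray(values, dtype=float)
    obs = (~np.isnan(x)).astype(float)
    xz = np.where(np.isnan(x), 0.0, x)
    n = obs.T @ obs                     # co-observation counts
    sx = xz.T @ obs                     # sum of x_j over co-observed rows (per pair)
    sxx = (xz * xz).T @ obs             # sum of x_j^2 over co-observed rows
    sxy = xz.T @ xz
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = sx / n
        my = mx.T
        cov = sxy / n - mx * my
        vx = sxx / n - mx * mx
        vy = vx.T
        corr = cov / np.sqrt(vx * vy)
    bad = (n < max(min_overlap, 2)) | ~np.isfinite(corr)
    corr = np.where(bad, np.nan, np.clip(corr, -1.0, 1.0))
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr, n.astype(np.int64)


@dataclass
class CorrelationHistograms:
    """Histograms of between-variable correlations for each cluster pair.

    Keys are unordered pairs (c, c') with c <= c'; all histograms share one
    set of strictly increasing bin edges spanning [-1, 1].
    """

    edges: NDArray[np.float64]
    probs: dict[tuple[int, int], NDArray[np.float64]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.edges[0] < -1.0 - 1e-12 or self.edges[-1] > 1.0 + 1e-12:
            raise ValueError("bin support must lie within [-1, 1]")
        norm = {}
        for key, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.size != self.edges.size - 1 or (p < 0).any():
                raise ValueError(f"invalid probabilities for pair {key}")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"probabilities for pair {key} do not sum to 1")
            norm[(min(key), max(key))] = p
        self.probs = norm

    def pair(self, c: int, cp: int) -> NDArray[np.float64]:
        return self.probs[(min(c, cp), max(c, cp))]

    def sample(self, c: int, cp: int, size: int, rng: np.random.Generator) -> NDArray:
        """Inverse-CDF sampling: pick a bin by its probability, uniform within."""
        p = self.pair(c, cp)
        idx = rng.choice(p.size, size=size, p=p)
        u = rng.random(size)
        w = np.diff(self.edges)
        return self.edges[idx] + u * w[idx]


def estimate_histograms(
    data: DataMatrix,
    assignment: ClusterAssignment,
    bins: int = 40,
    min_overlap: int = 100,
) -> CorrelationHistograms:
    """Histogram of pairwise-complete correlations for every cluster pair.

    Variable pairs with fewer than ``min_overlap`` co-observed rows are
    skipped (and counted in the log).  Mixed continuous/binary pairs use
    plain Pearson correlation on the observed values.
    """
    corr, counts = pairwise_complete_corr(data.values, min_overlap=min_overlap)
    edges = np.linspace(-1.0, 1.0, bins + 1)
    probs: dict[tuple[int, int], NDArray] = {}
    n_skipped = 0
    ids = assignment.cluster_ids
    for a_i, c in enumerate(ids):
        for cp in ids[a_i:]:
            ci = assignment.members(c)
            cj = assignment.members(cp)
            block = corr[np.ix_(ci, cj)].copy()
            nblock = counts[np.ix_(ci, cj)]
            if c == cp:
                iu = np.triu_indices(len(ci), k=1)
                r = block[iu]
                nb = nblock[iu]
            else:
                r = block.ravel()
                nb = nblock.ravel()
            ok = (~np.isnan(r)) & (nb >= min_overlap)
            n_skipped += int((~ok).sum())
            if not ok.any():
                raise ValueError(
                    f"no variable pair for clusters ({c}, {cp}) has overlap >= {min_overlap}"
                )
            h, _ = np.histogram(np.clip(r[ok], -1.0, 1.0 - 1e-12), bins=edges)
            probs[(c, cp)] = h / h.sum()
    if n_skipped:
        logger.info("estimate_histograms: skipped %d low-overlap pairs", n_skipped)
    return CorrelationHistograms(edges=edges, probs=probs)


def nearest_correlation(
    a: NDArray,
    tol: float = 1e-8,
    max_iter: int = 200,
    delta: float = 1e-8,
) -> NDArray[np.float64]:
    """Nearest positive-definite correlation matrix by alternating projections.

    Alternates projection onto the PSD cone (with Dykstra's correction) and
    onto the unit-diagonal affine set until the Frobenius-norm change falls
    below ``tol``; eigenvalues are finally floored at ``delta`` and the
    diagonal renormalised.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=1e-8):
        raise ValueError("input must have a unit diagonal")

    y = a.copy()
    ds = np.zeros_like(a)
    converged = False
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh(r)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        ds = x - r
        y_old = y
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        denom = max(np.linalg.norm(y), 1.0)
        if np.linalg.norm(y - y_old) / denom < tol:
            converged = True
            break
    if not converged:
        resid = float(np.linalg.norm(y - y_old) / denom)
        warnings.warn(
            f"nearest_correlation: max_iter={max_iter} reached, residual {resid:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    # floor the spectrum and restore the unit diagonal exactly
    w, v = np.linalg.eigh((y + y.T) / 2.0)
    if w.min() < delta:
        y = (v * np.clip(w, delta, None)) @ v.T
    d = np.sqrt(np.diag(y))
    y = y / np.outer(d, d)
    y = (y + y.T) / 2.0
    np.fill_diagonal(y, 1.0)
    return y


def sample_sigma(
    hists: CorrelationHistograms,
    labels: NDArray,
    sigma_core: NDArray | None = None,
    core_positions: NDArray | None = None,
    rng: np.random.Generator | None = None,
    delta: float = 1e-8,
    max_passes: int = 3,
) -> tuple[NDArray[np.float64], bool]:
    """Draw a full synthetic correlation matrix Sigma*.

    Each off-diagonal entry is drawn independently from the histogram of its
    cluster pair; the core-variable block is overwritten with ``sigma_core``;
    the matrix is projected to the nearest PD correlation matrix if its
    smallest eigenvalue falls below ``delta``.  Because projection perturbs
    the core block, the block is re-imposed and projection repeated for up
    to ``max_passes`` passes; if the conflict persists, the projected
    (non-exact-core) matrix is returned with a warning.

    Returns (sigma, is_projected).
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = np.asarray(labels)
    d = labels.size
    sigma = np.eye(d)
    ids = sorted(set(int(c) for c in labels))
    for a_i, c in enumerate(ids):
        for cp in ids[a_i:]:
            ci = np.flatnonzero(labels == c)
            cj = np.flatnonzero(labels == cp)
            if c == cp:
                iu = np.triu_indices(len(ci), k=1)
                vals = hists.sample(c, cp, iu[0].size, rng)
                block = sigma[np.ix_(ci, ci)]
                block[iu] = vals
                block.T[iu] = vals
                sigma[np.ix_(ci, ci)] = block
            else:
                vals = hists.sample(c, cp, len(ci) * len(cj), rng).reshape(len(ci), len(cj))
                sigma[np.ix_(ci, cj)] = vals
                sigma[np.ix_(cj, ci)] = vals.T

    def impose_core(mat: NDArray) -> NDArray:
        if sigma_core is not None and core_positions is not None:
            mat[np.ix_(core_positions, core_positions)] = sigma_core
        return mat

    sigma = impose_core(sigma)
    projected = False
    for _ in range(max_passes):
        if np.linalg.eigvalsh(sigma).min() >= delta:
            return sigma, projected
        sigma = nearest_correlation(sigma, delta=delta)
        projected = True
        sigma_proj = sigma.copy()
        sigma = impose_core(sigma)
        if sigma_core is None or core_positions is None:
            return sigma, projected
    if np.linalg.eigvalsh(sigma).min() < delta:
        warnings.warn(
            "sample_sigma: exact core block conflicts with positive definiteness; "
            "returning the projected matrix with an approximate core block",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma = sigma_proj
    return sigma, projected
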