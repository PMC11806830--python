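"""Missingness structure of incomplete mixed-type data.

This module holds the central objects of the analysis stage: the data matrix
with its missingness mask, variable-wise missingness distances, hierarchical
clustering of variables into sub-study blocks, identification of structured
missingness (SM, block-wise non-participation) and estimation of the
Beta-distributed rates of residual unstructured missingness (UM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
BINARY = "binary"


@dataclass
class DataMatrix:
    """Subjects-by-variables numeric table with explicit missing entries.

    Missing entries are NaN.  ``var_types`` tags each column as
    ``"continuous"`` or ``"binary"``; binary columns take values in {0, 1}
    where observed.
    """

    values: NDArray[np.float64]
    var_types: np.ndarray
    var_ids: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.var_types = np.asarray(self.var_types, dtype=object)
        self.var_ids = np.asarray(self.var_ids, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("data matrix must have at least one row and one column")
        if self.var_types.shape != (d,):
            raise ValueError("var_types must have one entry per column")
        bad = set(self.var_types) - {CONTINUOUS, BINARY}
        if bad:
            raise ValueError(f"unknown variable types: {sorted(bad)}")
        if len(set(self.var_ids)) != d:
            raise ValueError("var_ids must be unique")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        for j in np.flatnonzero(self.var_types == BINARY):
            col = self.values[:, j]
            obs = col[~np.isnan(col)]
            if obs.size and not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError(f"binary variable {self.var_ids[j]!r} has values outside {{0,1}}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, var_types) -> "DataMatrix":
        types = np.asarray([var_types[c] for c in frame.columns], dtype=object)
        return cls(
            values=frame.to_numpy(dtype=float),
            var_types=types,
            var_ids=frame.columns.to_numpy(dtype=object),
            subject_ids=frame.index.to_numpy(dtype=object),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.var_ids)


@dataclass
class ClusterAssignment:
    """Partition of variables into sub-study clusters.

    Labels are canonicalised so that the baseline cluster (lowest mean
    variable-wise missingness) is 0 and the remaining clusters are numbered
    by descending size, making results stable under column permutations.
    """

    labels: NDArray[np.int64]
    n_clusters: int
    baseline_cluster: int = 0

    def members(self, c: int) -> NDArray[np.int64]:
        return np.flatnonzero(self.labels == c)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(int(c) for c in self.labels))


@dataclass
class StructuredMissingness:
    """Per-cluster subject-wise SM indicator vectors and SM rates pi_c."""

    b: dict[int, NDArray[np.int8]]
    pi: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pi:
            self.pi = {c: float(np.mean(v)) for c, v in self.b.items()}


@dataclass
class UMRateModel:
    """Beta(alpha_c, beta_c) models of unstructured missingness rates.

    ``p_um`` holds the per-variable estimated UM rate (computed only over
    subjects without structured missingness for the variable's cluster).
    """

    alpha: dict[int, float]
    beta: dict[int, float]
    p_um: NDArray[np.float64]


def compute_mask(data: DataMatrix) -> NDArray[np.int8]:
    """Missingness indicator matrix M: M[i, j] = 1 iff value (i, j) is missing."""
    return np.isnan(data.values).astype(np.int8)


def variable_distance(mask: NDArray) -> NDArray[np.float64]:
    """Variable-wise missingness distance: proportion of discordant indicators.

    D[j, j'] = (1/n) * #{i : M[i, j] != M[i, j']}.  The subject-wise analogue
    is obtained by applying this function to the transposed mask.
    """
    m = np.asarray(mask, dtype=float)
    n = m.shape[0]
    if n < 1:
        raise ValueError("mask must have at least one row")
    co_mm = m.T @ m                    # both missing
    miss = m.sum(axis=0)
    # discordant = miss_j + miss_j' - 2 * both-missing
    d = (miss[:, None] + miss[None, :] - 2.0 * co_mm) / n
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def _linkage(distance: NDArray) -> NDArray:
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance must be a square matrix")
    return linkage(squareform(d, checks=False), method="complete")


def cluster_variables(
    distance: NDArray,
    n_clusters: int,
    missing_rates: NDArray | None = None,
) -> ClusterAssignment:
    """Complete-linkage agglomerative clustering of variables, cut at n_clusters.

    ``missing_rates`` (per-variable missingness fraction) designates the
    baseline cluster: the cluster with the lowest mean rate gets label 0.
    Without rates, the largest cluster is taken as baseline.
    """
    d = distance.shape[0]
    if not 1 <= n_clusters <= d:
        raise ValueError(f"n_clusters must be in [1, {d}], got {n_clusters}")
    raw = fcluster(_linkage(distance), t=n_clusters, criterion="maxclust")
    raw_ids = np.unique(raw)
    sizes = {int(c): int(np.sum(raw == c)) for c in raw_ids}
    if missing_rates is not None:
        rates = np.asarray(missing_rates, dtype=float)
        mean_rate = {int(c): float(rates[raw == c].mean()) for c in raw_ids}
        baseline = min(raw_ids, key=lambda c: (mean_rate[int(c)], -sizes[int(c)]))
    else:
        baseline = max(raw_ids, key=lambda c: (sizes[int(c)], -int(c)))
    others = sorted(
        (int(c) for c in raw_ids if c != baseline),
        key=lambda c: (-sizes[c], c),
    )
    remap = {int(baseline): 0, **{c: i + 1 for i, c in enumerate(others)}}
    labels = np.array([remap[int(c)] for c in raw], dtype=np.int64)
    return ClusterAssignment(labels=labels, n_clusters=len(raw_ids), baseline_cluster=0)


def dendrogram_heights(distance: NDArray, last_k: int) -> NDArray[np.float64]:
    """Heights of the final ``last_k`` complete-linkage merges (non-decreasing).

    Plotting these supports the user's choice of the number of clusters C.
    """
    d = distance.shape[0]
    if not 1 <= last_k <= d - 1:
        raise ValueError(f"last_k must be in [1, {d - 1}]")
    heights = _linkage(distance)[:, 2]
    return heights[-last_k:]


def identify_sm(
    mask: NDArray,
    assignment: ClusterAssignment,
    threshold: float = 0.9,
) -> StructuredMissingness:
    """Flag subjects as structurally missing for each non-baseline cluster.

    Subject i is structurally missing for cluster c when at least
    ``threshold`` (default 90%) of cluster-c variables are missing for i.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    m = np.asarray(mask)
    b: dict[int, NDArray[np.int8]] = {}
    for c in assignment.cluster_ids:
        if c == assignment.baseline_cluster:
            continue
        cols = assignment.members(c)
        if cols.size == 0:
            raise ValueError(f"cluster {c} is empty")
        frac = m[:, cols].mean(axis=1)
        b[c] = (frac >= threshold).astype(np.int8)
    return StructuredMissingness(b=b)


def beta_method_of_moments(
    rates: NDArray, strict: bool = False
) -> tuple[float, float]:
    """Invert Beta(alpha, beta) from the sample mean and variance of rates.

    alpha = m (m(1-m)/v - 1), beta = (1-m)(m(1-m)/v - 1).  When the moments
    are infeasible (v >= m(1-m)) or degenerate (v = 0), the variance is
    clipped to 0.99 m(1-m) (or, in strict mode, an error is raised).
    """
    r = np.asarray(rates, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two rates for a method-of-moments fit")
    m = float(r.mean())
    v = float(r.var(ddof=1))
    if not 0.0 < m < 1.0:
        raise ValueError(f"mean rate {m:.4f} outside (0, 1); beta fit impossible")
    vmax = m * (1.0 - m)
    if v < 1e-12 * vmax or v >= vmax:
        if strict:
            raise ValueError(
                f"sample variance {v:.3g} infeasible for beta moments (bound {vmax:.3g})"
            )
        warnings.warn(
            "infeasible beta moments; clipping variance to 0.99 m(1-m)",
            RuntimeWarning,
            stacklevel=2,
        )
        v = 0.99 * vmax if v >= vmax else 1e-6 * vmax  # near-degenerate spread
    t = vmax / v - 1.0
    return m * t, (1.0 - m) * t


def estimate_um(
    mask: NDArray,
    assignment: ClusterAssignment,
    sm: StructuredMissingness,
    strict: bool = False,
) -> UMRateModel:
    """Method-of-moments Beta fits to per-variable unstructured missingness rates.

    For each non-baseline cluster, the UM rate of variable j is its missing
    fraction among subjects *without* structured missingness for j's cluster;
    the baseline cluster's rates are computed over all subjects but no Beta
    model is fitted for it (it is assumed (near-)fully observed).
    """
    m = np.asarray(mask)
    p_um = np.full(m.shape[1], np.nan)
    alpha: dict[int, float] = {}
    beta: dict[int, float] = {}
    for c in assignment.cluster_ids:
        cols = assignment.members(c)
        if c == assignment.baseline_cluster:
            p_um[cols] = m[:, cols].mean(axis=0)
            continue
        keep = sm.b[c] == 0
        if cols.size < 2 or int(keep.sum()) < 2:
            raise ValueError(
                f"cluster {c}: need >= 2 variables and >= 2 subjects without SM"
            )
        rates = m[np.ix_(keep, cols)].mean(axis=0)
        p_um[cols] = rates
        alpha[c], beta[c] = beta_method_of_moments(rates, strict=strict)
    return UMRateModel(alpha=alpha, beta=beta, p_um=p_um)


def screen_variables(
    data: DataMatrix, max_missing: float | None = None
) -> tuple[NDArray[np.int64], pd.DataFrame]:
    """Pre-analysis variable screen.

    Drops variables with zero observed variance and, when ``max_missing`` is
    set, variables whose missingness rate exceeds it.  Returns the kept
    column indices and a manifest of exclusions.
    """
    mask = compute_mask(data)
    rate = mask.mean(axis=0)
    records = []
    keep = []
    for j in range(data.d):
        col = data.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0 or (obs.size > 0 and np.nanstd(obs) == 0.0):
            records.append((data.var_ids[j], "zero_variance", rate[j]))
        elif max_missing is not None and rate[j] > max_missing:
            records.append((data.var_ids[j], "too_missing", rate[j]))
        else:
            keep.append(j)
    manifest = pd.DataFrame(records, columns=["var_id", "reason", "missing_rate"])
    if len(records):
        logger.info("screen_variables: excluded %d variables", len(records))
    return np.asarray(keep, dtype=np.int64), manifest
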