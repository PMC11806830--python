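"""Synthetic-cohort generation: latent-Gaussian mixed data with calibrated
structured (MAR) and unstructured (MCAR) missingness.

Pipeline (see :func:`assemble_dataset`): core variables are drawn from
N(0, Sigma_core); per-cluster logistic models with equal coefficients are
calibrated by nested binary search so that their AUC and positive rate hit
the target (AUC_c, pi_c); structured-missingness indicators are Bernoulli
draws from those models; unstructured missingness rates come from
Beta(alpha_c, beta_c); the full correlation matrix Sigma* is sampled from
the cluster-pair histograms and projected to PD; the remaining variables
are completed conditionally on the core; a subset of columns is thresholded
to binary; and the combined mask is imposed on the complete data.

Structured missingness depends only on fully observed baseline variables,
so the combined mechanism is MAR by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import expit, logit, ndtr, ndtri

from ._stats import soft_rank_auc, substream
from .correlation import sample_sigma
from .params import ClusterSpec, GenerativeParams


@dataclass
class LogisticCalibration:
    """Calibrated per-cluster logistic SM model (shared coefficient)."""

    intercept: float
    weight: float
    achieved_auc: float
    achieved_pi: float


@dataclass
class SyntheticDataset:
    """A generated cohort with complete data, mask and all ground truth."""

    X_complete: NDArray[np.float64]
    M: NDArray[np.int8]
    b_sm: dict[int, NDArray[np.int8]]
    p_um: NDArray[np.float64]
    sigma_true: NDArray[np.float64]
    sigma_projected: bool
    thresholds: dict[int, tuple[float, float]]   # column -> (positive rate, latent cutoff)
    labels: NDArray[np.int64]
    var_types: NDArray
    var_ids: NDArray
    calibrations: dict[int, LogisticCalibration]
    params: GenerativeParams | None = None
    seed: int | None = None
    regime: str = "structured"

    _x_missing: NDArray[np.float64] | None = field(default=None, repr=False)

    @property
    def X_missing(self) -> NDArray[np.float64]:
        if self._x_missing is None:
            xm = self.X_complete.copy()
            xm[self.M == 1] = np.nan
            self._x_missing = xm
        return self._x_missing

    def save(self, out_dir: str | Path) -> None:
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cols = list(self.var_ids)
        pd.DataFrame(self.X_complete, columns=cols).to_csv(out / "X_complete.tsv", sep="\t", index=False)
        pd.DataFrame(self.X_missing, columns=cols).to_csv(out / "X_missing.tsv", sep="\t", index=False)
        pd.DataFrame(self.M, columns=cols).to_csv(out / "M.tsv", sep="\t", index=False)
        pd.DataFrame({"var_id": cols, "type": list(self.var_types)}).to_csv(
            out / "types.tsv", sep="\t", index=False
        )
        truth = {
            "regime": self.regime,
            "seed": self.seed,
            "p_um": self.p_um.tolist(),
            "pi_realized": {str(c): float(np.mean(b)) for c, b in self.b_sm.items()},
            "calibrations": {
                str(c): {
                    "intercept": cal.intercept,
                    "weight": cal.weight,
                    "achieved_auc": cal.achieved_auc,
                    "achieved_pi": cal.achieved_pi,
                }
                for c, cal in self.calibrations.items()
            },
            "thresholds": {str(j): list(v) for j, v in self.thresholds.items()},
        }
        import json

        (out / "truth.json").write_text(json.dumps(truth) + "\n")


def simulate_core(
    n: int, sigma_core: NDArray, rng: np.random.Generator
) -> NDArray[np.float64]:
    """n i.i.d. rows from N(0, sigma_core)."""
    sigma_core = np.asarray(sigma_core, dtype=float)
    try:
        chol = cholesky(sigma_core, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "sigma_core is not positive definite; project it with nearest_correlation first"
        ) from exc
    z = rng.standard_normal((n, sigma_core.shape[0]))
    return z @ chol.T


def calibrate_logistic(
    core_cov: NDArray,
    auc_target: float,
    pi_target: float,
    auc_tol: float = 0.005,
    pi_tol: float = 0.005,
    mc_n: int = 200_000,
    rng: np.random.Generator | None = None,
    max_grow: int = 40,
    max_bisect: int = 60,
) -> LogisticCalibration:
    """Nested binary search for the SM logistic model's (intercept, weight).

    The linear score of subject i is s_i = w * sum_j core_ij, whose
    population law is N(0, w^2 * 1'Sigma_cc 1).  The outer bisection adjusts
    the shared weight w to match the AUC (monotone increasing in w >= 0);
    for every candidate w the inner bisection sets the intercept so the
    positive rate matches pi_c.  Both quantities are evaluated on a fixed
    Monte-Carlo draw of size ``mc_n``, marginalising the Bernoulli outcomes
    analytically so the search targets are deterministic and monotone.
    """
    if not 0.5 <= auc_target < 1.0:
        raise ValueError("auc_target must lie in [0.5, 1)")
    if not 0.0 < pi_target < 1.0:
        raise ValueError("pi_target must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    var_sum = float(np.asarray(core_cov, dtype=float).sum())
    if var_sum <= 0:
        raise ValueError("core covariance has non-positive total variance")
    t = np.sort(rng.standard_normal(mc_n)) * np.sqrt(var_sum)

    def solve_intercept(w: float) -> float:
        lo, hi = -40.0, 40.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if float(np.mean(expit(mid + w * t))) < pi_target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def evaluate(w: float) -> tuple[float, float, float]:
        b0 = solve_intercept(w)
        p = expit(b0 + w * t)
        return b0, soft_rank_auc(t, p), float(p.mean())

    if auc_target <= 0.5 + 1e-12:
        b0 = float(logit(pi_target))
        return LogisticCalibration(b0, 0.0, 0.5, pi_target)

    w_lo, w_hi = 0.0, 1.0 / np.sqrt(var_sum)
    b0, auc_hi, _ = evaluate(w_hi)
    grew = 0
    while auc_hi < auc_target and grew < max_grow:
        w_lo = w_hi
        w_hi *= 2.0
        b0, auc_hi, _ = evaluate(w_hi)
        grew += 1
    if auc_hi < auc_target:
        raise RuntimeError(
            f"could not bracket AUC target {auc_target}; best achieved {auc_hi:.4f}"
        )
    best = None
    for _ in range(max_bisect):
        w_mid = 0.5 * (w_lo + w_hi)
        b0, auc_mid, pi_mid = evaluate(w_mid)
        best = LogisticCalibration(b0, w_mid, auc_mid, pi_mid)
        if abs(auc_mid - auc_target) <= 0.25 * auc_tol:
            break
        if auc_mid < auc_target:
            w_lo = w_mid
        else:
            w_hi = w_mid
    assert best is not None
    if abs(best.achieved_auc - auc_target) > auc_tol or abs(best.achieved_pi - pi_target) > pi_tol:
        raise RuntimeError(
            "calibration tolerance not reached: achieved "
            f"AUC={best.achieved_auc:.4f} (target {auc_target}), "
            f"pi={best.achieved_pi:.4f} (target {pi_target})"
        )
    return best


def generate_sm(
    core_slice: NDArray, calibration: LogisticCalibration, rng: np.random.Generator
) -> NDArray[np.int8]:
    """Bernoulli SM indicators from the calibrated logistic model."""
    s = calibration.weight * np.asarray(core_slice, dtype=float).sum(axis=1)
    p = expit(calibration.intercept + s)
    return (rng.random(p.size) < p).astype(np.int8)


def generate_um(
    labels: NDArray,
    clusters: list[ClusterSpec],
    n: int,
    rng: np.random.Generator,
) -> tuple[NDArray[np.float64], NDArray[np.int8]]:
    """Per-variable Beta UM rates and the i.i.d. Bernoulli UM mask."""
    labels = np.asarray(labels)
    d = labels.size
    p_um = np.zeros(d)
    for spec in clusters:
        if spec.is_baseline:
            continue
        cols = np.flatnonzero(labels == spec.cluster_id)
        p_um[cols] = rng.beta(spec.alpha, spec.beta, size=cols.size)
    mask = (rng.random((n, d)) < p_um[None, :]).astype(np.int8)
    return p_um, mask


def complete_data(
    core: NDArray,
    sigma: NDArray,
    core_positions: NDArray,
    rng: np.random.Generator,
) -> NDArray[np.float64]:
    """Fill in the non-core columns from the conditional multivariate normal.

    rest | core ~ N(Sigma_rc Sigma_cc^-1 x_core,
                    Sigma_rr - Sigma_rc Sigma_cc^-1 Sigma_cr).
    Core columns of the output equal the input core data exactly.
    """
    core = np.asarray(core, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    d = sigma.shape[0]
    core_positions = np.asarray(core_positions, dtype=np.int64)
    rest = np.setdiff1d(np.arange(d), core_positions)
    cc = sigma[np.ix_(core_positions, core_positions)]
    rc = sigma[np.ix_(rest, core_positions)]
    rr = sigma[np.ix_(rest, rest)]
    try:
        factor = cho_factor(cc)
    except np.linalg.LinAlgError as exc:
        raise ValueError("core block of sigma is not positive definite") from exc
    a = cho_solve(factor, rc.T).T                  # Sigma_rc Sigma_cc^-1
    cond = rr - a @ rc.T
    cond = (cond + cond.T) / 2.0
    w, v = np.linalg.eigh(cond)
    chol_like = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((core.shape[0], rest.size))
    out = np.empty((core.shape[0], d))
    out[:, core_positions] = core
    out[:, rest] = core @ a.T + z @ chol_like.T
    return out


def threshold_binaries(
    latent: NDArray,
    binary_positions: NDArray,
    labels: NDArray,
    clusters: list[ClusterSpec],
    rng: np.random.Generator,
    fallback_rate: float = 0.5,
) -> tuple[NDArray[np.float64], dict[int, tuple[float, float]]]:
    """Threshold designated latent columns to {0, 1}.

    For each binary column a positive rate p is drawn from its cluster's
    empirical rate pool (``fallback_rate`` when no pool is configured) and
    the cutoff is the upper p-quantile of the standard normal: the value is
    1 iff the latent variable exceeds Phi^-1(1 - p).
    """
    x = np.asarray(latent, dtype=float).copy()
    labels = np.asarray(labels)
    pools = {c.cluster_id: c.binary_rates for c in clusters}
    thresholds: dict[int, tuple[float, float]] = {}
    for j in np.asarray(binary_positions, dtype=np.int64):
        pool = pools.get(int(labels[j]))
        p = float(rng.choice(pool)) if pool else float(fallback_rate)
        cutoff = float(ndtri(1.0 - p))
        x[:, j] = (x[:, j] > cutoff).astype(float)
        thresholds[int(j)] = (p, cutoff)
    return x, thresholds


def assemble_dataset(
    params: GenerativeParams,
    n: int | None = None,
    seed: int | None = None,
    mc_n: int = 200_000,
) -> SyntheticDataset:
    """Run the full generation pipeline for one synthetic cohort.

    The mask is the elementwise union of structured missingness (a subject
    structurally missing for cluster c loses all cluster-c columns) and the
    unstructured MCAR mask.  All randomness flows from the master seed via
    named substreams, so identical parameters give identical datasets.
    """
    n = params.n if n is None else int(n)
    seed = params.seed if seed is None else int(seed)
    labels = params.labels()
    var_types = params.var_types()

    core = simulate_core(n, params.sigma_core, substream(seed, "core"))

    calibrations: dict[int, LogisticCalibration] = {}
    b_sm: dict[int, NDArray[np.int8]] = {}
    for spec in params.clusters[1:]:
        idx = np.asarray(params.core_assignment[spec.cluster_id], dtype=np.int64)
        cal = calibrate_logistic(
            params.sigma_core[np.ix_(idx, idx)],
            auc_target=spec.auc,
            pi_target=spec.pi,
            mc_n=mc_n,
            rng=substream(seed, "calibration", spec.cluster_id),
        )
        calibrations[spec.cluster_id] = cal
        b_sm[spec.cluster_id] = generate_sm(
            core[:, idx], cal, substream(seed, "sm", spec.cluster_id)
        )

    p_um, mask = generate_um(labels, params.clusters, n, substream(seed, "um"))

    sigma, projected = sample_sigma(
        params.histograms,
        labels,
        sigma_core=params.sigma_core,
        core_positions=params.core_positions(),
        rng=substream(seed, "sigma"),
    )
    latent = complete_data(core, sigma, params.core_positions(), substream(seed, "core", 1))
    x_complete, thresholds = threshold_binaries(
        latent, params.binary_positions(), labels, params.clusters, substream(seed, "thresholds")
    )

    for spec in params.clusters[1:]:
        cols = params.cluster_columns(spec.cluster_id)
        rows = b_sm[spec.cluster_id] == 1
        mask[np.ix_(rows, cols)] = 1

    return SyntheticDataset(
        X_complete=x_complete,
        M=mask,
        b_sm=b_sm,
        p_um=p_um,
        sigma_true=sigma,
        sigma_projected=projected,
        thresholds=thresholds,
        labels=labels,
        var_types=var_types,
        var_ids=params.var_ids(),
        calibrations=calibrations,
        params=params,
        seed=seed,
    )


def mcar_comparator(
    dataset: SyntheticDataset, rng: np.random.Generator
) -> SyntheticDataset:
    """Rate-matched completely unstructured comparator arm.

    Keeps X_complete and replaces the mask with i.i.d. Bernoulli entries per
    cluster, at that cluster's realised total missingness rate.
    """
    labels = dataset.labels
    n = dataset.X_complete.shape[0]
    mask = np.zeros_like(dataset.M)
    for c in sorted(set(int(x) for x in labels)):
        cols = np.flatnonzero(labels == c)
        rate = float(dataset.M[:, cols].mean())
        if rate > 0:
            mask[:, cols] = (rng.random((n, cols.size)) < rate).astype(np.int8)
    return SyntheticDataset(
        X_complete=dataset.X_complete,
        M=mask,
        b_sm={},
        p_um=dataset.p_um,
        sigma_true=dataset.sigma_true,
        sigma_projected=dataset.sigma_projected,
        thresholds=dataset.thresholds,
        labels=labels,
        var_types=dataset.var_types,
        var_ids=dataset.var_ids,
        calibrations=dataset.calibrations,
        params=dataset.params,
        seed=dataset.seed,
        regime="mcar",
    )
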