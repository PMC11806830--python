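"""End-to-end analysis: estimate generative parameters from incomplete data.

Chains the estimation stages — mask, variable-wise distances, complete-
linkage clustering, SM identification, Beta method-of-moments UM fits,
LASSO-LR core-variable selection with cross-validated AUC, core correlation
and cluster-pair correlation histograms — into one call that emits a
:class:`~missgen.params.GenerativeParams` ready for generation, plus a
per-variable cluster report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import informative, structure
from .correlation import estimate_histograms
from .params import ClusterSpec, GenerativeParams
from .structure import DataMatrix

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    params: GenerativeParams
    report: pd.DataFrame
    assignment: structure.ClusterAssignment
    sm: structure.StructuredMissingness
    um: structure.UMRateModel
    auc: dict[int, float]
    core_model: informative.CoreVariableModel
    screened: pd.DataFrame


def analyze_dataset(
    data: DataMatrix,
    n_clusters: int,
    sm_threshold: float = 0.9,
    lam: float | dict[int, float] | None = None,
    lambda_grid=None,
    folds: int = 5,
    bins: int = 40,
    min_overlap: int = 100,
    max_missing: float | None = None,
    drop_cluster_missing: float | None = 0.95,
    seed: int = 0,
    n_target: int | None = None,
) -> AnalysisResult:
    """Estimate all generative parameters from an incomplete data matrix.

    ``lam`` fixes the LASSO penalty (per-sample scale) globally or per
    cluster; when None, the penalty minimising cross-validated loss over
    ``lambda_grid`` is used.  Clusters whose median variable-wise missingness
    exceeds ``drop_cluster_missing`` are dropped from the generative model
    (they are too missing to be useful for imputation studies).
    """
    keep, screened = structure.screen_variables(data, max_missing=max_missing)
    if keep.size < data.d:
        data = DataMatrix(
            values=data.values[:, keep],
            var_types=data.var_types[keep],
            var_ids=data.var_ids[keep],
            subject_ids=data.subject_ids,
        )
    mask = structure.compute_mask(data)
    rates = mask.mean(axis=0)
    dist = structure.variable_distance(mask)
    assignment = structure.cluster_variables(dist, n_clusters, missing_rates=rates)

    # drop clusters that are almost entirely missing
    dropped: list[int] = []
    for c in assignment.cluster_ids:
        if c == assignment.baseline_cluster:
            continue
        med = float(np.median(rates[assignment.members(c)]))
        if drop_cluster_missing is not None and med > drop_cluster_missing:
            dropped.append(c)
    if dropped:
        logger.info("dropping clusters %s (median missingness too high)", dropped)
        keep_cols = ~np.isin(assignment.labels, dropped)
        data = DataMatrix(
            values=data.values[:, keep_cols],
            var_types=data.var_types[keep_cols],
            var_ids=data.var_ids[keep_cols],
            subject_ids=data.subject_ids,
        )
        mask = mask[:, keep_cols]
        rates = rates[keep_cols]
        dist = dist[np.ix_(keep_cols, keep_cols)]
        assignment = structure.cluster_variables(
            dist, n_clusters - len(dropped), missing_rates=rates
        )

    sm = structure.identify_sm(mask, assignment, threshold=sm_threshold)
    um = structure.estimate_um(mask, assignment, sm)

    base_cols = assignment.members(assignment.baseline_cluster)
    x0 = data.values[:, base_cols]
    base_types = data.var_types[base_cols]

    if lambda_grid is None:
        lambda_grid = np.exp(np.linspace(np.log(1e-4), np.log(0.3), 6))

    predictors: dict[int, informative.SMPredictor] = {}
    auc: dict[int, float] = {}
    lam_used: dict[int, float] = {}
    non_baseline = [c for c in assignment.cluster_ids if c != assignment.baseline_cluster]
    for c in non_baseline:
        if isinstance(lam, dict):
            lam_c = lam[c]
        elif lam is not None:
            lam_c = float(lam)
        else:
            rep = informative.lambda_report(
                x0, sm.b[c], lambda_grid, folds=folds, seed=seed, var_types=base_types
            )
            lam_c = float(rep.loc[rep["val_loss"].idxmin(), "lambda"])
        lam_used[c] = lam_c
        predictors[c] = informative.fit_sm_predictor(x0, sm.b[c], lam_c)
        auc[c] = informative.cv_auc(x0, sm.b[c], lam_c, folds=folds, seed=seed)
        predictors[c].auc = auc[c]
        n_bin_core = int(np.sum(base_types[predictors[c].core_idx] == "binary"))
        logger.info(
            "cluster %d: lambda=%.4g, cv AUC=%.4f, %d core variables (%d binary)",
            c, lam_c, auc[c], predictors[c].core_idx.size, n_bin_core,
        )

    core_union = np.unique(np.concatenate([predictors[c].core_idx for c in non_baseline]))
    if core_union.size < 2:
        warnings.warn(
            "fewer than two core variables selected; sigma_core falls back to identity "
            "over the two strongest baseline predictors",
            RuntimeWarning,
            stacklevel=2,
        )
        strength = np.zeros(x0.shape[1])
        for c in non_baseline:
            strength += np.abs(predictors[c].coef)
        core_union = np.argsort(-strength, kind="stable")[:2]
        core_union.sort()
    x0_core = x0[:, core_union]
    if np.isnan(x0_core).any():
        mu = np.nanmean(x0_core, axis=0)
        idx = np.where(np.isnan(x0_core))
        x0_core = x0_core.copy()
        x0_core[idx] = np.take(mu, idx[1])
    sigma_core = informative.estimate_sigma_core(x0_core)
    core_model = informative.CoreVariableModel(
        predictors=predictors, core_union=core_union, sigma_core=sigma_core
    )
    core_row = {int(g): i for i, g in enumerate(core_union)}

    hists = estimate_histograms(data, assignment, bins=bins, min_overlap=min_overlap)

    # assemble GenerativeParams: baseline first, then clusters by descending size
    specs: list[ClusterSpec] = []
    core_assignment: dict[int, list[int]] = {}
    for c in [assignment.baseline_cluster] + non_baseline:
        cols = assignment.members(c)
        types_c = data.var_types[cols]
        n_binary = int(np.sum(types_c == "binary"))
        pool = [
            float(np.nanmean(data.values[:, j]))
            for j in cols[types_c == "binary"]
        ]
        pool = [r for r in pool if 0.0 < r < 1.0] or None
        if c == assignment.baseline_cluster:
            # generation treats all core variables as continuous; cap the
            # baseline binary count so the core fits in the continuous block
            n_binary = min(n_binary, cols.size - core_union.size)
            specs.append(ClusterSpec(c, cols.size, max(n_binary, 0), binary_rates=pool))
        else:
            specs.append(
                ClusterSpec(
                    c, cols.size, n_binary,
                    pi=sm.pi[c], auc=min(auc[c], 1.0 - 1e-6),
                    alpha=um.alpha[c], beta=um.beta[c], binary_rates=pool,
                )
            )
            rows = [core_row[int(g)] for g in predictors[c].core_idx if int(g) in core_row]
            core_assignment[c] = rows or [core_row[int(g)] for g in core_union[:1]]

    params = GenerativeParams(
        n=n_target or data.n,
        clusters=specs,
        sigma_core=sigma_core,
        core_assignment=core_assignment,
        histograms=hists,
        seed=seed,
        meta={
            "source": "analyze",
            "lambda": {str(k): v for k, v in lam_used.items()},
            "dropped_clusters": dropped,
            "core_var_ids": [str(data.var_ids[base_cols[g]]) for g in core_union],
        },
    )

    report = pd.DataFrame(
        {
            "var_id": data.var_ids,
            "cluster": assignment.labels,
            "missing_rate": rates,
            "p_um": um.p_um,
        }
    )
    return AnalysisResult(
        params=params,
        report=report,
        assignment=assignment,
        sm=sm,
        um=um,
        auc=auc,
        core_model=core_model,
        screened=screened,
    )
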