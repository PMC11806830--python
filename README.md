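# missgen

Generative modelling of **structured missingness** for large epidemiological
cohorts: estimate a generative model from any incomplete mixed-type data
matrix, simulate calibrated synthetic cohorts with realistic "blocky"
informative missingness and full ground truth, and benchmark imputation
methods on them.

## Why

Large cohorts (the motivating case is a biobank brain-imaging cohort with
tens of thousands of mixed continuous/binary phenotypes) lose data in two
very different ways: *structured missingness* (SM) — non-participation in a
sub-study wipes out a whole block of variables for a subset of subjects —
and residual *unstructured missingness* (UM). SM is informative: who drops
out of a follow-up is predictable from baseline variables, which makes the
mechanism MAR, not MCAR. Most imputation benchmarks simulate none of this.
`missgen` reproduces it from data:

- variables are clustered into sub-studies by complete-linkage clustering of
  their missingness patterns (distance = proportion of discordant
  missingness indicators);
- a subject is structurally missing for cluster c when >= 90% of the
  cluster's variables are missing; the SM rate is pi_c;
- SM is driven by baseline "core" variables through a logistic model whose
  predictability AUC_c is estimated by cross-validated L1-penalised logistic
  regression and *re-calibrated exactly* in generation by a nested binary
  search on the model's shared coefficient and intercept;
- UM rates are per-variable draws from Beta(alpha_c, beta_c), fitted by the
  method of moments;
- values are latent-Gaussian with a full correlation matrix Sigma* sampled
  from per-cluster-pair correlation histograms and projected to the nearest
  positive-definite correlation matrix (Higham's alternating projections);
  binary variables are thresholded latent normals.

For chained-equation imputation in high dimensions the package also
implements a mixed-type predictor-selection score
`S_jj' = V_jj' x (maximum expected error reduction from j')`, where
`V = M^T(1 - M)` counts how often candidate j' is observed exactly when
target j is missing — predictors that are never co-observed are useless no
matter how correlated, and S handles all four continuous/binary type
combinations (via the biserial correlation and bivariate-normal orthant
probabilities for binary targets).

## Worked example

The packaged configuration `ukb_nidp_defaults.json` carries the published
cluster parameters of the motivating cohort (follow-up clusters labelled 2
and 3: AUC = 0.7167/0.8683, pi = 0.26/0.29, (alpha, beta) = (6.0, 4.6) and
(0.44, 4.4)) on a 1 000-variable desk-scale layout:

```python
import numpy as np
import missgen

params = missgen.default_params(n=20_000, seed=0)
ds = missgen.assemble_dataset(params)        # ~40 s on one CPU

for c, cal in ds.calibrations.items():
    print(f"cluster {c}: calibrated AUC={cal.achieved_auc:.4f} "
          f"pi={cal.achieved_pi:.4f} -> realized SM rate {ds.b_sm[c].mean():.4f}")
print("cluster-2 total missingness:",
      round(float(ds.M[:, ds.labels == 2].mean()), 3))
```

prints

```
cluster 2: calibrated AUC=0.7157 pi=0.2600 -> realized SM rate 0.2597
cluster 3: calibrated AUC=0.8683 pi=0.2900 -> realized SM rate 0.2887
cluster-2 total missingness: 0.679
```

i.e. the SM logistic models hit the published AUC/pi targets within the
0.005 calibration tolerance, and cluster 2's total missingness matches the
composition pi + (1 - pi) * alpha/(alpha + beta) ~ 0.26 + 0.74 x 0.566.
The returned `SyntheticDataset` carries the complete data, the mask, the
masked data and all ground truth (Sigma*, SM indicators, UM rates, binary
thresholds), so imputation error can be scored exactly.

The same pipeline runs from the shell:

```bash
missgen generate --n 20000 --seed 0 --mcar-arm --out synth/
missgen analyze  --data synth/X_missing.tsv --types synth/types.tsv \
                 --clusters 3 --lambda 0.003 --out analysis/
missgen score    --data synth/X_missing.tsv --types synth/types.tsv \
                 --strategy mixed_score --k 50 --out predictors.tsv
missgen evaluate --B 5 --seed 0 --out report/
```

`analyze` emits a `params.json` (the same schema as the packaged defaults)
estimated from the incomplete table, closing the loop: given a recovered
partition, pi_c and AUC_c come back within ~0.01 at this scale. (Recovery
of the partition itself by complete-linkage clustering is only approximate
when unstructured missingness rates are widely spread — see the round-trip
discussion in `docs/methods.md`.) `evaluate` scores mean imputation, SoftImpute-style low-rank
completion and deterministic chained-equation (ICE) imputation — with
predictor selection by |correlation|, co-observation or the mixed score —
by per-variable MSE (continuous) and balanced accuracy (binary), on both
the structured cohort and a rate-matched fully-MCAR comparator arm.

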