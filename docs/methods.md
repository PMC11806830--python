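# Methods

`missgen` models a subjects-by-variables matrix **X** (n x d, mixed
continuous/binary) together with its missingness indicator **M**
(M_ij = 1 iff X_ij is unobserved), for cohorts assembled from a baseline
study plus follow-up sub-studies. It has three stages: *analyze* (estimate
generative parameters from incomplete data), *generate* (simulate calibrated
synthetic cohorts with ground truth) and *evaluate* (benchmark imputation
methods on them).

## The generative model

Variables belong to C clusters (sub-studies), c = 0 being a fully observed
baseline. The model's parameters are:

- {rho}_{c,c'} — the distribution of latent-scale correlations between
  variables of clusters c and c', stored as histograms on [-1, 1];
- pi_c — the probability that a subject is structurally missing (SM) for
  cluster c, i.e. loses the whole block of cluster-c variables;
- AUC_c — the predictability of that SM event from the baseline "core"
  variables, via a logistic model whose coefficients are all equal;
- (alpha_c, beta_c) — shape parameters of the Beta law from which each
  variable's unstructured-missingness (UM) rate p_j^um is drawn; UM is MCAR
  given the rates;
- Sigma_core — the correlation matrix of the core variables.

Data are latent-Gaussian: all variables arise from a zero-mean,
unit-variance multivariate normal with correlation Sigma*; binary variables
are thresholded at the upper-p quantile (value 1 iff the latent exceeds
Phi^-1(1-p)), with positive rates p resampled from per-cluster empirical
pools. Because SM depends only on fully observed baseline columns and
exogenous noise, the combined mechanism is MAR by construction.

## Estimation (analyze)

1. **Mask and distances.** D^v_{jj'} = (1/n) #\{i : M_ij != M_ij'\}, the
   proportion of discordant indicators, computed with mask algebra
   (three matrix products), exactly.
2. **Clustering.** Complete-linkage agglomerative clustering of D^v, cut at
   a user-chosen C (merge heights are exposed to support that choice).
   Labels are canonicalised: the cluster with the lowest mean missingness is
   the baseline (label 0), the rest are numbered by descending size, so the
   result is stable under column permutations.
3. **SM identification.** Subject i is structurally missing for cluster c
   when at least 90% (configurable `sm_threshold`) of cluster-c variables
   are missing; pi_c is the mean of that indicator.
4. **UM rates.** p_j^um is variable j's missing fraction among subjects
   *without* SM for j's cluster; (alpha_c, beta_c) follow by method of
   moments: with sample mean m and variance v, t = m(1-m)/v - 1,
   alpha = m t, beta = (1-m) t. If v >= m(1-m) (moments infeasible) or
   v ~ 0, v is clipped to 0.99 m(1-m) with a warning (strict mode raises).
5. **Core variables.** Per non-baseline cluster, an L1-penalised logistic
   regression of the SM indicator on the (standardized) baseline columns;
   non-zero coefficients define the core set; AUC_c is the mean
   out-of-fold Mann-Whitney AUC over 5 stratified folds. The penalty
   `lam` is on a per-sample scale ((1/n) sum loss + lam ||w||_1); a
   cross-validated trade-off table (loss, AUC, core count, binary share)
   supports choosing a value that keeps only strongly predictive cores.
   Sigma_core is the sample correlation of the selected cores, projected to
   positive definite when needed.
6. **Correlation histograms.** Pairwise-complete Pearson correlations for
   every variable pair (computed by mask algebra; pairs with fewer than
   `min_overlap` = 100 co-observed rows are skipped), histogrammed per
   cluster pair with 40 bins on [-1, 1]. Mixed pairs use plain Pearson on
   the observed 0/1 and continuous values; no latent-scale estimator is
   substituted here.

Variables with zero observed variance are dropped before analysis, with a
manifest. A cap on variable-wise missingness (`max_missing`) exists but is
off by default: with the default generative parameters, one follow-up
cluster averages ~68% total missingness, and a 40% cap would silently
delete it. Clusters whose *median* missingness exceeds
`drop_cluster_missing` (default 0.95) are dropped from the emitted model,
mirroring the exclusion of near-empty sub-studies.

## Generation

Steps, each on its own named substream of one master seed (so stages are
reproducible in isolation):

1. Draw core data from N(0, Sigma_core).
2. **Calibrate** each cluster's SM logistic model by nested binary search:
   the linear score is s_i = w * sum(core_i); the outer bisection tunes the
   shared weight w to the target AUC_c (monotone in w), the inner bisection
   tunes the intercept to the target pi_c. Both are evaluated on a fixed
   Monte-Carlo draw of 2e5 scores with the Bernoulli outcomes marginalised
   analytically (a Rao-Blackwellised rank AUC), making the search targets
   deterministic and monotone. Tolerances: 0.005 on both AUC and pi;
   the search brackets w geometrically and errors out with the best
   achieved pair if a target is unreachable.
3. Draw SM indicators b_c ~ Bernoulli(sigmoid(b0_c + w_c sum(core_i))).
4. Draw UM rates p_j^um ~ Beta(alpha_c, beta_c) and an i.i.d. Bernoulli UM
   mask.
5. Sample Sigma* entrywise from the cluster-pair histograms (bin chosen by
   its probability, uniform within the bin), overwrite the core block with
   Sigma_core, and project to the nearest positive-definite correlation
   matrix when the smallest eigenvalue is below delta = 1e-8. The
   projection is Higham's alternating-projections scheme (PSD projection
   with Dykstra's correction alternated with unit-diagonal restoration,
   Frobenius tolerance 1e-8), with a final eigenvalue floor at delta. The
   core block is re-imposed after projection and projection repeated for up
   to 3 passes; a persistent conflict returns the projected
   (approximate-core) matrix with a warning.
6. Complete the non-core columns from the conditional multivariate normal
   given the core, threshold the designated binary columns, and impose the
   union of the SM block mask and the UM mask.

A rate-matched completely unstructured comparator replaces the mask by
i.i.d. Bernoulli entries per cluster at the cluster's realized total
missingness rate, keeping X complete identical.

## Predictor-selection scores

For chained-equation imputation each target j needs a small predictor set.
The co-observation matrix V = M^T (1 - M) counts, for target j and
candidate j', rows where j is missing and j' observed. The mixed-type
score S_jj' multiplies V_jj' by the maximum expected error reduction
obtainable from j' under the latent-Gaussian model:

- continuous target: S = V rho^2 (also with a binary predictor);
- binary target (rate p, threshold D = Phi^-1(p)), continuous predictor:
  the biserial correlation rho_b = rho sqrt(p(1-p))/phi(D) (clipped to
  [-1, 1] with a warning) drives a conditional-median prediction rule whose
  accuracy is a pair of semi-infinite Gaussian integrals; these reduce
  exactly to bivariate-normal CDFs (acc = 1 - Phi(D/rho_b) - Phi(D) +
  2 Phi2(D/rho_b, D; rho_b) for rho_b > 0 and the mirrored form for
  rho_b < 0), evaluated through Owen's T function; a direct adaptive
  quadrature of the integrals (abs. tol. 1e-8) is kept as a cross-check;
  S = V (acc - max(p, 1-p));
- two binary variables: the 2x2 joint table follows from the
  phi-coefficient identity P(1,1) = p p' + rho sqrt(p(1-p)p'(1-p'))
  (cells clipped to the Frechet bounds; clearly infeasible rho raises),
  and S = V (table accuracy - max(p, 1-p)).

S is directional (rows = targets) and non-negative; S = 0 whenever rho = 0
or V = 0. Top-k lists (strategies: |r|, V, or S) drop zero-criterion
candidates and break ties by ascending variable index so selection is
deterministic.

## Imputation benchmark

- **mean**: column means; binary columns binarised at 0.5.
- **softimpute**: iterative SVD completion at rank
  r = max(1, round(f * min(n, d))), f in {5%, 15%, 30%}, with singular
  values soft-thresholded by sigma_1/50. The soft threshold matters: a pure
  hard-rank iteration admits spurious self-consistent fixed points when r
  exceeds the effective rank (observed on a rank-1 fixture).
- **iterative (ICE)**: mean initialisation, then cyclic single-variable
  regressions (Bayesian ridge for continuous targets, ridge-penalised
  logistic with C = 1 for binary) on the selected predictors' current
  values, replacing missing entries by point predictions; no posterior
  noise anywhere, so the result is deterministic. Variable order: ascending
  missingness rate; stopping: largest relative change of imputed entries
  below 1e-3 or `max_iter` (default 10) sweeps.

Accuracy is scored per variable over its truly missing entries: MSE for
continuous (all continuous variables have unit variance, so mean imputation
sits near 1.0), balanced accuracy for binary (absent, with a log, when the
true missing values are single-class). The study harness runs B replicates
x methods x {structured, MCAR comparator} and reports a tidy long-format
table plus per-(regime, method, cluster) medians.

## Default configuration and problem sizes

The packaged configuration carries the published cluster parameters of the
motivating cohort — AUC = (0.7167, 0.8683), pi = (0.26, 0.29),
(alpha, beta) = (6.0, 4.6) and (0.44, 4.4) for the two follow-up clusters —
on a desk-scale layout chosen once: 1 000 variables (baseline 200 with 60%
binary; follow-ups 500/300 with 60%/13% binary, roughly preserving the
published binary shares), 8 + 12 core variables with exchangeable
within-cluster correlation 0.30 and zero between-cluster core correlation
(core blocks of different clusters are uncorrelated, so SM indicators of
different clusters are independent — no cross-cluster SM dependence is part
of the model). Correlation histograms emulate a sub-study cohort: within a
cluster a 60/40 mixture of a near-zero bulk (sd 0.12) and a positively
correlated tail (mean 0.45, sd 0.10); between clusters a zero-centred
component (sd 0.12). Binary positive-rate pools are Beta quantiles skewed
towards low prevalence (one-hot-like variables). A reduced layout
(d = 300, n = 5 000) is used for the imputation study so that the full
B = 5 x 6-method x 2-regime grid runs on a single CPU in minutes.

## What the synthetic data does and does not emulate

The generator reproduces blocky informative missingness, Beta-spread MCAR
noise, and the dependence of co-missingness on cluster membership. It does
not emulate non-Gaussian marginals, outliers, within-cluster factor
structure beyond exchangeable-plus-noise correlations, cross-cluster SM
dependence, or MNAR mechanisms; conclusions about imputation methods that
are sensitive to those features do not transfer.

Two quantitative caveats discovered while validating the round trip are
worth recording. First, when d is large, the sampled Sigma* is far from
positive definite (a random symmetric perturbation with entry scale s has
eigenvalues down to about -2 s sqrt(d)), so the projection shrinks
correlation magnitudes noticeably; realized correlations are therefore
closer to zero than the input histograms, exactly as in any entrywise
simulation of this kind. Second, with i.i.d. per-variable UM rates at the
spread of Beta(6.0, 4.6), a small fraction (~2-4%) of low-UM follow-up
variables are genuinely closer, in complete-linkage distance, to the fully
observed baseline than to the rest of their own cluster, so the planted
partition is only approximately recoverable; and with a few hundred
variables per cluster, the method-of-moments fit differs from the
generating (alpha, beta) by the sampling noise of the rate draws themselves
(relative error ~ sqrt(2/d_c)). pi_c and AUC_c are insensitive to both
effects and are recovered to within 0.01-0.03 at the default scale.

## Numerical choices

- Rank AUC via average ranks (ties share half credit); exact.
- Logistic fits: liblinear, tol 1e-6, predictors standardized; the
  per-sample penalty maps to scikit-learn's C = 1/(n lam).
- Nearest-correlation: tol 1e-8 on the relative Frobenius change, max 200
  iterations (a warning reports the residual if reached), eigenvalue floor
  1e-8.
- Histogram sampling is inverse-CDF by bin; reproducible bit-for-bit given
  the seed.
- Beta moment inversion uses the unbiased (ddof = 1) sample variance.
- se(R^2) = sqrt(4 R^2 (1-R^2)^2 (n-p-1)^2 / ((n^2-1)(n+3))) is provided
  for reporting the uncertainty of OLS R^2 at cohort scale.

## Limitations

Only two-level variable typing (continuous/binary) is supported; ordinal
and categorical variables must be pre-encoded. The analysis stage assumes
the baseline cluster is (near-)fully observed; residual baseline
missingness is mean-filled with a warning before the logistic fits. The
MCAR comparator matches missingness rates per cluster, not per variable.
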