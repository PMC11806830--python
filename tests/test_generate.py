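import numpy as np
import pytest
from scipy.special import expit, logit

from missgen._stats import rank_auc, substream
from missgen.generate import (
    assemble_dataset,
    calibrate_logistic,
    complete_data,
    generate_sm,
    generate_um,
    mcar_comparator,
    simulate_core,
    threshold_binaries,
)
from missgen.params import ClusterSpec, GenerativeParams, benchmark_params
from missgen.correlation import CorrelationHistograms


def _tiny_params(n=3000, seed=0, pi=0.25, auc=0.75, alpha=2.0, beta=6.0):
    edges = np.linspace(-1, 1, 21)
    probs = np.zeros(20)
    probs[10] = 1.0  # correlations near zero
    hists = CorrelationHistograms(
        edges=edges,
        probs={(c, cp): probs for c, cp in [(0, 0), (0, 1), (1, 1)]},
    )
    sigma_core = np.full((3, 3), 0.3)
    np.fill_diagonal(sigma_core, 1.0)
    return GenerativeParams(
        n=n,
        clusters=[
            ClusterSpec(0, n_vars=6, n_binary=2, binary_rates=[0.4]),
            ClusterSpec(1, n_vars=8, n_binary=3, pi=pi, auc=auc, alpha=alpha, beta=beta,
                        binary_rates=[0.3, 0.6]),
        ],
        sigma_core=sigma_core,
        core_assignment={1: [0, 1, 2]},
        histograms=hists,
        seed=seed,
    )


class TestSimulateCore:
    def test_sample_covariance_and_reproducibility(self):
        sigma = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.2], [0.1, 0.2, 1.0]])
        x1 = simulate_core(100_000, sigma, np.random.default_rng(0))
        x2 = simulate_core(100_000, sigma, np.random.default_rng(0))
        assert np.array_equal(x1, x2)
        emp = np.cov(x1, rowvar=False)
        assert np.abs(emp - sigma).max() < 0.02
        assert np.abs(x1.mean(axis=0)).max() < 3 / np.sqrt(100_000) * 1.5

    def test_non_pd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            simulate_core(10, bad, np.random.default_rng(0))


class TestCalibration:
    def test_no_signal_case(self):
        sigma = np.eye(4)
        cal = calibrate_logistic(sigma, 0.5, 0.3, rng=np.random.default_rng(0))
        assert cal.weight == 0.0
        assert cal.intercept == pytest.approx(logit(0.3))

    def test_achieved_pi_monotone_in_intercept(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(50_000)
        w = 0.4
        pis = [float(np.mean(expit(b0 + w * t))) for b0 in (-2.0, -1.0, 0.0, 1.0)]
        assert np.all(np.diff(pis) > 0)

    @pytest.mark.parametrize(
        "auc,pi", [(0.7167, 0.26), (0.8683, 0.29)]
    )
    def test_published_targets_reproduced_on_fresh_sample(self, auc, pi):
        sigma = np.full((5, 5), 0.3)
        np.fill_diagonal(sigma, 1.0)
        cal = calibrate_logistic(sigma, auc, pi, rng=np.random.default_rng(2))
        assert cal.achieved_auc == pytest.approx(auc, abs=0.005)
        assert cal.achieved_pi == pytest.approx(pi, abs=0.005)
        rng = np.random.default_rng(3)
        core = simulate_core(200_000, sigma, rng)
        b = generate_sm(core, cal, rng)
        assert b.mean() == pytest.approx(pi, abs=0.01)
        score = core.sum(axis=1)
        assert rank_auc(score, b) == pytest.approx(auc, abs=0.01)


class TestUnstructured:
    def test_beta_mean_of_rates(self):
        labels = np.array([0] * 2 + [1] * 3000)
        clusters = [
            ClusterSpec(0, 2, 0),
            ClusterSpec(1, 3000, 0, pi=0.29, auc=0.8683, alpha=0.44, beta=4.4),
        ]
        p_um, mask = generate_um(labels, clusters, 50, np.random.default_rng(0))
        assert p_um[:2].tolist() == [0.0, 0.0]
        assert p_um[2:].mean() == pytest.approx(0.44 / 4.84, abs=0.01)

    def test_column_missing_fraction_matches_rate(self):
        labels = np.array([0] + [1] * 5)
        clusters = [
            ClusterSpec(0, 1, 0),
            ClusterSpec(1, 5, 0, pi=0.2, auc=0.6, alpha=5.0, beta=5.0),
        ]
        p_um, mask = generate_um(labels, clusters, 20_000, np.random.default_rng(1))
        emp = mask.mean(axis=0)
        se = np.sqrt(p_um[1:] * (1 - p_um[1:]) / 20_000)
        assert np.all(np.abs(emp[1:] - p_um[1:]) < 4 * se + 1e-9)


class TestCompleteData:
    def test_identity_sigma_gives_independent_rest(self):
        rng = np.random.default_rng(4)
        core = rng.standard_normal((100_000, 2))
        out = complete_data(core, np.eye(5), np.array([0, 1]), rng)
        r = np.corrcoef(out, rowvar=False)
        assert np.abs(r[:2, 2:]).max() < 0.02

    def test_joint_covariance_matches_sigma(self):
        rng = np.random.default_rng(5)
        sigma = np.array(
            [
                [1.0, 0.5, 0.3, 0.2],
                [0.5, 1.0, 0.25, 0.1],
                [0.3, 0.25, 1.0, 0.4],
                [0.2, 0.1, 0.4, 1.0],
            ]
        )
        core = simulate_core(100_000, sigma[:2, :2], rng)
        out = complete_data(core, sigma, np.array([0, 1]), rng)
        emp = np.cov(out, rowvar=False)
        assert np.abs(emp - sigma).max() < 0.02
        assert np.array_equal(out[:, :2], core)


class TestThresholding:
    def test_rate_and_latent_correlation(self):
        rng = np.random.default_rng(6)
        latent = rng.standard_normal((200_000, 2))
        clusters = [ClusterSpec(0, 2, 1, binary_rates=[0.5])]
        mixed, thresholds = threshold_binaries(
            latent, np.array([1]), np.zeros(2, int), clusters, rng
        )
        p, cutoff = thresholds[1]
        assert p == 0.5 and cutoff == pytest.approx(0.0)
        assert mixed[:, 1].mean() == pytest.approx(0.5, abs=0.005)
        r = np.corrcoef(mixed[:, 1], latent[:, 1])[0, 1]
        assert r == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_empirical_rate_within_binomial_error(self):
        rng = np.random.default_rng(7)
        latent = rng.standard_normal((50_000, 1))
        clusters = [ClusterSpec(0, 1, 1, binary_rates=[0.15])]
        mixed, thr = threshold_binaries(latent, np.array([0]), np.zeros(1, int), clusters, rng)
        p, _ = thr[0]
        se = np.sqrt(p * (1 - p) / 50_000)
        assert abs(mixed[:, 0].mean() - p) < 4 * se


class TestAssemble:
    def test_sm_semantics_mask_union_and_reproducibility(self):
        params = _tiny_params()
        ds1 = assemble_dataset(params, mc_n=50_000)
        ds2 = assemble_dataset(params, mc_n=50_000)
        assert np.array_equal(ds1.X_complete, ds2.X_complete)
        assert np.array_equal(ds1.M, ds2.M)
        cols = np.flatnonzero(ds1.labels == 1)
        sm_rows = ds1.b_sm[1] == 1
        assert ds1.M[np.ix_(sm_rows, cols)].all()
        # baseline cluster fully observed
        assert ds1.M[:, ds1.labels == 0].sum() == 0
        # missing entries are NaN exactly where M == 1
        assert np.array_equal(np.isnan(ds1.X_missing), ds1.M == 1)
        obs = ds1.M == 0
        assert np.array_equal(ds1.X_missing[obs], ds1.X_complete[obs])
        # binary columns are 0/1
        for j in np.flatnonzero(ds1.var_types == "binary"):
            assert set(np.unique(ds1.X_complete[:, j])) <= {0.0, 1.0}

    def test_cluster_missingness_rate_composition(self):
        # per-cluster total missingness ~ pi + (1 - pi) * alpha/(alpha+beta)
        params = benchmark_params(n=20_000, seed=11)
        ds = assemble_dataset(params, mc_n=50_000)
        spec3 = next(c for c in params.clusters if c.cluster_id == 3)
        expected = spec3.pi + (1 - spec3.pi) * spec3.alpha / (spec3.alpha + spec3.beta)
        realized = ds.M[:, ds.labels == 3].mean()
        assert realized == pytest.approx(expected, abs=0.025)

    def test_near_zero_rates_give_near_empty_mask(self):
        params = _tiny_params(pi=1e-4, auc=0.5, alpha=1e-3, beta=10.0)
        ds = assemble_dataset(params, mc_n=20_000)
        assert ds.M.mean() < 1e-3

    def test_mar_audit_non_core_adds_little_auc(self):
        # SM depends only on core columns: refitting on completed non-core
        # baseline data should not materially improve the AUC
        from missgen.informative import cv_auc

        params = benchmark_params(n=8_000, seed=13)
        ds = assemble_dataset(params, mc_n=50_000)
        base_cols = np.flatnonzero(ds.labels == 0)
        core_cols = np.arange(params.d_core)
        b = ds.b_sm[3]
        auc_core = cv_auc(ds.X_complete[:, core_cols], b, lam=1e-3, seed=0)
        auc_all = cv_auc(ds.X_complete[:, base_cols], b, lam=1e-3, seed=0)
        assert auc_all - auc_core < 0.02


class TestMcarComparator:
    def test_rates_match_and_data_identical(self):
        params = benchmark_params(n=5_000, seed=17)
        ds = assemble_dataset(params, mc_n=50_000)
        arm = mcar_comparator(ds, substream(17, "mcar"))
        assert arm.X_complete is ds.X_complete or np.array_equal(arm.X_complete, ds.X_complete)
        for c in (2, 3):
            cols = ds.labels == c
            r_structured = ds.M[:, cols].mean()
            r_mcar = arm.M[:, cols].mean()
            assert abs(r_structured - r_mcar) < 0.005
        # under MCAR, losing an entire cluster requires ~rate^d_c probability
        cols3 = np.flatnonzero(ds.labels == 3)
        full_loss = (arm.M[:, cols3] == 1).all(axis=1).mean()
        assert full_loss < 0.005
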