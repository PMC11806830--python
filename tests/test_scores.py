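import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import norm

from missgen.scores import (
    biserial_from_pearson,
    co_observation,
    score_binary_binary,
    score_binary_target,
    score_continuous,
    score_matrix,
    select_predictors,
)


class TestCoObservation:
    def test_examples(self):
        m = np.column_stack([[1, 1, 0], [0, 1, 0]])
        v = co_observation(m)
        assert v[0, 1] == 1 and v[1, 0] == 0
        assert np.all(np.diag(v) == 0)
        assert co_observation(np.zeros((4, 3), dtype=int)).sum() == 0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        m = (rng.random((15, 6)) < 0.4).astype(np.int8)
        v = co_observation(m)
        for j in range(6):
            for k in range(6):
                assert v[j, k] == int(np.sum((m[:, j] == 1) & (m[:, k] == 0)))


class TestBiserial:
    def test_zero_and_printed_example(self):
        assert biserial_from_pearson(0.0, 0.3).rho_b == 0.0
        bp = biserial_from_pearson(0.3, 0.5)
        assert bp.D == pytest.approx(0.0)
        assert bp.rho_b == pytest.approx(0.3 * 0.5 / norm.pdf(0.0), abs=1e-10)
        assert bp.rho_b == pytest.approx(0.37599, abs=1e-4)

    def test_clipping_beyond_one(self):
        with pytest.warns(RuntimeWarning, match="clipping"):
            bp = biserial_from_pearson(0.9, 0.5)
        assert bp.rho_b == 1.0

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            biserial_from_pearson(0.2, 1.0)


class TestScoreFormulas:
    def test_continuous_arithmetic(self):
        assert score_continuous(100, 0.5) == pytest.approx(25.0)
        assert score_continuous(7, 0.0) == 0.0

    def test_continuous_equals_mse_reduction_oracle(self):
        rng = np.random.default_rng(1)
        n = 2_000_000
        for rho in (0.3, 0.7):
            z = rng.standard_normal((n, 2))
            x2 = z[:, 0]
            x1 = rho * x2 + np.sqrt(1 - rho**2) * z[:, 1]
            # paired estimator: MSE of the trivial (mean) predictor minus the
            # MSE of the best linear predictor, on the same draws
            reduction = np.mean(x1**2) - np.mean((x1 - rho * x2) ** 2)
            assert score_continuous(1.0, rho) == pytest.approx(reduction, abs=2e-3)

    def test_binary_target_zero_and_limit(self):
        assert score_binary_target(10.0, 0.0, 0.3) == 0.0
        # p = 0.5, |rho_b| -> 1: accuracy -> 1 so S -> 0.5 V
        rho_limit = norm.pdf(0.0) / 0.5  # rho giving rho_b exactly 1
        with pytest.warns(RuntimeWarning):
            s = score_binary_target(1.0, rho_limit * 1.01, 0.5)
        assert s == pytest.approx(0.5, abs=1e-9)

    def test_binary_target_bvn_equals_quadrature(self):
        for p in (0.1, 0.3, 0.5, 0.7):
            for rho in (-0.45, -0.2, 0.15, 0.4):
                s_bvn = score_binary_target(1.0, rho, p, method="bvn")
                s_quad = score_binary_target(1.0, rho, p, method="quad")
                assert s_bvn == pytest.approx(s_quad, abs=1e-7)

    def test_binary_target_montecarlo_oracle(self):
        rng = np.random.default_rng(2)
        n = 1_000_000
        p, rho = 0.3, 0.4
        bp = biserial_from_pearson(rho, p)
        z = rng.standard_normal((n, 2))
        x2 = z[:, 0]
        latent = bp.rho_b * x2 + np.sqrt(1 - bp.rho_b**2) * z[:, 1]
        cut = ndtri(1 - p)
        x = latent > cut
        pred = bp.rho_b * x2 > cut  # conditional-median rule
        gain = np.mean(pred == x) - max(p, 1 - p)
        assert score_binary_target(1.0, rho, p) == pytest.approx(gain, abs=2e-3)

    def test_binary_binary_table_bruteforce(self):
        p, p2, rho, v = 0.4, 0.3, 0.25, 1.0
        p11 = p * p2 + rho * np.sqrt(p * (1 - p) * p2 * (1 - p2))
        table_acc = max(p11, p2 - p11) + max(p - p11, 1 - p - p2 + p11)
        expected = v * (table_acc - max(p, 1 - p))
        assert score_binary_binary(v, rho, p, p2) == pytest.approx(expected, abs=1e-12)

    def test_binary_binary_limits_and_errors(self):
        assert score_binary_binary(5.0, 0.0, 0.4, 0.3) == 0.0
        assert score_binary_binary(1.0, 1.0 - 1e-12, 0.5, 0.5) == pytest.approx(0.5, abs=1e-6)
        with pytest.raises(ValueError, match="infeasible"):
            score_binary_binary(1.0, 0.9, 0.9, 0.1)
        with pytest.raises(ValueError):
            score_binary_binary(1.0, 0.2, 0.0, 0.5)

    def test_oracle_grid_all_cases(self):
        # expected-error-reduction Monte-Carlo oracles across the (rho, p) grid
        rng = np.random.default_rng(3)
        n = 200_000
        for rho in (-0.5, 0.2, 0.8):
            for p in (0.1, 0.3, 0.5):
                bp_ok = abs(rho * np.sqrt(p * (1 - p)) / norm.pdf(ndtri(p))) < 1
                if not bp_ok:
                    continue
                bp = biserial_from_pearson(rho, p)
                z = rng.standard_normal((n, 2))
                x2 = z[:, 0]
                latent = bp.rho_b * x2 + np.sqrt(1 - bp.rho_b**2) * z[:, 1]
                x = latent > ndtri(1 - p)
                pred = bp.rho_b * x2 > ndtri(1 - p)
                gain = np.mean(pred == x) - max(p, 1 - p)
                assert score_binary_target(1.0, rho, p) == pytest.approx(gain, abs=5e-3)


class TestScoreMatrix:
    def test_matches_scalar_formulas(self):
        rng = np.random.default_rng(4)
        n = 400
        z = rng.multivariate_normal(np.zeros(4), np.eye(4) * 0.4 + 0.6, size=n)
        x = z.copy()
        x[:, 2] = (x[:, 2] > 0.2).astype(float)
        x[:, 3] = (x[:, 3] > -0.5).astype(float)
        mask = (rng.random((n, 4)) < 0.3).astype(np.int8)
        xm = np.where(mask == 1, np.nan, x)
        types = np.array(["continuous", "continuous", "binary", "binary"], dtype=object)
        s = score_matrix(xm, types)
        from missgen.correlation import pairwise_complete_corr
        from missgen.scores import co_observation

        corr, _ = pairwise_complete_corr(xm)
        v = co_observation(mask)
        p = {j: np.nanmean(xm[:, j]) for j in (2, 3)}
        assert s[0, 1] == pytest.approx(v[0, 1] * corr[0, 1] ** 2, rel=1e-9)
        assert s[0, 3] == pytest.approx(v[0, 3] * corr[0, 3] ** 2, rel=1e-9)
        assert s[2, 0] == pytest.approx(
            score_binary_target(v[2, 0], corr[2, 0], p[2]), rel=1e-6
        )
        assert s[2, 3] == pytest.approx(
            score_binary_binary(v[2, 3], corr[2, 3], p[2], p[3]), rel=1e-6
        )
        assert np.all(s >= 0) and np.all(np.diag(s) == 0)


class TestSelectPredictors:
    def test_co_observation_single_missing_cell_ties(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((20, 5))
        x[0, 2] = np.nan
        lists = select_predictors(x, np.array(["continuous"] * 5, dtype=object),
                                  "co_observation", 3)
        assert list(lists.keys()) == [2]
        # all other variables tie at V=1; ties break by ascending index
        assert lists[2].tolist() == [0, 1, 3]

    def test_correlation_strategy_scale_invariant(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((200, 5))
        x[:, 1] += x[:, 0]
        x[rng.random((200, 5)) < 0.2] = np.nan
        types = np.array(["continuous"] * 5, dtype=object)
        a = select_predictors(x, types, "correlation", 3)
        b = select_predictors(x * np.array([1.0, 7.0, 0.2, 3.0, 1.0]), types,
                              "correlation", 3)
        assert {j: lst.tolist() for j, lst in a.items()} == {
            j: lst.tolist() for j, lst in b.items()
        }

    def test_mixed_score_demotes_never_co_observed_predictor(self):
        # variable 1 is the best-correlated partner of 0 but never observed
        # when 0 is missing (V=0); variable 2 is moderately correlated and
        # always co-observed: the mixed score must rank 2 over 1
        rng = np.random.default_rng(7)
        n = 600
        base = rng.standard_normal(n)
        x = np.column_stack([
            base,
            base + 0.1 * rng.standard_normal(n),
            0.7 * base + rng.standard_normal(n) * 0.7,
            rng.standard_normal(n),
        ])
        miss0 = np.zeros(n, bool)
        miss0[:200] = True
        x[miss0, 0] = np.nan
        x[miss0, 1] = np.nan  # co-missing with 0
        types = np.array(["continuous"] * 4, dtype=object)
        corr_lists = select_predictors(x, types, "correlation", 2)
        mixed_lists = select_predictors(x, types, "mixed_score", 2)
        assert corr_lists[0][0] == 1
        assert 1 not in mixed_lists[0].tolist()
        assert mixed_lists[0][0] == 2

    def test_invalid_k(self):
        x = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError):
            select_predictors(x, np.array(["continuous"] * 3, dtype=object),
                              "correlation", 3)
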