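import warnings

import numpy as np
import pytest

from tcvs.selection import (
    KnockoffStatistics,
    TcvsConfig,
    bic_score,
    default_lambda_grid,
    knockoff_statistics,
    knockoff_threshold,
    run_tcvs,
    tune_lambda,
)
from tcvs.simulation import (
    SimulationConfig,
    default_simulation_tree,
    simulate_dataset,
    synthetic_dm_parameters,
)
from tcvs.solver import TcvsFit


def _fit_with(beta, beta_tilde):
    return TcvsFit(beta=np.asarray(beta, float),
                   beta_tilde=None if beta_tilde is None else np.asarray(beta_tilde, float),
                   intercept=0.0, lam=0.1, objective_trace=np.zeros(1),
                   converged=True, constraint_violation=0.0, n_iter=1)


def brute_force_threshold(w, q):
    """Direct enumeration of the selection threshold over all candidates."""
    w = np.asarray(w, float)
    cands = np.unique(np.abs(w))
    cands = cands[cands > 0]
    feasible = [
        t for t in cands
        if np.count_nonzero(w <= -t) / max(1, np.count_nonzero(w >= t)) <= q
    ]
    return min(feasible) if feasible else float("inf")


class TestKnockoffStatistics:
    def test_importance_contrast(self):
        stats = knockoff_statistics(_fit_with([0.5, 1.0, 0.0], [0.2, 0.0, 2.0]))
        np.testing.assert_allclose(stats.w, [0.3, 1.0, -2.0])

    def test_equal_magnitudes_give_zero(self):
        stats = knockoff_statistics(_fit_with([0.4], [-0.4]))
        assert stats.w[0] == 0.0
        assert stats.nonzero_abs.size == 0

    def test_missing_knockoff_half_rejected(self):
        with pytest.raises(ValueError, match="knockoff"):
            knockoff_statistics(_fit_with([0.1], None))


class TestKnockoffThreshold:
    def test_enumerated_example(self):
        # candidates {1,2,3,4,5}: at t=2 the ratio is 1/4 <= 0.25
        stats = KnockoffStatistics(w=np.array([2, 3, -1, 4, -2, 5], float))
        assert knockoff_threshold(stats, q=0.25) == 2.0

    def test_all_positive_selects_at_minimum(self):
        stats = KnockoffStatistics(w=np.array([0.5, 1.5, 0.2]))
        assert knockoff_threshold(stats, q=0.01) == pytest.approx(0.2)

    def test_all_negative_gives_infinity(self):
        stats = KnockoffStatistics(w=np.array([-1.0, -2.0, -3.0]))
        assert knockoff_threshold(stats, q=0.5) == float("inf")

    def test_all_zero_gives_infinity(self):
        stats = KnockoffStatistics(w=np.zeros(5))
        assert knockoff_threshold(stats, q=0.2) == float("inf")

    def test_plus_variant_is_more_conservative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.normal(size=12)
            stats = KnockoffStatistics(w=w)
            t0 = knockoff_threshold(stats, 0.2, plus=False)
            t1 = knockoff_threshold(stats, 0.2, plus=True)
            assert t1 >= t0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = int(rng.integers(1, 13))
            w = np.round(rng.normal(size=p), 2)
            q = float(rng.uniform(0.02, 0.5))
            stats = KnockoffStatistics(w=w)
            assert knockoff_threshold(stats, q) == brute_force_threshold(w, q)

    def test_threshold_monotone_and_selection_nested_in_q(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=30)
        stats = KnockoffStatistics(w=w)
        prev_T, prev_S = np.inf, set()
        for q in [0.01, 0.05, 0.1, 0.2, 0.4]:
            T = knockoff_threshold(stats, q)
            S = set(np.flatnonzero(w >= T).tolist()) if np.isfinite(T) else set()
            assert T <= prev_T
            assert S >= prev_S
            prev_T, prev_S = T, S


class TestBic:
    def test_direct_formula(self):
        # RSS/n = 1 with K = 3 at n = 100 -> 3 log(100)
        y = np.concatenate([np.ones(50), -np.ones(50)])
        D = np.zeros((100, 4))
        coeffs = np.array([0.5, -0.5, 0.1, 0.0])
        D[:, 2] = 0.0
        assert bic_score(y, D, coeffs) == pytest.approx(3 * np.log(100))

    def test_increasing_in_support_at_fixed_rss(self):
        y = np.ones(50)
        D = np.zeros((50, 3))
        b1 = bic_score(y, D, np.array([1e-3, 0, 0]))
        b2 = bic_score(y, D, np.array([1e-3, 1e-3, 0]))
        assert b2 > b1

    def test_doubling_rss_adds_n_log_two(self):
        n = 64
        y1, y2 = np.ones(n), np.sqrt(2) * np.ones(n)
        D = np.zeros((n, 2))
        c = np.array([0.1, 0.0])
        assert bic_score(y2, D, c) - bic_score(y1, D, c) == pytest.approx(n * np.log(2))

    def test_saturated_fit_warns(self):
        y = np.zeros(10)
        D = np.zeros((10, 1))
        with pytest.warns(UserWarning, match="saturated"):
            assert bic_score(y, D, np.zeros(1)) == float("-inf")


class TestTuneLambda:
    def _data(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(60, 6))
        beta = np.array([1.5, -1.5, 0, 0, 0, 0])
        y = Z @ beta + 0.3 * rng.normal(size=60)
        return y, Z

    def test_grid_with_only_lambda_max_returns_null_fit(self):
        y, Z = self._data()
        from tcvs.solver import lambda_max

        lmax = lambda_max(y, Z) * 1.0001
        lam, table, best = tune_lambda(y, Z, None, None, np.array([lmax]))
        assert lam == pytest.approx(lmax)
        np.testing.assert_array_equal(best.beta, 0.0)

    def test_grid_order_invariance(self):
        y, Z = self._data()
        grid = default_lambda_grid(y, Z, n_lambda=15)
        rng = np.random.default_rng(4)
        lam1, _, _ = tune_lambda(y, Z, None, None, grid)
        lam2, _, _ = tune_lambda(y, Z, None, None, rng.permutation(grid))
        assert lam1 == lam2

    def test_strong_signal_support_recovery(self):
        y, Z = self._data()
        grid = default_lambda_grid(y, Z, n_lambda=25)
        lam, table, best = tune_lambda(y, Z, None, None, grid)
        support = set(np.flatnonzero(best.beta).tolist())
        assert {0, 1} <= support

    def test_empty_grid_rejected(self):
        y, Z = self._data()
        with pytest.raises(ValueError, match="grid"):
            tune_lambda(y, Z, None, None, np.array([]))


@pytest.fixture(scope="module")
def sim():
    params = synthetic_dm_parameters(60, seed=0)
    cfg = SimulationConfig(n=120, p=60, setting="I", seed=0)
    rng = np.random.default_rng(0)
    table, Z, y, beta_true = simulate_dataset(params, cfg, rng)
    tree = default_simulation_tree(60)
    return Z, y, beta_true, tree


class TestRunTcvs:

    def test_determinism(self, sim):
        Z, y, beta_true, tree = sim
        cfg = TcvsConfig(variant="tcvs", seed=5, n_lambda=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = run_tcvs(Z, tree, y, config=cfg)
            r2 = run_tcvs(Z, tree, y, config=cfg)
        np.testing.assert_array_equal(r1.selected, r2.selected)
        assert r1.lambda_opt == r2.lambda_opt
        np.testing.assert_array_equal(r1.w, r2.w)

    def test_strong_signal_recovery(self, sim):
        Z, y, beta_true, tree = sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_tcvs(Z, tree, y, config=TcvsConfig(variant="tcvs", seed=1))
        true_support = set(np.flatnonzero(beta_true).tolist())
        assert len(set(res.selected.tolist()) & true_support) >= 9

    def test_tree_variant_requires_tree(self, sim):
        Z, y, _, _ = sim
        with pytest.raises(ValueError, match="tree"):
            run_tcvs(Z, None, y, config=TcvsConfig(variant="tlasso"))

    def test_non_knockoff_variant_returns_bic_support(self, sim):
        Z, y, beta_true, tree = sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_tcvs(Z, tree, y, config=TcvsConfig(variant="classo", n_lambda=20))
        assert res.w is None and np.isnan(res.threshold)
        np.testing.assert_array_equal(res.selected, np.flatnonzero(res.fit.beta))

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError, match="q"):
            TcvsConfig(q=1.5)
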