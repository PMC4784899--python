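"""Coordinate-descent solver: update rules, bounds, oracles, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (convex_regression_oracle, gelnet_objective_loops,
                      weighted_least_squares)
from conftest import random_network
from gelnetx import (GELnet, GELnetResults, PenaltyConfig, FitControl,
                     build_laplacian, gelnet_fit, lambda1_max, objective,
                     soft_threshold)


def random_instance(rng, n=20, p=8, weighted=False):
    X = rng.standard_normal((n, p))
    w = rng.standard_normal(p) * (rng.random(p) < 0.5)
    y = X @ w + 0.3 * rng.standard_normal(n)
    a = rng.uniform(0.3, 2.0, n) if weighted else np.ones(n)
    return X, y, a


class TestSoftThreshold:
    @pytest.mark.parametrize("v,gamma,expect", [
        (0.5, 1.0, 0.0), (2.0, 0.0, 2.0), (-3.0, 1.0, -2.0),
        (1.0, 1.0, 0.0), (-0.2, 0.5, 0.0),
    ])
    def test_examples(self, v, gamma, expect):
        assert soft_threshold(v, gamma) == expect

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-1e6, 1e6), st.floats(0, 1e6))
    def test_shrinks_toward_zero_by_gamma(self, v, gamma):
        s = soft_threshold(v, gamma)
        assert abs(s) == pytest.approx(max(abs(v) - gamma, 0.0))
        assert s == 0.0 or np.sign(s) == np.sign(v)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestLambda1Max:
    def test_constant_response_gives_zero(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        assert lambda1_max(X, np.full(10, 2.5)) == 0.0

    def test_hand_case_and_boundary(self):
        # n=2, p=1, x=(1,-1), y=(1,-1): bound is exactly 1
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, -1.0])
        assert lambda1_max(X, y) == pytest.approx(1.0)
        m = GELnet(y, X)
        assert m.fit(1.0 + 1e-6, 0.0).nnz == 0
        assert m.fit(1.0 - 1e-6, 0.0).nnz == 1

    def test_scales_linearly_with_response(self):
        rng = np.random.default_rng(1)
        X, y, a = random_instance(rng, weighted=True)
        assert lambda1_max(X, 3.7 * y, a) == \
            pytest.approx(3.7 * lambda1_max(X, y, a))

    def test_all_zero_d_rejected(self):
        X, y, _ = random_instance(np.random.default_rng(2))
        with pytest.raises(ValueError, match="d_j"):
            lambda1_max(X, y, d=np.zeros(X.shape[1]))

    def test_guarantee_above_and_activity_below(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X, y, a = random_instance(rng, n=15, p=8, weighted=True)
            lm = lambda1_max(X, y, a)
            m = GELnet(y, X, weights=a)
            hi = m.fit(1.001 * lm, 0.5)
            assert hi.nnz == 0
            assert hi.intercept == pytest.approx(a @ y / a.sum())
            assert m.fit(0.9 * lm, 0.5).nnz >= 1


class TestFitCorrectness:
    def test_unpenalized_matches_weighted_least_squares(self):
        rng = np.random.default_rng(4)
        X, y, a = random_instance(rng, n=40, p=6, weighted=True)
        fit = GELnet(y, X, weights=a).fit(0.0, 0.0, tol=1e-12,
                                          max_iter=5000)
        w, b = weighted_least_squares(X, y, a)
        assert np.abs(fit.w - w).max() < 1e-6
        assert abs(fit.intercept - b) < 1e-6

    def test_matches_convex_oracle_elastic_net(self):
        # d=1, P=I: the classical elastic net special case
        rng = np.random.default_rng(5)
        for _ in range(5):
            X, y, a = random_instance(rng, n=20, p=5)
            lam1, lam2 = rng.uniform(0.02, 0.3), rng.uniform(0.1, 2.0)
            fit = GELnet(y, X).fit(lam1, lam2, tol=1e-9, max_iter=2000)
            wo, bo = convex_regression_oracle(X, y, a, lam1, lam2,
                                              np.ones(5), np.eye(5))
            assert np.abs(fit.w - wo).max() < 1e-5

    def test_matches_convex_oracle_network_penalty(self):
        rng = np.random.default_rng(6)
        net = random_network(6, rng, 0.5)
        P = build_laplacian(net)
        d = rng.uniform(0.5, 2.0, 6)
        X, y, a = random_instance(rng, n=25, p=6, weighted=True)
        fit = GELnet(y, X, weights=a, d=d, P=P).fit(0.1, 1.3, tol=1e-9,
                                                    max_iter=2000)
        wo, _ = convex_regression_oracle(X, y, a, 0.1, 1.3, d,
                                         P.toarray())
        assert np.abs(fit.w - wo).max() < 1e-5

    def test_objective_matches_naive_loops(self):
        rng = np.random.default_rng(7)
        X, y, a = random_instance(rng, n=12, p=5, weighted=True)
        net = random_network(5, rng, 0.5)
        P = build_laplacian(net)
        w = rng.standard_normal(5)
        pen = PenaltyConfig(0.2, 1.5, np.full(5, 0.7), P)
        val = objective(X, y, w, 0.4, pen, sample_weight=a)
        brute = gelnet_objective_loops(X, y, a, w, 0.4, 0.2, 1.5,
                                       np.full(5, 0.7), P.toarray())
        assert val == pytest.approx(brute, rel=1e-12)

    def test_final_trace_matches_recomputed_objective(self):
        rng = np.random.default_rng(8)
        X, y, _ = random_instance(rng)
        fit = GELnet(y, X).fit(0.05, 0.5)
        assert fit.objective() == pytest.approx(fit.objective_trace[-1],
                                                rel=1e-10)


class TestDiagnostics:
    def test_objective_monotone_and_kkt(self):
        rng = np.random.default_rng(9)
        for weighted in (False, True):
            for lam1, lam2 in [(0.0, 0.0), (0.1, 0.0), (0.05, 1.0),
                               (0.3, 10.0)]:
                X, y, a = random_instance(rng, weighted=weighted)
                fit = GELnet(y, X, weights=a).fit(lam1, lam2)
                diffs = np.diff(fit.objective_trace)
                slack = 1e-10 + 1e-12 * np.abs(fit.objective_trace[1:])
                assert (diffs <= slack).all()
                if fit.converged:
                    assert fit.kkt_residual <= 10 * fit.control.tol

    def test_cache_and_naive_paths_identical(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            X, y, a = random_instance(rng, n=15, p=12, weighted=True)
            net = random_network(12, rng, 0.2)
            P = build_laplacian(net, normalized=True)
            lam1 = 0.5 * lambda1_max(X, y, a)
            m = GELnet(y, X, weights=a, P=P)
            cached = m.fit(lam1, 2.0, skip_zero=True)
            naive = m.fit(lam1, 2.0, skip_zero=False)
            assert np.array_equal(cached.w, naive.w)
            assert cached.intercept == naive.intercept
            assert cached.n_iter == naive.n_iter

    def test_sparsity_non_increasing_along_lambda1_path(self):
        rng = np.random.default_rng(11)
        X, y, _ = random_instance(rng, n=30, p=15)
        lm = lambda1_max(X, y)
        m = GELnet(y, X)
        nnz = [m.fit(f * lm, 1.0).nnz
               for f in (0.01, 0.05, 0.1, 0.3, 0.6, 0.9, 1.01)]
        assert nnz == sorted(nnz, reverse=True)

    def test_zero_column_frozen_with_warning(self, caplog):
        rng = np.random.default_rng(12)
        X, y, _ = random_instance(rng, n=10, p=4)
        X[:, 2] = 0.0
        with caplog.at_level("WARNING"):
            fit = GELnet(y, X).fit(0.01, 0.0)
        assert fit.w[2] == 0.0
        assert "zero curvature" in caplog.text

    def test_nan_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            GELnet(np.ones(5), X)


class TestInterface:
    def test_predict_shapes_and_trivials(self):
        rng = np.random.default_rng(13)
        X, y, _ = random_instance(rng)
        fit = GELnet(y, X).fit(1e9, 0.0)  # above lambda1_max: w = 0
        assert np.allclose(fit.predict(), fit.intercept)
        with pytest.raises(ValueError):
            fit.predict(np.ones((3, 99)))

    def test_warm_start_reaches_same_solution(self):
        rng = np.random.default_rng(14)
        X, y, _ = random_instance(rng)
        m = GELnet(y, X)
        cold = m.fit(0.05, 1.0, tol=1e-10, max_iter=3000)
        warm = m.fit(0.05, 1.0, tol=1e-10, max_iter=3000,
                     w_init=rng.standard_normal(X.shape[1]))
        assert np.abs(cold.w - warm.w).max() < 1e-6

    def test_functional_front_end_and_from_dataframe(self):
        import pandas as pd
        rng = np.random.default_rng(15)
        X, y, _ = random_instance(rng, n=15, p=3)
        res1 = gelnet_fit(X, y, PenaltyConfig(0.1, 0.5),
                          FitControl(tol=1e-8))
        df = pd.DataFrame(X, columns=["g1", "g2", "g3"])
        df["resp"] = y
        res2 = GELnet.from_dataframe(df, "resp").fit(0.1, 0.5, tol=1e-8)
        assert np.allclose(res1.w, res2.w)
        assert list(res2.params.index) == ["g1", "g2", "g3"]
        assert "Generalized Elastic Net" in res2.summary()

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(16)
        X, y, _ = random_instance(rng)
        fit = GELnet(y, X).fit(0.05, 0.5)
        path = tmp_path / "model.tsv"
        fit.save(path)
        params, meta = GELnetResults.load_params(path)
        assert np.array_equal(params.to_numpy(), fit.w)
        assert meta["b"] == fit.intercept
        assert meta["lambda1"] == 0.05
        assert meta["converged"] == fit.converged
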