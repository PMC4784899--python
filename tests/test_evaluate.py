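"""Metrics, cross-validation, matched sparsity and the comparison grid."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_network
from gelnetx import (GELnet, Grids, Network, SimulationConfig,
                     build_laplacian, dispersion, identity_penalty,
                     lpocv_rmse, match_sparsity_lambda1, network_relevance,
                     reconstruction_error, rmse, run_comparison,
                     simulate_dataset)
from gelnetx.evaluate import sample_pairs


class TestReconstructionError:
    def test_collinear_is_zero(self):
        w = np.array([1.0, -2.0, 0.5])
        assert reconstruction_error(w, -3.2 * w) == pytest.approx(0.0)

    def test_orthogonal_is_one(self):
        assert reconstruction_error([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_half_for_45_degrees(self):
        assert reconstruction_error([1, 0], [1, 1]) == pytest.approx(0.5)

    def test_zero_estimate_scores_one(self):
        assert reconstruction_error([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_error([0.0, 0.0], [1.0, 0.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_invariant_to_rescaling(self, c1, c2):
        w1 = np.array([1.0, 2.0, -0.5])
        w2 = np.array([0.3, -1.0, 2.0])
        base = reconstruction_error(w1, w2)
        assert reconstruction_error(c1 * w1, c2 * w2) == \
            pytest.approx(base, abs=1e-10)


class TestRmse:
    def test_identical_is_zero(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_offset(self):
        y = np.arange(5.0)
        assert rmse(y, y + 3.0) == pytest.approx(3.0)

    def test_hand_case(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))


class TestDispersion:
    def test_star_leaves_score_one(self, star_network):
        w = np.zeros(7)
        w[1:] = 1.0  # the six leaves: degree 1, no mutual edges
        assert dispersion(w, star_network) == pytest.approx(1.0)

    def test_single_edge_pair_scores_zero(self):
        net = Network.from_edges([("a", "b")])
        assert dispersion(np.array([1.0, 1.0]), net) == pytest.approx(0.0)

    def test_internal_edges_lower_dispersion(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net = random_network(12, rng, 0.3)
            w = (rng.random(12) < 0.5).astype(float)
            if w.sum() == 0:
                continue
            Z = np.flatnonzero(w)
            internal = net.adjacency.toarray()[np.ix_(Z, Z)].sum()
            d = dispersion(w, net)
            assert d <= 1.0 + 1e-12
            if internal > 0:
                assert d < 1.0
            elif (net.degrees[Z] > 0).all():
                assert d == pytest.approx(1.0)

    def test_empty_selection_rejected(self, star_network):
        with pytest.raises(ValueError, match="no selected features"):
            dispersion(np.zeros(7), star_network)


class TestLpocv:
    def test_enumerates_all_pairs_and_matches_hand_loop(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 2))
        y = rng.standard_normal(4)

        def recipe(Xt, yt):
            return GELnet(yt, Xt).fit(0.1, 1.0)

        got = lpocv_rmse(X, y, recipe, n_pairs=10)
        errs = []
        for i in range(4):
            for j in range(i + 1, 4):
                mask = np.ones(4, bool)
                mask[[i, j]] = False
                fit = GELnet(y[mask], X[mask]).fit(0.1, 1.0)
                errs.extend((y[[i, j]] - fit.predict(X[[i, j]])) ** 2)
        assert got == pytest.approx(np.sqrt(np.mean(errs)))

    def test_constant_response_intercept_model_is_exact(self):
        X = np.random.default_rng(2).standard_normal((8, 3))
        y = np.full(8, 4.2)

        def recipe(Xt, yt):
            return GELnet(yt, Xt).fit(1e9, 0.0)  # intercept-only

        assert lpocv_rmse(X, y, recipe) == pytest.approx(0.0)

    def test_pair_sampling_seeded_and_distinct(self):
        p1 = sample_pairs(30, 50, seed=3)
        p2 = sample_pairs(30, 50, seed=3)
        assert np.array_equal(p1, p2)
        assert len(p1) == 50
        assert len({tuple(r) for r in p1}) == 50
        assert len(sample_pairs(10, 1000)) == 45  # all pairs when small


@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((30, 40))
    w = np.zeros(40)
    w[:8] = rng.standard_normal(8)
    y = X @ w + 0.2 * rng.standard_normal(30)
    return X, y


@pytest.fixture(scope="module")
def small_ds():
    return simulate_dataset(SimulationConfig(p=80, n=24, seed=5), "GGM+")


class TestMatchedSparsity:

    def test_target_zero_returns_above_lambda1_max(self, instance):
        X, y = instance
        lam = match_sparsity_lambda1(X, y, 0, lambda2=1.0)
        m = GELnet(y, X)
        assert lam > m.lambda1_max()
        assert m.fit(lam, 1.0).nnz == 0

    def test_recovers_grid_sparsity(self, instance):
        X, y = instance
        m = GELnet(y, X)
        lm = m.lambda1_max()
        target = m.fit(lm / 9, 1.0).nnz
        lam, fit = match_sparsity_lambda1(X, y, target, lambda2=1.0,
                                          return_fit=True)
        assert fit.nnz == target

    def test_lambda1_non_increasing_in_target(self, instance):
        X, y = instance
        lams = [match_sparsity_lambda1(X, y, t, lambda2=1.0)
                for t in (2, 5, 10, 20)]
        assert lams == sorted(lams, reverse=True)


class TestComparison:
    def test_identity_penalty_makes_methods_coincide(self, small_ds):
        grids = Grids(lambda2_grid=(10.0, 1.0),
                      lambda1_fractions=(1 / 9, 1 / 3))
        rep = run_comparison(small_ds, grids=grids, n_pairs=12, seed=6,
                             penalty=identity_penalty(80))
        wide = rep.cells.pivot_table(
            index=["lambda2", "lambda1_fraction"], columns="method",
            values=["reconstruction_error", "rmse", "dispersion"])
        for metric in ("reconstruction_error", "rmse", "dispersion"):
            diff = (wide[metric]["gelnet"]
                    - wide[metric]["elastic_net"]).abs()
            assert (diff.fillna(0.0) < 1e-8).all()
        # improvement of a method over itself is zero everywhere
        for v in rep.pct_improvement.values():
            assert abs(v) < 1e-6

    def test_report_shape_and_summary(self, small_ds):
        grids = Grids(lambda2_grid=(10.0, 1.0),
                      lambda1_fractions=(1 / 9, 1 / 3))
        rep = run_comparison(small_ds, grids=grids, n_pairs=12, seed=7)
        assert len(rep.cells) == 2 * 2 * 2  # cells x methods
        assert set(rep.marginal_means.index) == {"elastic_net", "gelnet"}
        assert "% improvement" in rep.summary()


class TestRelevanceRule:
    def _report(self, rmse_imp, disp_imp):
        import pandas as pd
        from gelnetx.evaluate import ComparisonReport
        return ComparisonReport(
            cells=pd.DataFrame(), marginal_means=pd.DataFrame(),
            pct_improvement={"rmse": rmse_imp, "dispersion": disp_imp,
                             "reconstruction_error": 0.0})

    def test_either_criterion_flags_relevant(self):
        assert network_relevance(self._report(3.0, 1.0))
        assert network_relevance(self._report(1.0, 6.0))
        assert not network_relevance(self._report(1.0, 1.0))

    def test_conservative_mode_requires_both(self):
        assert not network_relevance(self._report(3.0, 1.0),
                                     conservative=True)
        assert network_relevance(self._report(3.0, 6.0),
                                 conservative=True)
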