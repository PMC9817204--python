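"""Moran's I, correlograms, spatial weights, SAR-error ML and selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import identity
from scipy.sparse.linalg import spsolve

from phyloscape import (
    Grid,
    all_subsets_selection,
    build_weights,
    correlogram,
    fit_sar_error,
    morans_i,
    nagelkerke_r2,
    neighbor_threshold,
)
from phyloscape.sar import Correlogram, _ols_loglik


def morans_oracle(x, W):
    """Naive double-loop Moran's I."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    S0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            S0 += W[i, j]
    return (n / S0) * num / (z**2).sum()


def rook_weights(nx, ny):
    coords = np.array([(c, r) for r in range(ny) for c in range(nx)], float)
    D = np.abs(coords[:, None, :] - coords[None, :, :]).sum(-1)
    return (D == 1).astype(float), coords


class TestMoransI:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(10, 51))
            x = rng.standard_normal(n)
            W = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
            np.fill_diagonal(W, 0)
            if W.sum() == 0:
                W[0, 1] = 1.0
            res = morans_i(x, W)
            assert res["I"] == pytest.approx(morans_oracle(x, W), abs=1e-12)

    def test_expected_value_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(101)
        W = np.zeros((101, 101))
        W[np.arange(100), np.arange(1, 101)] = 1
        W += W.T
        assert morans_i(x, W)["expected"] == pytest.approx(-0.01)

    def test_checkerboard_rook_is_minus_one(self):
        W, coords = rook_weights(4, 4)
        vals = (coords.sum(axis=1) % 2).astype(float)
        assert morans_i(vals, W)["I"] == pytest.approx(-1.0)

    def test_smooth_field_significantly_positive(self):
        from phyloscape import simulate_env_layers

        g = Grid.regular(10, 10)
        W, _ = rook_weights(10, 10)
        hits = 0
        for s in range(40):
            layer = simulate_env_layers(g, 1, 3.0, seed=s)[0]
            r = morans_i(layer.values, W)
            hits += (r["I"] > 0) and (r["p"] < 0.05)
        assert hits >= 38

    def test_constant_values_error(self):
        W, _ = rook_weights(3, 3)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(9), W)


class TestCorrelogram:
    def test_single_class_equals_global_binary_i(self):
        rng = np.random.default_rng(2)
        g = Grid.regular(6, 6)
        x = rng.standard_normal(g.n_cells)
        dmax = np.sqrt(2) * 6
        corr = correlogram(x, g.coords, increment=dmax, max_distance=dmax)
        assert len(corr.table) == 1
        W = (np.linalg.norm(
            g.coords[:, None] - g.coords[None, :], axis=-1) <= dmax).astype(float)
        np.fill_diagonal(W, 0)
        assert corr.table["I"].iloc[0] == pytest.approx(
            morans_i(x, W)["I"], abs=1e-12
        )

    def test_white_noise_classes_near_null(self):
        rng = np.random.default_rng(3)
        g = Grid.regular(12, 12)
        x = rng.standard_normal(g.n_cells)
        corr = correlogram(x, g.coords, increment=2.0)
        t = corr.table[~corr.table.flagged]
        dev = (t["I"] - t["expected"]) / np.sqrt(t["variance"])
        assert (dev.abs() < 4).all()

    def test_empty_class_flagged_not_dropped(self):
        # two clusters of points with a gap: middle classes have no pairs
        coords = np.array([[0, 0], [0, 1], [1, 0], [10, 0], [10, 1], [11, 0]],
                          dtype=float)
        x = np.array([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        corr = correlogram(x, coords, increment=1.0)
        assert corr.table["flagged"].any()
        assert len(corr.table) >= 10  # classes contiguous from 0 to max dist

    def test_pair_counts_cover_all_pairs(self):
        rng = np.random.default_rng(4)
        g = Grid.regular(5, 5)
        x = rng.standard_normal(25)
        corr = correlogram(x, g.coords, increment=1.3)
        assert corr.table["n_pairs"].sum() == 25 * 24 // 2


class TestNeighborThreshold:
    def _corr(self, ps):
        t = pd.DataFrame(
            {"lower": np.arange(len(ps)) * 1.0,
             "upper": np.arange(1, len(ps) + 1) * 1.0,
             "n_pairs": 10, "I": 0.1, "expected": -0.1, "variance": 0.01,
             "p": ps, "flagged": [p is np.nan for p in ps]}
        )
        return Correlogram(t, 1.0)

    def test_first_nonsignificant_class(self):
        assert neighbor_threshold(self._corr([0.001, 0.001, 0.21, 0.001])) == 3.0

    def test_all_significant_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="every distance class"):
            assert neighbor_threshold(self._corr([0.01, 0.01, 0.01])) == 3.0

    def test_first_class_nonsignificant(self):
        assert neighbor_threshold(self._corr([0.5, 0.001])) == 1.0


class TestBuildWeights:
    def test_two_cells(self):
        w = build_weights(np.array([[0.0, 0.0], [1.0, 0.0]]), 1.5)
        assert np.allclose(w.W.toarray(), [[0, 1], [1, 0]])

    def test_rook_interior_quarter_weights(self):
        g = Grid.regular(5, 5)
        w = build_weights(g.coords, 1.01)
        interior = 12  # center cell of the 5x5
        row = w.W.toarray()[interior]
        assert np.isclose(row.sum(), 1.0)
        assert np.allclose(row[row > 0], 0.25)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        coords = rng.random((60, 2)) * 5
        w = build_weights(coords, 1.5)
        assert np.allclose(np.asarray(w.W.sum(axis=1)).ravel(), 1.0)
        assert np.allclose(w.W.diagonal(), 0.0)
        assert np.allclose((w.A - w.A.T).toarray(), 0)

    def test_islands_error_and_escape_hatch(self):
        coords = np.array([[0, 0], [1, 0], [50, 50]], float)
        with pytest.raises(ValueError, match="no neighbor"):
            build_weights(coords, 2.0, ids=("a", "b", "far"))
        w = build_weights(coords, 2.0, ids=("a", "b", "far"), drop_islands=True)
        assert w.ids == ("a", "b")
        assert w.n == 2


def simulate_sar(weights, X, beta, lam, sigma, rng):
    n = X.shape[0]
    eps = rng.standard_normal(n) * sigma
    u = spsolve((identity(n) - lam * weights.W).tocsc(), eps)
    return X @ beta + u


@pytest.fixture(scope="module")
def grid_weights():
    g = Grid.regular(15, 15)
    return g, build_weights(g.coords, 1.6)


@pytest.fixture(scope="module")
def subsets_setup():
    g = Grid.regular(12, 12)
    w = build_weights(g.coords, 1.6)
    rng = np.random.default_rng(13)
    cand = pd.DataFrame(
        rng.standard_normal((g.n_cells, 3)), columns=["x1", "x2", "x3"]
    )
    y = simulate_sar(
        w, np.column_stack([np.ones(g.n_cells), cand["x1"], cand["x2"]]),
        np.array([0.5, 1.2, -1.0]), 0.5, 1.0, rng,
    )
    return g, w, cand, y


class TestFitSarError:
    def test_fixed_lambda_zero_is_ols(self, grid_weights):
        g, w = grid_weights
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(g.n_cells),
                             rng.standard_normal((g.n_cells, 2))])
        y = X @ np.array([1.0, 0.5, -0.5]) + rng.standard_normal(g.n_cells)
        fit = fit_sar_error(y, X, w, fixed_lam=0.0)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.beta, ols, atol=1e-6)

    def test_lambda_zero_data_recovers_ols(self, grid_weights):
        g, w = grid_weights
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(g.n_cells),
                             rng.standard_normal((g.n_cells, 2))])
        y = X @ np.array([1.0, 0.5, -0.5]) + 0.1 * rng.standard_normal(g.n_cells)
        fit = fit_sar_error(y, X, w)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert abs(fit.lam) < 0.25
        assert np.allclose(fit.beta, ols, atol=0.05)

    def test_loglik_matches_dense_oracle(self, grid_weights):
        """Concentrated logL equals a dense-matrix oracle that forms
        (I - lambda W) explicitly, to 1e-6."""
        g, w = grid_weights
        rng = np.random.default_rng(8)
        n = g.n_cells
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = simulate_sar(w, X, np.array([1.0, 0.5]), 0.5, 1.0, rng)
        fit = fit_sar_error(y, X, w)
        M = np.eye(n) - fit.lam * w.W.toarray()
        ys, Xs = M @ y, M @ X
        b, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ b
        s2 = e @ e / n
        sign, logdet = np.linalg.slogdet(M)
        oracle = logdet - n / 2 * np.log(2 * np.pi * s2) - n / 2
        assert sign > 0
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_optimum_at_least_lambda_zero(self, grid_weights):
        g, w = grid_weights
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(g.n_cells),
                             rng.standard_normal(g.n_cells)])
        y = simulate_sar(w, X, np.array([0.5, 1.0]), 0.6, 1.0, rng)
        free = fit_sar_error(y, X, w)
        at_zero = fit_sar_error(y, X, w, fixed_lam=0.0)
        assert free.loglik >= at_zero.loglik - 1e-9

    def test_aic_counts_lambda_and_sigma(self, grid_weights):
        g, w = grid_weights
        rng = np.random.default_rng(10)
        X = np.column_stack([np.ones(g.n_cells),
                             rng.standard_normal(g.n_cells)])
        y = simulate_sar(w, X, np.array([0.5, 1.0]), 0.3, 1.0, rng)
        fit = fit_sar_error(y, X, w)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (2 + 2))

    def test_singular_design_errors(self, grid_weights):
        g, w = grid_weights
        rng = np.random.default_rng(11)
        x = rng.standard_normal(g.n_cells)
        X = np.column_stack([np.ones(g.n_cells), x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError):
            fit_sar_error(x, X, w)


class TestNagelkerke:
    def test_equal_likelihood_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 50) == pytest.approx(0.0)

    def test_perfect_fit_limit_one(self):
        assert nagelkerke_r2(1e6, -100.0, 50) == pytest.approx(1.0)

    def test_noiseless_linear_fit_near_one(self):
        g = Grid.regular(10, 10)
        w = build_weights(g.coords, 1.5)
        rng = np.random.default_rng(12)
        X = np.column_stack([np.ones(100), rng.standard_normal(100)])
        y = X @ np.array([1.0, 2.0]) + 1e-6 * rng.standard_normal(100)
        fit = fit_sar_error(y, X, w)
        assert nagelkerke_r2(fit.loglik, _ols_loglik(y), 100) > 0.99


class TestAllSubsets:

    def test_counts_all_subsets(self, subsets_setup):
        _, w, cand, y = subsets_setup
        rank = all_subsets_selection(y, cand, w)
        assert len(rank.table) == 8  # 2^3 including intercept-only

    def test_delta_aic_zero_for_best(self, subsets_setup):
        _, w, cand, y = subsets_setup
        rank = all_subsets_selection(y, cand, w)
        assert rank.table["delta_aic"].iloc[0] == 0.0
        assert rank.table["aic"].is_monotonic_increasing

    def test_strong_drivers_selected(self, subsets_setup):
        _, w, cand, y = subsets_setup
        rank = all_subsets_selection(y, cand, w)
        best = rank.table["subset"].iloc[0]
        assert "x1" in best and "x2" in best

    def test_extra_fixed_always_included(self, subsets_setup):
        _, w, cand, y = subsets_setup
        extra = pd.Series(np.linspace(-1, 1, len(y)), name="nullcov")
        rank = all_subsets_selection(y, cand, w, extra_fixed=extra)
        for fit in rank.fits:
            assert "nullcov" in fit.names

    def test_delta_aic_invariant_to_predictor_rescaling(self, subsets_setup):
        _, w, cand, y = subsets_setup
        a = all_subsets_selection(y, cand, w).table.set_index("subset")
        cand2 = cand * np.array([10.0, 0.2, 5.0]) + np.array([3.0, -1.0, 0.0])
        b = all_subsets_selection(y, cand2, w).table.set_index("subset")
        for sub in a.index:
            assert a.loc[sub, "delta_aic"] == pytest.approx(
                b.loc[sub, "delta_aic"], abs=1e-6
            )

    def test_too_many_candidates(self, subsets_setup):
        _, w, _, y = subsets_setup
        cand = pd.DataFrame(np.random.default_rng(14).standard_normal((len(y), 16)))
        cand.columns = [f"c{j}" for j in range(16)]
        with pytest.raises(ValueError, match="15"):
            all_subsets_selection(y, cand, w)

    def test_coefficient_stars(self, subsets_setup):
        _, w, cand, y = subsets_setup
        rank = all_subsets_selection(y, cand, w)
        coefs = rank.best.coefficients()
        assert set(coefs.columns) == {"estimate", "se", "z", "p", "sig"}
        assert (coefs.loc[coefs.p < 0.001, "sig"] == "***").all()
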