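"""Weights, Moran's I, Dutilleul's test, OLS/SAR fits, and AICc inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phylospat.spatial_stats import (
    _candidate_subsets,
    aicc,
    akaike_weights,
    all_subsets,
    build_weights,
    fit_ols,
    fit_sar_error,
    morans_i,
    pearson_dutilleul,
    significance_stars,
)
from tests.conftest import GRFSampler, lattice_cells


class TestBuildWeights:
    def test_2x2_queen_everyone_has_three_neighbors(self):
        w = build_weights(lattice_cells(2, 2), "queen", row_standardize=False)
        deg = np.asarray(w.matrix.sum(axis=1)).ravel()
        assert list(deg) == [3, 3, 3, 3]

    def test_3x3_rook_center_has_four_neighbors(self):
        w = build_weights(lattice_cells(3, 3), "rook", row_standardize=False)
        deg = np.asarray(w.matrix.sum(axis=1)).ravel()
        assert deg[4] == 4  # center cell, row-major
        assert sorted(deg) == [2, 2, 2, 2, 3, 3, 3, 3, 4]

    def test_row_standardized_rows_sum_to_one(self):
        w = build_weights(lattice_cells(4, 5), "queen", row_standardize=True)
        sums = np.asarray(w.matrix.sum(axis=1)).ravel()
        np.testing.assert_allclose(sums, 1.0)
        assert np.all(w.matrix.diagonal() == 0)

    def test_symmetric_neighbor_structure(self):
        w = build_weights(lattice_cells(3, 4), "rook", row_standardize=True)
        b = (w.matrix > 0).astype(int)
        assert (b != b.T).nnz == 0

    def test_isolated_cells(self):
        cells = pd.DataFrame({"x": [0.5, 10.5], "y": [0.5, 0.5]}, index=["a", "b"])
        with pytest.raises(ValueError, match="isolated"):
            build_weights(cells, "queen", cell_size=1.0)


class TestMoransI:
    def test_checkerboard_is_exactly_minus_one(self):
        cells = lattice_cells(6, 6)
        w = build_weights(cells, "rook", row_standardize=True)
        z = np.array(
            [1.0 if (i // 6 + i % 6) % 2 == 0 else -1.0 for i in range(36)]
        )
        res = morans_i(z, w, n_perm=499, seed=0)
        assert res.statistic == pytest.approx(-1.0, abs=1e-12)
        assert res.p_value < 0.05

    def test_permutation_null_mean_matches_closed_form(self):
        # E[I] under the permutation null is -1/(n-1)
        cells = lattice_cells(6, 6)
        w = build_weights(cells, "rook")
        rng = np.random.default_rng(8)
        z = rng.normal(size=36)
        z = z - z.mean()
        n_sh = 10_000
        sims = np.empty(n_sh)
        for b in range(n_sh):
            sims[b] = morans_i(rng.permutation(z), w, n_perm=0).statistic
        se = sims.std(ddof=1) / np.sqrt(n_sh)
        assert abs(sims.mean() - (-1.0 / 35.0)) < 3 * se

    def test_indicator_input_is_computable(self):
        w = build_weights(lattice_cells(3, 3), "queen")
        vals = np.zeros(9)
        vals[4] = 1.0
        res = morans_i(vals, w, n_perm=99, seed=1)
        assert np.isfinite(res.statistic)
        assert 0 < res.p_value <= 1

    def test_constant_input_rejected(self):
        w = build_weights(lattice_cells(3, 3), "queen")
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(9), w)


class TestDutilleul:
    def test_zero_correlation_gives_t_zero_p_one(self):
        # exactly orthogonal contrasts
        x = np.array([1.0, 1, -1, -1, 0, 0, 0, 0])
        y = np.array([0.0, 0, 0, 0, 1, 1, -1, -1])
        coords = np.column_stack([np.arange(8.0), np.zeros(8)])
        res = pearson_dutilleul(x, y, coords, n_distance_classes=4)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.t == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_iid_effective_sample_size_near_n(self):
        coords = np.array([[c + 0.5, r + 0.5] for r in range(10) for c in range(10)])
        rng = np.random.default_rng(10)
        ratios = [
            pearson_dutilleul(
                rng.standard_normal(100), rng.standard_normal(100), coords
            ).effective_sample_size
            / 100
            for _ in range(100)
        ]
        assert 0.85 <= np.mean(ratios) <= 1.1

    def test_autocorrelation_shrinks_effective_sample_size(self, grf_10x10):
        rng = np.random.default_rng(11)
        ess = [
            pearson_dutilleul(
                grf_10x10.draw(rng), grf_10x10.draw(rng), grf_10x10.coords
            ).effective_sample_size
            for _ in range(50)
        ]
        assert np.mean(ess) < 50  # far below n = 100

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_dutilleul([1, 2, 3], [1, 2, 3], np.zeros((3, 2)))


class TestOLS:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        y = 3.0 + 2.0 * x
        fit = fit_ols(y, pd.DataFrame({"x": x}))
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_intercept_only_is_the_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        fit = fit_ols(y, pd.DataFrame(index=range(4)))
        assert fit.params["intercept"] == pytest.approx(3.0)

    def test_slope_recovery_within_three_se(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=200)
        y = 1.0 + 2.0 * x + rng.normal(size=200)
        fit = fit_ols(y, pd.DataFrame({"x": x}))
        assert abs(fit.params["x"] - 2.0) < 3 * fit.bse["x"]

    def test_collinear_design_named(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match="x2"):
            fit_ols(x, pd.DataFrame({"x1": x, "x2": 2 * x}))


@pytest.fixture(scope="module")
def rook_15():
    return build_weights(lattice_cells(15, 15), "rook")


class TestSAR:
    def test_lambda_zero_matches_ols(self, rook_15):
        rng = np.random.default_rng(13)
        x = rng.normal(size=225)
        y = 1 + 0.5 * x + rng.normal(size=225)
        X = pd.DataFrame({"x": x}, index=rook_15.ids)
        ols = fit_ols(y, X)
        sar = fit_sar_error(y, X, rook_15, lam=0.0, moran_n_perm=0)
        assert abs(sar.loglik - ols.loglik) < 1e-6
        np.testing.assert_allclose(sar.params, ols.params, atol=1e-8)
        # AICc differs only through the extra lambda parameter
        assert sar.aicc == pytest.approx(
            aicc(ols.loglik, ols.k + 1, ols.n), abs=1e-6
        )

    def test_parameter_recovery(self, rook_15):
        # truth: lambda = 0.6, beta = (1, -0.5); 60 replicates here (the
        # acceptance test runs the full 200)
        n = 225
        W = rook_15.matrix.toarray()
        ainv = np.linalg.inv(np.eye(n) - 0.6 * W)
        rng = np.random.default_rng(14)
        lams, slopes = [], []
        for _ in range(60):
            x = rng.normal(size=n)
            y = 1.0 - 0.5 * x + ainv @ rng.normal(size=n)
            fit = fit_sar_error(y, pd.DataFrame({"x": x}), rook_15, moran_n_perm=0)
            lams.append(fit.lam)
            slopes.append(fit.params["x"])
        assert 0.5 <= np.mean(lams) <= 0.7
        assert abs(np.mean(slopes) + 0.5) < 0.05

    def test_filtered_residuals_lose_autocorrelation(self, rook_15):
        n = 225
        W = rook_15.matrix.toarray()
        ainv = np.linalg.inv(np.eye(n) - 0.6 * W)
        rng = np.random.default_rng(15)
        x = rng.normal(size=n)
        y = 1.0 - 0.5 * x + ainv @ rng.normal(size=n)
        fit = fit_sar_error(
            y, pd.DataFrame({"x": x}), rook_15, moran_n_perm=199, moran_seed=3
        )
        assert abs(fit.residual_moran.statistic) < 0.1
        assert fit.residual_moran.p_value > 0.05

    def test_pseudo_r2_in_unit_interval(self, rook_15):
        rng = np.random.default_rng(16)
        x = rng.normal(size=225)
        y = 2 * x + rng.normal(size=225)
        fit = fit_sar_error(y, pd.DataFrame({"x": x}), rook_15, moran_n_perm=0)
        assert 0.0 <= fit.pseudo_r2 <= 1.0
        assert 0.0 <= fit.r2_fitted_obs <= 1.0


class TestInformationCriteria:
    def test_closed_form_value(self):
        assert aicc(-100.0, 3, 50) == pytest.approx(200 + 6 + 24 / 46, abs=1e-10)

    def test_large_n_limit_is_aic(self):
        a = aicc(-100.0, 3, 10**8)
        assert abs(a - (200 + 6)) < 1e-6

    def test_fewer_parameters_win_at_equal_loglik(self):
        assert aicc(-50.0, 2, 40) < aicc(-50.0, 3, 40)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_single_model_weight_one(self):
        np.testing.assert_allclose(akaike_weights([123.4]), [1.0])

    def test_delta_two_closed_form(self):
        w = akaike_weights([10.0, 12.0])
        e = np.exp(-1.0)
        np.testing.assert_allclose(w, [1 / (1 + e), e / (1 + e)], atol=1e-10)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-500, 500), min_size=1, max_size=12))
    def test_weights_always_sum_to_one(self, vals):
        assert akaike_weights(vals).sum() == pytest.approx(1.0, abs=1e-12)


class TestAllSubsets:
    def test_marginality_restricts_quadratic(self):
        subsets = _candidate_subsets(["x", "x2"], [("x2", "x")])
        assert sorted(subsets) == [(), ("x",), ("x", "x2")]

    def test_free_terms_give_full_lattice(self):
        assert len(_candidate_subsets(list("abcd"), [])) == 16

    def test_term_in_every_model_has_importance_one(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=50)
        y = 1 + x + rng.normal(size=50)
        sel = all_subsets(y, pd.DataFrame({"x": x, "x2": x**2}),
                          marginality=[("x2", "x")], model_kind="ols")
        assert sel.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert sel.table["delta_aicc"].iloc[0] == 0.0
        assert 0 <= sel.importance.max() <= 1

    def test_quadratic_signal_is_detected(self, rook_15):
        # U-shaped response: the best model must pick up a positive x^2 term
        rng = np.random.default_rng(18)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=225)
            y = 0.2 + 0.6 * x**2 + 0.4 * rng.normal(size=225)
            sel = all_subsets(
                y,
                pd.DataFrame({"x": x, "x2": x**2}, index=rook_15.ids),
                marginality=[("x2", "x")],
                model_kind="sar",
                w=rook_15,
            )
            best = sel.best
            if "x2" in best.terms and best.params["x2"] > 0 and best.pvalues["x2"] < 0.05:
                hits += 1
        assert hits >= 18


def test_significance_star_levels():
    assert [significance_stars(p) for p in (0.0005, 0.005, 0.03, 0.2)] == [
        "***", "**", "*", "ns",
    ]
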