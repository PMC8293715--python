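"""OLS/SAR/random-forest layer: closed-form oracles and recovery checks."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elevrange import (
    InferenceError,
    build_weights,
    ols_single,
    rapoport_regression,
    rf_importance,
    sar_error_fit,
    significance_stars,
    standardize,
)
from elevrange.inference import SpatialWeights, oob_predictions


class TestStandardize:
    def test_closed_form(self):
        np.testing.assert_allclose(standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_idempotent_and_moments(self, rng):
        x = rng.normal(3.0, 7.0, size=50)
        z = standardize(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(InferenceError, match="constant"):
            standardize([2.0, 2.0, 2.0])


class TestOlsSingle:
    def test_identity_relationship(self, rng):
        x = rng.normal(size=30)
        res = ols_single(x, x)
        assert res.coef == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_orthogonal_predictor_has_zero_coefficient(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # orthogonal to x by construction
        assert ols_single(y, x).coef == pytest.approx(0.0, abs=1e-12)

    def test_coefficient_equals_pearson_r(self, rng):
        x = rng.normal(size=10)
        y = 0.3 * x + rng.normal(size=10)
        r = stats.pearsonr(x, y).statistic
        assert ols_single(y, x).coef == pytest.approx(r, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(InferenceError, match="length"):
            ols_single([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRapoportRegression:
    def profile(self, y):
        e = np.linspace(1800, 5400, len(y))
        return pd.DataFrame({"plot_id": range(len(y)), "elevation_m": e,
                             "group": "overall", "n_species": 5, "mean_range_m": y})

    def test_linear_increase_is_supported(self):
        y = np.linspace(500, 2000, 20)
        res, supported = rapoport_regression(self.profile(y))
        assert supported and res.coef > 0
        assert res.adj_r2 == pytest.approx(1.0)

    def test_constant_profile_not_supported(self):
        res, supported = rapoport_regression(self.profile(np.full(20, 900.0)))
        assert not supported

    def test_antisymmetry_under_elevation_negation(self, rng):
        y = np.linspace(500, 2000, 30) + rng.normal(0, 50, 30)
        prof = self.profile(y)
        res_pos, sup_pos = rapoport_regression(prof)
        flipped = prof.assign(elevation_m=-prof.elevation_m)
        res_neg, sup_neg = rapoport_regression(flipped)
        assert res_neg.coef == pytest.approx(-res_pos.coef)
        assert sup_pos and not sup_neg

    def test_too_few_plots(self):
        with pytest.raises(InferenceError, match=">= 3"):
            rapoport_regression(self.profile([1.0, 2.0]))

    def test_missing_plots_dropped(self):
        y = np.linspace(500, 2000, 20)
        y[3] = np.nan
        res, _ = rapoport_regression(self.profile(y))
        assert res.n == 19


class TestBuildWeights:
    def test_union_rule_on_collinear_plots(self):
        w = build_weights(np.array([0.0, 1.0, 10.0]), k=1)
        # middle plot is nearest neighbour of both ends -> two neighbours
        assert w.adjacency[1].sum() == 2
        assert w.adjacency[0, 1] == 1 and w.adjacency[2, 1] == 1

    def test_rows_sum_to_one(self, rng):
        w = build_weights(rng.uniform(0, 100, 20), k=5)
        np.testing.assert_allclose(w.matrix.sum(axis=1), 1.0)
        assert np.diag(w.matrix).sum() == 0

    def test_full_graph_when_k_is_n_minus_1(self):
        w = build_weights(np.arange(6.0), k=5)
        off = w.matrix[~np.eye(6, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 5.0)

    def test_needs_enough_plots(self):
        with pytest.raises(InferenceError, match="k"):
            build_weights(np.arange(4.0), k=5)


class TestSarErrorFit:
    def test_zero_weights_collapse_to_ols(self, rng):
        n = 40
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        W = SpatialWeights(matrix=np.zeros((n, n)), adjacency=np.zeros((n, n)),
                           neighbor_rule="none")
        s = sar_error_fit(y, x, W)
        o = ols_single(y, x, standardize_inputs=False)
        assert s.lam == 0.0
        assert s.coef == pytest.approx(o.coef, abs=1e-10)

    def test_lambda_estimator_is_unbiased_at_zero(self):
        W = build_weights(np.arange(200.0), k=5)
        lams = []
        for rep in range(30):
            rng = np.random.default_rng(rep)
            x = rng.normal(size=200)
            y = 0.5 * x + rng.normal(size=200)
            s = sar_error_fit(y, x, W)
            lams.append(s.lam)
            o = ols_single(y, x, standardize_inputs=False)
            assert abs(s.coef - o.coef) <= 2 * o.se
        assert abs(np.mean(lams)) < 0.08  # ~3 SE of the mean over 30 reps

    def test_aic_is_finite_and_reported(self, rng):
        W = build_weights(np.arange(50.0), k=3)
        s = sar_error_fit(rng.normal(size=50), rng.normal(size=50), W)
        assert np.isfinite(s.aic) and s.model_kind == "SAR"


class TestRfImportance:
    def make_data(self, rng, n=120):
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["signal", "n1", "n2"])
        y = 2.0 * X.signal.to_numpy() + 0.3 * rng.normal(size=n)
        return y, X

    def test_oob_mask_replication_matches_sklearn(self, rng):
        from sklearn.ensemble import RandomForestRegressor

        y, X = self.make_data(rng)
        f = RandomForestRegressor(n_estimators=50, random_state=3, oob_score=True)
        f.fit(X.to_numpy(), y)
        pred, cnt = oob_predictions(f, X.to_numpy())
        ok = cnt > 0
        r2 = 1 - np.sum((y[ok] - pred[ok]) ** 2) / np.sum((y[ok] - y[ok].mean()) ** 2)
        assert r2 == pytest.approx(f.oob_score_, abs=1e-12)

    def test_fixed_seed_is_deterministic(self, rng):
        y, X = self.make_data(rng)
        a = rf_importance(y, X, n_runs=3, seed=5, n_estimators=30)
        b = rf_importance(y, X, n_runs=3, seed=5, n_estimators=30)
        pd.testing.assert_frame_equal(a.importances, b.importances)
        assert a.pct_var_explained == b.pct_var_explained

    def test_top_ranking_invariant_under_affine_response_rescale(self, rng):
        # %IncMSE is a ratio of MSEs, so rescaling the response must not
        # change which predictor dominates (tree tie-breaks may perturb
        # the exact values)
        y, X = self.make_data(rng)
        a = rf_importance(y, X, n_runs=2, seed=1, n_estimators=30)
        b = rf_importance(5.0 * y + 7.0, X, n_runs=2, seed=1, n_estimators=30)
        ta = a.importances.set_index("predictor").mean_pct_inc_mse
        tb = b.importances.set_index("predictor").mean_pct_inc_mse
        assert ta.idxmax() == tb.idxmax() == "signal"
        assert tb["signal"] > 10 * max(tb["n1"], tb["n2"])

    def test_holdout_variant_also_ranks_signal_first(self, rng):
        y, X = self.make_data(rng, n=200)
        imp = rf_importance(y, X, n_runs=3, seed=2, n_estimators=50, method="holdout")
        t = imp.importances.set_index("predictor").mean_pct_inc_mse
        assert t["signal"] == t.max()

    def test_constant_response_rejected(self, rng):
        _, X = self.make_data(rng)
        with pytest.raises(InferenceError, match="constant"):
            rf_importance(np.ones(len(X)), X, n_runs=1, seed=0)

    def test_small_n_rejected(self, rng):
        with pytest.raises(InferenceError, match="n >= 20"):
            rf_importance(rng.normal(size=10), pd.DataFrame(rng.normal(size=(10, 2))),
                          n_runs=1, seed=0)


def test_significance_stars():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.0005) == "***"
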