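"""OLS panel: formulas, invariances, oracle cross-checks, recovery."""

import numpy as np
import pytest
import statsmodels.api as sm

from topoqspr import (
    DegenerateInputError,
    SimpleLinearRegression,
    fit_ols,
    pearson_r,
    predict,
    round_half_away,
)


class TestFitOls:
    def test_perfect_fit(self):
        ft = fit_ols([0, 1, 2], [0, 1, 2])
        assert (ft.a, ft.b, ft.r, ft.se) == (0, 1, 1, 0)
        assert ft.p == 0

    def test_flat_response_convention(self):
        ft = fit_ols([0, 1, 2], [1, 1, 1])
        assert (ft.a, ft.b, ft.r, ft.se, ft.f, ft.p) == (1, 0, 0, 0, 0, 1)

    def test_descriptor_vs_polarizability_panel(self, tables):
        """Second-Zagreb vs polarizability across the 11 drugs."""
        desc, props = tables
        ft = fit_ols(desc["M2"], props["polarizability"]).round(4)
        assert (ft.a, ft.b, ft.r, ft.r2, ft.se, ft.f) == (
            7.5184, 0.1832, 0.9587, 0.9191, 2.2492, 102.2225,
        )
        assert ft.p < 5e-4  # prints as 0.000

    @pytest.mark.parametrize(
        "x,y,err",
        [
            ([1, 2], [1, 2], DegenerateInputError),  # n < 3
            ([1, 1, 1], [1, 2, 3], DegenerateInputError),  # zero-variance x
            ([1, 2, 3], [1, 2], ValueError),  # length mismatch
        ],
    )
    def test_degenerate_inputs(self, x, y, err):
        with pytest.raises(err):
            fit_ols(x, y)

    def test_panel_internal_identities(self, tables):
        desc, props = tables
        for i in desc.columns:
            ft = fit_ols(desc[i], props["complexity"])
            assert -1 <= ft.r <= 1 and 0 <= ft.p <= 1 and ft.se >= 0
            assert ft.r2 == pytest.approx(ft.r**2, abs=1e-12)
            assert ft.f == pytest.approx((ft.n - 2) * ft.r2 / (1 - ft.r2), abs=1e-9)

    def test_against_statsmodels(self, tables):
        """Independent OLS oracle over all 42 descriptor/property pairs."""
        desc, props = tables
        for i in desc.columns:
            for p in props.columns:
                ft = fit_ols(desc[i], props[p])
                sm_fit = sm.OLS(props[p], sm.add_constant(desc[i].astype(float))).fit()
                assert ft.a == pytest.approx(sm_fit.params.iloc[0], rel=1e-9)
                assert ft.b == pytest.approx(sm_fit.params.iloc[1], rel=1e-9)
                assert ft.f == pytest.approx(sm_fit.fvalue, rel=1e-9)
                assert ft.p == pytest.approx(sm_fit.f_pvalue, abs=1e-12)
                assert ft.se == pytest.approx(
                    np.sqrt(sm_fit.mse_resid), rel=1e-9
                )


class TestPredict:
    def test_published_equation_prediction(self, tables):
        desc, props = tables
        ft = fit_ols(desc["M2"], props["polarizability"]).round(4)
        assert predict(ft, 97) == pytest.approx(25.2888, abs=5e-5)

    def test_line_passes_through_mean_point(self, tables):
        desc, props = tables
        x, y = desc["H"].to_numpy(), props["molar_volume"].to_numpy()
        ft = fit_ols(x, y)
        assert predict(ft, x.mean()) == pytest.approx(y.mean(), rel=1e-12)


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(5.0)
        assert pearson_r(x, 2 * x + 3) == pytest.approx(1.0)

    def test_first_zagreb_vs_polarizability(self, tables):
        desc, props = tables
        assert pearson_r(desc["M1"], props["polarizability"]) == pytest.approx(
            0.7466, abs=5e-5
        )

    def test_ss_vs_polarizability(self, tables):
        desc, props = tables
        assert pearson_r(desc["SS"], props["polarizability"]) == pytest.approx(
            0.9803, abs=5e-5
        )

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestInvariances:
    rng = np.random.default_rng(42)

    def test_residual_orthogonality(self):
        x = self.rng.normal(size=50)
        y = 2 + 3 * x + self.rng.normal(size=50)
        ft = fit_ols(x, y)
        resid = y - (ft.a + ft.b * x)
        assert abs(resid.sum()) < 1e-9
        assert abs((resid * x).sum()) < 1e-9

    def test_scale_equivariance(self):
        x = self.rng.normal(size=30)
        y = 1 + 0.5 * x + self.rng.normal(size=30)
        ft1, ft2 = fit_ols(x, y), fit_ols(10 * x, y)
        assert ft2.b == pytest.approx(ft1.b / 10, rel=1e-9)
        for stat in ("r", "r2", "f", "p"):
            assert getattr(ft2, stat) == pytest.approx(getattr(ft1, stat), rel=1e-9)

    def test_pvalue_monotone_in_f(self):
        from scipy import stats

        fs = [0.0, 0.5, 2.0, 10.0, 100.0]
        ps = [float(stats.f.sf(f, 1, 9)) for f in fs]
        assert ps[0] == 1.0
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_parameter_recovery_within_3_se(self):
        """y = 2 + 0.5x + N(0,1), n=200: 3-SE coverage >= 95% over 200 reps."""
        rng = np.random.default_rng(7)
        n, hits = 200, 0
        for _ in range(200):
            x = rng.uniform(0, 10, size=n)
            y = 2.0 + 0.5 * x + rng.normal(0, 1, size=n)
            ft = fit_ols(x, y)
            sxx = ((x - x.mean()) ** 2).sum()
            se_b = ft.se / np.sqrt(sxx)
            se_a = ft.se * np.sqrt(1 / n + x.mean() ** 2 / sxx)
            hits += abs(ft.b - 0.5) < 3 * se_b and abs(ft.a - 2.0) < 3 * se_a
        assert hits / 200 >= 0.95


class TestSklearnEstimator:
    def test_fit_predict_and_fitted_attrs(self):
        X = np.arange(10.0).reshape(-1, 1)
        y = 3 + 2 * X[:, 0]
        m = SimpleLinearRegression().fit(X, y)
        assert m.intercept_ == pytest.approx(3) and m.slope_ == pytest.approx(2)
        np.testing.assert_allclose(m.predict([[4.0]]), [11.0])
        assert m.score(X, y) == pytest.approx(1.0)

    def test_composes_in_pipeline_with_index_transformer(self, tables):
        """Graph -> descriptor -> regression, end to end through sklearn."""
        from sklearn.pipeline import make_pipeline

        from topoqspr import TopologicalIndexCalculator, drug_graph

        drugs = ["Sulfadiazine", "Dorzolamide", "Meticrane", "Famotidine",
                 "Dabrafenib", "Daranide", "Sulfapyridine"]
        graphs = [drug_graph(d).graph for d in drugs]
        _, props = tables
        y = props.loc[drugs, "polarizability"].to_numpy()
        pipe = make_pipeline(
            TopologicalIndexCalculator(indices=("SS",)), SimpleLinearRegression()
        )
        pipe.fit(graphs, y)
        assert pipe.score(graphs, y) > 0.9  # SS tracks polarizability closely

    def test_rejects_multicolumn_X(self):
        with pytest.raises(ValueError, match="one predictor"):
            SimpleLinearRegression().fit(np.ones((5, 2)), np.arange(5))


def test_round_half_away():
    assert round_half_away(0.05395, 4) == 0.054
    assert round_half_away(-0.00005, 4) == -0.0001
    assert round_half_away(1.0, 4) == 1.0
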