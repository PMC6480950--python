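import numpy as np
import pandas as pd
import pytest

import lurkit as lk
from lurkit.buffers import ColumnMeta, PredictorTable
from lurkit.model import RankDeficientError, summary_csv


def _table(frame: pd.DataFrame, priors: dict[str, str]) -> PredictorTable:
    data = frame.copy()
    data.insert(0, "period", "2010")
    data.insert(0, "station_id", [f"S{i}" for i in range(len(frame))])
    meta = {c: ColumnMeta(None, None, "", priors.get(c, "unconstrained"), "covariate")
            for c in frame.columns}
    return PredictorTable(data, meta)


class TestFitOLS:
    def test_perfect_linear_fit(self):
        x = np.arange(10.0)
        fit = lk.fit_ols(pd.DataFrame({"x": x}), 2.0 * x)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_convention(self):
        x = np.arange(10.0)
        fit = lk.fit_ols(pd.DataFrame({"x": x}), np.full(10, 5.0))
        assert fit.r2 == 0.0
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)

    def test_normal_equations_oracle(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        fit = lk.fit_ols(frame, y)
        # longhand normal equations, independent of the lstsq path
        A = np.column_stack([np.ones(12), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(fit.coefficients, beta[1:], atol=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        X = rng.normal(size=(40, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=40)
        frame = pd.DataFrame(X, columns=list("abcd"))
        fit = lk.fit_ols(frame, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params[1:], rtol=1e-10)
        np.testing.assert_allclose(fit.p_values, ref.pvalues[1:], rtol=1e-8)
        assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-12)
        assert fit.adjusted_r2 == pytest.approx(ref.rsquared_adj, rel=1e-12)

    def test_rank_deficiency_names_columns(self, rng):
        a = rng.normal(size=20)
        frame = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=20)})
        with pytest.raises(RankDeficientError, match="b"):
            lk.fit_ols(frame, rng.normal(size=20))


class TestVIF:
    def test_orthogonal_columns(self):
        # exactly sample-uncorrelated pair
        u = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        v = v - v.mean()
        v = v - u * (u @ v) / (u @ u)
        out = lk.vif(pd.DataFrame({"u": u, "v": v}))
        np.testing.assert_allclose(out.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_closed_form_correlation_08(self):
        # construct exact sample correlation 0.8 from an orthonormal pair
        n = 50
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        u, v = np.cos(t), np.sin(t)
        x1 = u
        x2 = 0.8 * u + 0.6 * v
        out = lk.vif(pd.DataFrame({"x1": x1, "x2": x2}))
        expect = 1.0 / (1.0 - 0.64)
        np.testing.assert_allclose(out.to_numpy(), [expect, expect], rtol=1e-10)

    def test_duplicate_column_infinite(self, rng):
        a = rng.normal(size=30)
        out = lk.vif(pd.DataFrame({"a": a, "b": a.copy()}))
        assert np.isinf(out).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        X = rng.normal(size=(60, 4))
        X[:, 3] = 0.7 * X[:, 0] + 0.3 * X[:, 3]
        frame = pd.DataFrame(X, columns=list("abcd"))
        mine = lk.vif(frame).to_numpy()
        A = np.column_stack([np.ones(60), X])
        ref = [variance_inflation_factor(A, j + 1) for j in range(4)]
        np.testing.assert_allclose(mine, ref, rtol=1e-8)


class TestUnivariateScreen:
    def test_self_predictor(self, rng):
        y = rng.normal(size=30)
        out = lk.univariate_screen(pd.DataFrame({"x": y}), y, {"x": "positive"})
        assert out.loc[0, "r2"] == pytest.approx(1.0)
        assert bool(out.loc[0, "eligible"])

    def test_sign_violation_ineligible(self, rng):
        y = rng.normal(size=30)
        out = lk.univariate_screen(pd.DataFrame({"x": -y}), y, {"x": "positive"})
        assert out.loc[0, "r2"] == pytest.approx(1.0)
        assert not bool(out.loc[0, "eligible"])

    def test_ranking_matches_per_column_fits(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        y = X["c"].to_numpy() + 0.5 * rng.normal(size=40)
        out = lk.univariate_screen(X, y)
        for _, row in out.iterrows():
            fit = lk.fit_ols(X[[row["column"]]], y)
            assert row["r2"] == pytest.approx(fit.r2, rel=1e-9)
        assert list(out["r2"]) == sorted(out["r2"], reverse=True)


class TestForwardSelect:
    def test_all_priors_violated_gives_intercept_only(self, rng):
        y = rng.normal(size=40)
        frame = pd.DataFrame({"a": -y, "b": -2 * y})
        table = _table(frame, {"a": "positive", "b": "positive"})
        model = lk.forward_select(table, y)
        assert model.terms == []
        assert model.intercept == pytest.approx(y.mean())

    def test_perfect_predictor_saturates(self, rng):
        y = rng.normal(size=40)
        frame = pd.DataFrame({"good": y.copy(),
                              "n1": rng.normal(size=40),
                              "n2": rng.normal(size=40)})
        table = _table(frame, {"good": "positive"})
        model = lk.forward_select(table, y)
        assert model.columns == ["good"]
        assert model.terms[0].incremental_r2 == pytest.approx(1.0)

    def test_deterministic_serialization(self, small_scene):
        _, design, y = small_scene
        a = lk.forward_select(design, y, lk.SelectionConfig()).to_json()
        b = lk.forward_select(design, y, lk.SelectionConfig()).to_json()
        assert a == b

    def test_gate_monotonicity_in_p_enter(self, small_scene):
        _, design, y = small_scene
        tight = lk.forward_select(design, y, lk.SelectionConfig(p_enter=0.005))
        loose = lk.forward_select(design, y, lk.SelectionConfig(p_enter=0.1))
        assert set(tight.columns) <= set(loose.columns)

    def test_invariants_on_fitted_model(self, small_scene):
        _, design, y = small_scene
        config = lk.SelectionConfig()
        model = lk.forward_select(design, y, config)
        lk.check_model_invariants(model, design, config)
        # adjusted R2 strictly increases along the entry sequence
        adj = []
        for k in range(1, len(model.columns) + 1):
            adj.append(lk.fit_ols(design.data[model.columns[:k]], y).adjusted_r2)
        assert all(b > a for a, b in zip(adj, adj[1:]))

    def test_max_terms_respected(self, small_scene):
        _, design, y = small_scene
        model = lk.forward_select(design, y, lk.SelectionConfig(max_terms=2))
        assert len(model.terms) == 2

    def test_log10_transform_predicts_on_original_scale(self, rng):
        x = rng.uniform(0, 2, 50)
        y = 10 ** (1.0 + 0.5 * x)
        table = _table(pd.DataFrame({"x": x}), {"x": "positive"})
        model = lk.forward_select(
            table, y, lk.SelectionConfig(response_transform="log10"))
        pred = model.predict(table.data)
        np.testing.assert_allclose(pred, y, rtol=1e-8)


class TestSummarize:
    def test_intercept_only(self):
        model = lk.LURModel(5.0, [], 0.0, 0.0, 1.0, 30)
        table = lk.summarize(model)
        assert len(table) == 1
        assert table.attrs["footer"]["n_obs"] == 30

    def test_entry_order_and_conservation(self, small_scene):
        _, design, y = small_scene
        model = lk.forward_select(design, y)
        table = lk.summarize(model)
        assert list(table["variable"])[1:] == model.columns
        assert table["incremental_r2"].dropna().sum() == pytest.approx(
            model.r2, abs=1e-9)

    def test_csv_round_trip_bytes(self, small_scene):
        _, design, y = small_scene
        model = lk.forward_select(design, y)
        text = summary_csv(model)
        again = summary_csv(lk.LURModel.from_json(model.to_json()))
        assert text == again
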