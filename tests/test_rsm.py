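"""Quadratic response-surface fitting, ANOVA arithmetic, linear regressions."""

import numpy as np
import pytest

from granmorph import rsm
from granmorph.errors import DesignError

GRID_LS = np.repeat([0.70, 0.85, 1.00, 1.15, 1.27], 3)
GRID_IS = np.tile([300.0, 500.0, 700.0], 5)


class TestDesignMatrix:
    @pytest.mark.parametrize("ls,is_rpm,row", [
        (1.0, 0.0, [1, 1, 0, 1, 0, 0]),
        (0.0, 0.0, [1, 0, 0, 0, 0, 0]),
        (1.0, 500.0, [1, 1, 500, 1, 250000, 500]),
    ])
    def test_single_rows(self, ls, is_rpm, row):
        ls_v = np.concatenate([[ls], np.linspace(0.5, 1.0, 5)])
        is_v = np.concatenate([[is_rpm], np.linspace(100, 900, 5)])
        X = rsm.build_design_matrix(ls_v, is_v)
        assert np.allclose(X[0], row)

    def test_underdetermined_design_rejected(self):
        with pytest.raises(DesignError):
            rsm.build_design_matrix([1.0] * 5, [500.0] * 5)

    def test_collinear_design_rejected(self):
        # a single impeller speed makes the IS and IS^2 columns collinear
        X = rsm.build_design_matrix(np.linspace(0.7, 1.2, 12), np.full(12, 500.0))
        with pytest.raises(DesignError):
            rsm.fit_quadratic(X, np.ones(12))


class TestFitQuadratic:
    @pytest.mark.parametrize("name", ["d_mean", "yield"])
    def test_noise_free_recovery_of_reference_coefficients(self, name):
        """OLS on exact surface data returns the printed coefficients."""
        ref = rsm.reference_models()[name]
        X = rsm.build_design_matrix(GRID_LS, GRID_IS)
        fit = rsm.fit_quadratic(X, ref.predict(GRID_LS, GRID_IS))
        assert np.allclose(fit.coefficients, ref.coefficients, rtol=1e-8, atol=0.0)
        assert fit.exact_fit

    def test_constant_responses_degenerate(self):
        X = rsm.build_design_matrix(GRID_LS, GRID_IS)
        fit = rsm.fit_quadratic(X, np.full(len(GRID_LS), 3.5))
        assert fit.b0 == pytest.approx(3.5, abs=1e-9)
        assert np.allclose(fit.coefficients[1:], 0.0, atol=1e-9)
        assert fit.degenerate_r2 and np.isnan(fit.r_squared)

    def test_noisy_recovery_within_confidence_interval(self):
        """Monte-Carlo: the yield L/S coefficient stays inside its own 95% CI."""
        ref = rsm.reference_models()["yield"]
        ls = np.tile(GRID_LS, 6)
        is_rpm = np.tile(GRID_IS, 6)
        X = rsm.build_design_matrix(ls, is_rpm)
        rng = np.random.default_rng(1)
        y = ref.predict(ls, is_rpm) + rng.normal(0.0, 2.0, size=90)
        fit = rsm.fit_quadratic(X, y)
        lo, hi = fit.conf_int()[1]
        assert lo <= 425.81688 <= hi

    def test_noise_free_recovery_of_arbitrary_quadratic(self):
        model = rsm.QuadraticModel(0.3, -1.2, 0.004, 2.5, -3e-6, -0.01)
        X = rsm.build_design_matrix(GRID_LS, GRID_IS)
        fit = rsm.fit_quadratic(X, model.predict(GRID_LS, GRID_IS))
        assert np.allclose(fit.coefficients, model.coefficients, rtol=1e-8)


class TestAnova:
    def _fit(self, sd=0.05, seed=0, n_rep=3):
        ref = rsm.reference_models()["d_mean"]
        ls, is_rpm = np.tile(GRID_LS, n_rep), np.tile(GRID_IS, n_rep)
        X = rsm.build_design_matrix(ls, is_rpm)
        rng = np.random.default_rng(seed)
        y = ref.predict(ls, is_rpm) + rng.normal(0, sd, size=len(ls))
        return rsm.fit_quadratic(X, y), X, y

    def test_model_mean_square_is_ss_over_df(self):
        """MS = SS/df row arithmetic, as in the published tables:
        8.49/5 = 1.70 and 63398.24/5 = 12679.65."""
        assert round(8.49 / 5, 2) == 1.70
        assert round(63398.24 / 5, 2) == 12679.65
        model, X, y = self._fit()
        for row in rsm.anova_quadratic(model, X, y):
            assert row.ms == pytest.approx(row.ss / row.df)

    def test_exact_fit_reports_infinite_f_with_flag(self):
        model, X, y = self._fit(sd=0.0)
        rows = rsm.anova_quadratic(model, X, y)
        assert all(r.exact_fit for r in rows)
        assert all(np.isinf(r.f) and r.p == 0.0 for r in rows)

    def test_model_ss_equals_sum_of_sequential_term_ss(self):
        model, X, y = self._fit(sd=0.08, seed=5)
        rows = rsm.anova_quadratic(model, X, y, ss_type="sequential")
        model_row = rows[0]
        assert sum(r.ss for r in rows[1:]) == pytest.approx(model_row.ss, rel=1e-9)

    def test_p_value_decreases_with_f(self):
        model, X, y = self._fit(sd=0.08, seed=2)
        rows = rsm.anova_quadratic(model, X, y)
        terms = sorted(rows[1:], key=lambda r: r.f)
        ps = [r.p for r in terms]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_published_yield_table_is_internally_consistent(self):
        """Term F = term MS / residual MS, with residual MS implied by the
        Model row (MS_model / F_model); printed rounding limits agreement."""
        table = rsm.reference_anova_tables()["yield"]
        model_row = table[table.term == "Model"].iloc[0]
        ms_resid = model_row.MS / model_row.F
        for _, row in table[table.term != "Model"].iterrows():
            implied_f = row.MS / ms_resid
            sig_figs = len(f"{row.F:.2f}".replace(".", "").lstrip("0"))
            tol = 0.001 if sig_figs >= 4 else 0.005
            assert implied_f == pytest.approx(row.F, rel=tol)

    def test_published_yield_ls_f_value(self):
        table = rsm.reference_anova_tables()["yield"]
        ms_resid = 12679.65 / 138.32
        assert 61713.25 / ms_resid == pytest.approx(673.21, rel=1e-3)


class TestPredictSurface:
    def test_size_surface_center_point(self):
        ref = rsm.reference_models()["d_mean"]
        grid = rsm.predict_surface(ref, [1.0], [500.0])
        assert grid.prediction.iloc[0] == pytest.approx(0.85997, abs=5e-6)

    def test_yield_surface_center_point(self):
        ref = rsm.reference_models()["yield"]
        grid = rsm.predict_surface(ref, [1.0], [500.0])
        assert grid.prediction.iloc[0] == pytest.approx(71.125, abs=5e-3)

    def test_zero_model_predicts_zero_everywhere(self):
        zero = rsm.QuadraticModel(0, 0, 0, 0, 0, 0)
        ls_grid, is_grid = rsm.default_prediction_grid(n=11)
        grid = rsm.predict_surface(zero, ls_grid, is_grid)
        assert (grid.prediction == 0).all()
        assert len(grid) == 121

    def test_prediction_is_linear_in_coefficients(self):
        a = rsm.QuadraticModel(1.0, 2.0, -0.01, 0.5, 1e-6, 0.002)
        b = rsm.QuadraticModel(-0.5, 1.0, 0.03, -2.0, -2e-6, 0.001)
        ab = rsm.QuadraticModel(*(a.coefficients + b.coefficients))
        ls_grid, is_grid = rsm.default_prediction_grid(n=7)
        pa = rsm.predict_surface(a, ls_grid, is_grid).prediction
        pb = rsm.predict_surface(b, ls_grid, is_grid).prediction
        pab = rsm.predict_surface(ab, ls_grid, is_grid).prediction
        assert np.allclose(pab, pa + pb)


class TestFitLinear:
    def test_roundness_sphericity_relation_recovered_exactly(self):
        """Points generated on r = 1.187 phi - 0.576 return that line, R^2 = 1."""
        phi = np.linspace(0.79, 0.94, 50)
        fit = rsm.fit_linear(phi, 1.187 * phi - 0.576)
        assert fit.slope == pytest.approx(1.187, rel=1e-12)
        assert fit.intercept == pytest.approx(-0.576, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_compressibility_ls_relation_recovered_exactly(self):
        """Points on CPS = 25.319 - 20.954 L/S return slope -20.954."""
        ls = np.linspace(0.70, 1.07, 20)
        fit = rsm.fit_linear(ls, 25.319 - 20.954 * ls)
        assert fit.slope == pytest.approx(-20.954, rel=1e-12)
        assert fit.intercept == pytest.approx(25.319, rel=1e-12)

    def test_constant_response_is_degenerate(self):
        fit = rsm.fit_linear([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0 and fit.degenerate

    def test_constant_predictor_is_an_error(self):
        with pytest.raises(DesignError):
            rsm.fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_collinear_points_give_unit_r_squared(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 30)
        fit = rsm.fit_linear(x, -3.0 * x + 7.0)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


class TestReferenceModels:
    def test_size_surface_coefficients_as_printed(self):
        m = rsm.reference_models()["d_mean"]
        assert m.b0 == 3.22765
        assert m.b1 == -6.10009
        assert m.b2 == 0.000907
        assert m.b11 == 4.41496
        assert m.b22 == 1.0458e-6
        assert m.b12 == -0.002795

    def test_yield_surface_constant_as_printed(self):
        m = rsm.reference_models()["yield"]
        assert m.b0 == -286.33147

    def test_coded_values_map_range_to_unit_interval(self):
        coded = rsm.coded_values([300.0, 500.0, 700.0], 300.0, 700.0)
        assert np.allclose(coded, [-1.0, 0.0, 1.0])
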