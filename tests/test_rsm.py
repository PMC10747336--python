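"""Box-Behnken design construction, desirability, quadratic fit, optimum."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbqc import rsm
from herbqc.exceptions import DataError, DomainError, ParameterError
from herbqc.rsm import (
    EXTRACTION_FACTORS,
    DesirabilityConfig,
    FactorSpec,
    bbd_design,
    desirability,
    fit_quadratic,
    model_matrix,
    optimize,
    overall_desirability,
    read_run_table,
    surface_grid,
)
from herbqc.synthetic import TrueSurface, make_bbd_responses


class TestDesign:
    def test_seventeen_runs(self):
        d = bbd_design(n_center=5)
        assert d.n_runs == 17
        assert int(d.center_mask.sum()) == 5

    def test_edge_midpoint_structure(self):
        d = bbd_design()
        non_center = d.runs[~d.center_mask]
        assert len(non_center) == 12
        assert all(np.sum(row == 0) == 1 for row in non_center)
        assert all(set(np.abs(row[row != 0])) == {1.0} for row in non_center)

    def test_balance(self):
        d = bbd_design()
        np.testing.assert_allclose(d.runs.sum(axis=0), 0.0)

    def test_center_count_validated(self):
        with pytest.raises(ParameterError):
            bbd_design(n_center=0)

    def test_factor_coding(self):
        f = FactorSpec("ratio", 8.0, 1.0)
        assert f.low == 7.0 and f.high == 9.0
        assert f.encode(9.0) == 1.0
        assert f.decode(-1.0) == 7.0


class TestDesirability:
    def test_endpoints_and_midpoint(self):
        y = np.array([2.0, 5.0, 8.0])
        d = desirability(y)
        np.testing.assert_allclose(d, [0.0, 0.5, 1.0])

    def test_observed_minimum_kills_od(self, bbd_table):
        """The run with the lowest marker content gets d = 0, hence OD = 0,
        matching the printed zeros of the design table."""
        ds = [desirability(bbd_table[c].to_numpy()) for c in ("CAGC", "CAC", "TSR")]
        od = overall_desirability(ds)
        run6 = bbd_table.index[bbd_table["run"] == 6][0]
        run17 = bbd_table.index[bbd_table["run"] == 17][0]
        assert od[run6] == 0.0
        assert od[run17] == 0.0

    def test_supplied_bounds_clip(self):
        cfg = DesirabilityConfig(0.0, 1.0, "supplied")
        np.testing.assert_allclose(desirability([-0.5, 0.5, 2.0], cfg), [0.0, 0.5, 1.0])

    def test_degenerate_bounds(self):
        with pytest.raises(ParameterError):
            DesirabilityConfig(1.0, 1.0)

    def test_geometric_mean_values(self):
        assert overall_desirability([np.ones(3)] * 4) == pytest.approx([1.0] * 3)
        od = overall_desirability([np.array([0.25]), np.array([1.0]), np.array([1.0])])
        assert od[0] == pytest.approx(0.25 ** (1 / 3), abs=1e-9)
        assert overall_desirability([np.array([0.0]), np.array([0.9])])[0] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            overall_desirability([np.array([-0.1])])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.lists(st.floats(min_value=0, max_value=1), min_size=4, max_size=4),
            min_size=1,
            max_size=5,
        )
    )
    def test_od_bounded_by_components_and_order_invariant(self, rows):
        ds = [np.array(r) for r in rows]
        od = overall_desirability(ds)
        D = np.column_stack(ds)
        assert np.all(od <= D.max(axis=1) + 1e-12)
        assert np.all(od >= D.min(axis=1) - 1e-12)
        np.testing.assert_allclose(od, overall_desirability(ds[::-1]), atol=1e-12)


class TestFit:
    def test_printed_coefficients(self, fitted_extraction_model):
        expected = {
            "b0": 0.8612, "b1": 0.3228, "b2": 0.1158, "b3": 0.1248,
            "b12": -0.1440, "b13": -0.1435, "b23": -0.0205,
            "b11": -0.2179, "b22": -0.0159, "b33": -0.0058,
        }
        for term, value in expected.items():
            assert fitted_extraction_model.coef[term] == pytest.approx(
                value, abs=1e-4
            ), term

    def test_noiseless_recovery(self):
        surface = TrueSurface(0.5, (0.3, -0.1, 0.2), (0.05, -0.02, 0.01),
                              (-0.2, 0.1, -0.05), noise_sd=0.0)
        design = bbd_design()
        y = make_bbd_responses(surface, design, seed=0)
        model = fit_quadratic(design, y)
        np.testing.assert_allclose(model.beta, surface.beta, atol=1e-10)

    def test_intercept_is_center_mean(self, bbd_table, fitted_extraction_model):
        centers = bbd_table.loc[bbd_table["run"].isin([2, 5, 10, 13, 16]), "OD"]
        assert fitted_extraction_model.coef["b0"] == pytest.approx(
            centers.mean(), abs=1e-10
        )

    def test_orthogonal_contrasts_match_ols(self, bbd_table, fitted_extraction_model):
        """BBD contrast arithmetic reproduces the OLS linear and interaction
        coefficients."""
        design, resp = read_run_table(bbd_table)
        y = resp["OD"].to_numpy()
        for j, term in enumerate(["b1", "b2", "b3"]):
            contrast = (y[design.runs[:, j] == 1].sum() - y[design.runs[:, j] == -1].sum()) / 8
            assert fitted_extraction_model.coef[term] == pytest.approx(contrast, abs=1e-10)
        pairs = {"b12": (0, 1), "b13": (0, 2), "b23": (1, 2)}
        for term, (a, b) in pairs.items():
            prod = design.runs[:, a] * design.runs[:, b]
            contrast = (y[prod == 1].sum() - y[prod == -1].sum()) / 4
            assert fitted_extraction_model.coef[term] == pytest.approx(contrast, abs=1e-10)

    def test_rank_deficiency_detected(self):
        design = bbd_design()
        design = rsm.BBDesign(design.factors, np.zeros_like(design.runs), 17)
        with pytest.raises(Exception):
            fit_quadratic(design, np.ones(17))


class TestAnova:
    def test_pure_error_definition(self, bbd_table, fitted_extraction_model):
        table = rsm.anova(fitted_extraction_model)
        centers = bbd_table.loc[bbd_table["run"].isin([2, 5, 10, 13, 16]), "OD"]
        expected = ((centers - centers.mean()) ** 2).sum()
        got = table.loc[table["source"] == "pure_error", "SS"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_significance_of_model_and_linear_terms(self, fitted_extraction_model):
        table = rsm.anova(fitted_extraction_model).set_index("source")
        assert table.loc["model", "p"] < 0.05
        for term in ("b1", "b2", "b3"):
            assert table.loc[term, "p"] < 0.05

    def test_noiseless_f_capped(self):
        surface = TrueSurface.reference(noise_sd=0.0)
        design = bbd_design()
        y = make_bbd_responses(surface, design, seed=0)
        table = rsm.anova(fit_quadratic(design, y)).set_index("source")
        assert table.loc["model", "F"] >= 1e12
        assert table.loc["model", "p"] == 0.0


class TestOptimize:
    def test_concave_separable_closed_form(self):
        design = bbd_design()
        coef = dict.fromkeys(rsm.TERM_NAMES, 0.0)
        coef.update({"b0": 2.0, "b11": -1.0, "b22": -1.0, "b33": -1.0})
        model = fit_quadratic(design, model_matrix(design.runs) @
                              np.array([coef[t] for t in rsm.TERM_NAMES]))
        res = optimize(model)
        np.testing.assert_allclose(res.argmax_coded, 0.0, atol=1e-12)
        assert res.predicted == pytest.approx(2.0)

    def test_extraction_optimum(self, fitted_extraction_model):
        res = optimize(fitted_extraction_model)
        assert res.argmax_actual[0] == pytest.approx(8.086, abs=0.01)
        assert res.argmax_actual[1] == pytest.approx(59.998, abs=0.05)
        assert res.argmax_actual[2] == pytest.approx(39.998, abs=0.05)
        assert res.predicted == pytest.approx(1.06, abs=0.005)

    def test_dominates_dense_grid(self, fitted_extraction_model):
        res = optimize(fitted_extraction_model)
        axis = np.linspace(-1, 1, 101)
        G = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
        grid_max = fitted_extraction_model.predict_coded(G).max()
        assert res.predicted >= grid_max - 1e-9

    def test_argmax_in_cube(self, fitted_extraction_model):
        res = optimize(fitted_extraction_model)
        assert np.all(np.abs(res.argmax_coded) <= 1 + 1e-12)


class TestPredict:
    def test_center_point(self, fitted_extraction_model):
        center = [f.center for f in EXTRACTION_FACTORS]
        assert fitted_extraction_model.predict(center)[0] == pytest.approx(
            fitted_extraction_model.coef["b0"]
        )

    def test_direct_polynomial_oracle(self, fitted_extraction_model):
        b = fitted_extraction_model.coef
        x1, x2, x3 = 1.0, -1.0, 0.0
        oracle = (b["b0"] + b["b1"] * x1 + b["b2"] * x2 + b["b3"] * x3
                  + b["b12"] * x1 * x2 + b["b13"] * x1 * x3 + b["b23"] * x2 * x3
                  + b["b11"] * x1**2 + b["b22"] * x2**2 + b["b33"] * x3**2)
        got = fitted_extraction_model.predict([9.0, 30.0, 30.0])[0]
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_warns_outside_range(self, fitted_extraction_model):
        with pytest.warns(UserWarning):
            fitted_extraction_model.predict([12.0, 45.0, 30.0])

    def test_pure_linear_term(self):
        design = bbd_design()
        beta = np.zeros(10)
        beta[1] = 2.0
        model = fit_quadratic(design, model_matrix(design.runs) @ beta)
        xs = np.linspace(-1, 1, 7)
        preds = model.predict_coded(np.column_stack([xs, 0 * xs, 0 * xs]))
        np.testing.assert_allclose(np.diff(preds, 2), 0.0, atol=1e-12)


class TestSurfaceGrid:
    def test_bounded_by_global_optimum(self, fitted_extraction_model):
        res = optimize(fitted_extraction_model)
        for pair in [(0, 1), (0, 2), (1, 2)]:
            grid = surface_grid(fitted_extraction_model, pair=pair)
            assert grid["predicted"].max() <= res.predicted + 1e-9

    def test_symmetric_without_interactions(self):
        design = bbd_design()
        beta = np.zeros(10)
        beta[0], beta[7], beta[8] = 1.0, -0.5, -0.3
        model = fit_quadratic(design, model_matrix(design.runs) @ beta)
        grid = surface_grid(model, pair=(0, 1), n=21)
        z = grid["predicted"].to_numpy().reshape(21, 21)
        np.testing.assert_allclose(z, z[::-1, :], atol=1e-12)
        np.testing.assert_allclose(z, z[:, ::-1], atol=1e-12)

    def test_deterministic(self, fitted_extraction_model):
        g1 = surface_grid(fitted_extraction_model)
        g2 = surface_grid(fitted_extraction_model)
        pd.testing.assert_frame_equal(g1, g2)


class TestRunTableIO:
    def test_actual_and_coded_equivalent(self, bbd_table):
        design_a, resp_a = read_run_table(bbd_table)
        coded = bbd_table.copy()
        coded[["X1", "X2", "X3"]] = design_a.runs
        design_c, resp_c = read_run_table(coded)
        np.testing.assert_allclose(design_a.runs, design_c.runs)
        model_a = fit_quadratic(design_a, resp_a["OD"].to_numpy())
        model_c = fit_quadratic(design_c, resp_c["OD"].to_numpy())
        np.testing.assert_allclose(model_a.beta, model_c.beta, atol=1e-12)

    def test_missing_columns(self):
        with pytest.raises(DataError):
            read_run_table(pd.DataFrame({"X1": [0], "X2": [0]}))
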