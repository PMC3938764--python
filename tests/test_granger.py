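import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from migranger.granger import (CausalGraph, EdgeCriterion, EdgeDecision,
                               LagModelPair, assemble_chain, bin_p_value,
                               build_lagged_design,
                               compare_conditions, fit_pooled_ar,
                               granger_sargent_test, infer_edge,
                               panel_autocorrelation, r2_surface,
                               reciprocal_analysis, significance_grid)
from migranger.synthetic import VarSpec, simulate_var_panel


def _spec(extra=None, rho=0.5):
    coupling = np.zeros((1, 2, 2))
    np.fill_diagonal(coupling[0], rho)
    if extra:
        for i, j, c in extra:
            coupling[0, i, j] = c
    return VarSpec(2, 1, coupling, feature_names=["X", "Y"])


class TestDesign:
    def test_row_count_single_track(self):
        """T = 20 with p_y = p_x = 3 contributes 17 rows."""
        panel, _ = simulate_var_panel(_spec(), 1, 20, seed=0)
        Z, y, cells = build_lagged_design(panel, "Y", "X", 3, 3)
        assert Z.shape == (17, 7)

    def test_rows_never_mix_tracks(self):
        """Tracks of 20 and 10 frames give 17 + 7 = 24 rows at p = 3."""
        panel, _ = simulate_var_panel(_spec(), 2, [20, 10], seed=0)
        Z, y, cells = build_lagged_design(panel, "Y", "X", 3, 3)
        assert Z.shape[0] == 24
        assert np.bincount(cells).tolist() == [17, 7]

    def test_design_matches_hand_built_matrix(self):
        """A 5-frame toy equals the hand-written lag matrix exactly."""
        y = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        x = np.array([0.5, 1.5, 2.5, 3.5, 4.5])
        panel = pd.DataFrame({
            "condition": "c", "repeat": 1, "cell_id": 1,
            "frame": np.arange(5), "Y": y, "X": x,
        })
        Z, resp, _ = build_lagged_design(panel, "Y", "X", 2, 1)
        expected = np.array([
            [1, 2, 1, 1.5],
            [1, 4, 2, 2.5],
            [1, 7, 4, 3.5],
        ], dtype=float)
        assert Z == pytest.approx(expected)
        assert resp == pytest.approx([4.0, 7.0, 11.0])

    def test_nan_rows_dropped(self):
        panel = pd.DataFrame({
            "condition": "c", "repeat": 1, "cell_id": 1,
            "frame": np.arange(6),
            "Y": [np.nan, 1, 2, 3, 4, 5.0], "X": np.ones(6),
        })
        Z, resp, _ = build_lagged_design(panel, "Y", "X", 1, 1)
        assert len(resp) == 4  # first usable response needs Y_{t-1} finite


class TestOls:
    def test_exact_ar1_recovered(self):
        """Noiseless Y_t = 0.5 Y_{t-1}: R^2 = 1, coefficient 0.5."""
        y = 10.0 * np.power(0.5, np.arange(30))
        panel = pd.DataFrame({
            "condition": "c", "repeat": 1, "cell_id": 1,
            "frame": np.arange(30), "Y": y, "X": np.zeros(30),
        })
        Z, resp, _ = build_lagged_design(panel, "Y", None, 1, 0)
        fit = fit_pooled_ar(Z, resp)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.coefficients[1] == pytest.approx(0.5, abs=1e-9)

    def test_adding_regressor_never_decreases_r2(self):
        panel, _ = simulate_var_panel(_spec(), 10, 30, seed=1)
        Z2, y2, _ = build_lagged_design(panel, "Y", "X", 2, 2)
        fit_small = fit_pooled_ar(Z2[:, :3], y2)
        fit_big = fit_pooled_ar(Z2, y2)
        assert fit_big.r2 >= fit_small.r2 - 1e-12

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        Z = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = rng.normal(size=40)
        fit = fit_pooled_ar(Z, y)
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        assert fit.coefficients == pytest.approx(beta, abs=1e-10)

    def test_rank_deficient_refused(self):
        Z = np.column_stack([np.ones(30), np.arange(30.0), np.arange(30.0)])
        with pytest.raises(ValueError, match="rank"):
            fit_pooled_ar(Z, np.random.default_rng(0).normal(size=30))


class TestGrangerSargent:
    def test_no_improvement_gives_statistic_zero(self):
        pair = LagModelPair("Y", "X", 2, 2, 100, 50.0, 50.0, np.nan, np.nan)
        stat, p = granger_sargent_test(pair)
        assert stat == 0.0 and p == 1.0

    def test_hand_arithmetic_example(self):
        """RSS_A=120, RSS_B=100, p_x=p_y=2, N=105: statistic 10, p from
        F(2, 100)."""
        pair = LagModelPair("Y", "X", 2, 2, 105, 120.0, 100.0, np.nan, np.nan)
        stat, p = granger_sargent_test(pair)
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(float(stats.f.sf(10.0, 2, 100)), abs=1e-15)

    def test_non_nested_rejected(self):
        pair = LagModelPair("Y", "X", 2, 0, 100, 50.0, 40.0, np.nan, np.nan)
        with pytest.raises(ValueError, match="nested"):
            granger_sargent_test(pair)

    def test_matches_brute_force_nested_ols_oracle(self):
        """p-values agree with an independent statsmodels nested-OLS F test
        within 1e-8 on 50 random designs."""
        rng = np.random.default_rng(3)
        max_diff = 0.0
        for _ in range(50):
            py, px = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            spec = _spec(extra=[(1, 0, float(rng.normal()) * 0.3)])
            panel, _ = simulate_var_panel(spec, int(rng.integers(3, 8)),
                                          int(rng.integers(12, 30)),
                                          seed=int(rng.integers(2 ** 31)))
            Zu, yu, _ = build_lagged_design(panel, "Y", "X", py, px)
            fit_u = fit_pooled_ar(Zu, yu)
            fit_r = fit_pooled_ar(Zu[:, :1 + py], yu)
            pair = LagModelPair("Y", "X", py, px, fit_u.n,
                                fit_r.rss, fit_u.rss, np.nan, np.nan)
            _, p = granger_sargent_test(pair)
            p_ref = sm.OLS(yu, Zu).fit().compare_f_test(
                sm.OLS(yu, Zu[:, :1 + py]).fit())[1]
            max_diff = max(max_diff, abs(p - p_ref))
        assert max_diff < 1e-8

    def test_chi2_form_available(self):
        pair = LagModelPair("Y", "X", 2, 2, 105, 120.0, 100.0, np.nan, np.nan)
        stat, p = granger_sargent_test(pair, form="chi2")
        assert stat == pytest.approx(105 * 20 / 100)


class TestSurfaceAndGrid:
    def test_surface_shape_and_nesting(self):
        panel, _ = simulate_var_panel(_spec(extra=[(1, 0, -0.4)]), 40, 40, seed=4)
        surf = r2_surface(panel, "Y", "X", L_max=10)
        assert surf.adjusted_r2.shape == (10, 10)
        assert np.isfinite(surf.adjusted_r2).all()

    def test_strong_coupling_beats_y_only_model(self):
        """With strong X->Y coupling the (1,1) model outperforms the Y-only
        model in nearly all seeds."""
        wins = 0
        for seed in range(20):
            panel, _ = simulate_var_panel(_spec(extra=[(1, 0, -0.5)]), 60, 40,
                                          seed=seed)
            surf = r2_surface(panel, "Y", "X", L_max=3)
            wins += surf.adjusted_r2[0, 0] > surf.y_only[0]
        assert wins >= 19

    def test_grid_shape_and_bins(self):
        panel, _ = simulate_var_panel(_spec(extra=[(1, 0, -0.5)]), 50, 40, seed=5)
        grid = significance_grid(panel, "Y", "X", L_max=10)
        assert grid.p_values.shape == (10, 10)
        assert grid.sign == "-"
        assert grid.autocorrelation[0] == 1.0

    def test_bin_thresholds(self):
        assert bin_p_value(0.02) == "<0.05"
        assert bin_p_value(0.0005) == "<0.001"
        assert bin_p_value(0.5) == "ns"
        assert bin_p_value(5e-5) == "<0.0001"
        assert bin_p_value(0.005) == "<0.01"

    def test_statistics_invariant_to_cell_relabeling(self):
        """Permuting track order / relabeling cells leaves the grid
        unchanged."""
        panel, _ = simulate_var_panel(_spec(extra=[(1, 0, 0.3)]), 20, 25, seed=6)
        grid1 = significance_grid(panel, "Y", "X", L_max=4)
        relabeled = panel.copy()
        relabeled["cell_id"] = 100 - relabeled["cell_id"]
        relabeled = relabeled.sort_values(["cell_id", "frame"]).reset_index(drop=True)
        grid2 = significance_grid(relabeled, "Y", "X", L_max=4)
        assert grid1.p_values == pytest.approx(grid2.p_values, rel=1e-9)


class TestEdgeInference:
    def _grid(self, pvals, sign="-"):
        from migranger.granger import SignificanceGrid
        L = pvals.shape[0]
        bins = np.empty_like(pvals, dtype=object)
        bins[:] = "ns"
        return SignificanceGrid("Y", "X", L, pvals, bins, sign,
                                np.ones(L + 1), np.full((L, L), 100))

    def test_fully_significant_grid_declares_edge(self):
        grid = self._grid(np.full((10, 10), 1e-6))
        decision = infer_edge(grid)
        assert decision.declared and decision.sign == "-"

    def test_all_ns_grid_declares_nothing(self):
        grid = self._grid(np.full((10, 10), 0.5))
        assert not infer_edge(grid).declared

    def test_scattered_null_grid_not_declared(self):
        """A grid with ~5% scattered significance fails the edge criterion."""
        rng = np.random.default_rng(7)
        pvals = rng.uniform(size=(10, 10))
        assert not infer_edge(self._grid(pvals)).declared

    def test_criterion_thresholds_configurable(self):
        pvals = np.full((10, 10), 0.03)
        grid = self._grid(pvals)
        assert not infer_edge(grid).declared  # fails the 0.0001 quota
        loose = EdgeCriterion(min_fraction_05=0.5, min_fraction_0001=0.0)
        assert infer_edge(grid, loose).declared


class TestReciprocal:
    def test_unidirectional_coupling_classified(self):
        panel, _ = simulate_var_panel(_spec(extra=[(1, 0, -0.5)]), 100, 50, seed=8)
        gxy, gyx, cls = reciprocal_analysis(panel, "X", "Y", L_max=10)
        assert cls == "X->Y"
        assert gxy.sign == "-"

    def test_independent_features_classified_none(self):
        panel, _ = simulate_var_panel(_spec(), 100, 50, seed=9)
        _, _, cls = reciprocal_analysis(panel, "X", "Y", L_max=10)
        assert cls == "none"

    def test_mutual_coupling_classified_bidirectional(self):
        panel, _ = simulate_var_panel(
            _spec(extra=[(1, 0, -0.4), (0, 1, 0.4)]), 100, 50, seed=10)
        _, _, cls = reciprocal_analysis(panel, "X", "Y", L_max=10)
        assert cls == "bidirectional"


class TestChainsAndComparison:
    def _graph_with(self, edges, condition="control"):
        g = CausalGraph(condition)
        for (a, b), (declared, sign) in edges.items():
            g.add(EdgeDecision(a, b, declared, sign, 1.0, 1.0, True))
        return g

    def test_intact_chain(self):
        g = self._graph_with({("A", "B"): (True, "-"), ("B", "C"): (True, "+")})
        links, intact, broken = assemble_chain(g, ["A", "B", "C"])
        assert intact and broken is None
        assert [l.sign for l in links] == ["-", "+"]

    def test_broken_chain_reports_position(self):
        g = self._graph_with({("A", "B"): (True, "-")})
        links, intact, broken = assemble_chain(g, ["A", "B", "C"])
        assert not intact and broken == 1

    def test_single_edge_chain_equals_edge_decision(self):
        g = self._graph_with({("A", "B"): (True, "+")})
        links, intact, _ = assemble_chain(g, ["A", "B"])
        assert intact and len(links) == 1

    def test_identical_graphs_all_conserved(self):
        edges = {("A", "B"): (True, "-"), ("B", "C"): (True, "+")}
        report = compare_conditions({
            "control": self._graph_with(edges),
            "treated": self._graph_with(edges, "treated"),
        }, reference="control")
        assert (report["status"] == "conserved").all()

    def test_sign_inversion_detected(self):
        report = compare_conditions({
            "control": self._graph_with({("A", "B"): (True, "+")}),
            "rho": self._graph_with({("A", "B"): (True, "-")}, "rho"),
        }, reference="control")
        assert report["status"].tolist() == ["sign-inverted"]

    def test_lost_and_gained_edges(self):
        report = compare_conditions({
            "control": self._graph_with({("A", "B"): (True, "+"),
                                         ("B", "C"): (False, "+")}),
            "rho": self._graph_with({("A", "B"): (False, "+"),
                                     ("B", "C"): (True, "-")}, "rho"),
        }, reference="control")
        status = dict(zip(zip(report["source"], report["target"]),
                          report["status"]))
        assert status[("A", "B")] == "lost"
        assert status[("B", "C")] == "gained"


def test_autocorrelation_lag_zero_is_one(tiny_panel):
    ac = panel_autocorrelation(tiny_panel, "Y", 5)
    assert ac[0] == 1.0
    assert len(ac) == 6
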