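"""Joint least-squares fitting: recovery, summaries, comparison, bootstrap."""

from __future__ import annotations

import numpy as np
import pytest

from gradshift.fitting import (
    GradientCurveFitter,
    bootstrap_parameters,
    build_design_matrix,
    compare_interactions,
    fit_gradients,
    residual_error,
)
from gradshift.model import GradientModel
from gradshift.stimuli import ExperimentDesign, ResponseTable

from _oracles import grid_best_objective
from conftest import noise_free_xy, simulate_count_tables


class TestEstimator:
    def test_noise_free_recovery_to_1e4(self):
        X, y = noise_free_xy(sigma=1.5, sigma_prime=0.9, cs_plus=6, cs_minus=8)
        est = GradientCurveFitter(cs_plus=6, cs_minus=8).fit(X, y)
        assert est.sigma_ == pytest.approx(1.5, abs=1e-4)
        assert est.sigma_prime_ == pytest.approx(0.9, abs=1e-4)
        assert est.objective_ == pytest.approx(0.0, abs=1e-8)
        assert not est.boundary_flag_

    def test_initialisation_independence_via_multistart(self):
        X, y = noise_free_xy(sigma=2.4, sigma_prime=0.3, cs_plus=9, cs_minus=7)
        wide = GradientCurveFitter(cs_plus=9, cs_minus=7).fit(X, y)
        narrow_start = GradientCurveFitter(cs_plus=9, cs_minus=7,
                                           start_grid=((2.4, 0.3),)).fit(X, y)
        assert wide.objective_ == pytest.approx(narrow_start.objective_, abs=1e-6)

    def test_predict_round_trips_the_model(self):
        X, y = noise_free_xy(sigma=1.7, sigma_prime=1.1, cs_plus=7, cs_minus=9)
        est = GradientCurveFitter(cs_plus=7, cs_minus=9).fit(X, y)
        assert np.allclose(est.predict(X), y, atol=1e-6)

    def test_sklearn_params_clone_contract(self):
        from sklearn.base import clone

        est = GradientCurveFitter(cs_plus=7, cs_minus=9, interaction="additive_clipped")
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_non_finite_percentages_rejected(self):
        X, y = noise_free_xy(sigma=1.5, sigma_prime=0.9, cs_plus=6, cs_minus=8)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            GradientCurveFitter(cs_plus=6, cs_minus=8).fit(X, y)

    def test_degenerate_no_inhibition_input_flags_boundary(self):
        """Differential data equal to the bare excitatory curve except for an
        exact zero at the CS- push sigma' to the lower bound."""
        design = ExperimentDesign("d", "differential", cs_plus=6, cs_minus=8,
                                  test_positions=(6, 7, 8, 9), n_ants=40)
        sigma = 1.5
        positions = np.array([6.0, 7.0, 8.0, 9.0])
        y_abs = 100 * np.exp(-((positions - 6) ** 2) / (2 * sigma**2))
        y_diff = y_abs.copy()
        y_diff[positions == 8] = 0.0
        X = np.column_stack([np.tile(positions, 2), np.repeat([0.0, 1.0], 4)])
        est = GradientCurveFitter(cs_plus=6, cs_minus=8).fit(X, np.concatenate([y_abs, y_diff]))
        assert est.boundary_flag_
        assert est.sigma_prime_ == pytest.approx(0.05, abs=1e-6)


class TestFitResult:
    def test_objective_consistent_with_residuals_and_summaries(self, paper_pairs):
        _, abs_table, diff_design, diff_table = paper_pairs[0]
        fit = fit_gradients(abs_table, diff_table, diff_design)
        assert fit.objective == pytest.approx(float(np.sum(fit.residuals**2)))
        assert fit.re_sum_abs == pytest.approx(float(np.sum(np.abs(fit.residuals))))
        assert fit.re_rms == pytest.approx(np.sqrt(fit.objective / fit.n_points))
        assert fit.n_points == 8
        assert (fit.predictions["observed_pct"] - fit.predictions["predicted_pct"]
                ).to_numpy() == pytest.approx(fit.residuals)

    def test_residual_error_conventions_arithmetic(self, paper_pairs):
        _, abs_table, diff_design, diff_table = paper_pairs[0]
        fit = fit_gradients(abs_table, diff_table, diff_design)
        fit.residuals = np.array([3.0, -4.0, 0, 0, 0, 0, 0, 0])
        fit.re_sum_abs, fit.re_sum_sq, fit.re_rms = 7.0, 25.0, np.sqrt(25 / 8)
        assert residual_error(fit, "sum_abs") == 7.0
        assert residual_error(fit, "sum_sq") == 25.0
        assert residual_error(fit, "rms") == pytest.approx(np.sqrt(25 / 8))
        with pytest.raises(ValueError):
            residual_error(fit, "median")

    def test_zero_residuals_give_zero_under_every_convention(self):
        X, y = noise_free_xy(sigma=1.5, sigma_prime=0.9, cs_plus=6, cs_minus=8)
        design = ExperimentDesign("d", "differential", cs_plus=6, cs_minus=8,
                                  test_positions=(6, 7, 8, 9), n_ants=1000)
        # counts at n=10**6 make the percentage quantisation negligible
        n = 10**6
        abs_table = ResponseTable((6, 7, 8, 9), (n,) * 4,
                                  tuple(int(round(v * n / 100)) for v in y[:4]))
        diff_table = ResponseTable((6, 7, 8, 9), (n,) * 4,
                                   tuple(int(round(v * n / 100)) for v in y[4:]))
        fit = fit_gradients(abs_table, diff_table, design)
        for convention in ("sum_abs", "sum_sq", "rms"):
            assert residual_error(fit, convention) == pytest.approx(0.0, abs=1e-2)


class TestPreconditions:
    def test_mismatched_positions_rejected(self, differential_design):
        abs_table = ResponseTable((5, 6, 7, 8), (40,) * 4, (1, 2, 3, 4))
        diff_table = ResponseTable((6, 7, 8, 9), (40,) * 4, (1, 2, 3, 4))
        with pytest.raises(ValueError, match="same test positions"):
            fit_gradients(abs_table, diff_table, differential_design)

    def test_absolute_design_rejected(self):
        design = ExperimentDesign("a", "absolute", cs_plus=7,
                                  test_positions=(6, 7, 8, 9), n_ants=30)
        table = ResponseTable((6, 7, 8, 9), (30,) * 4, (30, 20, 10, 5))
        with pytest.raises(ValueError, match="CS-"):
            fit_gradients(table, table, design)


class TestOptimizerOracle:
    def test_objective_not_worse_than_coarse_grid_search(self, differential_design):
        """The multi-start optimiser must reach at least the best objective an
        exhaustive 0.01-resolution (sigma, sigma') grid can find."""
        rng = np.random.default_rng(7)
        for _ in range(3):
            abs_table, diff_table = simulate_count_tables(
                sigma=rng.uniform(0.8, 2.5), sigma_prime=rng.uniform(0.5, 2.0),
                cs_plus=7, cs_minus=9, n=40, rng=rng)
            X, y = build_design_matrix(abs_table, diff_table)
            fit = fit_gradients(abs_table, diff_table, differential_design)
            oracle = grid_best_objective(X, y, cs_plus=7, cs_minus=9, step=0.01)
            assert fit.objective <= oracle + 1e-6


class TestParameterRecovery:
    def test_median_error_under_binomial_noise(self):
        """Across seeds, binomial sampling at n=40/group perturbs the width
        estimates by less than 0.2 carbons in the median."""
        rng = np.random.default_rng(11)
        design = ExperimentDesign("r", "differential", cs_plus=7, cs_minus=9,
                                  test_positions=(6, 7, 8, 9), n_ants=40)
        errors_sigma, errors_sigma_prime = [], []
        for _ in range(100):
            sigma = rng.uniform(0.8, 2.5)
            sigma_prime = rng.uniform(0.8, min(sigma, 2.0))
            abs_table, diff_table = simulate_count_tables(
                sigma, sigma_prime, cs_plus=7, cs_minus=9, n=40, rng=rng)
            fit = fit_gradients(abs_table, diff_table, design)
            errors_sigma.append(abs(fit.sigma_hat - sigma))
            errors_sigma_prime.append(abs(fit.sigma_prime_hat - sigma_prime))
        assert np.median(errors_sigma) < 0.2
        assert np.median(errors_sigma_prime) < 0.2


class TestCompareInteractions:
    def test_multiplicative_truth_ranks_multiplicative_first(self, differential_design):
        rng = np.random.default_rng(3)
        abs_table, diff_table = simulate_count_tables(
            sigma=1.7, sigma_prime=1.1, cs_plus=7, cs_minus=9, n=10**5, rng=rng)
        frame = compare_interactions(abs_table, diff_table, differential_design)
        assert frame.iloc[0]["interaction"] == "multiplicative"
        assert frame.iloc[0]["objective"] == pytest.approx(0.0, abs=0.5)
        assert set(frame["df_resid"]) == {5, 6}

    def test_additive_truth_not_beaten_by_multiplicative(self, differential_design):
        truth = GradientModel(sigma=1.6, sigma_prime=1.0, center_plus=7, center_minus=9,
                              interaction="additive_clipped")
        positions = np.array([6.0, 7.0, 8.0, 9.0])
        y_abs = 100 * truth.excitatory(positions)
        y_diff = np.asarray(truth.response(positions))
        n = 10**6
        abs_table = ResponseTable((6, 7, 8, 9), (n,) * 4,
                                  tuple(int(round(v * n / 100)) for v in y_abs))
        diff_table = ResponseTable((6, 7, 8, 9), (n,) * 4,
                                   tuple(int(round(v * n / 100)) for v in y_diff))
        frame = compare_interactions(abs_table, diff_table, differential_design)
        by_kind = frame.set_index("interaction")["objective"]
        assert by_kind["additive_clipped"] == pytest.approx(0.0, abs=1e-2)
        assert by_kind["additive_clipped"] <= by_kind["multiplicative"] + 1e-9

    def test_constant_saturated_responses_hit_boundary(self, differential_design):
        table = ResponseTable((6, 7, 8, 9), (40,) * 4, (40,) * 4)
        frame = compare_interactions(table, table, differential_design)
        mult = frame.set_index("interaction").loc["multiplicative"]
        assert bool(mult["boundary_flag"])


class TestBootstrap:
    def test_rejects_too_few_replicates(self, paper_pairs):
        _, abs_table, diff_design, diff_table = paper_pairs[0]
        with pytest.raises(ValueError):
            bootstrap_parameters(abs_table, diff_table, diff_design, n_boot=0, seed=1)

    def test_deterministic_given_seed(self, paper_pairs):
        _, abs_table, diff_design, diff_table = paper_pairs[0]
        first = bootstrap_parameters(abs_table, diff_table, diff_design, n_boot=25, seed=9)
        second = bootstrap_parameters(abs_table, diff_table, diff_design, n_boot=25, seed=9)
        assert first == second

    def test_interval_coverage_of_true_width(self):
        """Scaled-down parametric-bootstrap coverage check: the 95% interval
        for sigma should cover the generating value in most replications."""
        design = ExperimentDesign("c", "differential", cs_plus=7, cs_minus=9,
                                  test_positions=(6, 7, 8, 9), n_ants=40)
        rng = np.random.default_rng(2)
        hits = 0
        n_outer = 20
        for i in range(n_outer):
            abs_table, diff_table = simulate_count_tables(
                sigma=1.5, sigma_prime=1.0, cs_plus=7, cs_minus=9, n=40, rng=rng)
            ci = bootstrap_parameters(abs_table, diff_table, design, n_boot=99,
                                      seed=100 + i)
            lo, hi = ci["sigma"]
            hits += lo <= 1.5 <= hi
        assert hits >= int(0.8 * n_outer)
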