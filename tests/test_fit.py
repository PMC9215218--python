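import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from rk4sindy.benchmarks import BenchmarkSpec, generate, ground_truth_model
from rk4sindy.data import TrajectoryData
from rk4sindy.dictionary import (
    add_parameterized_features,
    build_polynomial_dictionary,
)
from rk4sindy.exceptions import AllPrunedError, InvalidArgumentError
from rk4sindy.fit import (
    FitConfig,
    OptimizerConfig,
    assess_polynomial_degree,
    fidelity_loss,
    fit_fixed_threshold,
    fit_iterative_threshold,
    optimize_coefficients,
    residual_loss,
)
from rk4sindy.models import CoefficientSet, LinearDictionaryModel


def taylor4(z):
    return sum(z ** j / math.factorial(j) for j in range(5))


def linear_1d_data(a=0.7, h=0.05, n=60, x0=1.0):
    """x_{k+1} = x_k * p(a h): data exactly consistent with one RK4 step."""
    x = x0 * taylor4(a * h) ** np.arange(n + 1)
    return TrajectoryData(h * np.arange(n + 1), x[:, None], ("x",))


class TestResidualLoss:
    def test_zero_at_truth_on_rk4_exact_data(self, rk4_exact_data):
        model = ground_truth_model(BenchmarkSpec("cubic_oscillator"))
        data = rk4_exact_data(model, [1.2, -0.3], 0.02, 100)
        assert residual_loss(model, data) < 1e-25

    def test_zero_model_gives_pure_data_term(self):
        data = linear_1d_data()
        d = build_polynomial_dictionary(("x",), 2)
        zero = LinearDictionaryModel(d, CoefficientSet.dense(d.m, 1), ("x",))
        expected = np.mean((data.states[1:] - data.states[:-1]) ** 2)
        assert residual_loss(zero, data) == pytest.approx(expected, rel=1e-12)

    def test_l1_term_added_for_nonzero_alpha(self):
        data = linear_1d_data()
        d = build_polynomial_dictionary(("x",), 1)
        xi = np.array([[0.0], [0.7]])
        m = LinearDictionaryModel(d, CoefficientSet(xi, np.ones_like(xi, bool)),
                                  ("x",))
        base = residual_loss(m, data, FitConfig(alpha=0.0))
        assert residual_loss(m, data, FitConfig(alpha=1e-3)) == pytest.approx(
            base + 1e-3 * 0.7, rel=1e-9
        )

    def test_truth_on_solver_data_small_but_nonzero(self):
        data = generate(BenchmarkSpec("fhn", tf=20.0, dt=0.1))
        loss = residual_loss(ground_truth_model(BenchmarkSpec("fhn")), data)
        assert 0.0 < loss < 1e-10  # truncation floor, not fit error

    def test_backward_weighting_is_convex(self, rk4_exact_data):
        model = ground_truth_model(BenchmarkSpec("linear_oscillator"))
        data = rk4_exact_data(model, [1.0, 0.0], 0.05, 50)
        fwd_only = FitConfig(use_backward=True, w_b=0.0)
        assert residual_loss(model, data, fwd_only) == pytest.approx(
            residual_loss(model, data, FitConfig()), rel=1e-12
        )


class TestOptimizeCoefficients:
    def test_one_parameter_recovery_matches_scalar_oracle(self):
        a_true, h = 0.7, 0.05
        data = linear_1d_data(a_true, h)
        d = build_polynomial_dictionary(("x",), 1, include_bias=False)
        model = LinearDictionaryModel(d, CoefficientSet.dense(1, 1), ("x",))
        fitted, _ = optimize_coefficients(model, data)

        x = data.states[:, 0]
        oracle = minimize_scalar(
            lambda a: np.mean((x[:-1] * taylor4(a * h) - x[1:]) ** 2),
            bounds=(0.0, 2.0), method="bounded",
            options={"xatol": 1e-12},
        ).x
        assert fitted.xi[0, 0] == pytest.approx(oracle, rel=1e-6)
        assert fitted.xi[0, 0] == pytest.approx(a_true, rel=1e-4)

    def test_fully_frozen_support_is_a_no_op(self):
        data = linear_1d_data()
        d = build_polynomial_dictionary(("x",), 2)
        model = LinearDictionaryModel(d, CoefficientSet.dense(d.m, 1), ("x",))
        frozen = np.ones((d.m, 1), dtype=bool)
        fitted, _ = optimize_coefficients(model, data, frozen_support=frozen)
        np.testing.assert_array_equal(fitted.xi, 0.0)
        assert fitted.n_free == 0

    def test_gradient_descent_method_recovers_linear_problem(self):
        data = linear_1d_data()
        d = build_polynomial_dictionary(("x",), 1, include_bias=False)
        model = LinearDictionaryModel(d, CoefficientSet.dense(1, 1), ("x",))
        cfg = FitConfig(optimizer=OptimizerConfig(
            method="gd", learning_rate=0.5, steps=5000, convergence_tol=1e-14))
        fitted, history = optimize_coefficients(model, data, cfg)
        assert fitted.xi[0, 0] == pytest.approx(0.7, rel=1e-3)
        assert history[-1] <= history[0]  # monotone-or-stop acceptance

    def test_unknown_method_rejected(self):
        data = linear_1d_data()
        d = build_polynomial_dictionary(("x",), 1)
        model = LinearDictionaryModel(d, CoefficientSet.dense(d.m, 1), ("x",))
        with pytest.raises(InvalidArgumentError):
            optimize_coefficients(
                model, data, FitConfig(optimizer=OptimizerConfig(method="adam")))

    def test_trainable_exponential_rate_recovered(self):
        # dx/dt = -x + exp(-1.75 x): the rate enters the feature nonlinearly
        data = generate(BenchmarkSpec("exp_decay"))
        base = build_polynomial_dictionary(("x",), 1)
        d = add_parameterized_features(
            base, [{"kind": "exponential", "argument": "x"}], rng=42)
        model = LinearDictionaryModel(d, CoefficientSet.dense(d.m, 1), ("x",))
        fitted, _ = optimize_coefficients(
            model, data, FitConfig(optimizer=OptimizerConfig(seed=0)))
        assert abs(fitted.dictionary.eta[0] - (-1.75)) < 0.05
        assert fitted.xi[2, 0] == pytest.approx(1.0, abs=1e-3)
        assert fitted.xi[1, 0] == pytest.approx(-1.0, abs=1e-3)


class TestFixedThreshold:
    def test_linear_oscillator_degree5_support_and_coefficients(self):
        data = generate(BenchmarkSpec("linear_oscillator", dt=1e-2))
        dictionary = build_polynomial_dictionary(("x", "y"), 5)
        res = fit_fixed_threshold(data, dictionary, FitConfig(cutoff=5e-2))
        labels = dictionary.labels()
        expected = {0: {"x": -0.1, "y": 2.0}, 1: {"x": -2.0, "y": -0.1}}
        for eq, terms in expected.items():
            nz = {labels[a]: res.model.xi[a, eq]
                  for a in range(dictionary.m)
                  if res.model.coefficients.support[a, eq]}
            assert set(nz) == set(terms)
            for lab, val in terms.items():
                assert nz[lab] == pytest.approx(val, rel=1e-4)

    def test_cubic_oscillator_picks_cubic_monomials(self):
        data = generate(BenchmarkSpec("cubic_oscillator", dt=1e-2))
        dictionary = build_polynomial_dictionary(("x", "y"), 5)
        res = fit_fixed_threshold(data, dictionary, FitConfig(cutoff=5e-2))
        labels = np.array(dictionary.labels())
        for eq in (0, 1):
            sel = set(labels[res.model.coefficients.support[:, eq]])
            assert sel == {"x^3", "y^3"}

    def test_constant_data_flagged_not_errored(self):
        t = np.linspace(0, 1, 60)
        data = TrajectoryData(t, np.full((60, 1), 3.0), ("x",))
        res = fit_fixed_threshold(
            data, build_polynomial_dictionary(("x",), 2), FitConfig(cutoff=0.05))
        assert res.constant_states == ["x"]
        assert res.model.total_nnz() == 0

    def test_overlarge_cutoff_on_dynamic_data_raises(self):
        data = linear_1d_data(a=0.05)  # true coefficient below the cut-off
        with pytest.raises(AllPrunedError):
            fit_fixed_threshold(
                data, build_polynomial_dictionary(("x",), 2), FitConfig(cutoff=10.0))

    def test_support_never_grows_between_rounds(self):
        data = generate(BenchmarkSpec("linear_oscillator", dt=1e-2))
        res = fit_fixed_threshold(
            data, build_polynomial_dictionary(("x", "y"), 5), FitConfig(cutoff=5e-2))
        counts = [sum(m.sum() for m in masks.values())
                  for masks in res.threshold_rounds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestIterativeThreshold:
    def test_full_pareto_has_one_point_per_coefficient(self):
        data = linear_1d_data()
        d = build_polynomial_dictionary(("x",), 2)  # 3 coefficients
        res = fit_iterative_threshold(data, d, FitConfig())
        assert [k for k, _ in res.pareto] == [3, 2, 1]

    def test_sparse_truth_with_loose_tolerance_stops_immediately(self, rk4_exact_data):
        truth = ground_truth_model(BenchmarkSpec("linear_oscillator"))
        data = rk4_exact_data(truth, [1.0, 0.5], 0.02, 150)
        res = fit_iterative_threshold(
            data, truth.copy(), FitConfig(fidelity_tol=1e-12))
        np.testing.assert_array_equal(
            res.model.coefficients.support, truth.coefficients.support)
        assert res.fidelity <= 1e-12

    def test_selected_model_sits_at_the_elbow(self, rk4_exact_data):
        truth = ground_truth_model(BenchmarkSpec("linear_oscillator"))
        data = rk4_exact_data(truth, [1.0, 0.5], 0.02, 200)
        d = build_polynomial_dictionary(("x", "y"), 2)
        res = fit_iterative_threshold(data, d, FitConfig())
        assert res.model.total_nnz() == 4
        # row-major (feature, equation) order: x->eq0, x->eq1, y->eq0, y->eq1
        np.testing.assert_allclose(
            res.model.xi[res.model.coefficients.support],
            [-0.1, -2.0, 2.0, -0.1], rtol=1e-6,
        )

    def test_pareto_fidelity_non_increasing_in_support_size(self, rk4_exact_data):
        truth = ground_truth_model(BenchmarkSpec("linear_oscillator"))
        data = rk4_exact_data(truth, [1.0, 0.5], 0.02, 200)
        d = build_polynomial_dictionary(("x", "y"), 2)
        res = fit_iterative_threshold(data, d, FitConfig())
        front = sorted(res.pareto)  # ascending support size
        fids = [f for _, f in front]
        # allow machine-floor jitter (~1e-30) among exactly-fitting models
        assert all(a + 1e-15 >= b for a, b in zip(fids, fids[1:]))

    def test_support_never_grows_between_rounds(self, rk4_exact_data):
        truth = ground_truth_model(BenchmarkSpec("linear_oscillator"))
        data = rk4_exact_data(truth, [1.0, 0.5], 0.02, 150)
        d = build_polynomial_dictionary(("x", "y"), 2)
        res = fit_iterative_threshold(data, d, FitConfig())
        counts = [k for k, _ in res.pareto]
        assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_best_refit_pruning_agrees_with_magnitude_on_clean_data(
            self, rk4_exact_data):
        truth = ground_truth_model(BenchmarkSpec("linear_oscillator"))
        data = rk4_exact_data(truth, [1.0, 0.5], 0.02, 120)
        d = build_polynomial_dictionary(("x", "y"), 1)
        by_mag = fit_iterative_threshold(data, d, FitConfig())
        by_refit = fit_iterative_threshold(
            data, d, FitConfig(prune="best_refit", beam_width=2))
        np.testing.assert_array_equal(
            by_refit.model.coefficients.support,
            by_mag.model.coefficients.support)
        np.testing.assert_allclose(by_refit.model.xi, by_mag.model.xi, rtol=1e-6)

    def test_exact_size_cap_replaces_suboptimal_front_points(self, rk4_exact_data):
        """Exhaustive small-size refinement must find the best support of
        each small size even if the greedy path missed it."""
        truth = ground_truth_model(BenchmarkSpec("linear_oscillator"))
        data = rk4_exact_data(truth, [1.0, 0.5], 0.02, 120)
        d = build_polynomial_dictionary(("x", "y"), 1)  # 6 coefficients
        res = fit_iterative_threshold(data, d, FitConfig(exact_size_cap=4))
        sizes = dict(res.pareto)
        # at size 4 the exact optimum is the true support: fidelity at floor
        assert sizes[4] < 1e-20
        assert res.model.total_nnz() == 4


class TestSmallStepLimit:
    def test_rk4_fit_approaches_derivative_least_squares(self):
        """As h -> 0 one RK4 step is x + h f(x) + O(h^2), so minimizing the
        RK4 residual approaches the classical regression of finite
        differences on the dictionary (normal-equations oracle)."""
        h = 1e-3
        model = ground_truth_model(BenchmarkSpec("linear_oscillator"))
        t = h * np.arange(401)
        from rk4sindy.models import simulate

        data = simulate(model, [1.0, 0.4], t)
        d = build_polynomial_dictionary(("x", "y"), 2)
        dense = LinearDictionaryModel(d, CoefficientSet.dense(d.m, 2), ("x", "y"))
        fitted, _ = optimize_coefficients(dense, data)

        Phi = d.evaluate(data.states[:-1])
        target = (data.states[1:] - data.states[:-1]) / h
        oracle, *_ = np.linalg.lstsq(Phi, target, rcond=None)
        np.testing.assert_allclose(fitted.xi, oracle, atol=5e-3)


class TestDegreeAssessment:
    def test_linear_system_plateau_starts_at_degree_one(self):
        data = generate(BenchmarkSpec("linear_oscillator", dt=1e-2, tf=5.0))
        table, selected = assess_polynomial_degree(data, [1, 2, 3])
        assert selected == 1
        assert list(table["degree"]) == [1, 2, 3]

    def test_single_degree_gives_table_without_selection(self):
        data = generate(BenchmarkSpec("linear_oscillator", dt=1e-2, tf=2.0))
        table, selected = assess_polynomial_degree(data, [2])
        assert len(table) == 1 and selected is None

    def test_empty_degree_list_rejected(self):
        data = linear_1d_data()
        with pytest.raises(InvalidArgumentError):
            assess_polynomial_degree(data, [])
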