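import numpy as np
import pytest

from rk4sindy.benchmarks import BenchmarkSpec, ground_truth_model
from rk4sindy.dictionary import build_polynomial_dictionary
from rk4sindy.exceptions import (
    DenominatorDegeneracyError,
    UnsupportedTransformError,
)
from rk4sindy.models import (
    AffineTransform,
    CoefficientSet,
    LinearDictionaryModel,
    RationalModel,
    evaluate_field,
    parse_equations,
    simulate,
    symbolic_export,
    transform_model,
)


def scalar_rational(g_entries, h_entries, k_entries=None, degree=2):
    phi_g = build_polynomial_dictionary(("x",), degree)
    phi_h = build_polynomial_dictionary(("x",), degree, include_bias=False)
    g = np.zeros((phi_g.m, 1))
    for idx, c in g_entries.items():
        g[idx] = c
    h = np.zeros((phi_h.m, 1))
    for idx, c in h_entries.items():
        h[idx] = c
    kwargs = {}
    if k_entries is not None:
        phi_k = build_polynomial_dictionary(("x",), degree)
        k = np.zeros((phi_k.m, 1))
        for idx, c in k_entries.items():
            k[idx] = c
        kwargs = {"phi_k": phi_k, "coeff_k": CoefficientSet(k)}
    return RationalModel(phi_g, phi_h, CoefficientSet(g), CoefficientSet(h),
                         ("x",), **kwargs)


class TestEvaluateField:
    def test_zero_coefficients_zero_field(self):
        d = build_polynomial_dictionary(("x", "y"), 2)
        m = LinearDictionaryModel(d, CoefficientSet.dense(d.m, 2), ("x", "y"))
        np.testing.assert_array_equal(
            evaluate_field(m, [[1.0, 2.0], [3.0, -1.0]]), np.zeros((2, 2))
        )

    def test_michaelis_menten_rational_value(self):
        # g = 0.6 - 3 s over [1, s]; h = (10/3) s: the saturating uptake law
        model = ground_truth_model(BenchmarkSpec("michaelis_menten"))
        got = evaluate_field(model, [[0.3]])[0, 0]
        oracle = 0.6 - 1.5 * 0.3 / (0.3 + 0.3)   # original saturating form
        assert got == pytest.approx(oracle) and got == pytest.approx(-0.15)

    def test_composite_form_value(self):
        # dx/dt = -x - x/(1+x) at x=1 -> -1.5
        model = scalar_rational({1: -1.0}, {0: 1.0}, k_entries={1: -1.0}, degree=1)
        assert evaluate_field(model, [[1.0]])[0, 0] == pytest.approx(-1.5)

    def test_denominator_guard_raises_with_snapshots(self):
        model = scalar_rational({0: 1.0}, {0: 1.0}, degree=1)  # 1/(1+x)
        with pytest.raises(DenominatorDegeneracyError) as err:
            evaluate_field(model, [[0.5], [-1.0], [2.0]])
        assert 1 in err.value.snapshot_indices

    def test_rational_with_zero_h_equals_linear(self):
        rng = np.random.default_rng(5)
        d = build_polynomial_dictionary(("x",), 3)
        xi = rng.normal(size=(d.m, 1))
        linear = LinearDictionaryModel(d, CoefficientSet(xi), ("x",))
        rational = scalar_rational(
            {i: xi[i, 0] for i in range(d.m)}, {}, degree=3)
        V = rng.normal(size=(30, 1))
        np.testing.assert_array_equal(rational.value(V), linear.value(V))

    def test_composite_equals_single_fraction_rewrite(self):
        # k=-x, g=-x, h=x  ==  g2/(1+h) with g2 = -(x^2 + 2x)
        composite = scalar_rational({1: -1.0}, {0: 1.0}, k_entries={1: -1.0}, degree=1)
        single = scalar_rational({1: -2.0, 2: -1.0}, {0: 1.0}, degree=2)
        V = np.linspace(-0.5, 3.0, 25)[:, None]
        np.testing.assert_allclose(
            composite.value(V), single.value(V), rtol=1e-12
        )


class TestSimulate:
    def test_linear_oscillator_matches_closed_form(self):
        model = ground_truth_model(BenchmarkSpec("linear_oscillator"))
        t = np.arange(0.0, 3.0, 0.01)
        tr = simulate(model, [1.0, 0.0], t)
        expected = np.exp(-0.1 * t)[:, None] * np.column_stack(
            [np.cos(2 * t), -np.sin(2 * t)])
        np.testing.assert_allclose(tr.states, expected, atol=1e-7)

    def test_zero_field_constant_trajectory(self):
        d = build_polynomial_dictionary(("x",), 1)
        m = LinearDictionaryModel(d, CoefficientSet.dense(d.m, 1), ("x",))
        tr = simulate(m, [2.5], np.linspace(0, 1, 11))
        np.testing.assert_allclose(tr.states, 2.5)

    def test_michaelis_menten_decays_to_equilibrium(self):
        model = ground_truth_model(BenchmarkSpec("michaelis_menten"))
        tr = simulate(model, [2.0], np.linspace(0, 40, 200))
        s = tr.states[:, 0]
        assert np.all(np.diff(s) < 1e-7)           # monotone decay (solver tol)
        assert s[-1] == pytest.approx(0.2, abs=1e-5)  # root of the rate law


class TestSymbolicExport:
    def test_single_term(self):
        d = build_polynomial_dictionary(("x", "y"), 1)
        xi = np.zeros((d.m, 2))
        xi[2, 0] = 2.0  # feature y in equation x
        m = LinearDictionaryModel(d, CoefficientSet(xi), ("x", "y"))
        assert symbolic_export(m, precision=6).splitlines()[0] == "dx/dt = 2*y"

    def test_fhn_term_counts(self):
        model = ground_truth_model(BenchmarkSpec("fhn"))
        lines = symbolic_export(model).splitlines()
        assert lines[0].count("*") == 4  # v, w, v^3, constant
        assert lines[1].count("*") == 3  # v, w, constant

    def test_print_parse_round_trip_exact(self):
        rng = np.random.default_rng(11)
        d = build_polynomial_dictionary(("x", "y"), 3)
        xi = np.where(rng.random((d.m, 2)) < 0.4, rng.normal(size=(d.m, 2)), 0.0)
        m = LinearDictionaryModel(d, CoefficientSet(xi), ("x", "y"))
        parsed = parse_equations(symbolic_export(m), d, ("x", "y"))
        np.testing.assert_array_equal(parsed.xi, m.xi)


class TestAffineTransform:
    def test_lorenz_rescaling_reproduces_printed_model(self):
        lorenz = ground_truth_model(BenchmarkSpec("lorenz"))
        T = AffineTransform(scale=[8.0, 8.0, 8.0], shift=[0.0, 0.0, 25.0])
        tilde = transform_model(lorenz, T, "forward")
        labels = tilde.dictionary.labels()
        # exact substitution z = 8 z~ + 25 turns 28 - z into 3 - 8 z~, so the
        # y-equation constant is 3 (not the unsubstituted 28)
        expect = {
            0: {"x": -10.0, "y": 10.0},
            1: {"x": 3.0, "y": -1.0, "x*z": -8.0},
            2: {"x*y": 8.0, "z": -8.0 / 3.0, "1": -25.0 / 3.0},
        }
        for eq, terms in expect.items():
            nz = {labels[a]: tilde.xi[a, eq]
                  for a in range(len(labels)) if tilde.coefficients.support[a, eq]}
            assert set(nz) == set(terms)
            for lab, val in terms.items():
                assert nz[lab] == pytest.approx(val, rel=1e-12)

    def test_identity_transform_keeps_model(self):
        lorenz = ground_truth_model(BenchmarkSpec("lorenz"))
        same = transform_model(lorenz, AffineTransform.identity(3), "forward")
        np.testing.assert_allclose(
            sorted(same.xi[same.coefficients.support]),
            sorted(lorenz.xi[lorenz.coefficients.support]), rtol=1e-14,
        )

    def test_forward_then_inverse_round_trip(self):
        lorenz = ground_truth_model(BenchmarkSpec("lorenz"))
        T = AffineTransform(scale=[8.0, 8.0, 8.0], shift=[0.0, 0.0, 25.0])
        back = transform_model(transform_model(lorenz, T, "forward"), T, "inverse")
        orig_map = {(a, i): lorenz.xi[a, i]
                    for a in range(lorenz.dictionary.m) for i in range(3)
                    if lorenz.coefficients.support[a, i]}
        exps = {f.exponents: a for a, f in enumerate(back.dictionary.features)}
        for (a, i), val in orig_map.items():
            a2 = exps[lorenz.dictionary.features[a].exponents]
            assert back.xi[a2, i] == pytest.approx(val, abs=1e-12)

    def test_commutes_with_simulation_on_lorenz(self):
        lorenz = ground_truth_model(BenchmarkSpec("lorenz"))
        T = AffineTransform(scale=[8.0, 8.0, 8.0], shift=[0.0, 0.0, 25.0])
        tilde = transform_model(lorenz, T, "forward")
        t = np.linspace(0.0, 2.0, 201)
        x0 = np.array([-8.0, 7.0, 27.0])
        direct = simulate(lorenz, x0, t).states
        via = simulate(tilde, T.apply(x0), t).states
        np.testing.assert_allclose(T.apply(direct), via, atol=1e-6)

    def test_rational_transform_round_trip(self):
        mm = ground_truth_model(BenchmarkSpec("michaelis_menten"))
        T = AffineTransform(scale=[0.35], shift=[0.8])
        back = transform_model(transform_model(mm, T, "forward"), T, "inverse")
        np.testing.assert_allclose(back.coeff_g.xi[:2, 0], [0.6, -3.0], rtol=1e-10)
        assert back.coeff_h.xi[0, 0] == pytest.approx(10.0 / 3.0, rel=1e-10)

    def test_non_polynomial_features_rejected(self):
        model = ground_truth_model(BenchmarkSpec("exp_decay"))
        with pytest.raises(UnsupportedTransformError):
            transform_model(model, AffineTransform(scale=[2.0], shift=[0.0]))

    def test_zero_scale_rejected(self):
        from rk4sindy.exceptions import InvalidArgumentError

        with pytest.raises(InvalidArgumentError):
            AffineTransform(scale=[0.0], shift=[1.0])
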