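import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rk4sindy.dictionary import (
    FeatureDescriptor,
    FeatureDictionary,
    add_parameterized_features,
    build_controlled_dictionary,
    build_polynomial_dictionary,
    parse_label,
)
from rk4sindy.exceptions import InvalidArgumentError, InvalidDataError


class TestPolynomialBuilder:
    def test_degree2_two_variables_order_and_labels(self):
        d = build_polynomial_dictionary(["v1", "v2"], 2)
        assert d.labels() == ["1", "v1", "v2", "v1^2", "v1*v2", "v2^2"]
        assert d.m == 6

    def test_degree0_constant_only(self):
        d = build_polynomial_dictionary(["x"], 0)
        assert d.labels() == ["1"] and d.m == 1

    def test_three_vars_degree3_count_by_enumeration(self):
        d = build_polynomial_dictionary(["x", "y", "z"], 3)
        # independent oracle: enumerate exponent triples with sum <= 3
        count = sum(
            1
            for a in range(4)
            for b in range(4)
            for c in range(4)
            if a + b + c <= 3
        )
        assert d.m == count == 20

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    @pytest.mark.parametrize("deg", [0, 1, 2, 3, 4, 5])
    def test_feature_count_is_binomial(self, n, deg):
        d = build_polynomial_dictionary([f"x{i}" for i in range(n)], deg)
        assert d.m == math.comb(n + deg, deg)

    def test_no_bias_excludes_constant(self):
        d = build_polynomial_dictionary(["x"], 2, include_bias=False)
        assert d.labels() == ["x", "x^2"]

    def test_negative_degree_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_polynomial_dictionary(["x"], -1)

    def test_empty_variables_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_polynomial_dictionary([], 2)


class TestControlledBuilder:
    def test_state_input_cross_terms(self):
        d = build_controlled_dictionary(["x"], ["u"], 2)
        assert d.labels() == ["1", "x", "u", "x^2", "x*u", "u^2"]

    def test_no_inputs_reduces_to_state_dictionary(self):
        d = build_controlled_dictionary(["x", "y"], [], 1)
        assert d.labels() == ["1", "x", "y"]

    def test_two_inputs_count(self):
        d = build_controlled_dictionary(["x"], ["u1", "u2"], 2)
        assert d.m == math.comb(3 + 2, 2) == 10

    def test_empty_states_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_controlled_dictionary([], ["u"], 2)


class TestEvaluation:
    def test_direct_substitution_row(self):
        d = build_polynomial_dictionary(["v1", "v2"], 2)
        np.testing.assert_allclose(d.evaluate([[2.0, 3.0]]), [[1, 2, 3, 4, 6, 9]])

    def test_zero_vector_hits_only_bias(self):
        d = build_polynomial_dictionary(["x", "y"], 3)
        row = d.evaluate([[0.0, 0.0]])[0]
        assert row[0] == 1.0 and np.all(row[1:] == 0.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        d = build_polynomial_dictionary(["x", "y", "z"], 3)
        V = rng.normal(size=(20, 3))
        perm = rng.permutation(20)
        np.testing.assert_array_equal(d.evaluate(V)[perm], d.evaluate(V[perm]))

    def test_nonfinite_snapshots_rejected(self):
        d = build_polynomial_dictionary(["x"], 2)
        with pytest.raises(InvalidDataError):
            d.evaluate([[np.nan]])

    def test_wrong_column_count_rejected(self):
        d = build_polynomial_dictionary(["x", "y"], 2)
        with pytest.raises(InvalidArgumentError):
            d.evaluate([[1.0, 2.0, 3.0]])

    def test_gradients_match_finite_differences(self):
        base = build_polynomial_dictionary(["x", "y"], 3)
        d = add_parameterized_features(
            base,
            [{"kind": "sine", "argument": "x"},
             {"kind": "exponential", "argument": "x*y"}],
            rng=0,
        )
        rng = np.random.default_rng(1)
        V = rng.normal(size=(5, 2))
        F, dV, dE = d.evaluate_with_grad(V)
        eps = 1e-7
        for k in range(2):
            Vp = V.copy()
            Vp[:, k] += eps
            np.testing.assert_allclose(
                (d.evaluate(Vp) - F) / eps, dV[:, :, k], atol=1e-5
            )
        for e in range(d.n_eta):
            d2 = d.copy()
            d2.eta[e] += eps
            np.testing.assert_allclose(
                (d2.evaluate(V) - F) / eps, dE[:, :, e], atol=1e-5
            )


class TestParameterizedFeatures:
    def test_empty_specs_is_identity(self):
        d = build_polynomial_dictionary(["x"], 2)
        d2 = add_parameterized_features(d, [])
        assert d2.labels() == d.labels() and d2.n_eta == 0

    def test_fresh_eta_appended_and_seed_reproducible(self):
        d = build_polynomial_dictionary(["x"], 1)
        d1 = add_parameterized_features(
            d, [{"kind": "exponential", "argument": "x"}], rng=42)
        d2 = add_parameterized_features(
            d, [{"kind": "exponential", "argument": "x"}], rng=42)
        assert d1.n_eta == 1 and d1.m == d.m + 1
        assert -1.0 <= d1.eta[0] <= 1.0
        np.testing.assert_array_equal(d1.eta, d2.eta)
        assert d1.labels()[-1] == "exp(eta0*x)"

    def test_fixed_coefficient_sine_closed_form(self):
        d = build_polynomial_dictionary(["x"], 1)
        d = add_parameterized_features(
            d, [{"kind": "sine", "argument": "x", "coeff": 2.0}])
        val = d.evaluate([[np.pi / 4]])[0, -1]
        assert val == pytest.approx(1.0)  # sin(2 * pi/4)

    def test_exponential_at_zero_is_one(self):
        d = build_polynomial_dictionary(["x"], 1)
        d = add_parameterized_features(
            d, [{"kind": "exponential", "argument": "x", "coeff": -1.75}])
        assert d.evaluate([[0.0]])[0, -1] == pytest.approx(1.0)

    def test_unsupported_kind_rejected(self):
        d = build_polynomial_dictionary(["x"], 1)
        with pytest.raises(InvalidArgumentError):
            add_parameterized_features(d, [{"kind": "tanh", "argument": "x"}])


class TestLabelsAndSerialization:
    @pytest.mark.parametrize("descriptor", [
        FeatureDescriptor("monomial", (0, 0)),
        FeatureDescriptor("monomial", (2, 1)),
        FeatureDescriptor("sine", (1, 0), coeff=2.5),
        FeatureDescriptor("cosine", (0, 2), coeff_param_index=0),
        FeatureDescriptor("exponential", (1, 1), coeff=-1.75),
    ])
    def test_label_round_trip(self, descriptor):
        variables = ("x", "y")
        assert parse_label(descriptor.label(variables), variables) == descriptor

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=4))
    @settings(deadline=None, derandomize=True)
    def test_monomial_label_round_trip_property(self, exps):
        variables = tuple(f"v{i}" for i in range(len(exps)))
        desc = FeatureDescriptor("monomial", tuple(exps))
        assert parse_label(desc.label(variables), variables) == desc

    def test_config_round_trip_exact(self):
        d = build_polynomial_dictionary(["x", "y"], 2)
        d = add_parameterized_features(
            d,
            [{"kind": "sine", "argument": "x"},
             {"kind": "exponential", "argument": "y^2", "coeff": 0.5}],
            rng=7,
        )
        d2 = FeatureDictionary.from_config(d.to_config())
        assert d2.labels() == d.labels()
        np.testing.assert_array_equal(d2.eta, d.eta)

    def test_duplicate_labels_rejected(self):
        f = FeatureDescriptor("monomial", (1,))
        with pytest.raises(InvalidArgumentError):
            FeatureDictionary(("x",), (f, f))
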