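"""Learn a feature's internal rate constant along with the sparse model.

The field dx/dt = -x + exp(-1.75 x) contains an exponential whose rate is
unknown a priori; enumerating exp(b x) for every b is impossible.  Instead
the dictionary carries one trainable feature exp(eta * x) and eta is
optimized jointly with the coefficients (with seeded restarts, since the
loss is non-convex in eta).  The fit should report eta close to -1.75 with
unit coefficient on the exponential and -1 on x.
"""

from rk4sindy import (
    BenchmarkSpec,
    CoefficientSet,
    FitConfig,
    LinearDictionaryModel,
    OptimizerConfig,
    add_parameterized_features,
    build_polynomial_dictionary,
    generate,
    optimize_coefficients,
    symbolic_export,
)

data = generate(BenchmarkSpec("exp_decay"))   # two ICs, dt = 0.05
dictionary = add_parameterized_features(
    build_polynomial_dictionary(data.variable_names, 1),
    [{"kind": "exponential", "argument": "x"}],
    rng=42,
)
print(f"initial eta (random draw): {dictionary.eta[0]:+.3f}")

model = LinearDictionaryModel(
    dictionary, CoefficientSet.dense(dictionary.m, 1), data.state_names)
fitted, _ = optimize_coefficients(
    model, data, FitConfig(optimizer=OptimizerConfig(seed=0)))

print(f"recovered eta: {fitted.dictionary.eta[0]:+.5f}  (generating value -1.75)")
print("recovered model:", symbolic_export(fitted, precision=4))
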