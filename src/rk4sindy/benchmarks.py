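"""Benchmark systems and data generation.

Every experiment in the package is synthetic: the generator integrates a
known ground-truth model with a high-accuracy adaptive solver and samples
it on a regular grid, optionally corrupting the samples with Gaussian
noise.  The systems are the standard sparse-identification benchmarks:

* ``linear_oscillator``  -- damped linear 2-D oscillator,
  dx/dt = -0.1 x + 2 y, dy/dt = -2 x - 0.1 y
* ``cubic_oscillator``   -- same damping/rotation structure on cubes,
  dx/dt = -0.1 x^3 + 2 y^3, dy/dt = -2 x^3 - 0.1 y^3
* ``fhn``                -- FitzHugh-Nagumo neuron model,
  dv/dt = v - w - v^3/3 + 0.5, dw/dt = 0.040 v - 0.028 w + 0.032
* ``lorenz``             -- chaotic Lorenz-63,
  dx/dt = 10(y-x), dy/dt = x(28-z) - y, dz/dt = xy - (8/3) z
* ``michaelis_menten``   -- substrate kinetics with a saturating uptake,
  ds/dt = 0.6 - 1.5 s/(0.3 + s), written as the rational field
  (0.6 - 3 s)/(1 + (10/3) s)
* ``hopf``               -- normal form of a supercritical Hopf bifurcation
  over states (x, y) and parameter mu (omega = A = 1 by default), one
  trajectory per mu value
* ``exp_decay``          -- scalar field with an exponential feature,
  dx/dt = -x + exp(-1.75 x)

The generator integrates at rtol 1e-9 so that the data error stays far
below the O(h^5) one-step truncation floor of the fitting residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TrajectoryCollection
from .dictionary import add_parameterized_features, build_polynomial_dictionary
from .exceptions import InvalidArgumentError
from .models import CoefficientSet, LinearDictionaryModel, RationalModel, simulate
from .preprocess import NoiseSpec, add_noise

__all__ = ["BenchmarkSpec", "ground_truth_model", "generate", "BENCHMARKS"]

BENCHMARKS = (
    "linear_oscillator", "cubic_oscillator", "fhn", "lorenz",
    "michaelis_menten", "hopf", "exp_decay",
)

_DEFAULTS = {
    # (initial conditions, t0, tf, dt)
    "linear_oscillator": ([(2.0, 0.0)], 0.0, 10.0, 1e-2),
    "cubic_oscillator": ([(2.0, 0.0)], 0.0, 10.0, 1e-2),
    "fhn": ([(0.0, 0.0)], 0.0, 600.0, 1e-1),
    "lorenz": ([(-8.0, 7.0, 27.0)], 0.0, 20.0, 1e-2),
    "michaelis_menten": ([(0.5,), (1.0,), (1.5,), (2.0,)], 0.0, 8.0, 5e-2),
    "hopf": ([(1.0, 0.0)], 0.0, 20.0, 2e-1),
    "exp_decay": ([(0.5,), (1.5,)], 0.0, 5.0, 5e-2),
}


@dataclass
class BenchmarkSpec:
    name: str
    initial_conditions: list | None = None
    t0: float | None = None
    tf: float | None = None
    dt: float | None = None
    times: np.ndarray | None = None
    # hopf extras
    mu_values: np.ndarray | None = None
    omega: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.name not in BENCHMARKS:
            raise InvalidArgumentError(
                f"unknown benchmark {self.name!r}; choose from {BENCHMARKS}"
            )
        ics, t0, tf, dt = _DEFAULTS[self.name]
        if self.initial_conditions is None:
            self.initial_conditions = [tuple(ic) for ic in ics]
        else:
            self.initial_conditions = [tuple(np.atleast_1d(ic)) for ic in self.initial_conditions]
        self.t0 = t0 if self.t0 is None else float(self.t0)
        self.tf = tf if self.tf is None else float(self.tf)
        self.dt = dt if self.dt is None else float(self.dt)
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if self.name == "hopf" and self.mu_values is None:
            self.mu_values = np.linspace(-0.2, 0.6, 8)

    def time_grid(self) -> np.ndarray:
        if self.times is not None:
            return np.asarray(self.times, dtype=float)
        n = int(round((self.tf - self.t0) / self.dt))
        return self.t0 + self.dt * np.arange(n + 1)


def _sparse_linear(variables, degree, entries, state_names=None, include_bias=True):
    """Model from {(monomial exponents, eq): coeff} entries."""
    d = build_polynomial_dictionary(variables, degree, include_bias)
    index = {f.exponents: a for a, f in enumerate(d.features)}
    n = len(state_names or variables)
    xi = np.zeros((d.m, n))
    for (exps, eq), c in entries.items():
        xi[index[tuple(exps)], eq] = c
    return LinearDictionaryModel(d, CoefficientSet(xi), state_names or variables)


def ground_truth_model(spec: BenchmarkSpec):
    """The generating model with its printed coefficients."""
    name = spec.name
    if name == "linear_oscillator":
        return _sparse_linear(
            ("x", "y"), 1,
            {((1, 0), 0): -0.1, ((0, 1), 0): 2.0, ((1, 0), 1): -2.0, ((0, 1), 1): -0.1},
        )
    if name == "cubic_oscillator":
        return _sparse_linear(
            ("x", "y"), 3,
            {((3, 0), 0): -0.1, ((0, 3), 0): 2.0, ((3, 0), 1): -2.0, ((0, 3), 1): -0.1},
        )
    if name == "fhn":
        return _sparse_linear(
            ("v", "w"), 3,
            {
                ((1, 0), 0): 1.0, ((0, 1), 0): -1.0, ((3, 0), 0): -1.0 / 3.0,
                ((0, 0), 0): 0.5,
                ((1, 0), 1): 0.040, ((0, 1), 1): -0.028, ((0, 0), 1): 0.032,
            },
        )
    if name == "lorenz":
        return _sparse_linear(
            ("x", "y", "z"), 2,
            {
                ((1, 0, 0), 0): -10.0, ((0, 1, 0), 0): 10.0,
                ((1, 0, 0), 1): 28.0, ((1, 0, 1), 1): -1.0, ((0, 1, 0), 1): -1.0,
                ((1, 1, 0), 2): 1.0, ((0, 0, 1), 2): -8.0 / 3.0,
            },
        )
    if name == "michaelis_menten":
        # ds/dt = 0.6 - 1.5 s/(0.3+s)  ==  (0.6 - 3 s) / (1 + (10/3) s)
        phi_g = build_polynomial_dictionary(("s",), 1)
        phi_h = build_polynomial_dictionary(("s",), 1, include_bias=False)
        return RationalModel(
            phi_g, phi_h,
            CoefficientSet(np.array([[0.6], [-3.0]])),
            CoefficientSet(np.array([[10.0 / 3.0]])),
            ("s",),
        )
    if name == "hopf":
        w, A = spec.omega, spec.amplitude
        return _sparse_linear(
            ("x", "y", "mu"), 3,
            {
                ((1, 0, 1), 0): 1.0, ((0, 1, 0), 0): -w,
                ((3, 0, 0), 0): -A, ((1, 2, 0), 0): -A,
                ((1, 0, 0), 1): w, ((0, 1, 1), 1): 1.0,
                ((2, 1, 0), 1): -A, ((0, 3, 0), 1): -A,
            },
            state_names=("x", "y"),
        )
    if name == "exp_decay":
        base = build_polynomial_dictionary(("x",), 1)
        d = add_parameterized_features(
            base, [{"kind": "exponential", "argument": "x", "coeff": -1.75}]
        )
        xi = np.zeros((d.m, 1))
        xi[1, 0] = -1.0   # x term
        xi[2, 0] = 1.0    # exp(-1.75 x)
        return LinearDictionaryModel(d, CoefficientSet(xi), ("x",))
    raise InvalidArgumentError(f"unknown benchmark {name!r}")


def generate(spec: BenchmarkSpec, noise: NoiseSpec | None = None,
             seed: int | None = None) -> TrajectoryCollection:
    """Integrate the ground truth on the spec's grid, one trajectory per
    initial condition (per (mu, IC) pair for ``hopf``), with optional noise.

    ``seed`` overrides ``noise.seed`` when both are given.
    """
    model = ground_truth_model(spec)
    times = spec.time_grid()
    trajectories = []
    if spec.name == "hopf":
        for j, mu in enumerate(np.asarray(spec.mu_values, dtype=float)):
            for i, ic in enumerate(spec.initial_conditions):
                tr = simulate(model, ic, times, params=[mu],
                              trajectory_id=f"hopf_mu{j}_ic{i}")
                trajectories.append(tr)
    else:
        for i, ic in enumerate(spec.initial_conditions):
            tr = simulate(model, ic, times, trajectory_id=f"{spec.name}_ic{i}")
            trajectories.append(tr)
    collection = TrajectoryCollection(trajectories)
    if noise is not None and noise.sigma > 0:
        if seed is not None:
            noise = NoiseSpec(noise.sigma, noise.relative, seed, noise.kind)
        collection = add_noise(collection, noise)
    return collection
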