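"""Symbolic feature dictionaries.

A :class:`FeatureDictionary` is an ordered list of candidate features
``phi_1 ... phi_m`` over a fixed, ordered variable list (states first, then
inputs, then parameters).  Evaluating the dictionary on a batch of snapshots
``V`` (shape ``N x n_vars``) yields the ``N x m`` regressor matrix used by
the sparse fits.  Because the fitting objective propagates gradients through
the Runge-Kutta stages, every feature also exposes closed-form derivatives
with respect to the variables and with respect to any trainable feature
parameters ``eta`` (e.g. the rate in ``exp(eta*x)``).

Monomials are ordered graded-lexicographically: the constant (if present),
then degree-1 terms in variable order, then for each higher degree the
monomials produced by combinations-with-replacement of the variables; for
two variables and degree 2 this reads ``[1, v1, v2, v1^2, v1*v2, v2^2]``.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError, InvalidDataError

__all__ = [
    "FeatureDescriptor",
    "FeatureDictionary",
    "build_polynomial_dictionary",
    "build_controlled_dictionary",
    "add_parameterized_features",
    "parse_label",
]

_KINDS = ("monomial", "sine", "cosine", "exponential")
_FUNC_NAME = {"sine": "sin", "cosine": "cos", "exponential": "exp"}
_NAME_FUNC = {v: k for k, v in _FUNC_NAME.items()}


@dataclass(frozen=True)
class FeatureDescriptor:
    """One dictionary entry.

    ``exponents`` is the exponent vector of the monomial itself (kind
    ``monomial``) or of the monomial *argument* of a trig/exp feature.
    A trig/exp feature carries either a fixed scalar ``coeff`` c, giving
    e.g. ``sin(c * x^2)``, or an index ``coeff_param_index`` into the
    dictionary's trainable vector ``eta``.
    """

    kind: str
    exponents: tuple[int, ...]
    coeff: float | None = None
    coeff_param_index: int | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidArgumentError(f"unsupported feature kind {self.kind!r}")
        if any((e < 0 or int(e) != e) for e in self.exponents):
            raise InvalidArgumentError("monomial exponents must be non-negative integers")
        if self.kind == "monomial":
            if self.coeff is not None or self.coeff_param_index is not None:
                raise InvalidArgumentError("monomial features take no coefficient")
        else:
            if (self.coeff is None) == (self.coeff_param_index is None):
                raise InvalidArgumentError(
                    "trig/exp features need exactly one of coeff / coeff_param_index"
                )

    @property
    def degree(self) -> int:
        return int(sum(self.exponents))

    def label(self, variables: tuple[str, ...]) -> str:
        mono = _monomial_label(self.exponents, variables)
        if self.kind == "monomial":
            return mono
        c = f"eta{self.coeff_param_index}" if self.coeff is None else repr(float(self.coeff))
        return f"{_FUNC_NAME[self.kind]}({c}*{mono})"


def _monomial_label(exponents, variables) -> str:
    parts = []
    for name, e in zip(variables, exponents):
        if e == 1:
            parts.append(name)
        elif e > 1:
            parts.append(f"{name}^{e}")
    return "*".join(parts) if parts else "1"


def parse_label(label: str, variables: tuple[str, ...]) -> FeatureDescriptor:
    """Invert :meth:`FeatureDescriptor.label` (round-trip stable)."""
    m = re.match(r"^(sin|cos|exp)\((.+)\)$", label)
    if m:
        inner = m.group(2)
        coeff_str, _, mono_str = inner.partition("*")
        exps = _parse_monomial(mono_str if mono_str else "1", variables)
        if coeff_str.startswith("eta"):
            return FeatureDescriptor(_NAME_FUNC[m.group(1)], exps,
                                     coeff_param_index=int(coeff_str[3:]))
        return FeatureDescriptor(_NAME_FUNC[m.group(1)], exps, coeff=float(coeff_str))
    return FeatureDescriptor("monomial", _parse_monomial(label, variables))


def _parse_monomial(s: str, variables) -> tuple[int, ...]:
    exps = [0] * len(variables)
    if s.strip() == "1":
        return tuple(exps)
    index = {name: i for i, name in enumerate(variables)}
    for part in s.split("*"):
        name, _, p = part.partition("^")
        if name not in index:
            raise InvalidArgumentError(f"unknown variable {name!r} in label {s!r}")
        exps[index[name]] += int(p) if p else 1
    return tuple(exps)


@dataclass
class FeatureDictionary:
    """Ordered feature list with optional trainable parameters ``eta``."""

    variables: tuple[str, ...]
    features: tuple[FeatureDescriptor, ...]
    eta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.variables = tuple(self.variables)
        self.features = tuple(self.features)
        self.eta = np.asarray(self.eta, dtype=float).reshape(-1)
        if len(self.features) < 1:
            raise InvalidArgumentError("a dictionary needs at least one feature")
        labels = self.labels()
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError("feature labels must be unique")
        for f in self.features:
            if len(f.exponents) != len(self.variables):
                raise InvalidArgumentError("feature exponent length must match variables")
            if f.coeff_param_index is not None and not (
                0 <= f.coeff_param_index < self.eta.size
            ):
                raise InvalidArgumentError("coeff_param_index out of range of eta")

    # -- introspection ---------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.features)

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def n_eta(self) -> int:
        return int(self.eta.size)

    def labels(self) -> list[str]:
        return [f.label(self.variables) for f in self.features]

    def is_polynomial(self) -> bool:
        return all(f.kind == "monomial" for f in self.features)

    def max_degree(self) -> int:
        return max(f.degree for f in self.features)

    def has_constant(self) -> bool:
        return any(f.kind == "monomial" and f.degree == 0 for f in self.features)

    def copy(self) -> "FeatureDictionary":
        return FeatureDictionary(self.variables, self.features, self.eta.copy())

    # -- evaluation ------------------------------------------------------
    def _check_snapshots(self, V) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        if V.ndim == 1:
            V = V[None, :]
        if V.shape[1] != self.n_vars:
            raise InvalidArgumentError(
                f"snapshots have {V.shape[1]} columns, dictionary has "
                f"{self.n_vars} variables"
            )
        if not np.all(np.isfinite(V)):
            raise InvalidDataError("snapshots contain non-finite entries")
        return V

    def evaluate(self, snapshots) -> np.ndarray:
        """Row-wise feature evaluation: returns an ``N x m`` matrix."""
        V = self._check_snapshots(snapshots)
        out = np.empty((V.shape[0], self.m))
        # overflow (e.g. exp during optimizer exploration) yields inf and is
        # handled by the callers' finiteness guards
        with np.errstate(over="ignore", invalid="ignore"):
            for j, f in enumerate(self.features):
                out[:, j] = self._feature_value(f, V)
        return out

    def evaluate_with_grad(self, snapshots, n_grad_vars: int | None = None):
        """Features plus derivatives.

        Returns ``(F, dF_dV, dF_deta)`` with shapes ``(N, m)``,
        ``(N, m, n_grad_vars)`` and ``(N, m, n_eta)``.  ``n_grad_vars``
        restricts variable derivatives to the first columns (the states);
        parameters/inputs are constant along RK4 stages so their
        derivatives are never needed.
        """
        V = self._check_snapshots(snapshots)
        N = V.shape[0]
        ng = self.n_vars if n_grad_vars is None else int(n_grad_vars)
        F = np.empty((N, self.m))
        dV = np.zeros((N, self.m, ng))
        dE = np.zeros((N, self.m, self.n_eta))
        with np.errstate(over="ignore", invalid="ignore"):
            for j, f in enumerate(self.features):
                a = _monomial_value(f.exponents, V)
                da = [_monomial_grad(f.exponents, V, k) for k in range(ng)]
                if f.kind == "monomial":
                    F[:, j] = a
                    for k in range(ng):
                        dV[:, j, k] = da[k]
                    continue
                c = self.eta[f.coeff_param_index] if f.coeff is None else float(f.coeff)
                if f.kind == "sine":
                    val, outer, douter_dc = np.sin(c * a), np.cos(c * a), a * np.cos(c * a)
                elif f.kind == "cosine":
                    val, outer, douter_dc = np.cos(c * a), -np.sin(c * a), -a * np.sin(c * a)
                else:  # exponential
                    val = np.exp(c * a)
                    outer, douter_dc = val, a * val
                F[:, j] = val
                for k in range(ng):
                    dV[:, j, k] = c * outer * da[k]
                if f.coeff is None:
                    dE[:, j, f.coeff_param_index] = douter_dc
        return F, dV, dE

    def _feature_value(self, f: FeatureDescriptor, V) -> np.ndarray:
        a = _monomial_value(f.exponents, V)
        if f.kind == "monomial":
            return a
        c = self.eta[f.coeff_param_index] if f.coeff is None else float(f.coeff)
        if f.kind == "sine":
            return np.sin(c * a)
        if f.kind == "cosine":
            return np.cos(c * a)
        return np.exp(c * a)

    # -- serialization ---------------------------------------------------
    def to_config(self) -> dict:
        feats = []
        for f in self.features:
            d = {"kind": f.kind, "exponents": list(f.exponents)}
            if f.coeff is not None:
                d["coeff"] = float(f.coeff)
            if f.coeff_param_index is not None:
                d["coeff_param_index"] = int(f.coeff_param_index)
            feats.append(d)
        return {
            "variables": list(self.variables),
            "features": feats,
            "eta": [float(v) for v in self.eta],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "FeatureDictionary":
        feats = tuple(
            FeatureDescriptor(
                d["kind"],
                tuple(int(e) for e in d["exponents"]),
                coeff=d.get("coeff"),
                coeff_param_index=d.get("coeff_param_index"),
            )
            for d in cfg["features"]
        )
        return cls(tuple(cfg["variables"]), feats, np.asarray(cfg.get("eta", []), dtype=float))


def _monomial_value(exponents, V) -> np.ndarray:
    out = np.ones(V.shape[0])
    for k, e in enumerate(exponents):
        if e:
            out = out * V[:, k] ** e
    return out


def _monomial_grad(exponents, V, k) -> np.ndarray:
    e = exponents[k]
    if e == 0:
        return np.zeros(V.shape[0])
    out = e * V[:, k] ** (e - 1)
    for l, el in enumerate(exponents):
        if el and l != k:
            out = out * V[:, l] ** el
    return out


def _graded_lex_monomials(n_vars: int, degree: int, include_bias: bool):
    feats = []
    for d in range(0 if include_bias else 1, degree + 1):
        for combo in itertools.combinations_with_replacement(range(n_vars), d):
            exps = [0] * n_vars
            for idx in combo:
                exps[idx] += 1
            feats.append(FeatureDescriptor("monomial", tuple(exps)))
    if not feats:  # degree 0 without bias
        raise InvalidArgumentError("dictionary would be empty")
    return tuple(feats)


def build_polynomial_dictionary(
    variables, degree: int, include_bias: bool = True
) -> FeatureDictionary:
    """All monomials of total degree <= ``degree`` in graded-lex order.

    With the bias included the feature count is the binomial
    ``C(n_vars + degree, degree)``.
    """
    variables = tuple(variables)
    if not variables:
        raise InvalidArgumentError("at least one variable is required")
    if degree < 0:
        raise InvalidArgumentError("degree must be >= 0")
    feats = _graded_lex_monomials(len(variables), degree, include_bias)
    if include_bias:
        assert len(feats) == math.comb(len(variables) + degree, degree)
    return FeatureDictionary(variables, feats)


def build_controlled_dictionary(state_names, input_names, degree: int) -> FeatureDictionary:
    """Monomials over the concatenated (states, inputs) list, cross terms included."""
    state_names = tuple(state_names)
    if not state_names:
        raise InvalidArgumentError("at least one state variable is required")
    if degree < 1:
        raise InvalidArgumentError("controlled dictionaries need degree >= 1")
    return build_polynomial_dictionary(state_names + tuple(input_names), degree)


def add_parameterized_features(
    dictionary: FeatureDictionary,
    specs,
    rng: np.random.Generator | int | None = None,
) -> FeatureDictionary:
    """Append trig/exp features with trainable (or fixed) inner coefficients.

    Each spec is a mapping ``{"kind": ..., "argument": ...}`` where the
    argument is a monomial given as a variable name, a label like ``"x^2"``,
    or an exponent tuple.  Specs without a ``"coeff"`` entry get a fresh
    trainable ``eta`` entry, initialized uniformly in [-1, 1] from ``rng``.
    """
    if not specs:
        return dictionary.copy()
    rng = np.random.default_rng(rng)
    feats = list(dictionary.features)
    eta = list(dictionary.eta)
    for spec in specs:
        kind = spec["kind"]
        if kind not in ("sine", "cosine", "exponential"):
            raise InvalidArgumentError(f"unsupported parameterized feature kind {kind!r}")
        arg = spec["argument"]
        if isinstance(arg, str):
            exps = _parse_monomial(arg, dictionary.variables)
        else:
            exps = tuple(int(e) for e in arg)
        if "coeff" in spec and spec["coeff"] is not None:
            feats.append(FeatureDescriptor(kind, exps, coeff=float(spec["coeff"])))
        else:
            feats.append(FeatureDescriptor(kind, exps, coeff_param_index=len(eta)))
            eta.append(float(rng.uniform(-1.0, 1.0)))
    return FeatureDictionary(dictionary.variables, tuple(feats), np.asarray(eta))
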