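"""Right-hand-side model families built from dictionaries and sparse coefficients.

Two families are provided:

* :class:`LinearDictionaryModel` -- ``f(x) = Phi(x) Xi`` with a sparse
  coefficient matrix ``Xi`` (one column per state equation).  Covers the
  plain, controlled (states + inputs) and parametric (states + parameters)
  cases.
* :class:`RationalModel` -- per-state rational fields
  ``f_i(x) = k_i(x) + g_i(x) / (1 + h_i(x))`` with each part a sparse
  combination of its own dictionary.  The denominator dictionary carries no
  constant feature, so the leading ``1 +`` normalization is structural and
  removes the scale ambiguity of a quotient.  A pure quotient
  ``g/(1+h)`` is the special case without the additive ``k`` part.

Both families expose closed-form Jacobians with respect to the states and
with respect to their free parameters (packed coefficient entries followed
by any trainable dictionary parameters ``eta``); the sparse-regression
objective differentiates through the four RK4 stages using these.

Affine changes of coordinates ``x~ = (x - shift)/scale`` (used to condition
polynomial dictionaries) act exactly on polynomial models via symbolic
substitution, so fitted coefficients can always be mapped back to original
coordinates for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .data import TrajectoryData
from .dictionary import FeatureDictionary, build_polynomial_dictionary
from .exceptions import (
    DenominatorDegeneracyError,
    InvalidArgumentError,
    InvalidDataError,
    SimulationError,
    UnsupportedTransformError,
)

__all__ = [
    "CoefficientSet",
    "LinearDictionaryModel",
    "RationalModel",
    "AffineTransform",
    "evaluate_field",
    "simulate",
    "symbolic_export",
    "parse_equations",
    "transform_model",
]

EPS_DEN = 1e-8  # hard guard on |1 + h(x)|; degeneracy is an error, never clipped


@dataclass
class CoefficientSet:
    """Sparse coefficient matrix ``m x n`` with an explicit support mask."""

    xi: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self):
        self.xi = np.atleast_2d(np.asarray(self.xi, dtype=float))
        if self.support is None:
            self.support = self.xi != 0.0
        self.support = np.asarray(self.support, dtype=bool)
        if self.support.shape != self.xi.shape:
            raise InvalidArgumentError("support mask must match coefficient shape")
        self.xi = np.where(self.support, self.xi, 0.0)

    @classmethod
    def dense(cls, m: int, n: int) -> "CoefficientSet":
        return cls(np.zeros((m, n)), np.ones((m, n), dtype=bool))

    @property
    def shape(self):
        return self.xi.shape

    @property
    def nnz(self) -> int:
        return int(self.support.sum())

    def copy(self) -> "CoefficientSet":
        return CoefficientSet(self.xi.copy(), self.support.copy())

    def column_empty(self) -> np.ndarray:
        """Boolean per equation: no active feature left."""
        return ~self.support.any(axis=0)


class _ModelBase:
    """Shared parameter packing and RK4-facing callable interface."""

    state_names: tuple[str, ...]
    variables: tuple[str, ...]

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def __call__(self, V: np.ndarray) -> np.ndarray:
        return self.value(V)

    # packing ------------------------------------------------------------
    def coeff_entries(self):
        """Deterministic order of free coefficient entries.

        Yields ``(block_name, coeffs, feature_index, eq_index)`` sorted by
        (block, feature, equation) -- the tie-break order used when several
        coefficients share the smallest magnitude.
        """
        for name, cs in self._blocks():
            for a in range(cs.shape[0]):
                for i in range(cs.shape[1]):
                    if cs.support[a, i]:
                        yield name, cs, a, i

    def get_theta(self) -> np.ndarray:
        parts = [cs.xi[a, i] for _, cs, a, i in self.coeff_entries()]
        for d in self._dictionaries():
            parts.extend(d.eta.tolist())
        return np.asarray(parts, dtype=float)

    def set_theta(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float).reshape(-1)
        entries = list(self.coeff_entries())
        n_eta = sum(d.n_eta for d in self._dictionaries())
        if theta.size != len(entries) + n_eta:
            raise InvalidArgumentError("theta length does not match free parameters")
        for val, (_, cs, a, i) in zip(theta, entries):
            cs.xi[a, i] = val
        pos = len(entries)
        for d in self._dictionaries():
            if d.n_eta:
                d.eta[:] = theta[pos:pos + d.n_eta]
                pos += d.n_eta

    def theta_coeff_mask(self) -> np.ndarray:
        """True for packed entries that are Xi coefficients (l1-penalized)."""
        n_coeff = sum(1 for _ in self.coeff_entries())
        n_eta = sum(d.n_eta for d in self._dictionaries())
        return np.concatenate([np.ones(n_coeff, bool), np.zeros(n_eta, bool)])

    @property
    def n_free(self) -> int:
        return self.get_theta().size

    def total_nnz(self) -> int:
        return sum(cs.nnz for _, cs in self._blocks())

    def prune_entry(self, index: int) -> None:
        """Zero and freeze the ``index``-th packed coefficient entry."""
        for pos, (_, cs, a, i) in enumerate(self.coeff_entries()):
            if pos == index:
                cs.xi[a, i] = 0.0
                cs.support[a, i] = False
                return
        raise InvalidArgumentError("coefficient index out of range")


class LinearDictionaryModel(_ModelBase):
    """``f(x) = Phi(x) Xi`` over a single feature dictionary."""

    def __init__(self, dictionary: FeatureDictionary, coefficients: CoefficientSet,
                 state_names, form: str = "linear_in_dictionary"):
        if coefficients.shape != (dictionary.m, len(tuple(state_names))):
            raise InvalidArgumentError("coefficient shape must be (m, n_states)")
        self.dictionary = dictionary
        self.coefficients = coefficients
        self.state_names = tuple(state_names)
        self.variables = dictionary.variables
        if self.variables[: self.n_states] != self.state_names:
            raise InvalidArgumentError("dictionary variables must start with the states")
        self.form = form

    @property
    def xi(self) -> np.ndarray:
        return self.coefficients.xi

    def _blocks(self):
        return [("xi", self.coefficients)]

    def _dictionaries(self):
        return [self.dictionary]

    def copy(self) -> "LinearDictionaryModel":
        return LinearDictionaryModel(
            self.dictionary.copy(), self.coefficients.copy(), self.state_names, self.form
        )

    def value(self, V: np.ndarray) -> np.ndarray:
        return self.dictionary.evaluate(V) @ self.xi

    def value_and_jacobians(self, V: np.ndarray, need_theta: bool = True):
        ns = self.n_states
        F, dV, dE = self.dictionary.evaluate_with_grad(V, n_grad_vars=ns)
        f = F @ self.xi
        Jx = np.einsum("nmk,mi->nik", dV, self.xi)
        Jt = None
        if need_theta:
            N = V.shape[0]
            Jt = np.zeros((N, ns, self.n_free))
            for pos, (_, _, a, i) in enumerate(self.coeff_entries()):
                Jt[:, i, pos] = F[:, a]
            if self.dictionary.n_eta:
                Jt[:, :, -self.dictionary.n_eta:] = np.einsum("nme,mi->nie", dE, self.xi)
        return f, Jx, Jt


class RationalModel(_ModelBase):
    """Per-state rational fields ``k_i + g_i / (1 + h_i)``."""

    def __init__(self, phi_g: FeatureDictionary, phi_h: FeatureDictionary,
                 coeff_g: CoefficientSet, coeff_h: CoefficientSet,
                 state_names, phi_k: FeatureDictionary | None = None,
                 coeff_k: CoefficientSet | None = None, eps_den: float = EPS_DEN):
        self.state_names = tuple(state_names)
        n = len(self.state_names)
        if phi_h.has_constant():
            raise InvalidArgumentError(
                "denominator dictionary must not contain a constant feature "
                "(the '1 +' normalization is structural)"
            )
        for d in (phi_g, phi_h) + (() if phi_k is None else (phi_k,)):
            if d.variables != phi_g.variables:
                raise InvalidArgumentError("all rational dictionaries must share variables")
        if phi_g.variables[:n] != self.state_names:
            raise InvalidArgumentError("dictionary variables must start with the states")
        if coeff_g.shape != (phi_g.m, n) or coeff_h.shape != (phi_h.m, n):
            raise InvalidArgumentError("coefficient shapes must be (m, n_states)")
        if (phi_k is None) != (coeff_k is None):
            raise InvalidArgumentError("phi_k and coeff_k must be given together")
        self.phi_g, self.phi_h, self.phi_k = phi_g, phi_h, phi_k
        self.coeff_g, self.coeff_h, self.coeff_k = coeff_g, coeff_h, coeff_k
        self.variables = phi_g.variables
        self.eps_den = float(eps_den)
        self.form = "rational" if phi_k is None else "composite_rational"

    def _blocks(self):
        blocks = []
        if self.coeff_k is not None:
            blocks.append(("k", self.coeff_k))
        blocks += [("g", self.coeff_g), ("h", self.coeff_h)]
        return blocks

    def _dictionaries(self):
        ds = [] if self.phi_k is None else [self.phi_k]
        return ds + [self.phi_g, self.phi_h]

    def copy(self) -> "RationalModel":
        return RationalModel(
            self.phi_g.copy(), self.phi_h.copy(), self.coeff_g.copy(), self.coeff_h.copy(),
            self.state_names,
            None if self.phi_k is None else self.phi_k.copy(),
            None if self.coeff_k is None else self.coeff_k.copy(),
            self.eps_den,
        )

    def _denominator(self, Fh: np.ndarray) -> np.ndarray:
        D = 1.0 + Fh @ self.coeff_h.xi
        bad = np.abs(D) < self.eps_den
        if bad.any():
            idx = np.unique(np.nonzero(bad)[0])
            raise DenominatorDegeneracyError(
                f"rational denominator within {self.eps_den:g} of zero at "
                f"{idx.size} snapshot(s), e.g. rows {idx[:5].tolist()}",
                snapshot_indices=idx,
            )
        return D

    def value(self, V: np.ndarray) -> np.ndarray:
        G = self.phi_g.evaluate(V) @ self.coeff_g.xi
        D = self._denominator(self.phi_h.evaluate(V))
        out = G / D
        if self.phi_k is not None:
            out = out + self.phi_k.evaluate(V) @ self.coeff_k.xi
        return out

    def value_and_jacobians(self, V: np.ndarray, need_theta: bool = True):
        ns = self.n_states
        N = V.shape[0]
        Fg, dVg, dEg = self.phi_g.evaluate_with_grad(V, n_grad_vars=ns)
        Fh, dVh, dEh = self.phi_h.evaluate_with_grad(V, n_grad_vars=ns)
        G = Fg @ self.coeff_g.xi
        D = self._denominator(Fh)
        dG = np.einsum("nmk,mi->nik", dVg, self.coeff_g.xi)
        dD = np.einsum("nmk,mi->nik", dVh, self.coeff_h.xi)
        f = G / D
        Jx = (dG * D[:, :, None] - G[:, :, None] * dD) / (D ** 2)[:, :, None]
        Fk = dEk = None
        if self.phi_k is not None:
            Fk, dVk, dEk = self.phi_k.evaluate_with_grad(V, n_grad_vars=ns)
            f = f + Fk @ self.coeff_k.xi
            Jx = Jx + np.einsum("nmk,mi->nik", dVk, self.coeff_k.xi)
        Jt = None
        if need_theta:
            Jt = np.zeros((N, ns, self.n_free))
            for pos, (name, _, a, i) in enumerate(self.coeff_entries()):
                if name == "k":
                    Jt[:, i, pos] = Fk[:, a]
                elif name == "g":
                    Jt[:, i, pos] = Fg[:, a] / D[:, i]
                else:  # h
                    Jt[:, i, pos] = -G[:, i] * Fh[:, a] / D[:, i] ** 2
            pos = sum(1 for _ in self.coeff_entries())
            for d, dE, kind in self._eta_blocks(dEg, dEh, dEk):
                if d.n_eta:
                    if kind == "k":
                        contrib = np.einsum("nme,mi->nie", dE, self.coeff_k.xi)
                    elif kind == "g":
                        contrib = np.einsum("nme,mi->nie", dE, self.coeff_g.xi) / D[:, :, None]
                    else:
                        contrib = -(G / D ** 2)[:, :, None] * np.einsum(
                            "nme,mi->nie", dE, self.coeff_h.xi
                        )
                    Jt[:, :, pos:pos + d.n_eta] = contrib
                    pos += d.n_eta
        return f, Jx, Jt

    def _eta_blocks(self, dEg, dEh, dEk):
        blocks = []
        if self.phi_k is not None:
            blocks.append((self.phi_k, dEk, "k"))
        blocks += [(self.phi_g, dEg, "g"), (self.phi_h, dEh, "h")]
        return blocks


@dataclass
class AffineTransform:
    """Per-state normalization ``x~ = (x - shift) / scale``."""

    scale: np.ndarray
    shift: np.ndarray

    def __post_init__(self):
        self.scale = np.asarray(self.scale, dtype=float).reshape(-1)
        self.shift = np.asarray(self.shift, dtype=float).reshape(-1)
        if self.scale.size != self.shift.size:
            raise InvalidArgumentError("scale and shift must have equal length")
        if np.any(self.scale == 0.0):
            raise InvalidArgumentError("scales must be nonzero")

    @classmethod
    def identity(cls, n: int) -> "AffineTransform":
        return cls(np.ones(n), np.zeros(n))

    @property
    def inverse(self) -> "AffineTransform":
        # x = scale*x~ + shift  <=>  x = (x~ - (-shift/scale)) / (1/scale)
        return AffineTransform(1.0 / self.scale, -self.shift / self.scale)

    def apply(self, states: np.ndarray) -> np.ndarray:
        return (states - self.shift) / self.scale

    def invert(self, states: np.ndarray) -> np.ndarray:
        return states * self.scale + self.shift

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(
            np.all(np.abs(self.scale - 1.0) <= tol) and np.all(np.abs(self.shift) <= tol)
        )


def evaluate_field(model, snapshot_batch) -> np.ndarray:
    """Evaluate the right-hand side on a batch of snapshots (rows)."""
    V = np.atleast_2d(np.asarray(snapshot_batch, dtype=float))
    if V.shape[1] != len(model.variables):
        raise InvalidArgumentError(
            f"snapshot batch has {V.shape[1]} columns, model has "
            f"{len(model.variables)} variables"
        )
    if not np.all(np.isfinite(V)):
        raise InvalidDataError("snapshot batch contains non-finite entries")
    return model.value(V)


def simulate(model, x0, times, params=None, method: str = "DOP853",
             rtol: float = 1e-9, atol: float = 1e-12,
             trajectory_id: str = "sim") -> TrajectoryData:
    """Integrate the model with an adaptive solver and sample on ``times``."""
    from scipy.integrate import solve_ivp

    times = np.asarray(times, dtype=float).reshape(-1)
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    params = None if params is None else np.asarray(params, dtype=float).reshape(-1)
    n = model.n_states
    extra = np.zeros(0) if params is None else params

    def rhs(t, x):
        V = np.concatenate([x, extra])[None, :]
        return model.value(V)[0]

    try:
        sol = solve_ivp(rhs, (times[0], times[-1]), x0, t_eval=times,
                        method=method, rtol=rtol, atol=atol)
    except (DenominatorDegeneracyError, FloatingPointError) as exc:
        raise SimulationError(f"integration aborted: {exc}") from exc
    if not sol.success or sol.y.shape[1] != times.size:
        last = sol.t[-1] if sol.t.size else times[0]
        raise SimulationError(
            f"integration failed at t={last:g}: {sol.message}", last_valid_time=last
        )
    param_names = model.variables[n:] if params is not None else ()
    return TrajectoryData(times, sol.y.T, model.state_names,
                          params=params, param_names=param_names,
                          trajectory_id=trajectory_id)


# ---------------------------------------------------------------------------
# symbolic export / parse-back
# ---------------------------------------------------------------------------

def _fmt(c: float, precision: int | None) -> str:
    return repr(float(c)) if precision is None else f"{c:.{precision}g}"


def _poly_string(dictionary: FeatureDictionary, coeffs: CoefficientSet, eq: int,
                 precision: int | None) -> str:
    labels = dictionary.labels()
    terms = [
        f"{_fmt(coeffs.xi[a, eq], precision)}*{labels[a]}"
        for a in range(dictionary.m)
        if coeffs.support[a, eq]
    ]
    return " + ".join(terms) if terms else "0"


def symbolic_export(model, precision: int | None = None) -> str:
    """Render one equation line per state.

    At the default full precision (``repr`` of each float) the text
    round-trips exactly through :func:`parse_equations`.
    """
    lines = []
    for i, name in enumerate(model.state_names):
        if isinstance(model, LinearDictionaryModel):
            rhs = _poly_string(model.dictionary, model.coefficients, i, precision)
        else:
            g = _poly_string(model.phi_g, model.coeff_g, i, precision)
            h = _poly_string(model.phi_h, model.coeff_h, i, precision)
            rhs = f"({g}) / (1 + {h})"
            if model.phi_k is not None:
                k = _poly_string(model.phi_k, model.coeff_k, i, precision)
                rhs = f"{k} + {rhs}"
        lines.append(f"d{name}/dt = {rhs}")
    return "\n".join(lines)


def parse_equations(text: str, dictionary: FeatureDictionary,
                    state_names) -> CoefficientSet:
    """Invert :func:`symbolic_export` for linear-in-dictionary models."""
    state_names = tuple(state_names)
    label_index = {lab: a for a, lab in enumerate(dictionary.labels())}
    xi = np.zeros((dictionary.m, len(state_names)))
    support = np.zeros_like(xi, dtype=bool)
    for line in text.strip().splitlines():
        lhs, _, rhs = line.partition("=")
        name = lhs.strip().removeprefix("d").removesuffix("/dt").strip()
        i = state_names.index(name)
        if rhs.strip() == "0":
            continue
        for term in rhs.split(" + "):
            cstr, _, label = term.strip().partition("*")
            a = label_index[label]
            xi[a, i] = float(cstr)
            support[a, i] = True
    return CoefficientSet(xi, support)


# ---------------------------------------------------------------------------
# affine coordinate changes of polynomial models
# ---------------------------------------------------------------------------

def _sym_vars(names):
    return sp.symbols(list(names))


def _poly_expr(dictionary: FeatureDictionary, coeffs: CoefficientSet, eq: int, syms):
    expr = sp.Integer(0)
    for a, f in enumerate(dictionary.features):
        if not coeffs.support[a, eq]:
            continue
        mono = sp.Integer(1)
        for s, e in zip(syms, f.exponents):
            if e:
                mono *= s ** e
        expr += sp.Float(coeffs.xi[a, eq], 17) * mono
    return expr


def _extract_poly(expr, syms, out_dict: FeatureDictionary, chop: float = 1e-12):
    """Collect monomial coefficients of ``expr`` onto ``out_dict`` features."""
    exp_index = {f.exponents: a for a, f in enumerate(out_dict.features)}
    poly = sp.Poly(sp.expand(expr), *syms)
    xi = np.zeros(out_dict.m)
    for monom, coeff in poly.terms():
        key = tuple(int(e) for e in monom)
        if key not in exp_index:
            raise UnsupportedTransformError(
                f"monomial exponents {key} exceed the output dictionary degree"
            )
        xi[exp_index[key]] = float(coeff)
    scale = max(1.0, float(np.max(np.abs(xi))) if xi.size else 1.0)
    xi[np.abs(xi) < chop * scale] = 0.0
    return xi


def _substitution(variables, state_names, T: AffineTransform, direction: str, syms):
    """Return (subs map, per-state rhs scale factor) for the requested direction."""
    n = len(state_names)
    subs = {}
    if direction == "forward":
        # new coords x~ = (x - shift)/scale; substitute x = scale*x~ + shift
        for j in range(n):
            subs[syms[j]] = sp.Float(T.scale[j], 17) * syms[j] + sp.Float(T.shift[j], 17)
        rhs_scale = 1.0 / T.scale
    elif direction == "inverse":
        for j in range(n):
            subs[syms[j]] = (syms[j] - sp.Float(T.shift[j], 17)) / sp.Float(T.scale[j], 17)
        rhs_scale = T.scale.copy()
    else:
        raise InvalidArgumentError("direction must be 'forward' or 'inverse'")
    return subs, rhs_scale


def transform_model(model, T: AffineTransform, direction: str = "forward"):
    """Exact affine change of state coordinates for polynomial models.

    ``forward`` maps a model over ``x`` to the model over
    ``x~ = (x - shift)/scale`` via substitution and the chain rule
    ``d x~/dt = (1/scale) dx/dt``; ``inverse`` undoes it.  Non-state
    variables (inputs, parameters) are untouched.
    """
    if T.scale.size != model.n_states:
        raise InvalidArgumentError("transform length must equal the state count")
    syms = _sym_vars(model.variables)
    subs, rhs_scale = _substitution(model.variables, model.state_names, T, direction, syms)

    if isinstance(model, LinearDictionaryModel):
        if not model.dictionary.is_polynomial():
            raise UnsupportedTransformError(
                "affine substitution is only closed over polynomial dictionaries"
            )
        out_dict = build_polynomial_dictionary(
            model.variables, model.dictionary.max_degree(), include_bias=True
        )
        xi = np.zeros((out_dict.m, model.n_states))
        for i in range(model.n_states):
            expr = _poly_expr(model.dictionary, model.coefficients, i, syms)
            expr = sp.Float(rhs_scale[i], 17) * expr.xreplace(subs)
            xi[:, i] = _extract_poly(expr, syms, out_dict)
        return LinearDictionaryModel(out_dict, CoefficientSet(xi), model.state_names,
                                     model.form)

    if isinstance(model, RationalModel):
        for d in model._dictionaries():
            if not d.is_polynomial():
                raise UnsupportedTransformError(
                    "affine substitution is only closed over polynomial dictionaries"
                )
        out_g = build_polynomial_dictionary(model.variables, model.phi_g.max_degree())
        out_h = build_polynomial_dictionary(model.variables, model.phi_h.max_degree(),
                                            include_bias=False)
        out_h_with1 = build_polynomial_dictionary(model.variables, model.phi_h.max_degree())
        n = model.n_states
        xg = np.zeros((out_g.m, n))
        xh = np.zeros((out_h.m, n))
        xk = None
        out_k = None
        if model.phi_k is not None:
            out_k = build_polynomial_dictionary(model.variables, model.phi_k.max_degree())
            xk = np.zeros((out_k.m, n))
        h_index = {f.exponents: a for a, f in enumerate(out_h.features)}
        for i in range(n):
            g_expr = _poly_expr(model.phi_g, model.coeff_g, i, syms).xreplace(subs)
            d_expr = (sp.Integer(1)
                      + _poly_expr(model.phi_h, model.coeff_h, i, syms).xreplace(subs))
            den = _extract_poly(d_expr, syms, out_h_with1)
            const_idx = next(
                a for a, f in enumerate(out_h_with1.features) if f.degree == 0
            )
            c0 = den[const_idx]
            if abs(c0) < EPS_DEN:
                raise UnsupportedTransformError(
                    "transformed denominator has (near-)zero constant term; the "
                    "'1 +' normalization cannot be restored"
                )
            xg[:, i] = _extract_poly(
                sp.Float(rhs_scale[i] / c0, 17) * g_expr, syms, out_g
            )
            for a, f in enumerate(out_h_with1.features):
                if f.degree == 0:
                    continue
                xh[h_index[f.exponents], i] = den[a] / c0
            if model.phi_k is not None:
                k_expr = _poly_expr(model.phi_k, model.coeff_k, i, syms).xreplace(subs)
                xk[:, i] = _extract_poly(sp.Float(rhs_scale[i], 17) * k_expr, syms, out_k)
        return RationalModel(
            out_g, out_h, CoefficientSet(xg), CoefficientSet(xh), model.state_names,
            phi_k=out_k, coeff_k=None if xk is None else CoefficientSet(xk),
            eps_den=model.eps_den,
        )

    raise UnsupportedTransformError(f"cannot transform model of type {type(model).__name__}")
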