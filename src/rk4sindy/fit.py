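"""Derivative-free sparse regression: the RK4 residual objective and the
sequential-thresholding solvers.

The objective compares each observed snapshot with a single RK4 step taken
from its neighbour,

    L(theta) = mean( (X - X_F(f_theta))^2 )  [+ w_b-weighted backward term]
               + alpha * ||Xi||_1 ,

where ``f_theta`` is a dictionary model (linear or rational) and the mean
runs over every sample and state.  Because one RK4 step composes the model
with itself four times, the prediction is nonlinear in the coefficients even
for linear-in-dictionary models; gradients and Jacobians are propagated
through the four stages in closed form (forward mode), so no derivative of
the *data* is ever formed.

Two model-selection strategies mirror the sequential-thresholding family:

* :func:`fit_fixed_threshold` -- optimize, zero every coefficient with
  magnitude below a fixed cut-off ``lambda``, re-optimize the survivors
  (warm-started) and repeat until all surviving coefficients clear the
  cut-off.
* :func:`fit_iterative_threshold` -- repeatedly remove the single smallest
  nonzero coefficient, re-optimize, and track the (support size, fidelity)
  Pareto front; the returned model sits at the front's elbow (or at the
  last point satisfying ``fidelity_tol``).

The default optimizer is a damped Gauss-Newton solve of the nonlinear
least-squares problem (``scipy.optimize.least_squares`` with the analytic
Jacobian), followed by a proximal Gauss-Newton loop when ``alpha > 0``
(linearized LASSO subproblems solved exactly by FISTA).  A full-batch
fixed-learning-rate gradient descent with step-halving acceptance is
available as ``method="gd"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import TrajectoryCollection, as_collection
from .dictionary import FeatureDictionary, build_polynomial_dictionary
from .exceptions import (
    AllPrunedError,
    DenominatorDegeneracyError,
    InvalidArgumentError,
    NumericalOverflowError,
    OptimizationDivergedError,
)
from .models import CoefficientSet, LinearDictionaryModel, RationalModel

__all__ = [
    "OptimizerConfig",
    "FitConfig",
    "FitResult",
    "RationalSpec",
    "residual_loss",
    "optimize_coefficients",
    "fit_fixed_threshold",
    "fit_iterative_threshold",
    "assess_polynomial_degree",
]


@dataclass
class OptimizerConfig:
    """Inner-solver settings.

    ``method``: ``"auto"`` (Gauss-Newton, plus a proximal Gauss-Newton
    loop when the l1 weight is active), ``"gauss_newton"``, or ``"gd"``
    (full-batch descent at fixed ``learning_rate`` with step-halving
    acceptance, the scheme the sequential-thresholding algorithms were
    originally stated with).
    """

    method: str = "auto"
    steps: int = 50_000
    learning_rate: float = 1e-2
    convergence_tol: float = 1e-10
    seed: int | None = None
    max_nfev: int = 300
    eta_restarts: int = 5   # seeded redraws of trainable feature parameters


@dataclass
class FitConfig:
    alpha: float = 0.0              # l1 weight on the coefficients
    cutoff: float = 5e-2            # fixed threshold lambda (Algorithm 1)
    fidelity_tol: float | None = None   # stopping tolerance (Algorithm 2)
    elbow_kappa: float = 2.0        # Pareto elbow: fidelity <= kappa * dense fidelity
    prune: str = "smallest"         # iterative pruning rule: smallest | best_refit
    beam_width: int = 1             # supports kept per size under best_refit
    exact_size_cap: int = 0         # exhaustively refit front points up to this size
    use_backward: bool = False
    w_b: float = 0.5                # convex weight of the backward residual
    debias_final: bool = True       # refit the selected support with alpha=0
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self):
        if self.alpha < 0:
            raise InvalidArgumentError("alpha must be >= 0")
        if self.cutoff is not None and self.cutoff <= 0:
            raise InvalidArgumentError("cutoff lambda must be > 0")
        if not (0.0 <= self.w_b <= 1.0):
            raise InvalidArgumentError("w_b must lie in [0, 1]")
        if self.prune not in ("smallest", "best_refit"):
            raise InvalidArgumentError("prune must be 'smallest' or 'best_refit'")
        if self.beam_width < 1:
            raise InvalidArgumentError("beam_width must be >= 1")


@dataclass
class RationalSpec:
    """Dictionaries for a rational fit ``k + g/(1+h)`` (``phi_k`` optional)."""

    phi_g: FeatureDictionary
    phi_h: FeatureDictionary
    phi_k: FeatureDictionary | None = None

    def make_model(self, state_names) -> RationalModel:
        n = len(tuple(state_names))
        return RationalModel(
            self.phi_g.copy(), self.phi_h.copy(),
            CoefficientSet.dense(self.phi_g.m, n), CoefficientSet.dense(self.phi_h.m, n),
            state_names,
            phi_k=None if self.phi_k is None else self.phi_k.copy(),
            coeff_k=None if self.phi_k is None else CoefficientSet.dense(self.phi_k.m, n),
        )


@dataclass
class FitResult:
    model: object
    loss_history: list
    pareto: list                    # [(nonzero_count, fidelity), ...]
    threshold_rounds: list          # support masks per round, {block: mask}
    constant_states: list
    fidelity: float
    config: FitConfig
    seed: int | None = None
    pareto_models: list | None = None
    selected_index: int | None = None


# ---------------------------------------------------------------------------
# RK4 predictions with parameter Jacobians (forward mode through the stages)
# ---------------------------------------------------------------------------

def _stage(model, Z, name, need_jac):
    f, Jx, Jt = model.value_and_jacobians(Z, need_theta=need_jac)
    if not np.all(np.isfinite(f)):
        raise NumericalOverflowError(
            f"vector field produced non-finite values at RK4 stage {name}"
        )
    return f, Jx, Jt


def _rk4_pred_jac(model, V, h, need_jac):
    """One RK4 step per row with d(prediction)/d(theta).

    ``V`` holds start snapshots (states + frozen inputs/params), ``h`` the
    signed per-row steps.  Returns ``(pred, Jpred)`` with shapes
    ``(N, n)`` and ``(N, n, P)`` (``Jpred`` is None when not requested).
    """
    ns = model.n_states
    V = np.asarray(V, dtype=float)
    h1 = np.asarray(h, dtype=float)[:, None]
    h2 = h1[:, :, None]
    X0 = V[:, :ns]

    def with_states(X):
        Z = V.copy()
        Z[:, :ns] = X
        return Z

    f1, _, d1 = _stage(model, V, "k1", need_jac)
    Z = with_states(X0 + 0.5 * h1 * f1)
    f2, Jx2, t2 = _stage(model, Z, "k2", need_jac)
    if need_jac:
        d2 = t2 + np.einsum("nij,njp->nip", Jx2, 0.5 * h2 * d1)
    Z = with_states(X0 + 0.5 * h1 * f2)
    f3, Jx3, t3 = _stage(model, Z, "k3", need_jac)
    if need_jac:
        d3 = t3 + np.einsum("nij,njp->nip", Jx3, 0.5 * h2 * d2)
    Z = with_states(X0 + h1 * f3)
    f4, Jx4, t4 = _stage(model, Z, "k4", need_jac)
    if need_jac:
        d4 = t4 + np.einsum("nij,njp->nip", Jx4, h2 * d3)
    pred = X0 + (h1 / 6.0) * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
    Jpred = None
    if need_jac:
        Jpred = (h2 / 6.0) * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
    return pred, Jpred


def _residual_blocks(model, collection: TrajectoryCollection, config: FitConfig,
                     need_jac: bool):
    """Stacked scaled residual vector (and Jacobian) over the collection.

    The scaling makes ``sum(r^2)`` equal the mean-squared residual
    (convex forward/backward combination when the backward term is on).
    """
    n = model.n_states
    total = sum(tr.n_steps for tr in collection) * n
    w_f = (1.0 - config.w_b) if config.use_backward else 1.0
    parts, jparts = [], []
    for direction, w in (("f", w_f), ("b", config.w_b if config.use_backward else 0.0)):
        if w == 0.0 and direction == "b":
            continue
        for tr in collection:
            V = tr.snapshot_matrix()
            if direction == "f":
                start, target, h = V[:-1], tr.states[1:], tr.steps
            else:
                start, target, h = V[1:], tr.states[:-1], -tr.steps
            pred, Jpred = _rk4_pred_jac(model, start, h, need_jac)
            scale = np.sqrt(w / total)
            parts.append(((pred - target) * scale).ravel())
            if need_jac:
                jparts.append((Jpred * scale).reshape(-1, Jpred.shape[-1]))
    r = np.concatenate(parts)
    J = np.vstack(jparts) if need_jac else None
    return r, J


def fidelity_loss(model, data, config: FitConfig | None = None) -> float:
    """Mean-squared RK4 residual (no regularization term)."""
    config = config or FitConfig()
    r, _ = _residual_blocks(model, as_collection(data), config, need_jac=False)
    return float(r @ r)


def residual_loss(model, data, config: FitConfig | None = None) -> float:
    """Full objective: mean-squared residual plus ``alpha * ||Xi||_1``."""
    config = config or FitConfig()
    smooth = fidelity_loss(model, data, config)
    if config.alpha:
        theta = model.get_theta()
        smooth += config.alpha * float(np.abs(theta[model.theta_coeff_mask()]).sum())
    return smooth


# ---------------------------------------------------------------------------
# inner optimizers
# ---------------------------------------------------------------------------

def _apply_frozen(model, frozen):
    if frozen is None:
        return
    blocks = dict(model._blocks())
    if isinstance(frozen, dict):
        items = frozen.items()
    else:
        items = [(next(iter(blocks)), frozen)]
    for name, mask in items:
        cs = blocks[name]
        mask = np.asarray(mask, dtype=bool)
        cs.support &= ~mask
        cs.xi[mask] = 0.0


def optimize_coefficients(model, data, config: FitConfig | None = None,
                          frozen_support=None):
    """Optimize the free coefficients (and eta) of ``model`` on ``data``.

    Returns ``(fitted_model, loss_history)``.  The input model is left
    untouched; entries marked in ``frozen_support`` stay zero.  The
    returned loss never exceeds the warm-start loss (the warm start is
    kept if the solver fails to improve on it).
    """
    config = config or FitConfig()
    collection = as_collection(data)
    work = model.copy()
    _apply_frozen(work, frozen_support)
    if work.n_free == 0:
        return work, [residual_loss(work, collection, config)]
    theta0 = work.get_theta()
    loss0 = residual_loss(work, collection, config)
    method = config.optimizer.method

    if method in ("auto", "gauss_newton"):
        history = _gauss_newton(work, collection, config, theta0)
        if config.alpha > 0.0:
            history += _prox_gauss_newton(work, collection, config)
        # the loss is non-convex in trainable feature parameters (eta);
        # seeded restarts over eta guard against spurious basins
        n_eta = sum(d.n_eta for d in work._dictionaries())
        if n_eta and config.optimizer.eta_restarts > 1:
            rng = np.random.default_rng(config.optimizer.seed)
            best_loss = residual_loss(work, collection, config)
            cmask = work.theta_coeff_mask()
            for _ in range(config.optimizer.eta_restarts - 1):
                trial = work.copy()
                theta = theta0.copy()
                theta[~cmask] = rng.uniform(-3.0, 3.0, n_eta)
                try:
                    trial_hist = _gauss_newton(trial, collection, config, theta)
                    if config.alpha > 0.0:
                        trial_hist += _prox_gauss_newton(trial, collection, config)
                    trial_loss = residual_loss(trial, collection, config)
                except (OptimizationDivergedError, DenominatorDegeneracyError,
                        NumericalOverflowError):
                    continue
                if np.isfinite(trial_loss) and trial_loss < best_loss:
                    work.set_theta(trial.get_theta())
                    best_loss, history = trial_loss, trial_hist
    elif method == "gd":
        history = _gradient_descent(work, collection, config, theta0)
    else:
        raise InvalidArgumentError(f"unknown optimizer method {method!r}")

    final = residual_loss(work, collection, config)
    if not np.isfinite(final):
        raise OptimizationDivergedError(
            "optimization diverged (non-finite loss); try a smaller learning rate"
        )
    if final > loss0:
        work.set_theta(theta0)
        history.append(loss0)
    return work, [loss0] + history


def _objective_parts(model, collection, config, theta):
    model.set_theta(theta)
    r, J = _residual_blocks(model, collection, config, need_jac=True)
    return r, J


def _gauss_newton(model, collection, config, theta0):
    # a trial step that lands on a degenerate rational denominator (or
    # overflows) is scored prohibitively so the trust region backs off,
    # rather than aborting the whole fit
    n_resid = (sum(tr.n_steps for tr in collection) * model.n_states
               * (2 if config.use_backward else 1))

    def fun(theta):
        model.set_theta(theta)
        try:
            r, _ = _residual_blocks(model, collection, config, need_jac=False)
        except (DenominatorDegeneracyError, NumericalOverflowError):
            return np.full(n_resid, 1e30)
        return r

    def jac(theta):
        try:
            _, J = _objective_parts(model, collection, config, theta)
        except (DenominatorDegeneracyError, NumericalOverflowError):
            return np.zeros((n_resid, theta.size))
        return J

    r0 = fun(theta0)
    if not np.all(np.isfinite(r0)) or r0[0] >= 1e30:
        raise OptimizationDivergedError(
            "Gauss-Newton start point is infeasible (degenerate denominator)"
        )
    sol = least_squares(
        fun, theta0, jac=jac, method="trf", tr_solver="exact",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=config.optimizer.max_nfev,
    )
    model.set_theta(sol.x)
    return [2.0 * float(sol.cost)]


def _soft(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _fista_lasso(J, r0, z0, alpha, cmask, max_iter=3000, tol=1e-13):
    """min_z ||r0 + J z||^2 + alpha ||z[cmask]||_1 by accelerated proximal
    gradient at fixed J (the Gauss-Newton linearization)."""
    lip = 2.0 * np.linalg.norm(J, 2) ** 2
    step = 1.0 / max(lip, 1e-300)
    z = z0.copy()
    y = z0.copy()
    t = 1.0
    scale = max(np.max(np.abs(z0)), 1.0)
    for _ in range(max_iter):
        grad = 2.0 * (J.T @ (r0 + J @ y))
        z_new = y - step * grad
        z_new[cmask] = _soft(z_new[cmask], step * alpha)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = z_new + ((t - 1.0) / t_new) * (z_new - z)
        delta = np.max(np.abs(z_new - z))
        z, t = z_new, t_new
        if delta < tol * scale:
            break
    return z


def _prox_gauss_newton(model, collection, config, max_outer: int = 30):
    """Proximal Gauss-Newton for the l1-regularized residual.

    Each outer round linearizes the RK4 residual and solves the resulting
    LASSO subproblem exactly (FISTA at fixed Jacobian), then line-searches
    along the step.  The l1 term is what collapses the continuum of
    equivalent over-parameterized representations (notably the common
    polynomial factors of rational models) toward the sparse one.
    """
    alpha = config.alpha
    cmask = model.theta_coeff_mask()
    theta = model.get_theta()
    r, J = _objective_parts(model, collection, config, theta)
    obj = float(r @ r) + alpha * np.abs(theta[cmask]).sum()
    history = []
    for _ in range(max_outer):
        r0 = r - J @ theta
        z = _fista_lasso(J, r0, theta, alpha, cmask)
        accepted = False
        t = 1.0
        for _ in range(30):
            cand = theta + t * (z - theta)
            try:
                r_c, J_c = _objective_parts(model, collection, config, cand)
            except (DenominatorDegeneracyError, NumericalOverflowError):
                t *= 0.5
                continue
            cand_obj = float(r_c @ r_c) + alpha * np.abs(cand[cmask]).sum()
            if np.isfinite(cand_obj) and cand_obj <= obj:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        rel = (obj - cand_obj) / max(obj, 1e-300)
        theta, r, J, obj = cand, r_c, J_c, cand_obj
        history.append(obj)
        if rel < 1e-14:
            break
    model.set_theta(theta)
    return history


def _gradient_descent(model, collection, config, theta0):
    """Full-batch descent at fixed learning rate with step-halving acceptance."""
    opt = config.optimizer
    alpha = config.alpha
    cmask = model.theta_coeff_mask()
    theta = theta0.copy()
    r, J = _objective_parts(model, collection, config, theta)
    loss = float(r @ r) + alpha * np.abs(theta[cmask]).sum()
    history = [loss]
    window = []
    for it in range(opt.steps):
        grad = 2.0 * J.T @ r
        if alpha:
            grad = grad + alpha * np.sign(theta) * cmask
        lr = opt.learning_rate
        accepted = False
        for _ in range(40):
            cand = theta - lr * grad
            try:
                r_c, J_c = _objective_parts(model, collection, config, cand)
            except (DenominatorDegeneracyError, NumericalOverflowError):
                lr *= 0.5
                continue
            cand_loss = float(r_c @ r_c) + alpha * np.abs(cand[cmask]).sum()
            if np.isfinite(cand_loss) and cand_loss <= loss:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            break
        theta, r, J, loss = cand, r_c, J_c, cand_loss
        history.append(loss)
        window.append(loss)
        if len(window) > 100:
            window.pop(0)
            if abs(window[0] - loss) / max(window[0], 1e-300) < opt.convergence_tol:
                break
    if not np.isfinite(loss):
        raise OptimizationDivergedError(
            "gradient descent diverged; try a smaller learning rate"
        )
    model.set_theta(theta)
    return history


def _debias(model, collection, config):
    """Relaxed refit: once the support is selected, re-optimize its
    coefficients with the l1 weight off so the reported values carry no
    shrinkage bias.  The regularized objective still governs the selection
    path; this only polishes the final model."""
    if not (config.debias_final and config.alpha > 0.0 and model.n_free > 0):
        return model
    plain = replace(config, alpha=0.0)
    model, _ = optimize_coefficients(model, collection, plain)
    return model


# ---------------------------------------------------------------------------
# Algorithm 1: fixed cut-off thresholding
# ---------------------------------------------------------------------------

def _support_snapshot(model):
    return {name: cs.support.copy() for name, cs in model._blocks()}


def _flag_constant_states(model, collection):
    """States with an empty equation: constant data is flagged, otherwise the
    pruning was too aggressive."""
    empty = np.ones(model.n_states, dtype=bool)
    for _, cs in model._blocks():
        empty &= cs.column_empty()
    if not empty.any():
        return []
    pooled = collection.pooled_states()
    spread = pooled.max(axis=0) - pooled.min(axis=0)
    scale = np.maximum(np.abs(pooled).max(axis=0), 1.0)
    is_const = spread <= 1e-10 * scale
    names = list(collection.state_names)
    flagged = [names[i] for i in range(model.n_states) if empty[i] and is_const[i]]
    if empty.all() and not is_const.all():
        raise AllPrunedError(
            "thresholding removed every coefficient of every equation although the "
            "data is not constant; try a smaller cut-off lambda"
        )
    return flagged


def fit_fixed_threshold(data, dictionary: FeatureDictionary,
                        config: FitConfig | None = None) -> FitResult:
    """Algorithm 1: alternate optimization with a fixed cut-off ``lambda``.

    Coefficients with magnitude below ``config.cutoff`` are zeroed and
    frozen after each optimization; survivors are re-optimized from their
    current values until every surviving coefficient clears the cut-off.
    """
    config = config or FitConfig()
    collection = as_collection(data)
    if dictionary.variables != collection.variable_names:
        raise InvalidArgumentError(
            "dictionary variables must match the trajectory variables "
            f"({dictionary.variables} vs {collection.variable_names})"
        )
    model = LinearDictionaryModel(
        dictionary.copy(),
        CoefficientSet.dense(dictionary.m, collection.n_states),
        collection.state_names,
    )
    return _threshold_loop(model, collection, config)


def _threshold_loop(model, collection, config) -> FitResult:
    lam = config.cutoff
    histories, rounds, pareto = [], [], []
    for _ in range(100):
        model, hist = optimize_coefficients(model, collection, config)
        histories.append(hist)
        rounds.append(_support_snapshot(model))
        fid = fidelity_loss(model, collection, config)
        pareto.append((model.total_nnz(), fid))
        removed = 0
        for _, cs in model._blocks():
            small = cs.support & (np.abs(cs.xi) < lam)
            removed += int(small.sum())
            cs.xi[small] = 0.0
            cs.support[small] = False
        if removed == 0:
            break
        if model.total_nnz() == 0:
            rounds.append(_support_snapshot(model))
            pareto.append((0, fidelity_loss(model, collection, config)))
            break
    model = _debias(model, collection, config)
    constant = _flag_constant_states(model, collection)
    return FitResult(
        model=model, loss_history=histories, pareto=pareto,
        threshold_rounds=rounds, constant_states=constant,
        fidelity=fidelity_loss(model, collection, config),
        config=config, seed=config.optimizer.seed,
    )


# ---------------------------------------------------------------------------
# Algorithm 2: iterative smallest-coefficient thresholding
# ---------------------------------------------------------------------------

def _smallest_entry_index(model) -> int:
    """Packed index of the smallest-magnitude nonzero coefficient.

    Ties resolve to the first entry in packing order, i.e. the lowest
    (block, feature index, equation index).
    """
    best, best_pos = np.inf, -1
    for pos, (_, cs, a, i) in enumerate(model.coeff_entries()):
        v = abs(cs.xi[a, i])
        if v < best:
            best, best_pos = v, pos
    return best_pos


def _support_key(model):
    return tuple((name, a, i) for name, _, a, i in model.coeff_entries())


def _beam_children(beam, collection, config):
    """Backward-elimination step: expand every single-entry removal of every
    beam member, refit each (warm-started Gauss-Newton), keep the best
    ``beam_width`` distinct supports ordered by regularized objective.

    This is the classical backward stepwise selection the iterative
    thresholding is a shortcut for; the beam keeps near-tied supports alive,
    which matters when a weakly identifiable true term sits within the noise
    floor of a spurious alternative at intermediate support sizes.  Fully
    deterministic (ties resolve on the support signature).
    """
    score_cfg = replace(config, optimizer=replace(config.optimizer, max_nfev=80))

    def refit_obj(trial, theta0):
        try:
            if trial.n_free:
                _gauss_newton(trial, collection, score_cfg, theta0)
            return residual_loss(trial, collection, config)
        except (DenominatorDegeneracyError, NumericalOverflowError,
                OptimizationDivergedError):
            return np.inf

    children = {}
    for parent in beam:
        n_par = sum(1 for _ in parent.coeff_entries())
        for pos in range(n_par):
            trial = parent.copy()
            trial.prune_entry(pos)
            key = _support_key(trial)
            if key in children:
                continue
            # score from the warm start AND a cold zero start: a child whose
            # surviving term sat near zero in the parent cannot escape the
            # parent's basin in one warm refit
            obj = refit_obj(trial, trial.get_theta())
            cold = trial.copy()
            cold_obj = refit_obj(cold, np.zeros(cold.n_free))
            if cold_obj < obj:
                trial, obj = cold, cold_obj
            children[key] = (obj, key, trial)
    ranked = sorted(children.values(), key=lambda t: (t[0], t[1]))
    return [c for _, _, c in ranked[:config.beam_width]]


def _restricted_copy(model, keep_positions):
    work = model.copy()
    entries = list(work.coeff_entries())
    keep = set(keep_positions)
    for pos, (_, cs, a, i) in enumerate(entries):
        if pos not in keep:
            cs.support[a, i] = False
            cs.xi[a, i] = 0.0
    return work


def _exact_small_supports(dense_model, collection, config, pareto, snapshots):
    """Replace front points at small support sizes by their exact optima.

    Competing representations (notably polynomial vs rational) run
    near-tied at large support sizes and only separate at small ones, where
    a greedy/beam path may already have discarded the winning support.  For
    every recorded size not above ``exact_size_cap`` (and combinatorially
    cheap), all supports of that size are enumerated and refitted from a
    cold start; the front point and its model are replaced when a better
    support exists.  Deterministic; exact best-subset selection at the
    sizes where model selection actually happens.
    """
    m_total = len(list(dense_model.coeff_entries()))
    import itertools as it
    import math as m

    for idx, (size, _) in enumerate(pareto):
        if size > config.exact_size_cap or m.comb(m_total, size) > 200:
            continue
        best_obj = residual_loss(snapshots[idx], collection, config)
        best_model = snapshots[idx]
        for combo in it.combinations(range(m_total), size):
            trial = _restricted_copy(dense_model, combo)
            try:
                _gauss_newton(trial, collection, config,
                              np.zeros(trial.n_free))
                obj = residual_loss(trial, collection, config)
            except (DenominatorDegeneracyError, NumericalOverflowError,
                    OptimizationDivergedError):
                continue
            if obj < best_obj:
                best_obj, best_model = obj, trial
        if best_model is not snapshots[idx]:
            snapshots[idx] = best_model
            pareto[idx] = (size, fidelity_loss(best_model, collection, config))


def fit_iterative_threshold(data, spec, config: FitConfig | None = None) -> FitResult:
    """Algorithm 2: remove the smallest nonzero coefficient per round.

    ``spec`` is a :class:`FeatureDictionary` (linear fit) or a
    :class:`RationalSpec` (joint pruning over the k/g/h coefficient
    blocks).  Each round records a Pareto point (support size, fidelity).
    With ``config.fidelity_tol`` set, pruning stops once fidelity exceeds
    the tolerance and the last admissible model is returned; otherwise the
    full front is traced down to a single coefficient and the returned
    model is the elbow: the smallest support whose fidelity is at most
    ``elbow_kappa`` times the dense-model fidelity.
    """
    config = config or FitConfig()
    collection = as_collection(data)
    if isinstance(spec, FeatureDictionary):
        if spec.variables != collection.variable_names:
            raise InvalidArgumentError("dictionary variables must match the data")
        model = LinearDictionaryModel(
            spec.copy(), CoefficientSet.dense(spec.m, collection.n_states),
            collection.state_names,
        )
    elif isinstance(spec, RationalSpec):
        model = spec.make_model(collection.state_names)
    else:
        model = spec.copy()

    histories, rounds, pareto, snapshots = [], [], [], []
    model, hist = optimize_coefficients(model, collection, config)
    histories.append(hist)
    rounds.append(_support_snapshot(model))
    fid = fidelity_loss(model, collection, config)
    pareto.append((model.total_nnz(), fid))
    snapshots.append(model.copy())

    tol = config.fidelity_tol
    beam = [model]
    while model.total_nnz() > 1:
        if config.prune == "smallest":
            pruned = model.copy()
            pruned.prune_entry(_smallest_entry_index(pruned))
        else:
            beam = _beam_children(beam, collection, config)
            pruned = beam[0]
        candidate, hist = optimize_coefficients(pruned, collection, config)
        if config.prune == "smallest":
            # warm starts can jam in a poor local minimum after a prune; a
            # cold restart from zero coefficients is cheap insurance (the
            # beam variant re-scores every child itself, so it skips this)
            cold = pruned.copy()
            cold.set_theta(np.zeros(cold.n_free))
            cold, cold_hist = optimize_coefficients(cold, collection, config)
            if residual_loss(cold, collection, config) < residual_loss(
                    candidate, collection, config):
                candidate, hist = cold, cold_hist
        fid = fidelity_loss(candidate, collection, config)
        if tol is not None and fid > tol:
            break
        model = candidate
        if config.prune == "best_refit":
            beam[0] = candidate
        histories.append(hist)
        rounds.append(_support_snapshot(model))
        pareto.append((model.total_nnz(), fid))
        snapshots.append(model.copy())

    if config.exact_size_cap > 0:
        _exact_small_supports(snapshots[0], collection, config, pareto, snapshots)

    if tol is not None:
        selected = len(snapshots) - 1
    else:
        dense_fid = pareto[0][1]
        threshold = config.elbow_kappa * dense_fid + 1e-300
        admissible = [k for k, (_, f) in enumerate(pareto) if f <= threshold]
        selected = max(admissible) if admissible else 0

    chosen = _debias(snapshots[selected], collection, config)
    constant = _flag_constant_states(chosen, collection)
    return FitResult(
        model=chosen, loss_history=histories, pareto=pareto,
        threshold_rounds=rounds, constant_states=constant,
        fidelity=pareto[selected][1], config=config,
        seed=config.optimizer.seed,
        pareto_models=snapshots, selected_index=selected,
    )


# ---------------------------------------------------------------------------
# polynomial-degree assessment
# ---------------------------------------------------------------------------

def assess_polynomial_degree(data, degrees, config: FitConfig | None = None):
    """Dense (unthresholded) fidelity as a function of dictionary degree.

    Returns ``(table, selected_degree)``.  Fidelity falls as the dictionary
    grows until every feature of the generating field is available, then
    plateaus at the data's noise/truncation floor.  The selected degree is
    the smallest one already on the plateau (the next degree improves
    fidelity by less than 10%) that itself improved on its predecessor by
    at least 10% (or is the first degree assessed); ``None`` when the curve
    never plateaus.
    """
    config = config or FitConfig()
    collection = as_collection(data)
    degrees = list(degrees)
    if not degrees:
        raise InvalidArgumentError("degrees list must be non-empty")
    rows = []
    for d in degrees:
        dictionary = build_polynomial_dictionary(collection.variable_names, d)
        model = LinearDictionaryModel(
            dictionary, CoefficientSet.dense(dictionary.m, collection.n_states),
            collection.state_names,
        )
        model, _ = optimize_coefficients(model, collection, config)
        rows.append({
            "degree": d,
            "n_features": dictionary.m,
            "fidelity": fidelity_loss(model, collection, config),
        })
    table = pd.DataFrame(rows)
    selected = None
    fid = table["fidelity"].to_numpy()
    tau = 0.9

    def on_plateau(i):
        if i + 1 >= len(degrees):
            return False  # cannot confirm a plateau at the last degree
        return fid[i] <= 0 or fid[i + 1] / fid[i] > tau

    for i in range(len(degrees)):
        if not on_plateau(i):
            continue
        improved = i == 0 or fid[i - 1] <= 0 or fid[i] / fid[i - 1] <= tau
        if i > 0 and fid[i - 1] <= 0:
            improved = False  # predecessor already at an exact-zero floor
        if improved:
            selected = degrees[i]
            break
    return table, selected
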