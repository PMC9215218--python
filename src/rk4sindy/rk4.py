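"""Classical fourth-order Runge-Kutta step and derivative-free prediction matrices.

The discovery objective never differentiates the data.  Instead, each
observed snapshot is compared against a single RK4 step taken from its
neighbour: the *forward* prediction matrix stacks
``F_RK4(f, x(t_k), h_{k+1})`` for ``k = 0 ... N-1`` and is compared to the
rows ``x(t_1) ... x(t_N)``; the *backward* matrix steps with negative ``h``
from ``x(t_{k+1})`` and is compared to ``x(t_0) ... x(t_{N-1})``.  The local
error of one step is O(h^5) for smooth fields, so on clean data the residual
at the true model sits at the truncation floor rather than at a
finite-difference floor.

Vector fields are batch callables: ``f(V) -> dX`` with ``V`` of shape
``(N, n_vars)`` (states first, then any input/parameter columns, which stay
frozen across the RK4 stages) and ``dX`` of shape ``(N, n_states)``.
"""

from __future__ import annotations

import numpy as np

from .data import TrajectoryData
from .exceptions import NumericalOverflowError

__all__ = ["rk4_step", "rk4_step_batch", "forward_predictions", "backward_predictions"]


def _eval_stage(f, Z, stage: str) -> np.ndarray:
    k = np.asarray(f(Z), dtype=float)
    if not np.all(np.isfinite(k)):
        raise NumericalOverflowError(
            f"vector field produced non-finite values at RK4 stage {stage}"
        )
    return k


def rk4_step_batch(f, V0: np.ndarray, h: np.ndarray, n_states: int) -> np.ndarray:
    """One signed RK4 step per row of ``V0``; extra columns are held constant."""
    V0 = np.atleast_2d(np.asarray(V0, dtype=float))
    h = np.broadcast_to(np.asarray(h, dtype=float), (V0.shape[0],))[:, None]
    X0 = V0[:, :n_states]

    def with_states(X):
        Z = V0.copy()
        Z[:, :n_states] = X
        return Z

    k1 = _eval_stage(f, V0, "k1")
    k2 = _eval_stage(f, with_states(X0 + 0.5 * h * k1), "k2")
    k3 = _eval_stage(f, with_states(X0 + 0.5 * h * k2), "k3")
    k4 = _eval_stage(f, with_states(X0 + h * k3), "k4")
    return X0 + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def rk4_step(f, x, h: float):
    """Single-vector convenience wrapper; ``f`` maps a vector to a vector.

    Negative ``h`` integrates backward in time.
    """
    x = np.asarray(x, dtype=float).reshape(-1)

    def f_batch(V):
        return np.atleast_2d(np.asarray(f(V[0]), dtype=float))

    out = rk4_step_batch(f_batch, x[None, :], float(h), x.size)
    return out[0]


def forward_predictions(f, data: TrajectoryData) -> np.ndarray:
    """Row ``k`` is the RK4 step from snapshot ``k`` over interval ``h_{k+1}``.

    Compared against ``data.states[1:]``; rows are mutually independent, so
    irregular step sequences are handled per interval.
    """
    V = data.snapshot_matrix()
    return rk4_step_batch(f, V[:-1], data.steps, data.n_states)


def backward_predictions(f, data: TrajectoryData) -> np.ndarray:
    """Row ``k`` is the RK4 step from snapshot ``k+1`` with step ``-h_{k+1}``.

    Compared against ``data.states[:-1]``.
    """
    V = data.snapshot_matrix()
    return rk4_step_batch(f, V[1:], -data.steps, data.n_states)
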