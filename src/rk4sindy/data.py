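"""Trajectory containers.

A :class:`TrajectoryData` holds one time-stamped trajectory: a strictly
increasing time grid ``t_0 ... t_N`` (steps need not be equal), the state
snapshots, optional exogenous input samples and optional per-trajectory
constant parameters (e.g. the bifurcation parameter of a parametric
system).  A :class:`TrajectoryCollection` groups several trajectories that
are fitted jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidDataError

__all__ = ["TrajectoryData", "TrajectoryCollection"]


@dataclass
class TrajectoryData:
    times: np.ndarray                      # (N+1,)
    states: np.ndarray                     # (N+1, n)
    state_names: tuple[str, ...]
    inputs: np.ndarray | None = None       # (N+1, p)
    input_names: tuple[str, ...] = ()
    params: np.ndarray | None = None       # (q,) constant over the trajectory
    param_names: tuple[str, ...] = ()
    trajectory_id: str = "traj0"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.size:
            raise InvalidDataError(
                f"trajectory {self.trajectory_id!r}: {self.times.size} times but "
                f"{self.states.shape[0]} state rows"
            )
        if self.times.size < 2:
            raise InvalidDataError(
                f"trajectory {self.trajectory_id!r}: need at least one interval (N >= 1)"
            )
        if not np.all(np.diff(self.times) > 0):
            raise InvalidDataError(
                f"trajectory {self.trajectory_id!r}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.states)):
            raise InvalidDataError(f"trajectory {self.trajectory_id!r}: non-finite states")
        self.state_names = tuple(self.state_names)
        if len(self.state_names) != self.states.shape[1]:
            raise InvalidDataError("state_names length must match state columns")
        if self.inputs is not None:
            self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
            if self.inputs.shape[0] != self.times.size:
                raise InvalidDataError("inputs must align with times")
            self.input_names = tuple(self.input_names)
            if len(self.input_names) != self.inputs.shape[1]:
                raise InvalidDataError("input_names length must match input columns")
        if self.params is not None:
            self.params = np.asarray(self.params, dtype=float).reshape(-1)
            self.param_names = tuple(self.param_names)
            if len(self.param_names) != self.params.size:
                raise InvalidDataError("param_names length must match params")

    # -- geometry --------------------------------------------------------
    @property
    def n_states(self) -> int:
        return self.states.shape[1]

    @property
    def n_steps(self) -> int:
        return self.times.size - 1

    @property
    def steps(self) -> np.ndarray:
        """Per-interval step sizes ``h_k = t_k - t_{k-1}`` (length N)."""
        return np.diff(self.times)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return self.state_names + self.input_names + self.param_names

    def snapshot_matrix(self) -> np.ndarray:
        """States, inputs and (broadcast) parameters side by side: (N+1) x n_vars."""
        cols = [self.states]
        if self.inputs is not None:
            cols.append(self.inputs)
        if self.params is not None:
            cols.append(np.broadcast_to(self.params, (self.times.size, self.params.size)))
        return np.hstack(cols) if len(cols) > 1 else self.states

    def with_states(self, states: np.ndarray) -> "TrajectoryData":
        return TrajectoryData(
            self.times.copy(), np.asarray(states, dtype=float), self.state_names,
            None if self.inputs is None else self.inputs.copy(), self.input_names,
            None if self.params is None else self.params.copy(), self.param_names,
            self.trajectory_id,
        )

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        h = self.steps
        return bool(np.all(np.abs(h - h[0]) <= rtol * abs(h[0])))


class TrajectoryCollection:
    """An ordered set of trajectories sharing variable names."""

    def __init__(self, trajectories):
        if isinstance(trajectories, TrajectoryData):
            trajectories = [trajectories]
        self.trajectories = list(trajectories)
        if not self.trajectories:
            raise InvalidDataError("empty trajectory collection")
        names = self.trajectories[0].variable_names
        for tr in self.trajectories[1:]:
            if tr.variable_names != names:
                raise InvalidDataError("trajectories in a collection must share variables")

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self):
        return len(self.trajectories)

    def __getitem__(self, i):
        return self.trajectories[i]

    @property
    def state_names(self) -> tuple[str, ...]:
        return self.trajectories[0].state_names

    @property
    def variable_names(self) -> tuple[str, ...]:
        return self.trajectories[0].variable_names

    @property
    def n_states(self) -> int:
        return self.trajectories[0].n_states

    def total_steps(self) -> int:
        return sum(tr.n_steps for tr in self.trajectories)

    def pooled_states(self) -> np.ndarray:
        return np.vstack([tr.states for tr in self.trajectories])

    def map_states(self, fn) -> "TrajectoryCollection":
        return TrajectoryCollection([tr.with_states(fn(tr.states)) for tr in self])


def as_collection(data) -> TrajectoryCollection:
    if isinstance(data, TrajectoryCollection):
        return data
    return TrajectoryCollection(data)
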