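"""Exception hierarchy for rk4sindy.

All package errors derive from :class:`RK4SindyError` so callers can catch
one base class; the concrete subclasses mirror the failure modes of the
pipeline (bad arguments, bad data, numerical blow-up, degenerate rational
denominators, diverged optimization, over-aggressive thresholding).
"""


class RK4SindyError(Exception):
    """Base class for all rk4sindy errors."""


class InvalidArgumentError(RK4SindyError, ValueError):
    """An argument violates a documented precondition."""


class InvalidDataError(RK4SindyError, ValueError):
    """Input data is malformed (non-finite entries, non-monotone times, ...)."""


class NumericalOverflowError(RK4SindyError, FloatingPointError):
    """A vector-field evaluation produced non-finite values; the message
    names the RK4 stage at which it happened."""


class DenominatorDegeneracyError(RK4SindyError, FloatingPointError):
    """A rational model denominator fell below the guard threshold.

    Carries the indices of the offending snapshots in ``snapshot_indices``.
    """

    def __init__(self, message: str, snapshot_indices=None):
        super().__init__(message)
        self.snapshot_indices = snapshot_indices


class OptimizationDivergedError(RK4SindyError, RuntimeError):
    """The coefficient optimization produced NaN/inf loss."""


class AllPrunedError(RK4SindyError, RuntimeError):
    """Thresholding removed every coefficient of every (non-constant) state."""


class UnsupportedTransformError(RK4SindyError, ValueError):
    """Affine coordinate changes are only closed over polynomial features."""


class SimulationError(RK4SindyError, RuntimeError):
    """ODE integration failed; ``last_valid_time`` holds the last time reached."""

    def __init__(self, message: str, last_valid_time=None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class TrajectoryParseError(RK4SindyError, ValueError):
    """A trajectory table could not be parsed; message carries line numbers."""
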