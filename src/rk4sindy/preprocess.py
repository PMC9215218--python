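"""Noise injection, Savitzky-Golay denoising and standardization.

Noise levels can be absolute (a standard deviation in state units) or
relative (a fraction of each state's pooled sample standard deviation,
the reading used for "1% sensor noise").  Standardization maps each state
to zero mean and unit standard deviation, pooled over all trajectories of
a collection so a single affine transform applies globally and fitted
models can be mapped back exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .data import TrajectoryCollection, TrajectoryData, as_collection
from .exceptions import InvalidArgumentError, InvalidDataError
from .models import AffineTransform

__all__ = ["NoiseSpec", "add_noise", "savgol_denoise", "standardize"]


@dataclass
class NoiseSpec:
    """Zero-mean Gaussian perturbation of the state samples."""

    sigma: float
    relative: bool = False   # True: sigma is a fraction of the pooled per-state std
    seed: int | None = None
    kind: str = "gaussian"

    def __post_init__(self):
        if self.kind != "gaussian":
            raise InvalidArgumentError("only Gaussian noise is supported")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise InvalidArgumentError("sigma must be finite and >= 0")


def add_noise(data, spec: NoiseSpec):
    """Perturb every state sample i.i.d.; times are untouched.

    Reproducible under ``spec.seed``.  Returns the same container type as
    the input (single trajectory or collection).
    """
    single = isinstance(data, TrajectoryData)
    collection = as_collection(data)
    if spec.sigma == 0.0:
        out = [tr.with_states(tr.states.copy()) for tr in collection]
        return out[0] if single else TrajectoryCollection(out)
    rng = np.random.default_rng(spec.seed)
    if spec.relative:
        sigma = spec.sigma * collection.pooled_states().std(axis=0, ddof=0)
    else:
        sigma = np.full(collection.n_states, spec.sigma)
    out = []
    for tr in collection:
        noisy = tr.states + rng.standard_normal(tr.states.shape) * sigma
        out.append(tr.with_states(noisy))
    return out[0] if single else TrajectoryCollection(out)


def savgol_denoise(data, window: int = 21, polyorder: int = 3):
    """Per-state Savitzky-Golay smoothing on a uniform grid.

    Edge samples are handled by evaluating the polynomial fitted to the
    first/last window (``mode="interp"``), so polynomial signals of degree
    at most ``polyorder`` pass through unchanged everywhere.
    """
    single = isinstance(data, TrajectoryData)
    collection = as_collection(data)
    if window % 2 != 1:
        raise InvalidArgumentError("window must be odd")
    if polyorder >= window:
        raise InvalidArgumentError("polyorder must be smaller than window")
    out = []
    for tr in collection:
        if window > tr.times.size:
            raise InvalidArgumentError(
                f"window {window} exceeds trajectory length {tr.times.size}"
            )
        if not tr.is_uniform():
            raise InvalidArgumentError(
                "Savitzky-Golay smoothing assumes a uniform time grid"
            )
        smoothed = savgol_filter(tr.states, window, polyorder, axis=0, mode="interp")
        out.append(tr.with_states(smoothed))
    return out[0] if single else TrajectoryCollection(out)


def standardize(data, transform: AffineTransform | None = None):
    """Map states to zero mean / unit std (pooled over the collection).

    Returns ``(transformed_data, transform)``.  A custom
    :class:`AffineTransform` (e.g. a physically motivated rescaling)
    overrides the statistics-based default and is applied as given.
    """
    single = isinstance(data, TrajectoryData)
    collection = as_collection(data)
    if transform is None:
        pooled = collection.pooled_states()
        mu = pooled.mean(axis=0)
        sigma = pooled.std(axis=0, ddof=0)
        if np.any(sigma <= 0):
            bad = [collection.state_names[i] for i in np.nonzero(sigma <= 0)[0]]
            raise InvalidDataError(f"zero-variance state(s) {bad}; cannot standardize")
        transform = AffineTransform(scale=sigma, shift=mu)
    out = collection.map_states(transform.apply)
    return (out[0] if single else out), transform
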