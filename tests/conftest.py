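import numpy as np
import pytest

from rk4sindy.data import TrajectoryData
from rk4sindy.rk4 import rk4_step_batch


def make_rk4_exact_data(model, x0, h, n_steps, params=None, trajectory_id="rk4"):
    """A trajectory that satisfies the one-step RK4 map *exactly*, so the
    discovery residual at the generating model is identically zero."""
    x0 = np.asarray(x0, dtype=float)
    extra = np.zeros(0) if params is None else np.asarray(params, dtype=float)
    states = [x0]
    for _ in range(n_steps):
        V = np.concatenate([states[-1], extra])[None, :]
        states.append(rk4_step_batch(model, V, h, x0.size)[0])
    times = h * np.arange(n_steps + 1)
    param_names = () if params is None else tuple(model.variables[x0.size:])
    return TrajectoryData(times, np.vstack(states), model.state_names,
                          params=None if params is None else extra,
                          param_names=param_names, trajectory_id=trajectory_id)


@pytest.fixture
def rk4_exact_data():
    return make_rk4_exact_data
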