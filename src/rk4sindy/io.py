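"""Trajectory tables and model files.

Trajectories travel as delimited text with a header: a ``t`` column, one
column per state, optional ``u_*`` input columns, optional parameter
columns and an optional ``trajectory_id`` column for multi-trajectory
files.  Models are JSON documents carrying the dictionary configuration,
the coefficient arrays with their support masks, and any coordinate
transform applied before fitting, so a file round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TrajectoryCollection, TrajectoryData, as_collection
from .dictionary import FeatureDictionary
from .exceptions import TrajectoryParseError
from .models import (
    AffineTransform,
    CoefficientSet,
    LinearDictionaryModel,
    RationalModel,
)

__all__ = [
    "save_trajectories", "load_trajectories",
    "model_to_dict", "model_from_dict", "save_model", "load_model",
]


def save_trajectories(data, path) -> None:
    collection = as_collection(data)
    frames = []
    for tr in collection:
        df = pd.DataFrame({"t": tr.times})
        for j, name in enumerate(tr.state_names):
            df[name] = tr.states[:, j]
        for j, name in enumerate(tr.input_names):
            df[name] = tr.inputs[:, j]
        for j, name in enumerate(tr.param_names):
            df[name] = tr.params[j]
        df["trajectory_id"] = tr.trajectory_id
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def load_trajectories(path, state_names=None) -> TrajectoryCollection:
    """Read a trajectory table; columns are classified by name.

    Without an explicit ``state_names`` list, every non-``t`` /
    non-``trajectory_id`` column that varies within a trajectory is a state
    unless it starts with ``u_`` (input); constant non-state columns are
    parameters.
    """
    path = Path(path)
    try:
        # round_trip parsing so a table written by save_trajectories loads
        # bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    if "t" not in df.columns:
        raise TrajectoryParseError(f"{path}: missing required column 't'")
    ids = df["trajectory_id"] if "trajectory_id" in df.columns else pd.Series(
        ["traj0"] * len(df)
    )
    value_cols = [c for c in df.columns if c not in ("t", "trajectory_id")]
    input_cols = [c for c in value_cols if c.startswith("u_")]
    rest = [c for c in value_cols if not c.startswith("u_")]
    if state_names is None:
        # parameters are constant within every trajectory
        param_cols = [
            c for c in rest
            if all(df.loc[ids == g, c].nunique() == 1 for g in ids.unique())
        ]
        state_cols = [c for c in rest if c not in param_cols]
        if not state_cols:   # all-constant data: treat everything as states
            state_cols, param_cols = rest, []
    else:
        state_cols = list(state_names)
        param_cols = [c for c in rest if c not in state_cols]
    trajectories = []
    for gid in ids.unique():
        sub = df[ids == gid]
        first_line = int(sub.index[0]) + 2  # header + 1-based
        times = sub["t"].to_numpy(dtype=float)
        if times.size < 2:
            raise TrajectoryParseError(
                f"{path}: trajectory {gid!r} starting at line {first_line} has "
                f"fewer than 2 rows (N >= 1 intervals required)"
            )
        if not np.all(np.diff(times) > 0):
            bad = int(np.nonzero(np.diff(times) <= 0)[0][0])
            raise TrajectoryParseError(
                f"{path}: non-monotone times in trajectory {gid!r} near line "
                f"{first_line + bad + 1}"
            )
        params = None
        if param_cols:
            params = np.array([float(sub[c].iloc[0]) for c in param_cols])
        trajectories.append(TrajectoryData(
            times, sub[state_cols].to_numpy(dtype=float), tuple(state_cols),
            inputs=sub[input_cols].to_numpy(dtype=float) if input_cols else None,
            input_names=tuple(input_cols),
            params=params, param_names=tuple(param_cols),
            trajectory_id=str(gid),
        ))
    return TrajectoryCollection(trajectories)


# ---------------------------------------------------------------------------
# model (de)serialization
# ---------------------------------------------------------------------------

def _coeffs_to_dict(cs: CoefficientSet) -> dict:
    return {"xi": cs.xi.tolist(), "support": cs.support.tolist()}


def _coeffs_from_dict(d: dict) -> CoefficientSet:
    return CoefficientSet(np.asarray(d["xi"], dtype=float),
                          np.asarray(d["support"], dtype=bool))


def model_to_dict(model, transform: AffineTransform | None = None) -> dict:
    if isinstance(model, LinearDictionaryModel):
        doc = {
            "form": model.form,
            "state_names": list(model.state_names),
            "dictionary": model.dictionary.to_config(),
            "coefficients": _coeffs_to_dict(model.coefficients),
        }
    elif isinstance(model, RationalModel):
        doc = {
            "form": model.form,
            "state_names": list(model.state_names),
            "phi_g": model.phi_g.to_config(),
            "phi_h": model.phi_h.to_config(),
            "coeff_g": _coeffs_to_dict(model.coeff_g),
            "coeff_h": _coeffs_to_dict(model.coeff_h),
        }
        if model.phi_k is not None:
            doc["phi_k"] = model.phi_k.to_config()
            doc["coeff_k"] = _coeffs_to_dict(model.coeff_k)
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    if transform is not None:
        doc["transform"] = {"scale": transform.scale.tolist(),
                            "shift": transform.shift.tolist()}
    return doc


def model_from_dict(doc: dict):
    transform = None
    if "transform" in doc:
        transform = AffineTransform(np.asarray(doc["transform"]["scale"]),
                                    np.asarray(doc["transform"]["shift"]))
    if doc["form"] in ("rational", "composite_rational"):
        model = RationalModel(
            FeatureDictionary.from_config(doc["phi_g"]),
            FeatureDictionary.from_config(doc["phi_h"]),
            _coeffs_from_dict(doc["coeff_g"]), _coeffs_from_dict(doc["coeff_h"]),
            tuple(doc["state_names"]),
            phi_k=FeatureDictionary.from_config(doc["phi_k"]) if "phi_k" in doc else None,
            coeff_k=_coeffs_from_dict(doc["coeff_k"]) if "coeff_k" in doc else None,
        )
    else:
        model = LinearDictionaryModel(
            FeatureDictionary.from_config(doc["dictionary"]),
            _coeffs_from_dict(doc["coefficients"]),
            tuple(doc["state_names"]), doc["form"],
        )
    return model, transform


def save_model(model, path, transform: AffineTransform | None = None) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model, transform), indent=1))


def load_model(path):
    return model_from_dict(json.loads(Path(path).read_text()))
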