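"""Configuration loading, result serialization and run manifests.

Model and experiment parameters live in a YAML file whose keys mirror
the :class:`~myospace.model.ModelParameters` fields (SI units).  Time
series are written as CSV with unit-annotated headers at full double
precision (shortest round-trip decimal), and every output directory
receives exactly one JSON manifest capturing the resolved parameters
and SHA-256 digests of the written files.  The standalone halfspace
format is plain text: first line ``<rows> <cols>``, then one row
``z_1 ... z_r beta`` per line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .control import SimulationResult
from .exceptions import ConfigurationError, InvalidInputError
from .model import ModelParameters, MusclePath
from .polytope import Halfspaces

__all__ = [
    "load_config", "save_config", "default_config_dict", "RunManifest",
    "write_timeseries", "read_timeseries", "write_hrep", "read_hrep",
]

_MODEL_KEYS = {"segment_lengths", "com_distances", "masses", "inertias",
               "gravity", "muscles", "f_max", "joint_damping"}
_OPTIONAL_MODEL_KEYS = {"joint_damping"}
_MUSCLE_KEYS = {"name", "points"}


def _params_to_dict(params: ModelParameters) -> dict:
    return {
        "segment_lengths": list(params.segment_lengths),
        "com_distances": list(params.com_distances),
        "masses": list(params.masses),
        "inertias": list(params.inertias),
        "gravity": list(params.gravity),
        "f_max": list(params.f_max),
        "joint_damping": list(params.joint_damping),
        "muscles": [
            {"name": mus.name,
             "points": [[int(seg), [float(x), float(y)]]
                        for seg, (x, y) in mus.points]}
            for mus in params.muscles
        ],
    }


def _params_from_dict(d: dict) -> ModelParameters:
    unknown = set(d) - _MODEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown model key(s): {sorted(unknown)}")
    missing = _MODEL_KEYS - _OPTIONAL_MODEL_KEYS - set(d)
    if missing:
        raise ConfigurationError(f"missing model key(s): {sorted(missing)}")
    muscles = []
    for i, mus in enumerate(d["muscles"]):
        unknown = set(mus) - _MUSCLE_KEYS
        if unknown:
            raise ConfigurationError(
                f"muscles[{i}]: unknown key(s) {sorted(unknown)}")
        pts = tuple((int(seg), (float(xy[0]), float(xy[1])))
                    for seg, xy in mus["points"])
        muscles.append(MusclePath(name=str(mus["name"]), points=pts))
    params = ModelParameters(
        segment_lengths=tuple(float(v) for v in d["segment_lengths"]),
        com_distances=tuple(float(v) for v in d["com_distances"]),
        masses=tuple(float(v) for v in d["masses"]),
        inertias=tuple(float(v) for v in d["inertias"]),
        gravity=tuple(float(v) for v in d["gravity"]),
        muscles=tuple(muscles),
        f_max=tuple(float(v) for v in d["f_max"]),
        joint_damping=tuple(float(v) for v in d.get("joint_damping", ())),
    )
    params.validate()
    return params


def default_config_dict() -> dict:
    """Config dictionary of the bundled arm with default experiment params."""
    from .model import default_arm_parameters

    return {
        "model": _params_to_dict(default_arm_parameters()),
        "experiments": {
            "reflex": {"kp": 10.0, "kd": 10.0, "tau_so": 0.02,
                       "disturbance": {"a": 15.0, "t0": 0.1, "sigma": 0.01,
                                       "direction": [-1.0, 0.0]}},
            "task": {"kp": 50.0, "kd": 5.0,
                     "trajectory": {"a": 0.3, "b": 4.0, "t0": 1.0,
                                    "gamma": 0.0}},
            "simulation": {"dt": 0.001, "duration": 2.0},
        },
    }


def load_config(path):
    """Load and validate a model + experiment configuration.

    Returns ``(ModelParameters, experiments_dict)``.  Unknown keys are
    rejected with the offending key named; invariant violations report
    the field path.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - {"model", "experiments"}
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    if "model" not in raw:
        raise ConfigurationError("missing top-level key: model")
    params = _params_from_dict(raw["model"])
    return params, raw.get("experiments", {})


def save_config(params: ModelParameters, experiments: dict, path) -> None:
    doc = {"model": _params_to_dict(params), "experiments": experiments or {}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# run manifests and time series
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record written once per experiment output directory."""

    parameters: dict
    version: str = __version__
    digests: dict = field(default_factory=dict)
    timestamp: str = ""
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=float)

    @staticmethod
    def from_json(text: str) -> "RunManifest":
        return RunManifest(**json.loads(text))

    def write(self, directory) -> Path:
        path = Path(directory) / "manifest.json"
        path.write_text(self.to_json())
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest round-trip decimal


def write_timeseries(result: SimulationResult, directory,
                     extra_parameters: dict | None = None) -> RunManifest:
    """Write a simulation result as CSV files plus a JSON manifest.

    ``joint_states.csv`` (rad, rad/s), ``muscle_states.csv`` (m, m/s, N)
    and ``task.csv`` (m, N) hold one row per integration step; numbers
    use the shortest decimal representation that round-trips exactly.
    """
    if result.time.size == 0:
        raise InvalidInputError("empty simulation result")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = result.q.shape[1]
    names = list(result.muscle_names) or [
        f"m{i}" for i in range(result.lm.shape[1])]

    frames = {}
    joint_cols = {"time[s]": result.time}
    for j in range(n):
        joint_cols[f"q{j + 1}[rad]"] = result.q[:, j]
    for j in range(n):
        joint_cols[f"qd{j + 1}[rad/s]"] = result.qdot[:, j]
    frames["joint_states.csv"] = pd.DataFrame(joint_cols)

    mus_cols = {"time[s]": result.time}
    for i, nm in enumerate(names):
        mus_cols[f"lm_{nm}[m]"] = result.lm[:, i]
    for i, nm in enumerate(names):
        mus_cols[f"lmdot_{nm}[m/s]"] = result.lmdot[:, i]
    if result.fm is not None:
        for i, nm in enumerate(names):
            mus_cols[f"fm_{nm}[N]"] = result.fm[:, i]
    frames["muscle_states.csv"] = pd.DataFrame(mus_cols)

    task_cols = {"time[s]": result.time,
                 "xt_x[m]": result.xt[:, 0], "xt_y[m]": result.xt[:, 1]}
    if result.ft is not None:
        task_cols["ft_x[N]"] = result.ft[:, 0]
        task_cols["ft_y[N]"] = result.ft[:, 1]
    frames["task.csv"] = pd.DataFrame(task_cols)

    digests = {}
    for fname, frame in frames.items():
        path = directory / fname
        with open(path, "w") as fh:
            fh.write(",".join(frame.columns) + "\n")
            for row in frame.itertuples(index=False):
                fh.write(",".join(_fmt(v) for v in row) + "\n")
        digests[fname] = _sha256(path)

    manifest = RunManifest(
        parameters={**result.parameters, **(extra_parameters or {})},
        digests=digests,
        timestamp=_time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(directory)
    return manifest


def read_timeseries(directory) -> dict:
    """Read back the CSV files of :func:`write_timeseries` as DataFrames."""
    directory = Path(directory)
    out = {}
    for fname in ("joint_states.csv", "muscle_states.csv", "task.csv"):
        path = directory / fname
        if path.exists():
            out[fname] = pd.read_csv(path, float_precision="round_trip")
    return out


# ---------------------------------------------------------------------------
# H-representation text format
# ---------------------------------------------------------------------------

def write_hrep(H: Halfspaces, path) -> None:
    """Write ``Z y <= beta`` as plain text: ``rows cols`` header, then one
    ``z_1 ... z_r beta`` line per row (exact decimal round-trip)."""
    k, r = H.Z.shape
    with open(path, "w") as fh:
        fh.write(f"{k} {r}\n")
        for row, b in zip(H.Z, H.beta):
            fh.write(" ".join(_fmt(v) for v in row) + " " + _fmt(b) + "\n")


def read_hrep(path) -> Halfspaces:
    """Read a halfspace system written by :func:`write_hrep`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise InvalidInputError("H-representation header must be 'rows cols'")
        k, r = int(header[0]), int(header[1])
        rows = []
        for line in fh:
            vals = [float(v) for v in line.split()]
            if vals:
                rows.append(vals)
    if len(rows) != k or any(len(row) != r + 1 for row in rows):
        raise InvalidInputError("H-representation body does not match header")
    arr = np.asarray(rows, dtype=float)
    return Halfspaces(Z=arr[:, :r], beta=arr[:, r])
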