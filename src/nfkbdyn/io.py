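"""Readers and writers for result artifacts.

Trajectories go to TSV (time_h, one column per species, then the derived
NF-kBn / nRelA / nRelB curves) at full float precision so read(write(x))
reproduces the arrays bit for bit.  Parameter sets use the structured YAML
dialect of :mod:`nfkbdyn.parameters`; checklists and run records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .parameters import ParameterSet
from .system import Trajectory

_FLOAT_FMT = "%.17g"


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False,
                           float_format=_FLOAT_FMT)


def read_trajectory(path) -> pd.DataFrame:
    """Read a trajectory TSV back as a DataFrame (schema-checked)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "time_h" not in df.columns:
        raise ValidationError(f"{path}: missing 'time_h' column")
    if df["time_h"].size >= 2 and not np.all(np.diff(df["time_h"]) > 0):
        raise ValidationError(f"{path}: time_h must be strictly increasing")
    return df


def write_parameter_set(params: ParameterSet, path) -> None:
    params.to_yaml(path)


def read_parameter_set(path) -> ParameterSet:
    """Read and validate a parameter YAML file.

    Malformed YAML raises a parse error with line context; negative rates
    and missing group labels raise validation errors naming the offenders.
    """
    try:
        return ParameterSet.from_yaml(path)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValidationError(f"{path}: YAML parse error{where}: {exc}") from exc


def write_checklist(checks: list[dict], path) -> None:
    payload = {"checks": checks,
               "all_passed": all(c["passed"] for c in checks)}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.bool_,)):
        return bool(value)
    raise TypeError(f"not JSON serialisable: {type(value)}")
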