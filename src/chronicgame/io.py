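"""Configuration parsing and serialization of trajectories and reports.

Config files are flat key→number mappings (YAML or JSON) whose keys are
exactly the model's parameter names; unknown keys are rejected, and the
dynamically inert parameters may be omitted (they default to 0, with a log
note). JSON output uses sorted keys so repeated runs are byte-stable.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Any

import yaml

from .dynamics import Trajectory
from .parameters import CANCELLED_PARAMETERS, PARAMETER_NAMES, ParameterSet

__all__ = [
    "load_parameters",
    "dump_parameters",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_json_report",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Malformed parameter configuration file."""


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a parameter set from a flat YAML/JSON key-value file.

    Raises :class:`ConfigError` on unknown keys, non-numeric values, or
    missing non-defaultable parameters. Omitted inert parameters are
    defaulted to 0 and noted in the log.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    unknown = sorted(set(raw) - PARAMETER_NAMES)
    if unknown:
        raise ConfigError(
            f"{path}: unknown parameter key(s) {unknown}; "
            f"valid keys are {sorted(PARAMETER_NAMES)}"
        )
    values: dict[str, float] = {}
    for key, value in raw.items():
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: value for {key} is not numeric: {value!r}")
        values[key] = float(value)
    omitted = [k for k in CANCELLED_PARAMETERS if k not in values]
    if omitted:
        logger.info(
            "%s: inert parameter(s) %s omitted; defaulting to 0 "
            "(they cancel from all payoff differences)", path, omitted,
        )
    missing = sorted(
        PARAMETER_NAMES - set(values) - set(CANCELLED_PARAMETERS)
    )
    if missing:
        raise ConfigError(f"{path}: missing required parameter(s) {missing}")
    try:
        return ParameterSet(**values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = params.as_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with header ``t,x,y,z,p``."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "x", "y", "z", "p"])
        for t, row in zip(traj.times, traj.states):
            writer.writerow([repr(float(t))] + [repr(float(v)) for v in row])


def read_trajectory_csv(path: str | Path) -> tuple[list[float], list[list[float]]]:
    """Read back a trajectory CSV; returns (times, states)."""
    times, states = [], []
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["t", "x", "y", "z", "p"]:
            raise ConfigError(f"{path}: unexpected trajectory header {header}")
        for row in reader:
            times.append(float(row[0]))
            states.append([float(v) for v in row[1:]])
    return times, states


def write_json_report(report: Any, path: str | Path) -> None:
    """Serialize a report object (anything with ``as_dict``) to stable JSON."""
    data = report.as_dict() if hasattr(report, "as_dict") else report
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
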