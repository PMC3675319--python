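"""Readers/writers for timecourse tables, parameter files and run configs.

Timecourse tables are comma-delimited with the header
``experiment,observable,time_min,mean,sd,n``; parameter files are flat JSON
mappings of parameter names to numbers.  A packaged ``table1.json``
carries the extracted TIM-2 pathway constants plus documented defaults for
the homeostasis-core constants.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .inference import DATASET_COLUMNS, TimecourseDataset
from .model import ModelParameters

__all__ = [
    "ParseError",
    "read_timecourse",
    "write_timecourse",
    "read_params",
    "write_params",
    "load_table1",
    "RunConfig",
    "load_config",
    "setup_logging",
]

log = logging.getLogger("tim2iron")


class ParseError(ValueError):
    """A data or config file failed validation."""


def read_timecourse(path) -> TimecourseDataset:
    """Read a delimited timecourse table, preserving row order."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"could not read timecourse table {path}: {exc}") from exc
    missing = [c for c in DATASET_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    try:
        return TimecourseDataset(table)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_timecourse(dataset: TimecourseDataset, path) -> None:
    dataset.table.to_csv(path, index=False)


def read_params(path) -> ModelParameters:
    try:
        return ModelParameters.from_json(path)
    except (OSError, json.JSONDecodeError, TypeError, ValueError) as exc:
        raise ParseError(f"could not read parameter file {path}: {exc}") from exc


def write_params(params: ModelParameters, path) -> None:
    params.to_json(path)


def load_table1() -> ModelParameters:
    """The packaged reference parameter set (extracted TIM-2 constants)."""
    with resources.files("tim2iron").joinpath("data/table1.json").open() as fh:
        return ModelParameters.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_COMMANDS = ("simulate", "generate", "fit", "recover", "report")


@dataclass
class RunConfig:
    """One command-line run: command, file paths and settings."""

    command: str
    params_path: str | None = None
    protocol: str | None = None
    cell_line: str = "tim2"
    data_paths: list = field(default_factory=list)
    seed: int = 0
    out_dir: str = "."
    cv: float = 0.10
    sd_floor: float = 0.0
    n_reps: int = 3
    n_starts: int = 16
    n_seeds: int = 20
    free: list = field(default_factory=list)
    media_label: float | None = None
    verbose: bool = False

    def __post_init__(self):
        if self.command not in _COMMANDS:
            raise ParseError(f"unknown command {self.command!r}; expected one of {_COMMANDS}")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ParseError(f"seed must be an integer, got {self.seed!r}")
        for name in ("params_path",):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ParseError(f"referenced file does not exist: {p}")
        for p in self.data_paths:
            if not Path(p).exists():
                raise ParseError(f"referenced data file does not exist: {p}")


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Read a YAML/JSON config file; explicit CLI flags override its keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"config {path} must be a mapping, got {type(raw).__name__}")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"config {path}: unknown key(s) {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ParseError(f"config {path}: {exc}") from exc


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
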