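"""Synthetic triplicate timecourses emulating the 55Fe measurements.

The source study's raw triplicate counts are not published, so every stage of the
pipeline is exercised against synthetic data: noise-free observables are
simulated from the model and Gaussian replicate scatter is added around
them (SD = cv * mean with an optional absolute floor, draws clipped at
zero counts).  Per-point means and standard deviations are then computed
from the replicates, exactly as a triplicate experiment would report them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .inference import DATASET_COLUMNS, TimecourseDataset
from .model import ModelParameters
from .protocols import Protocol, build_protocol, observe, simulate

__all__ = ["NoiseModel", "generate", "fixture_suite", "DEFAULT_OBSERVABLES"]

# observables measured in each experiment
DEFAULT_OBSERVABLES = {
    "uptake": ("cell_total_55fe",),
    "storage": ("biotinylated_55fe", "nonbiotinylated_55fe"),
    "export": ("media_55fe",),
}


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level measurement scatter.

    ``cv``: coefficient of variation (SD = cv * mean); ``sd_floor``:
    absolute SD floor in pmol per 10^6 cells.  Replicate draws are clipped
    at zero, as counts cannot be negative.
    """

    cv: float = 0.10
    sd_floor: float = 0.0

    def __post_init__(self):
        if self.cv < 0 or self.sd_floor < 0:
            raise ValueError("cv and sd_floor must be >= 0")


def generate(
    params: ModelParameters,
    protocol: Protocol,
    noise: NoiseModel = NoiseModel(),
    n_reps: int = 3,
    seed: int = 0,
    observables=None,
    experiment: str | None = None,
) -> TimecourseDataset:
    """Noisy replicate dataset for one protocol; deterministic given seed.

    Simulates the noise-free observables, draws ``n_reps`` Gaussian
    replicates per point (SD = max(cv * mean, sd_floor), clipped at 0) and
    reports per-point mean, SD (ddof=1) and replicate count.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if observables is None:
        observables = DEFAULT_OBSERVABLES.get(protocol.name, ("cell_total_55fe",))
    if experiment is None:
        experiment = f"{protocol.name}_{protocol.cell_line}"

    rng = np.random.default_rng(seed)
    traj = simulate(protocol, params)
    records = []
    for obs in observables:
        times, values = observe(traj, obs)
        for t, v in zip(times, values):
            sd = max(noise.cv * v, noise.sd_floor)
            reps = np.clip(rng.normal(v, sd, size=n_reps), 0.0, None) if sd > 0 else np.full(n_reps, v)
            records.append(
                {
                    "experiment": experiment,
                    "observable": obs,
                    "time_min": float(t),
                    "mean": float(np.mean(reps)),
                    "sd": float(np.std(reps, ddof=1)) if n_reps > 1 else 0.0,
                    "n": n_reps,
                }
            )
    return TimecourseDataset(pd.DataFrame.from_records(records, columns=list(DATASET_COLUMNS)))


def fixture_suite(
    seed: int,
    params: ModelParameters | None = None,
    noise: NoiseModel = NoiseModel(cv=0.10),
    n_reps: int = 3,
) -> dict:
    """The three-experiment synthetic study at the reference parameters.

    Returns ``{"uptake": ..., "storage": ..., "export": ...}`` on the
    experiments' sampling grids: uptake and export for both the TIM-2 and
    vector cell lines, storage for the TIM-2 line.
    """
    if params is None:
        params = ModelParameters()
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=8)
    suite = {}
    suite["uptake"] = TimecourseDataset.concat([
        generate(params, build_protocol("uptake", "tim2"), noise, n_reps, int(child[0])),
        generate(params, build_protocol("uptake", "vector"), noise, n_reps, int(child[1])),
    ])
    suite["storage"] = generate(
        params, build_protocol("storage", "tim2"), noise, n_reps, int(child[2])
    )
    suite["export"] = TimecourseDataset.concat([
        generate(params, build_protocol("export", "tim2"), noise, n_reps, int(child[3])),
        generate(params, build_protocol("export", "vector"), noise, n_reps, int(child[4])),
    ])
    return suite


def noise_metadata(noise: NoiseModel, seed: int, n_reps: int) -> str:
    """Sidecar JSON describing how a synthetic dataset was generated."""
    return json.dumps({"seed": seed, "n_reps": n_reps, **asdict(noise)}, indent=1)
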