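"""Stance-phase gait kinematics: from per-step angle series to species theta_obs.

One step is one stance phase, from touch-down to take-off.  Following
the video protocol, each step is reduced to six frames at relative times
0, 0.2, ..., 1.0 (five equal intervals); the species-level observed
angle theta_obs is the mean over the pooled 6 x n_steps frame angles,
and the max-deviation statistic is the largest distance from theta_obs
to any pooled frame angle.  The deviation is what justifies treating a
single mean angle as representative of the whole stance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import DegenerateGeometryError

__all__ = [
    "StepAngleSeries",
    "SpeciesGaitRecord",
    "frame_angle",
    "resample_stance",
    "species_theta_obs",
    "count_small_deviation",
    "read_step_csv",
    "write_gait_csv",
    "STANCE_GRID",
]

#: Relative stance times of the six analysed frames.
STANCE_GRID = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


@dataclass
class StepAngleSeries:
    """Tibia-metatarsus angles through one stance phase.

    ``samples`` is a sequence of (relative_time, angle_deg) pairs with
    strictly increasing times; times are normalized on construction so
    that the first sample sits at 0 (touch-down) and the last at 1
    (take-off).
    """

    species_id: str
    step_id: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("samples must be an (n, 2) array of (time, angle)")
        if len(arr) < 2:
            raise ValueError(f"step {self.step_id}: need >= 2 samples, got {len(arr)}")
        t = arr[:, 0]
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"step {self.step_id}: relative times must strictly increase")
        span = t[-1] - t[0]
        arr = arr.copy()
        arr[:, 0] = (t - t[0]) / span
        self.samples = arr

    @property
    def times(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def angles(self) -> np.ndarray:
        return self.samples[:, 1]


@dataclass(frozen=True)
class SpeciesGaitRecord:
    """Species-level stance summary.

    ``max_deviation`` is NaN for literature-cited species whose raw
    frame angles are unavailable.
    """

    species_id: str
    theta_obs: float
    n_steps: int
    max_deviation: float


def frame_angle(
    tibia_proximal: Sequence[float],
    ankle: Sequence[float],
    mt_line: tuple[Sequence[float], Sequence[float]],
) -> float:
    """Tibia-metatarsus angle on one video frame, in (0, 180].

    The tibia ray runs from the ankle joint to the proximal end of the
    tibia (parallel to the Achilles tendon); the metatarsal ray runs
    proximal-to-distal along the dorsal margin of metatarsal III.
    """
    tp = np.asarray(tibia_proximal, float)
    ak = np.asarray(ankle, float)
    p0 = np.asarray(mt_line[0], float)
    p1 = np.asarray(mt_line[1], float)
    u = tp - ak
    v = p1 - p0
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("coincident points define no direction")
    ang = math.degrees(math.acos(float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))))
    if ang == 0.0:
        raise DegenerateGeometryError("tibia and metatarsal rays coincide (0 deg)")
    return ang


def resample_stance(series: StepAngleSeries) -> np.ndarray:
    """Angles at relative times 0, 0.2, ..., 1.0 by linear interpolation."""
    return np.interp(STANCE_GRID, series.times, series.angles)


def species_theta_obs(steps: Sequence[StepAngleSeries]) -> SpeciesGaitRecord:
    """Pool six resampled frames per step; mean is theta_obs, extremes give max_deviation."""
    if not steps:
        raise ValueError("steps must be non-empty")
    species = {s.species_id for s in steps}
    if len(species) != 1:
        raise ValueError(f"steps mix species: {sorted(species)}")
    pooled = np.concatenate([resample_stance(s) for s in steps])
    theta = float(pooled.mean())
    dev = float(max(pooled.max() - theta, theta - pooled.min()))
    return SpeciesGaitRecord(
        species_id=species.pop(), theta_obs=theta, n_steps=len(steps), max_deviation=dev
    )


def count_small_deviation(records: Sequence[SpeciesGaitRecord], limit: float) -> int:
    """Number of species whose max deviation is strictly below ``limit`` degrees."""
    if not records:
        raise ValueError("records must be non-empty")
    if not (limit > 0):
        raise ValueError("limit must be positive")
    return sum(1 for r in records if r.max_deviation < limit)


def read_step_csv(path: str | Path) -> list[StepAngleSeries]:
    """Read per-sample rows (species, step_id, rel_time, angle_deg) into step series."""
    df = pd.read_csv(path)
    required = {"species", "step_id", "rel_time", "angle_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"step CSV missing columns: {sorted(missing)}")
    steps = []
    for (species, step_id), grp in df.groupby(["species", "step_id"], sort=False):
        grp = grp.sort_values("rel_time")
        steps.append(
            StepAngleSeries(
                species_id=str(species),
                step_id=str(step_id),
                samples=grp[["rel_time", "angle_deg"]].to_numpy(float),
            )
        )
    return steps


def write_gait_csv(path: str | Path, records: Sequence[SpeciesGaitRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "species": [r.species_id for r in records],
            "theta_obs_deg": [r.theta_obs for r in records],
            "n_steps": [r.n_steps for r in records],
            "max_deviation_deg": [r.max_deviation for r in records],
        }
    )
    df.to_csv(path, index=False)
    return df
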