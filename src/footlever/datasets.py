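"""Packaged comparative datasets and the species-table loader.

Two fixture tables ship with the package, transcribed cell-for-cell
from the published study:

* ``table3.csv`` — the main 27-row comparative dataset (two Equus
  caballus breeds as separate operational taxa): observed and estimated
  ankle angles, printed mechanical advantage, body mass in kg, and
  locomotor mode.
* ``table6.csv`` — the discussion-stage recomputation table: ln body
  mass, printed advantage, angles, the regression-predicted angle
  (theta_r-obs) and the printed differences.

The two tables disagree in a few printed cells (gerbil advantage 0.88
vs 0.87, tapir theta_est 102 vs 103, macaque theta_est 109 vs 111,
reindeer angles transposed); both are kept verbatim, and analyses take
the main table by default.  Where the source tables misalign species
and common names across rows, the fixtures follow the recomputation
table's species naming.

Mass is stored in grams internally; the on-disk unit is declared by the
column header (``body_mass_kg``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .lever import AdvantageRecord, mechanical_advantage
from .stats import RegressionCoefficients

__all__ = [
    "SpeciesRecord",
    "LOCOMOTOR_MODES",
    "PUBLISHED_PGLS_COEFFICIENTS",
    "DatasetVariant",
    "load_species_table",
    "load_table3",
    "load_table6",
    "table6_records",
    "records_to_frame",
]

LOCOMOTOR_MODES = ("unguligrade", "digitigrade", "plantigrade", "pentapedal")

DatasetVariant = Literal[
    "all_27_rows", "kiso_as_horse", "thoroughbred_as_horse", "exclude_horse"
]

#: Published PGLS coefficient sets (intercept, theta_est slope, ln-mass slope),
#: one per dataset variant used to fit them.
PUBLISHED_PGLS_COEFFICIENTS: dict[str, RegressionCoefficients] = {
    "kiso_as_horse": RegressionCoefficients(4.90, 0.48, 4.87),
    "thoroughbred_as_horse": RegressionCoefficients(8.42, 0.43, 4.87),
    "exclude_horse": RegressionCoefficients(5.46, 0.47, 4.61),
}

_KISO = "Equus caballus (Kiso horse)"
_THOROUGHBRED = "Equus caballus (thoroughbred)"


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the comparative dataset (mass in grams)."""

    species_id: str
    theta_obs: float
    theta_est: float
    advantage: float
    body_mass: float
    ln_body_mass: float
    locomotor_mode: str
    order: str

    def __post_init__(self) -> None:
        if not (self.body_mass > 0):
            raise ValueError(f"{self.species_id}: body mass must be positive")
        if abs(self.ln_body_mass - math.log(self.body_mass)) > 1e-9:
            raise ValueError(f"{self.species_id}: ln_body_mass inconsistent with body_mass")
        if self.locomotor_mode not in LOCOMOTOR_MODES:
            raise ValueError(
                f"{self.species_id}: unknown locomotor mode {self.locomotor_mode!r}"
            )
        implied = mechanical_advantage(self.theta_obs, self.theta_est)
        if abs(self.advantage - implied) > 1e-12:
            raise ValueError(f"{self.species_id}: advantage inconsistent with angles")

    def to_advantage_record(self) -> AdvantageRecord:
        return AdvantageRecord(self.species_id, self.theta_obs, self.theta_est)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("footlever").joinpath("data", name)))


def load_species_table(path: str | Path, mass_unit: str = "kg") -> list[SpeciesRecord]:
    """Read and validate a species trait CSV into :class:`SpeciesRecord` rows.

    Required columns: species, theta_obs_deg, theta_est_deg,
    ``body_mass_<unit>``, locomotor_mode; optional: order, sin_alpha.
    The advantage is recomputed from the angles; when a printed
    ``sin_alpha`` column is present, any row differing from the
    recomputed value by more than 0.01 triggers a warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unreadable species table") from exc
    mass_col = f"body_mass_{mass_unit}"
    to_grams = {"kg": 1000.0, "g": 1.0}
    if mass_unit not in to_grams:
        raise ValueError(f"unsupported mass unit {mass_unit!r}")
    required = {"species", "theta_obs_deg", "theta_est_deg", mass_col, "locomotor_mode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    records = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based with header line
        try:
            obs = float(row["theta_obs_deg"])
            est = float(row["theta_est_deg"])
            mass_g = float(row[mass_col]) * to_grams[mass_unit]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} row {rowno}: non-numeric angle or mass") from exc
        if not (math.isfinite(obs) and math.isfinite(est)):
            raise ValueError(f"{path} row {rowno}: non-finite angle")
        if not (mass_g > 0) or not math.isfinite(mass_g):
            raise ValueError(f"{path} row {rowno}: non-positive body mass")
        adv = mechanical_advantage(obs, est)
        if "sin_alpha" in df.columns and pd.notna(row["sin_alpha"]):
            printed = float(row["sin_alpha"])
            if abs(printed - adv) > 0.01:
                warnings.warn(
                    f"{row['species']}: printed advantage {printed} differs from "
                    f"recomputed {adv:.4f} by more than 0.01",
                    stacklevel=2,
                )
        records.append(
            SpeciesRecord(
                species_id=str(row["species"]),
                theta_obs=obs,
                theta_est=est,
                advantage=adv,
                body_mass=mass_g,
                ln_body_mass=math.log(mass_g),
                locomotor_mode=str(row["locomotor_mode"]),
                order=str(row.get("order", "")),
            )
        )
    if not records:
        raise ValueError(f"{path}: species table has no data rows")
    return records


def _apply_variant(records: list[SpeciesRecord], variant: DatasetVariant) -> list[SpeciesRecord]:
    drop = {
        "all_27_rows": set(),
        "kiso_as_horse": {_THOROUGHBRED},
        "thoroughbred_as_horse": {_KISO},
        "exclude_horse": {_KISO, _THOROUGHBRED},
    }
    try:
        excluded = drop[variant]
    except KeyError:
        raise ValueError(f"unknown dataset variant {variant!r}") from None
    return [r for r in records if r.species_id not in excluded]


def load_table3(variant: DatasetVariant = "all_27_rows") -> list[SpeciesRecord]:
    """The main 27-row comparative dataset, optionally filtered to one horse breed."""
    return _apply_variant(load_species_table(_data_path("table3.csv")), variant)


def load_table6() -> pd.DataFrame:
    """The recomputation table exactly as printed (ln masses, predicted angles)."""
    return pd.read_csv(_data_path("table6.csv"))


def table6_records(variant: DatasetVariant = "all_27_rows") -> list[SpeciesRecord]:
    """Recomputation-table rows as :class:`SpeciesRecord` (mass from its ln column).

    Locomotor mode and order are joined in from the main table.
    """
    meta = {r.species_id: r for r in load_table3()}
    records = []
    for _, row in load_table6().iterrows():
        m = meta[str(row["species"])]
        mass_g = math.exp(float(row["ln_bm"]))
        records.append(
            SpeciesRecord(
                species_id=str(row["species"]),
                theta_obs=float(row["theta_obs_deg"]),
                theta_est=float(row["theta_est_deg"]),
                advantage=mechanical_advantage(
                    float(row["theta_obs_deg"]), float(row["theta_est_deg"])
                ),
                body_mass=mass_g,
                ln_body_mass=math.log(mass_g),
                locomotor_mode=m.locomotor_mode,
                order=m.order,
            )
        )
    return _apply_variant(records, variant)


def records_to_frame(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [r.species_id for r in records],
            "theta_obs_deg": [r.theta_obs for r in records],
            "theta_est_deg": [r.theta_est for r in records],
            "advantage": [r.advantage for r in records],
            "body_mass_g": [r.body_mass for r in records],
            "ln_body_mass": [r.ln_body_mass for r in records],
            "locomotor_mode": [r.locomotor_mode for r in records],
            "order": [r.order for r in records],
        }
    )
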