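"""Estimation of theta_est from digitized 2-D lateral-view foot landmarks.

The construction mirrors how the angle is measured on a reassembled
skeleton photograph:

1. fit a circle to points digitized along the ridge of the talar
   trochlea; its centre O approximates the ankle hinge axis;
2. find the calcaneal outline point C farthest from O (the contact point
   of the largest concentric circle, i.e. the distal tip of the tuber);
3. draw the line through O perpendicular to OC — the tibia/force line in
   the configuration where the extensor moment arm is maximal — and the
   line through the dorsal tips of the proximal and distal epiphyses of
   metatarsal III;
4. the angle between those two lines, read with the orientation rule
   below, is the specimen's theta_est.

Orientation rule.  Two undirected lines meet at two supplementary
angles.  We direct the metatarsal ray from the proximal to the distal
tip, and direct the tibia ray along the perpendicular on the side of the
line OC that contains the metatarsal midpoint (the dorsal side).  The
reported angle is the angle between these two rays, in (0, 180).  This
reproduces the usual reading: an extended ungulate ankle measures above
90 deg, a flexed rodent ankle below, and the result is invariant under
rotation, translation, uniform scaling and reflection of the landmark
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateGeometryError",
    "LandmarkSet2D",
    "CircleFit",
    "ThetaEstMeasurement",
    "fit_trochlea_circle",
    "locate_calcaneal_point",
    "theta_est_from_landmarks",
    "species_theta_est",
    "read_landmark_csv",
    "write_theta_est_csv",
]


class DegenerateGeometryError(ValueError):
    """Raised when landmarks do not define the construction (collinear arc, coincident points)."""


def _as_points(points: Iterable[Sequence[float]]) -> np.ndarray:
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of planar points, got shape {arr.shape}")
    return arr


def _collinear(points: np.ndarray, rtol: float = 1e-12) -> bool:
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    return s[-1] <= rtol * scale


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: centre O, radius, RMS orthogonal residual."""

    center: tuple[float, float]
    radius: float
    rms_residual: float
    n_points: int


@dataclass
class LandmarkSet2D:
    """Digitized landmarks of one reassembled foot skeleton (lateral view)."""

    specimen_id: str
    trochlea_points: np.ndarray
    calcaneus_points: np.ndarray
    mt_proximal: np.ndarray
    mt_distal: np.ndarray
    view_side: str = "lateral"

    def __post_init__(self) -> None:
        self.trochlea_points = _as_points(self.trochlea_points)
        self.calcaneus_points = _as_points(self.calcaneus_points)
        self.mt_proximal = np.asarray(self.mt_proximal, dtype=float).reshape(2)
        self.mt_distal = np.asarray(self.mt_distal, dtype=float).reshape(2)
        if self.view_side not in ("lateral", "medial"):
            raise ValueError(f"view_side must be 'lateral' or 'medial', got {self.view_side!r}")
        if len(self.trochlea_points) < 3:
            raise DegenerateGeometryError(
                f"{self.specimen_id}: need >= 3 trochlea points, got {len(self.trochlea_points)}"
            )
        if _collinear(self.trochlea_points):
            raise DegenerateGeometryError(f"{self.specimen_id}: trochlea points are collinear")
        if len(self.calcaneus_points) == 0:
            raise DegenerateGeometryError(f"{self.specimen_id}: no calcaneus points")
        if np.allclose(self.mt_proximal, self.mt_distal):
            raise DegenerateGeometryError(
                f"{self.specimen_id}: metatarsal epiphysis tips coincide"
            )


@dataclass(frozen=True)
class ThetaEstMeasurement:
    """Specimen-level theta_est with the fitted circle and calcaneal point used."""

    specimen_id: str
    theta_est: float
    oc_length: float
    circle: CircleFit
    point_c: tuple[float, float]


def fit_trochlea_circle(points: Iterable[Sequence[float]]) -> CircleFit:
    """Least-squares circle through >= 3 non-collinear points.

    An algebraic (Kasa) fit provides the start value; a Gauss-Newton
    iteration on the orthogonal distances refines it to relative
    tolerance 1e-10.  Three non-collinear points give the exact
    circumcircle.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateGeometryError(f"need >= 3 points for a circle fit, got {len(pts)}")
    if _collinear(pts):
        raise DegenerateGeometryError("points are collinear; no finite circle fits them")

    x, y = pts[:, 0], pts[:, 1]
    # Kasa: minimize sum((x-a)^2 + (y-b)^2 - r^2)^2, linear in (a, b, a^2+b^2-r^2)
    A = np.column_stack([2 * x, 2 * y, np.ones(len(pts))])
    b = x**2 + y**2
    (a0, b0, c0), *_ = np.linalg.lstsq(A, b, rcond=None)
    center = np.array([a0, b0])
    radius = float(np.sqrt(max(c0 + a0**2 + b0**2, 0.0)))

    # Gauss-Newton on residuals r_i = |p_i - center| - radius
    for _ in range(100):
        d = pts - center
        dist = np.hypot(d[:, 0], d[:, 1])
        if np.any(dist == 0):  # centre on a data point: nudge via mean direction
            dist = np.where(dist == 0, np.finfo(float).tiny, dist)
        res = dist - radius
        J = np.column_stack([-d[:, 0] / dist, -d[:, 1] / dist, -np.ones(len(pts))])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        center = center + step[:2]
        radius = radius + step[2]
        if np.linalg.norm(step) <= 1e-10 * max(radius, 1.0):
            break
    d = pts - center
    res = np.hypot(d[:, 0], d[:, 1]) - radius
    if radius <= 0:
        raise DegenerateGeometryError("circle fit collapsed to non-positive radius")
    return CircleFit(
        center=(float(center[0]), float(center[1])),
        radius=float(radius),
        rms_residual=float(np.sqrt(np.mean(res**2))),
        n_points=len(pts),
    )


def locate_calcaneal_point(
    center: Sequence[float], calcaneus_points: Iterable[Sequence[float]]
) -> tuple[float, float]:
    """Calcaneal outline point farthest from the joint centre (the insertion point C).

    Ties are broken by first occurrence in input order.
    """
    pts = _as_points(calcaneus_points)
    if len(pts) == 0:
        raise ValueError("calcaneus_points must be non-empty")
    c = np.asarray(center, dtype=float).reshape(2)
    d2 = ((pts - c) ** 2).sum(axis=1)
    i = int(np.argmax(d2))  # argmax returns the first maximal index
    return (float(pts[i, 0]), float(pts[i, 1]))


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def theta_est_from_landmarks(lm: LandmarkSet2D) -> ThetaEstMeasurement:
    """theta_est of one specimen via the circle-and-lines construction."""
    circle = fit_trochlea_circle(lm.trochlea_points)
    o = np.array(circle.center)
    c = np.array(locate_calcaneal_point(o, lm.calcaneus_points))
    oc = c - o
    oc_length = float(np.linalg.norm(oc))
    if oc_length == 0.0:
        raise DegenerateGeometryError(
            f"{lm.specimen_id}: calcaneal point coincides with the joint centre"
        )
    if oc_length < circle.radius:
        warnings.warn(
            f"{lm.specimen_id}: calcaneal insertion point lies inside the trochlea "
            f"circle (|OC| = {oc_length:.3g} < radius {circle.radius:.3g}); "
            "probable digitization mix-up",
            stacklevel=2,
        )
    # Tibia ray: perpendicular to OC through O, directed to the side of line OC
    # holding the metatarsal midpoint (the dorsal side).
    perp = np.array([-oc[1], oc[0]]) / oc_length
    midpoint = 0.5 * (lm.mt_proximal + lm.mt_distal)
    if np.dot(perp, midpoint - o) < 0:
        perp = -perp
    mt_dir = lm.mt_distal - lm.mt_proximal
    theta = _angle_between(perp, mt_dir)
    if not (0.0 < theta < 180.0):
        # metatarsal exactly parallel/antiparallel to the tibia ray
        raise DegenerateGeometryError(
            f"{lm.specimen_id}: joint angle degenerate ({theta} deg)"
        )
    return ThetaEstMeasurement(
        specimen_id=lm.specimen_id,
        theta_est=theta,
        oc_length=oc_length,
        circle=circle,
        point_c=(float(c[0]), float(c[1])),
    )


def species_theta_est(measurements: Sequence[ThetaEstMeasurement]) -> float:
    """Species-level theta_est: arithmetic mean over its specimens."""
    if not measurements:
        raise ValueError("measurements must be non-empty")
    return float(np.mean([m.theta_est for m in measurements]))


# ---------------------------------------------------------------------------
# CSV interfaces

_STRUCTURES = ("trochlea", "calcaneus", "mt_proximal", "mt_distal")


def read_landmark_csv(path: str | Path) -> tuple[dict[str, LandmarkSet2D], dict[str, str]]:
    """Read per-point landmark rows into one :class:`LandmarkSet2D` per specimen.

    Expected columns: specimen_id, species, structure (one of trochlea /
    calcaneus / mt_proximal / mt_distal), x, y; optional view_side.
    Returns (landmarks by specimen, species by specimen).
    """
    df = pd.read_csv(path)
    required = {"specimen_id", "species", "structure", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    bad = set(df["structure"]) - set(_STRUCTURES)
    if bad:
        raise ValueError(f"unknown landmark structure labels: {sorted(bad)}")
    landmarks: dict[str, LandmarkSet2D] = {}
    species_of: dict[str, str] = {}
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        parts = {s: grp[grp["structure"] == s][["x", "y"]].to_numpy(float) for s in _STRUCTURES}
        for tip in ("mt_proximal", "mt_distal"):
            if len(parts[tip]) != 1:
                raise ValueError(
                    f"specimen {spec_id}: expected exactly one {tip} point, got {len(parts[tip])}"
                )
        view = "lateral"
        if "view_side" in grp.columns and grp["view_side"].notna().any():
            view = str(grp["view_side"].dropna().iloc[0])
        landmarks[str(spec_id)] = LandmarkSet2D(
            specimen_id=str(spec_id),
            trochlea_points=parts["trochlea"],
            calcaneus_points=parts["calcaneus"],
            mt_proximal=parts["mt_proximal"][0],
            mt_distal=parts["mt_distal"][0],
            view_side=view,
        )
        species_of[str(spec_id)] = str(grp["species"].iloc[0])
    return landmarks, species_of


def write_theta_est_csv(
    path: str | Path,
    measurements: Sequence[ThetaEstMeasurement],
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Write specimen-level measurements (and return them as a DataFrame)."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "specimen_id": m.specimen_id,
                "species": (species_of or {}).get(m.specimen_id, ""),
                "theta_est_deg": m.theta_est,
                "oc_length": m.oc_length,
                "circle_x": m.circle.center[0],
                "circle_y": m.circle.center[1],
                "radius": m.circle.radius,
                "rms_residual": m.circle.rms_residual,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
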