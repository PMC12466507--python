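"""Mechanical model of the ankle extensor apparatus.

The ankle extensors (m. gastrocnemius, m. soleus, m. flexor digitorum
superficialis) insert via the Achilles tendon on the most distal point of
the calcaneal tuber, C, and their net force line runs parallel to the
tibia.  With the foot treated as a rigid body hinging about the ankle
rotation centre O, the extensor torque is

    tau = l * F,        l = OC * sin(alpha),

where alpha is the functional ankle extension angle (FAEA) between the
force line and the segment OC.  The moment arm l is maximal (l = OC) when
alpha = 90 deg; sin(alpha) is the *mechanical advantage of the calcaneal
lever*.  Because the foot rotates rigidly about O while the force line
stays tied to the tibia, alpha changes one-for-one with the tibia-
metatarsus joint angle theta, so at an observed joint angle theta_obs

    alpha = 90 + (theta_obs - theta_est),

where theta_est is the joint angle at which alpha = 90 deg (measured from
skeletal landmarks, see :mod:`footlever.geometry`).

All public angle arguments and return values are in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

__all__ = [
    "LeverConfiguration",
    "AdvantageRecord",
    "moment_arm",
    "extensor_torque",
    "functional_angle",
    "mechanical_advantage",
    "count_above_threshold",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def moment_arm(oc_length: float, alpha: float) -> float:
    """Extensor moment arm l = OC * sin(alpha).

    Parameters
    ----------
    oc_length
        Distance OC from the ankle rotation centre to the calcaneal
        insertion point, in the unit of the landmark coordinates (> 0).
    alpha
        Functional ankle extension angle in degrees.
    """
    if not (oc_length > 0):
        raise ValueError(f"oc_length must be positive, got {oc_length!r}")
    return oc_length * math.sin(math.radians(alpha))


def extensor_torque(moment_arm: float, force: float) -> float:
    """Extensor torque tau = l * F for contractile force F >= 0."""
    if force < 0:
        raise ValueError(f"force must be nonnegative, got {force!r}")
    return moment_arm * force


def functional_angle(theta_obs: float, theta_est: float) -> float:
    """FAEA alpha at joint angle theta_obs: 90 + (theta_obs - theta_est).

    Follows from rigid rotation of the foot about O with the force line
    parallel to the tibia: every degree of joint extension rotates OC by
    one degree relative to the fixed force line.
    """
    if not (math.isfinite(theta_obs) and math.isfinite(theta_est)):
        raise ValueError("theta_obs and theta_est must be finite")
    return 90.0 + (theta_obs - theta_est)


def mechanical_advantage(theta_obs: float, theta_est: float) -> float:
    """Mechanical advantage of the calcaneal lever, sin(alpha) = cos(theta_obs - theta_est).

    Equals 1 exactly when the observed joint angle matches theta_est and
    decreases symmetrically as the joint flexes or extends away from it.
    Not clamped: |theta_obs - theta_est| > 90 deg yields a negative value,
    as the lever model itself permits.
    """
    return math.sin(math.radians(functional_angle(theta_obs, theta_est)))


@dataclass(frozen=True)
class LeverConfiguration:
    """One configuration of the calcaneal lever (OC, alpha, F)."""

    oc_length: float
    alpha: float
    force: float = 0.0

    def __post_init__(self) -> None:
        if not (self.oc_length > 0):
            raise ValueError("oc_length must be > 0")
        if self.force < 0:
            raise ValueError("force must be >= 0")

    @property
    def moment_arm(self) -> float:
        return moment_arm(self.oc_length, self.alpha)

    @property
    def torque(self) -> float:
        return extensor_torque(self.moment_arm, self.force)


@dataclass(frozen=True)
class AdvantageRecord:
    """Species-level lever summary: observed/estimated angles and sin(alpha).

    ``advantage`` defaults to the value implied by the two angles; if
    given explicitly it must agree with them to 1e-12.
    """

    species_id: str
    theta_obs: float
    theta_est: float
    advantage: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        implied = mechanical_advantage(self.theta_obs, self.theta_est)
        if self.advantage is None:
            object.__setattr__(self, "advantage", implied)
        elif abs(self.advantage - implied) > 1e-12:
            raise ValueError(
                f"{self.species_id}: advantage {self.advantage} inconsistent with "
                f"angles (implies {implied})"
            )


def count_above_threshold(
    records: Sequence[AdvantageRecord], threshold: float
) -> tuple[int, float]:
    """Number (and fraction) of records with advantage strictly above ``threshold``."""
    if not records:
        raise ValueError("records must be non-empty")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold!r}")
    n = sum(1 for r in records if r.advantage > threshold)
    return n, n / len(records)
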