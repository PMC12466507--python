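"""Seeded synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:
ultrametric trees, Brownian-motion trait vectors, digitized foot
landmarks with a known theta_est, stance-phase angle traces with a known
mean and half-range, and full comparative cohorts with planted
regression coefficients and phylogenetic signal.  Each generator is a
pure function of its seed.

Cohort defaults mirror the empirical study conditions: 27 taxa, body
masses spanning 0.06-3,400 kg (ln grams ~ 4.1-15.0), a strong
phylogenetic signal (lambda 0.94), and the fitted regression
theta_obs = 4.90 + 0.48 * theta_est + 4.87 * ln(body mass).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy import linalg

from .lever import mechanical_advantage
from .phylo import bm_covariance, tip_depths
from .stats import RegressionCoefficients
from .gait import StepAngleSeries
from .geometry import LandmarkSet2D

__all__ = [
    "SyntheticFootSpec",
    "SyntheticCohortSpec",
    "generate_tree",
    "simulate_bm_traits",
    "generate_foot_landmarks",
    "generate_stance_trace",
    "generate_cohort",
]

#: Locomotor-mode frequencies of the empirical 27-row dataset.
MODE_FREQUENCIES = {
    "unguligrade": 12,
    "digitigrade": 8,
    "plantigrade": 5,
    "pentapedal": 2,
}


@dataclass(frozen=True)
class SyntheticFootSpec:
    """Parameters of one synthetic foot-landmark set.

    ``theta_est_true`` is the exact angle the circle-and-lines
    construction recovers at zero noise; ``arc_span`` is the angular
    coverage of the digitized trochlea arc (the trochlea is an arc, not
    a full circle); ``landmark_noise_sd`` is isotropic Gaussian noise
    added to every point, in coordinate units.
    """

    theta_est_true: float = 120.0
    trochlea_radius: float = 8.0
    oc_length: float = 20.0
    n_trochlea_points: int = 12
    arc_span: float = 120.0
    landmark_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_est_true < 180.0):
            raise ValueError("theta_est_true must lie in (0, 180)")
        if not (self.oc_length > self.trochlea_radius > 0):
            raise ValueError("need oc_length > trochlea_radius > 0")
        if self.n_trochlea_points < 3:
            raise ValueError("need >= 3 trochlea points")
        if not (10.0 < self.arc_span <= 180.0):
            raise ValueError("arc_span must lie in (10, 180]")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic comparative cohort (tree + trait table)."""

    n_taxa: int = 27
    birth_rate: float = 1.0
    bm_sigma2: float = 1.0
    lambda_true: float = 0.94
    beta_true: RegressionCoefficients = field(
        default_factory=lambda: RegressionCoefficients(4.90, 0.48, 4.87)
    )
    residual_sd: float = 8.0
    mass_range_ln: tuple[float, float] = (4.1, 15.0)
    theta_est_mean: float = 120.0
    theta_est_sd: float = 12.0
    mode_assignment: str = "empirical_frequencies"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 5:
            raise ValueError("n_taxa must be >= 5")
        if self.birth_rate <= 0 or self.bm_sigma2 <= 0:
            raise ValueError("rates must be positive")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must lie in [0, 1]")


def generate_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0, unit_depth: bool = True
) -> dendropy.Tree:
    """Seeded pure-birth (Yule) ultrametric tree.

    By default the tree is rescaled to unit root-to-tip depth so that
    trait variance rates are interpretable per total tree depth.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # the generator stops at the n-th split, leaving two zero-length tip
    # branches; continue the Yule process by the waiting time to the
    # (unrealized) next split so every tip branch is positive
    extra = rng.expovariate(n_taxa * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extra
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    tree.seed_node.edge.length = None  # drop the meaningless pre-root stem
    if unit_depth:
        depth = max(tip_depths(tree).values())
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= depth
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float,
    lam: float = 1.0,
    seed: int = 0,
    root_value: float = 0.0,
    taxa: list[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """One draw of tip traits under Brownian motion with Pagel's lambda.

    Multivariate normal with mean ``root_value`` and covariance
    ``sigma2 * C_lambda``; returns (tip labels, trait vector).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    labels, C = bm_covariance(tree, lam, taxa)
    rng = np.random.default_rng(seed)
    if sigma2 == 0.0:
        return labels, np.full(len(labels), root_value)
    L = linalg.cholesky(sigma2 * C, lower=True)
    return labels, root_value + L @ rng.standard_normal(len(labels))


def generate_foot_landmarks(spec: SyntheticFootSpec) -> LandmarkSet2D:
    """Landmark set whose circle-and-lines construction yields ``theta_est_true``.

    Construction (before a seeded global rotation and noise): the joint
    centre O sits at the origin; C at distance ``oc_length`` in a seeded
    direction; trochlea points lie on the arc of radius
    ``trochlea_radius`` facing away from C; the metatarsal tips are
    placed so the proximal-to-distal ray makes exactly
    ``theta_est_true`` with the dorsally directed perpendicular to OC.
    """
    rng = np.random.default_rng(spec.seed)
    psi = rng.uniform(0.0, 2.0 * math.pi)  # direction of C from O
    u = np.array([math.cos(psi), math.sin(psi)])
    perp = np.array([-u[1], u[0]])  # dorsal side: metatarsal midpoint goes here

    o = np.zeros(2)
    c = spec.oc_length * u
    # trochlea arc centred on the direction opposite C (the articular face)
    arc_mid = psi + math.pi
    half = math.radians(spec.arc_span) / 2.0
    angs = arc_mid + np.linspace(-half, half, spec.n_trochlea_points)
    trochlea = spec.trochlea_radius * np.column_stack([np.cos(angs), np.sin(angs)])

    # metatarsal ray at theta_est_true from the dorsal perpendicular;
    # rotate towards -u (plantar) so the angle opens across the foot
    th = math.radians(spec.theta_est_true)
    mt_dir = math.cos(th) * perp - math.sin(th) * u
    mt_len = 1.5 * spec.oc_length
    mt_prox = o + 0.8 * spec.oc_length * perp - 0.2 * spec.oc_length * u
    mt_dist = mt_prox + mt_len * mt_dir
    # midpoint must lie dorsal of line OC for the orientation rule
    assert np.dot(perp, 0.5 * (mt_prox + mt_dist) - o) > 0

    pts = {
        "trochlea": trochlea,
        "calcaneus": np.vstack([c, 0.6 * c, 0.85 * c + 0.1 * spec.oc_length * perp]),
        "mt_proximal": mt_prox[None, :],
        "mt_distal": mt_dist[None, :],
    }
    if spec.landmark_noise_sd > 0:
        for key, arr in pts.items():
            pts[key] = arr + rng.normal(0.0, spec.landmark_noise_sd, size=arr.shape)
    return LandmarkSet2D(
        specimen_id=f"synthetic-{spec.seed}",
        trochlea_points=pts["trochlea"],
        calcaneus_points=pts["calcaneus"],
        mt_proximal=pts["mt_proximal"][0],
        mt_distal=pts["mt_distal"][0],
    )


def generate_stance_trace(
    theta_mean: float,
    amplitude: float = 10.0,
    n_frames: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    species_id: str = "synthetic",
    step_id: str = "step1",
) -> StepAngleSeries:
    """Smooth stance-phase angle trace around ``theta_mean``.

    The noiseless curve is a two-harmonic waveform normalized so that,
    sampled on the six-frame analysis grid (multiples of 0.2), its mean
    is exactly ``theta_mean`` and its extremes are theta_mean +/-
    ``amplitude``.  Use n_frames = 5k + 1 (6, 11, 16, ...) to place
    samples exactly on that grid.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    t = np.linspace(0.0, 1.0, n_frames)
    wave = np.sin(2 * math.pi * t) + 0.15 * np.sin(4 * math.pi * t)
    grid = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    gw = np.sin(2 * math.pi * grid) + 0.15 * np.sin(4 * math.pi * grid)
    angles = theta_mean + amplitude * wave / np.abs(gw).max()
    if noise_sd > 0:
        angles = angles + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_frames)
    return StepAngleSeries(
        species_id=species_id, step_id=step_id, samples=np.column_stack([t, angles])
    )


def _assign_modes(n: int, rule: str, rng: np.random.Generator) -> list[str]:
    if rule == "empirical_frequencies":
        modes = list(MODE_FREQUENCIES)
        weights = np.array(list(MODE_FREQUENCIES.values()), dtype=float)
        return list(rng.choice(modes, size=n, p=weights / weights.sum()))
    if rule == "uniform":
        return list(rng.choice(list(MODE_FREQUENCIES), size=n))
    raise ValueError(f"unknown mode_assignment rule {rule!r}")


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Tree plus species table with a planted linear signal and BM residuals.

    theta_obs = beta0 + beta1 * theta_est + beta2 * ln(body mass) +
    residual, where the residual vector is Brownian motion with Pagel's
    ``lambda_true`` scaled to marginal standard deviation
    ``residual_sd``.  The advantage column is filled by the lever model.
    """
    rng = np.random.default_rng(spec.seed)
    tree = generate_tree(spec.n_taxa, spec.birth_rate, seed=int(rng.integers(2**31)))
    labels, C = bm_covariance(tree, spec.lambda_true)
    ln_bm = rng.uniform(*spec.mass_range_ln, size=spec.n_taxa)
    theta_est = rng.normal(spec.theta_est_mean, spec.theta_est_sd, size=spec.n_taxa)
    theta_est = np.clip(theta_est, 60.0, 175.0)
    # BM residuals scaled so tip marginal SD equals residual_sd
    if spec.residual_sd > 0:
        scale = spec.residual_sd / math.sqrt(float(np.mean(np.diag(C))) * spec.bm_sigma2)
        L = linalg.cholesky(spec.bm_sigma2 * C, lower=True)
        resid = scale * (L @ rng.standard_normal(spec.n_taxa))
    else:
        resid = np.zeros(spec.n_taxa)
    b = spec.beta_true
    theta_obs = b.beta0 + b.beta1 * theta_est + b.beta2 * ln_bm + resid
    table = pd.DataFrame(
        {
            "species": labels,
            "theta_obs_deg": theta_obs,
            "theta_est_deg": theta_est,
            "advantage": [
                mechanical_advantage(o, e) for o, e in zip(theta_obs, theta_est)
            ],
            "body_mass_kg": np.exp(ln_bm) / 1000.0,
            "ln_body_mass": ln_bm,
            "locomotor_mode": _assign_modes(spec.n_taxa, spec.mode_assignment, rng),
            "order": "Synthetica",
        }
    )
    return tree, table
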