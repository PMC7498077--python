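"""Growth-unit trajectories for roots and stems.

A root axis is grown as a chain of fixed-length growth units.  Each unit
advances the tip one unit length ``l`` along the local Y axis and then
deflects it by a radial rotation ``gamma`` about Z and an axial rotation
``theta`` about X, written in the row-vector homogeneous-transform
convention: the step displacement in the local frame is

    [0, l, 0] . R(gamma, theta)
      = l . (-cos(theta) sin(gamma), cos(theta) cos(gamma), sin(theta))

The per-step orientation is accumulated so every later step bends relative to
the direction the tip already has; a single step from the identity
orientation reproduces the bare matrix product exactly.  Rotations are
isometries, so every segment of the generated polyline has length ``l``.

World frame: right-handed, z is soil depth, positive downward, soil surface
at z = 0, seed-potato center at (0, 0, z0).  The axial placement angle is
measured from the upward underground-stem direction, so 90 degrees is
horizontal and 180 degrees is straight down; the radial placement angle spins
the axis about the vertical, measured from +Y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distributions import DistributionSpec, sample_parameter

__all__ = ["RootAxis", "growth_step", "generate_axis", "axis_depth",
           "deflection_matrix"]


def deflection_matrix(gamma_deg: float, theta_deg: float) -> np.ndarray:
    """3x3 row-vector rotation: gamma about Z then theta about X."""
    g = np.radians(gamma_deg)
    t = np.radians(theta_deg)
    cg, sg, ct, st = np.cos(g), np.sin(g), np.cos(t), np.sin(t)
    return np.array([
        [cg, sg, 0.0],
        [-ct * sg, ct * cg, st],
        [st * sg, -st * cg, ct],
    ])


def growth_step(
    point: np.ndarray,
    orientation: np.ndarray,
    l: float,
    gamma_deg: float,
    theta_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the tip one growth unit of length ``l`` with a deflection.

    Returns the new tip position and the updated orientation matrix.  From
    the identity orientation the step is exactly the homogeneous-transform
    product (translate ``l`` along Y, then rotate); subsequent calls compose
    each deflection onto the accumulated frame.
    """
    if l <= 0:
        raise ValueError(f"growth unit length must be > 0, got {l}")
    R = deflection_matrix(gamma_deg, theta_deg)
    new_orientation = R @ orientation
    step = np.array([0.0, l, 0.0]) @ new_orientation
    return np.asarray(point, float) + step, new_orientation


@dataclass
class RootAxis:
    """Polyline of growth-unit endpoints plus the taper radii.

    ``points`` has N+1 rows for N unit steps; consecutive points are exactly
    one unit length apart.
    """

    points: np.ndarray
    l_unit: float
    theta0_deg: float
    eta0_deg: float
    r0: float = 0.0
    r_tip: float = 0.0
    gammas_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    thetas_deg: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_steps(self) -> int:
        return len(self.points) - 1

    def length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum()
        )


def _axial_placement(theta0_deg: float) -> np.ndarray:
    # rotate about X by (theta0 - 90): +Y -> (0, sin(theta0), -cos(theta0)),
    # so 90 deg is horizontal and 180 deg points straight down (z-down frame)
    a = np.radians(theta0_deg - 90.0)
    ca, sa = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, ca, sa], [0, -sa, ca]])


def _radial_placement(eta0_deg: float) -> np.ndarray:
    e = np.radians(eta0_deg)
    ce, se = np.cos(e), np.sin(e)
    return np.array([[ce, se, 0], [-se, ce, 0], [0, 0, 1]])


def generate_axis(
    start,
    theta0_deg: float,
    eta0_deg: float,
    total_length: float,
    l_unit: float = 1.0,
    phi_axial_deg: float = 0.0,
    phi_radial_deg: float = 0.0,
    r0: float = 0.0,
    r_tip: float = 0.0,
    rng: np.random.Generator | None = None,
    gamma_spec: DistributionSpec | None = None,
    theta_spec: DistributionSpec | None = None,
) -> RootAxis:
    """Grow a full axis, then place it by its initial angles and start point.

    ``N = round(total_length / l_unit)`` unit steps are grown in the
    canonical frame.  By default the measured total deflection is spread
    uniformly over the steps (per-step angles ``phi/N``) — bending is treated
    as a uniform change.  If ``gamma_spec``/``theta_spec`` are given, the
    per-step deflections are instead sampled from those database specs, one
    draw per growth unit.  The finished polyline is rigidly rotated by the
    axial angle (about X, measured from the upward stem direction) and the
    radial angle (about the vertical) and translated to ``start``.
    """
    if total_length <= 0:
        raise ValueError(f"total_length must be > 0, got {total_length}")
    if l_unit <= 0:
        raise ValueError(f"l_unit must be > 0, got {l_unit}")
    if l_unit > total_length:
        warnings.warn(
            f"l_unit {l_unit} exceeds total_length {total_length}; "
            "emitting a single-step degenerate axis",
            stacklevel=2,
        )
        n = 1
    else:
        n = max(1, round(total_length / l_unit))

    if gamma_spec is not None or theta_spec is not None:
        if rng is None:
            raise ValueError("per-step sampled deflections require rng")
        gammas = (
            np.array([sample_parameter(gamma_spec, rng) for _ in range(n)])
            if gamma_spec is not None else np.zeros(n)
        )
        thetas = (
            np.array([sample_parameter(theta_spec, rng) for _ in range(n)])
            if theta_spec is not None else np.zeros(n)
        )
    else:
        gammas = np.full(n, phi_radial_deg / n)
        thetas = np.full(n, phi_axial_deg / n)

    pts = np.zeros((n + 1, 3))
    point = np.zeros(3)
    orientation = np.eye(3)
    for i in range(n):
        point, orientation = growth_step(
            point, orientation, l_unit, gammas[i], thetas[i]
        )
        pts[i + 1] = point

    placement = _axial_placement(theta0_deg) @ _radial_placement(eta0_deg)
    pts = pts @ placement + np.asarray(start, float)
    return RootAxis(
        points=pts,
        l_unit=l_unit,
        theta0_deg=theta0_deg,
        eta0_deg=eta0_deg,
        r0=r0,
        r_tip=r_tip,
        gammas_deg=gammas,
        thetas_deg=thetas,
    )


def axis_depth(axis: RootAxis) -> float:
    """Deepest point reached by the axis (z-down convention), in mm."""
    if axis.points is None or len(axis.points) == 0:
        raise ValueError("empty axis has no depth")
    return float(np.max(axis.points[:, 2]))
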