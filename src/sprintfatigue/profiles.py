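"""Fatigue-free force-velocity and power-velocity profiles for sprint cycling.

Under maximal voluntary effort the relationship between mean pedal force and
pedaling rate (cadence) in multi-joint cycling is reliably linear, in contrast
to the hyperbolic force-velocity relation of isolated muscle.  This module
provides both representations:

* :class:`LinearFvProfile` -- the linear profile ``F(PR) = a*PR + F_max`` with
  negative slope ``a`` (N per rpm) and isometric intercept ``F_max`` (N).
  It is the substrate of the time-based fatigue model (PASA).
* :class:`HillFvProfile` -- Hill's rectangular hyperbola
  ``(F + c)(v + d) = (F_max + c) d``, whose power-velocity product can be
  approximated near v = 0 by a third-order polynomial
  (:class:`CubicPvProfile`); the cubic is the substrate of the stroke-based
  model (PESA) when a cadence-resolved peak power is needed.

Cadence is expressed in rpm at every public interface; internal conversions to
rev/s use the factor 1/60.  Velocity ``v`` for the Hill profile is tangential
pedal speed in m/s, derived from cadence and crank length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "RPM_PER_REV_S",
    "CrankGeometry",
    "LinearFvProfile",
    "DerivedMetrics",
    "HillFvProfile",
    "CubicPvProfile",
    "FvPoint",
    "linear_force",
    "linear_power",
    "derived_metrics",
    "hill_force",
    "cubic_from_hill",
    "fit_linear_fv",
]

#: rpm per rev/s
RPM_PER_REV_S = 60.0


@dataclass(frozen=True)
class CrankGeometry:
    """Crank length, the only geometric quantity the per-revolution analysis needs.

    Parameters
    ----------
    crank_length_m
        Crank length in meters.  Track sprint cranks are typically 0.165-0.175 m;
        values outside [0.10, 0.25] are rejected as implausible.
    """

    crank_length_m: float = 0.17

    def __post_init__(self) -> None:
        if not 0.10 <= self.crank_length_m <= 0.25:
            raise ValueError(
                f"crank_length_m={self.crank_length_m!r} outside plausible range [0.10, 0.25] m"
            )

    def tangential_speed(self, cadence_rpm: ArrayLike) -> np.ndarray | float:
        """Tangential pedal speed (m/s) at the given cadence (rpm)."""
        return 2.0 * math.pi * self.crank_length_m * np.asarray(cadence_rpm, float) / RPM_PER_REV_S


@dataclass(frozen=True)
class LinearFvProfile:
    """Linear force-velocity profile ``F(PR) = slope_a * PR + fmax_N``.

    ``slope_a`` is in N per rpm and must be negative (force declines with
    cadence); ``fmax_N`` is the isometric intercept in N.
    """

    slope_a: float
    fmax_N: float

    def __post_init__(self) -> None:
        if not self.slope_a < 0:
            raise ValueError(f"slope_a must be negative, got {self.slope_a!r}")
        if not self.fmax_N > 0:
            raise ValueError(f"fmax_N must be positive, got {self.fmax_N!r}")

    @property
    def prmax_rpm(self) -> float:
        """Cadence at which the extrapolated force reaches zero."""
        return -self.fmax_N / self.slope_a

    @property
    def propt_rpm(self) -> float:
        """Power-maximizing cadence; exactly half of :attr:`prmax_rpm`."""
        return -self.fmax_N / (2.0 * self.slope_a)


@dataclass(frozen=True)
class DerivedMetrics:
    """Performance metrics derived from a linear F-v profile."""

    fmax_N: float
    prmax_rpm: float
    propt_rpm: float
    pmax_W: float


@dataclass(frozen=True)
class HillFvProfile:
    """Hill rectangular hyperbola ``(F + c)(v + d) = (fmax_N + c) d``.

    ``c`` (N) and ``d`` (same unit as the velocity argument) are the force-like
    and velocity-like curvature constants; both must be positive.
    """

    fmax_N: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.fmax_N > 0 and self.c > 0 and self.d > 0):
            raise ValueError("HillFvProfile requires fmax_N > 0, c > 0, d > 0")


@dataclass(frozen=True)
class CubicPvProfile:
    """Third-order polynomial power-velocity profile ``P(v) = k1 v + k2 v^2 + k3 v^3``.

    ``k1`` must be positive so that power is positive on an open interval
    ``(0, v_zero)``.
    """

    k1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError(f"k1 must be positive, got {self.k1!r}")

    def power(self, v: ArrayLike) -> np.ndarray | float:
        v = np.asarray(v, float)
        return self.k1 * v + self.k2 * v**2 + self.k3 * v**3


@dataclass(frozen=True)
class FvPoint:
    """A single fatigue-free (cadence, force) observation used for profile fitting.

    ``source`` tags where the point came from: early acceleration revolutions of
    the isokinetic sprint (``"acceleration"``) or high-cadence revolutions of a
    low-resistance motoric sprint (``"motoric"``).
    """

    cadence_rpm: float
    force_N: float
    source: str = "acceleration"

    def __post_init__(self) -> None:
        if not self.cadence_rpm > 0:
            raise ValueError("cadence_rpm must be positive")
        if self.force_N < 0:
            raise ValueError("force_N must be non-negative")
        if self.source not in ("acceleration", "motoric"):
            raise ValueError(f"unknown source tag {self.source!r}")


def linear_force(profile: LinearFvProfile, cadence_rpm: ArrayLike) -> np.ndarray | float:
    """Mean pedal force (N) of the linear profile at ``cadence_rpm``.

    Values above ``prmax_rpm`` yield negative forces; no clamping is applied so
    the algebra stays exact for convergence analysis (callers clamp if needed).
    """
    pr = np.asarray(cadence_rpm, float)
    return profile.slope_a * pr + profile.fmax_N


def linear_power(
    profile: LinearFvProfile, geometry: CrankGeometry, cadence_rpm: ArrayLike
) -> np.ndarray | float:
    """Mean power (W): force times tangential pedal speed ``2*pi*r*PR`` (PR in rev/s)."""
    return linear_force(profile, cadence_rpm) * geometry.tangential_speed(cadence_rpm)


def derived_metrics(profile: LinearFvProfile, geometry: CrankGeometry) -> DerivedMetrics:
    """Maximal force, maximal and optimal cadence, and maximal power of a linear profile.

    ``PR_max = -F_max/a``, ``PR_opt = -F_max/(2a)`` and ``P_max`` is the power
    at ``PR_opt`` (equivalently ``-F_max^2/(4a) * 2*pi*r/60``).
    """
    propt = profile.propt_rpm
    return DerivedMetrics(
        fmax_N=profile.fmax_N,
        prmax_rpm=profile.prmax_rpm,
        propt_rpm=propt,
        pmax_W=float(linear_power(profile, geometry, propt)),
    )


def hill_force(profile: HillFvProfile, v: ArrayLike) -> np.ndarray | float:
    """Force of the Hill hyperbola at velocity ``v``: ``(F_max + c) d / (v + d) - c``."""
    v = np.asarray(v, float)
    if np.any(v + profile.d <= 0):
        raise ValueError("hill_force requires v + d > 0")
    return (profile.fmax_N + profile.c) * profile.d / (v + profile.d) - profile.c


def cubic_from_hill(profile: HillFvProfile) -> CubicPvProfile:
    """Taylor expansion about v = 0 of the Hill power ``P(v) = F(v) * v``.

    Expanding ``1/(v + d)`` geometrically gives
    ``P(v) = F_max v - (F_max + c)/d v^2 + (F_max + c)/d^2 v^3 + O(v^4)``,
    i.e. ``k1 = F_max``, ``k2 = -(F_max + c)/d``, ``k3 = (F_max + c)/d^2``.
    """
    s = profile.fmax_N + profile.c
    return CubicPvProfile(k1=profile.fmax_N, k2=-s / profile.d, k3=s / profile.d**2)


def fit_linear_fv(points: Iterable[FvPoint] | Sequence[FvPoint]) -> tuple[LinearFvProfile, float]:
    """Ordinary least squares of force on cadence across fatigue-free points.

    Returns the fitted :class:`LinearFvProfile` and the coefficient of
    determination R^2.  Raises ``ValueError`` with fewer than two distinct
    cadences (the slope would be unidentified).
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("fit_linear_fv needs at least 2 points")
    pr = np.array([p.cadence_rpm for p in pts], float)
    f = np.array([p.force_N for p in pts], float)
    if np.unique(pr).size < 2:
        raise ValueError("fit_linear_fv needs at least 2 distinct cadences")
    slope, intercept = np.polyfit(pr, f, 1)
    resid = f - (slope * pr + intercept)
    sstot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    return LinearFvProfile(slope_a=float(slope), fmax_N=float(intercept)), r2
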