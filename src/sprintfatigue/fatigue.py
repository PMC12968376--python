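"""The two deterministic fatigue models and their cross-representation conversions.

PASA (Parallel Shift Approach) -- time-based.  Only the intercept of the linear
F-v profile decays; the slope is preserved (a parallel downward shift):

    F_max(t) = (F_max - C_F) * exp(min(0, -(t - TD)/tau_F)) + C_F
    F(PR, t) = a*PR + F_max(t)

with limiting asymptote ``C_F`` (the residual, aerobically sustainable force),
time constant ``tau_F`` and a fatigue-free delay ``TD``.

PESA (Pedal Stroke-Based Approach) -- stroke-based.  Peak power at the
evaluation cadence decays by a constant relative fraction ``delta`` per
completed pedal stroke after a stroke delay ``ND``:

    P(n) = P_peak * (1 - delta)^max(0, n - ND)          (exponential form)
    P(n) = P_peak * (1 - delta * max(0, n - ND))        (legacy linear form)

The linear form crosses zero near ``n = ND + 1/delta`` and goes negative; it is
retained only to demonstrate that pathology.

The bridge between the representations is the stroke count
``n(t) = integral of PR(t') dt'`` (PR in rev/s).  At constant cadence the
stroke-based PASA with per-stroke decrement

    dF_max = 1 - exp(-1 / (PR * tau_F))

is algebraically identical to the time-based form at every stroke boundary,
which is the core duality this module exposes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from numpy.typing import ArrayLike

from .profiles import (
    RPM_PER_REV_S,
    CrankGeometry,
    CubicPvProfile,
    LinearFvProfile,
    linear_force,
)

__all__ = [
    "PasaParams",
    "PesaParams",
    "CadenceSeries",
    "pasa_fmax_at_time",
    "pasa_force",
    "pasa_power",
    "strokes_at_time",
    "nd_from_td",
    "pesa_power_linear",
    "pesa_power_exp",
    "pesa_power_at_time",
    "pasa_per_stroke_decrement",
    "pasa_fmax_at_stroke",
]


@dataclass(frozen=True)
class PasaParams:
    """PASA parameters on top of a fatigue-free linear profile.

    The amplitude ``A_F = fmax_N - cf_N`` is implied rather than stored, so the
    identity ``F_max = A_F + C_F`` holds by construction.  The physiological
    ordering constraint ``A_F > C_F > 0`` and the box ``0 < tau_s < 100``,
    ``td_s >= 0`` are enforced at construction.
    """

    base: LinearFvProfile
    cf_N: float
    tau_s: float
    td_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.cf_N > 0:
            raise ValueError(f"cf_N must be positive, got {self.cf_N!r}")
        if not self.af_N > self.cf_N:
            raise ValueError(
                f"amplitude A_F={self.af_N:.1f} must exceed asymptote C_F={self.cf_N:.1f}"
            )
        if not 0 < self.tau_s < 100:
            raise ValueError(f"tau_s must lie in (0, 100), got {self.tau_s!r}")
        if self.td_s < 0:
            raise ValueError(f"td_s must be non-negative, got {self.td_s!r}")

    @property
    def af_N(self) -> float:
        """Decay amplitude ``A_F = F_max - C_F`` (N)."""
        return self.base.fmax_N - self.cf_N


PeakPower = Union[float, CubicPvProfile]


@dataclass(frozen=True)
class PesaParams:
    """PESA parameters: peak power, per-stroke decrement and stroke delay.

    ``peak_power_W`` is either a scalar peak power at the (single) evaluation
    cadence -- what an isokinetic protocol identifies -- or a
    :class:`~sprintfatigue.profiles.CubicPvProfile` for cadence-resolved use.
    """

    peak_power_W: PeakPower
    delta: float
    nd_strokes: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.delta < 1:
            raise ValueError(f"delta must lie in [0, 1), got {self.delta!r}")
        if self.nd_strokes < 0:
            raise ValueError(f"nd_strokes must be non-negative, got {self.nd_strokes!r}")
        if isinstance(self.peak_power_W, (int, float)) and not self.peak_power_W > 0:
            raise ValueError(f"peak_power_W must be positive, got {self.peak_power_W!r}")

    def peak_at(
        self, cadence_rpm: float | None = None, geometry: CrankGeometry | None = None
    ) -> float:
        """Fatigue-free peak power (W).

        A scalar peak is returned as-is (it is only meaningful at its
        calibration cadence); a cubic profile is evaluated at the tangential
        pedal speed for ``cadence_rpm``, which then requires ``geometry``.
        """
        if isinstance(self.peak_power_W, CubicPvProfile):
            if cadence_rpm is None or geometry is None:
                raise ValueError("cadence_rpm and geometry required for a cadence-resolved peak")
            return float(self.peak_power_W.power(geometry.tangential_speed(cadence_rpm)))
        return float(self.peak_power_W)


@dataclass(frozen=True)
class CadenceSeries:
    """Ordered (time, cadence) samples defining the stroke-count clock n(t)."""

    times_s: np.ndarray
    cadence_rpm: np.ndarray
    _cum_strokes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, float)
        pr = np.asarray(self.cadence_rpm, float)
        if t.ndim != 1 or t.size < 2 or t.shape != pr.shape:
            raise ValueError("times_s and cadence_rpm must be 1-D arrays of equal length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if np.any(pr < 0):
            raise ValueError("cadence_rpm must be non-negative")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "cadence_rpm", pr)
        # cumulative trapezoid of cadence in rev/s; exact for piecewise-linear cadence
        rev_s = pr / RPM_PER_REV_S
        cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * (rev_s[:-1] + rev_s[1:]) / 2.0)])
        object.__setattr__(self, "_cum_strokes", cum)

    @classmethod
    def constant(cls, cadence_rpm: float, duration_s: float) -> "CadenceSeries":
        return cls(np.array([0.0, duration_s]), np.array([cadence_rpm, cadence_rpm]))


def pasa_fmax_at_time(params: PasaParams, t_s: ArrayLike) -> np.ndarray | float:
    """Time course of the decaying intercept ``F_max(t)``.

    Constant at ``F_max`` during the delay ``t <= TD``, then exponential decay
    with time constant ``tau_s`` toward the asymptote ``cf_N``.
    """
    t = np.asarray(t_s, float)
    exponent = np.minimum(0.0, -(t - params.td_s) / params.tau_s)
    return (params.base.fmax_N - params.cf_N) * np.exp(exponent) + params.cf_N


def pasa_force(params: PasaParams, cadence_rpm: ArrayLike, t_s: ArrayLike) -> np.ndarray | float:
    """Time-dependent F-v relation ``F(PR, t) = a*PR + F_max(t)`` (parallel shift)."""
    pr = np.asarray(cadence_rpm, float)
    return params.base.slope_a * pr + pasa_fmax_at_time(params, t_s)


def pasa_power(
    params: PasaParams,
    geometry: CrankGeometry,
    cadence_rpm: ArrayLike,
    t_s: ArrayLike,
) -> np.ndarray | float:
    """PASA power: time-dependent force times tangential pedal speed."""
    return pasa_force(params, cadence_rpm, t_s) * geometry.tangential_speed(cadence_rpm)


def strokes_at_time(series: CadenceSeries, t_s: ArrayLike) -> np.ndarray | float:
    """Cumulative (real-valued) stroke count ``n(t)``, the integral of cadence in rev/s.

    Exact for piecewise-linear cadence.  ``t_s`` must lie within the series span.
    """
    t = np.asarray(t_s, float)
    t0, t1 = series.times_s[0], series.times_s[-1]
    if np.any(t < t0) or np.any(t > t1):
        raise ValueError(f"t_s outside cadence series span [{t0}, {t1}]")
    idx = np.clip(np.searchsorted(series.times_s, t, side="right") - 1, 0, series.times_s.size - 2)
    ta, tb = series.times_s[idx], series.times_s[idx + 1]
    pa, pb = series.cadence_rpm[idx] / RPM_PER_REV_S, series.cadence_rpm[idx + 1] / RPM_PER_REV_S
    frac = (t - ta) / (tb - ta)
    pr_t = pa + (pb - pa) * frac
    n = series._cum_strokes[idx] + (t - ta) * (pa + pr_t) / 2.0
    return n if n.ndim else float(n)


def nd_from_td(series: CadenceSeries, td_s: float) -> int:
    """Stroke delay ND: completed strokes accumulated during the temporal delay TD."""
    return int(math.floor(strokes_at_time(series, td_s)))


def pesa_power_linear(params: PesaParams, n: ArrayLike) -> np.ndarray | float:
    """Legacy linear PESA ``P_peak * (1 - delta * max(0, n - ND))``.

    Goes negative once ``n`` exceeds ``ND + 1/delta``; retained deliberately to
    reproduce that non-physiological behaviour.
    """
    n = np.asarray(n, float)
    peak = params.peak_at()
    return peak * (1.0 - params.delta * np.maximum(0.0, n - params.nd_strokes))


def pesa_power_exp(params: PesaParams, n: ArrayLike) -> np.ndarray | float:
    """Exponential PESA ``P_peak * (1 - delta)^max(0, n - ND)``; strictly positive.

    ``n`` may be real-valued (continuous exponent) for time-based evaluation.
    """
    n = np.asarray(n, float)
    peak = params.peak_at()
    return peak * (1.0 - params.delta) ** np.maximum(0.0, n - params.nd_strokes)


def pesa_power_at_time(
    params: PesaParams, series: CadenceSeries, t_s: ArrayLike
) -> np.ndarray | float:
    """Time-based PESA: exponential form evaluated at the real-valued n(t)."""
    return pesa_power_exp(params, strokes_at_time(series, t_s))


def pasa_per_stroke_decrement(params: PasaParams, cadence_rev_s: float) -> float:
    """Per-stroke decrement of F_max at constant cadence: ``1 - exp(-1/(PR*tau_F))``.

    ``cadence_rev_s`` is in rev/s.  Lies in (0, 1) for any positive cadence.
    """
    if cadence_rev_s <= 0:
        raise ValueError("cadence_rev_s must be positive")
    return 1.0 - math.exp(-1.0 / (cadence_rev_s * params.tau_s))


def pasa_fmax_at_stroke(
    params: PasaParams, n: ArrayLike, cadence_rev_s: float
) -> np.ndarray | float:
    """Stroke-indexed PASA intercept at constant cadence.

    ``F_max(n) = (F_max - C_F) * (1 - dF_max)^max(0, n - ND) + C_F`` with the
    per-stroke decrement from :func:`pasa_per_stroke_decrement` and the integer
    stroke delay ``ND = floor(PR * TD)`` (completed strokes).  Because
    ``(1 - dF_max)^k = exp(-k / (PR * tau_F))``, the stroke form is
    algebraically identical to :func:`pasa_fmax_at_time` evaluated at
    ``t = TD + (n - ND)/PR`` for every stroke count ``n >= ND``.
    """
    n = np.asarray(n, float)
    d = pasa_per_stroke_decrement(params, cadence_rev_s)
    nd = math.floor(cadence_rev_s * params.td_s)
    exponent = np.maximum(0.0, n - nd)
    return (params.base.fmax_N - params.cf_N) * (1.0 - d) ** exponent + params.cf_N
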