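"""Where the time-based and stroke-based fatigue models agree, and where not.

The two models coincide exactly only where

    (1 - delta)^n(t) = (a*PR + F_max(t)) / (a*PR + F_max),

which for a pure exponential force decay pins a single congruence cadence per
(delta, tau_F) pair:

    tau = 1 / (PR * ln(1/(1 - delta)))        (PR in rev/s)

Away from that cadence the models diverge systematically -- PESA predicts
higher power than PASA at high cadence and late in the sprint, because PASA
decays toward a finite residual force while PESA decays multiplicatively
toward zero.  This module quantifies the divergence over a cadence x time
grid (:func:`divergence_map`), by linear regression of one model's
predictions on the other's at fixed cadence (:func:`regress_predictions`),
and as mean absolute differences per sprint phase (:func:`phase_differences`).

For cadence-resolved comparison both models must share a fatigue-free
baseline.  By default the stroke-based model's peak power at each cadence is
read off the same linear F-v profile that underlies the time-based model, so
every difference in the map is attributable to the decay laws alone; a cubic
power-velocity profile carried by :class:`~sprintfatigue.fatigue.PesaParams`
is used instead when present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fatigue import PasaParams, PesaParams, pasa_per_stroke_decrement, pasa_power
from .profiles import RPM_PER_REV_S, CrankGeometry, CubicPvProfile, linear_power

__all__ = [
    "ConvergenceMap",
    "PredictionRegression",
    "congruent_tau",
    "equivalence_residual",
    "divergence_map",
    "regress_predictions",
    "phase_differences",
    "DEFAULT_CADENCE_GRID",
    "DEFAULT_TIME_GRID",
]

#: cadence 60-180 rpm in 5 rpm steps; spans the competitively relevant range
DEFAULT_CADENCE_GRID = np.arange(60.0, 180.0 + 1e-9, 5.0)
#: time 0-60 s in 0.5 s steps; long enough to expose late-sprint divergence
DEFAULT_TIME_GRID = np.arange(0.0, 60.0 + 1e-9, 0.5)


@dataclass
class ConvergenceMap:
    """Cadence x time grid of inter-model differences with an epsilon corridor.

    ``abs_diff_W`` and ``rel_err`` have shape ``(len(cadence_grid_rpm),
    len(time_grid_s))``; ``rel_err`` is normalised by the time-based (PASA)
    prediction, the reference model.  ``corridor_mask`` marks cells with
    ``rel_err < eps``.
    """

    cadence_grid_rpm: np.ndarray
    time_grid_s: np.ndarray
    p_pasa_W: np.ndarray
    p_pesa_W: np.ndarray
    abs_diff_W: np.ndarray
    rel_err: np.ndarray
    corridor_mask: np.ndarray
    eps: float

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (cadence, time) cell."""
        c, t = np.meshgrid(self.cadence_grid_rpm, self.time_grid_s, indexing="ij")
        return pd.DataFrame(
            {
                "cadence_rpm": c.ravel(),
                "time_s": t.ravel(),
                "P_pasa_W": self.p_pasa_W.ravel(),
                "P_pesa_W": self.p_pesa_W.ravel(),
                "abs_diff_W": self.abs_diff_W.ravel(),
                "rel_err": self.rel_err.ravel(),
                "in_corridor": self.corridor_mask.ravel(),
            }
        )

    def corridor_area_fraction(self) -> float:
        return float(np.mean(self.corridor_mask))

    def plot(self, path: str | None = None):
        """Heatmap of the relative error with the corridor contour."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        im = ax.pcolormesh(
            self.time_grid_s, self.cadence_grid_rpm, self.rel_err,
            shading="auto", cmap="viridis", vmin=0.0,
        )
        ax.contour(
            self.time_grid_s, self.cadence_grid_rpm, self.rel_err,
            levels=[self.eps], colors="white", linewidths=1.5,
        )
        ax.set_xlabel("time [s]")
        ax.set_ylabel("cadence [rpm]")
        ax.set_title(f"|P_PASA - P_PESA| / P_PASA (corridor: < {self.eps:g})")
        fig.colorbar(im, ax=ax, label="relative error")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


@dataclass(frozen=True)
class PredictionRegression:
    """OLS of stroke-based on time-based power predictions at a fixed cadence."""

    cadence_rpm: float
    slope: float
    intercept_W: float
    r2: float


def congruent_tau(delta: float, cadence_rev_s: float) -> float:
    """Time constant at which a per-stroke decrement ``delta`` matches an
    exponential time decay at cadence ``cadence_rev_s`` (rev/s):
    ``tau = 1 / (PR * ln(1/(1 - delta)))``.

    Exact inverse of :func:`~sprintfatigue.fatigue.pasa_per_stroke_decrement`.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    if cadence_rev_s <= 0:
        raise ValueError("cadence_rev_s must be positive")
    return 1.0 / (cadence_rev_s * math.log(1.0 / (1.0 - delta)))


def equivalence_residual(
    pasa: PasaParams,
    pesa: PesaParams,
    cadence_rpm: float,
    t_s: float | np.ndarray,
) -> float | np.ndarray:
    """Deviation from the exact-congruence condition at (cadence, time).

    Returns ``(1 - delta)^max(0, n(t) - ND) - (a*PR + F_max(t))/(a*PR + F_max)``
    under a shared delay convention ``ND = n(TD) = PR * TD`` (real-valued).
    Zero means the stroke-based decay reproduces the time-based relative force
    trajectory exactly at that point; positive values mean the stroke-based
    model sits above.  Raises if the fatigue-free force at ``cadence_rpm`` is
    not positive (beyond PR_max).
    """
    from .fatigue import pasa_fmax_at_time

    pr_rev_s = cadence_rpm / RPM_PER_REV_S
    f0 = pasa.base.slope_a * cadence_rpm + pasa.base.fmax_N
    if f0 <= 0:
        raise ValueError("fatigue-free force must be positive (cadence beyond PR_max)")
    t = np.asarray(t_s, float)
    nd = pr_rev_s * pasa.td_s
    exponent = np.maximum(0.0, pr_rev_s * t - nd)
    lhs = (1.0 - pesa.delta) ** exponent
    rhs = (pasa.base.slope_a * cadence_rpm + pasa_fmax_at_time(pasa, t)) / f0
    out = lhs - rhs
    return out if out.ndim else float(out)


def _pesa_peak_fn(
    pasa: PasaParams,
    pesa: PesaParams,
    geometry: CrankGeometry,
    peak_power: Callable[[np.ndarray], np.ndarray] | None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Cadence-resolved fatigue-free peak power for the stroke-based model."""
    if peak_power is not None:
        return peak_power
    if isinstance(pesa.peak_power_W, CubicPvProfile):
        cubic = pesa.peak_power_W
        return lambda pr: np.asarray(cubic.power(geometry.tangential_speed(pr)), float)
    # shared baseline: both models start from the same linear F-v surface
    return lambda pr: np.asarray(linear_power(pasa.base, geometry, pr), float)


def _pesa_surface(
    pasa: PasaParams,
    pesa: PesaParams,
    geometry: CrankGeometry,
    cadence_rpm: np.ndarray,
    time_s: np.ndarray,
    peak_power: Callable | None,
) -> np.ndarray:
    """(cadence, time) grid of stroke-based power; constant cadence per row."""
    peak = _pesa_peak_fn(pasa, pesa, geometry, peak_power)(cadence_rpm)[:, None]
    pr_rev_s = (cadence_rpm / RPM_PER_REV_S)[:, None]
    exponent = np.maximum(0.0, pr_rev_s * time_s[None, :] - pesa.nd_strokes)
    return peak * (1.0 - pesa.delta) ** exponent


def divergence_map(
    pasa: PasaParams,
    pesa: PesaParams,
    geometry: CrankGeometry,
    cadence_grid_rpm: np.ndarray | None = None,
    time_grid_s: np.ndarray | None = None,
    eps: float = 0.05,
    peak_power: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ConvergenceMap:
    """Absolute and relative inter-model power differences over a grid.

    Each model keeps its own delay (TD in time for PASA, ND in strokes for
    PESA).  ``rel_err = |P_pasa - P_pesa| / P_pasa``; cells where the PASA
    prediction is non-positive (cadence beyond the fatigued PR_max) get
    ``rel_err = inf`` and fall outside every corridor.
    """
    cadence = np.asarray(
        DEFAULT_CADENCE_GRID if cadence_grid_rpm is None else cadence_grid_rpm, float
    )
    time = np.asarray(DEFAULT_TIME_GRID if time_grid_s is None else time_grid_s, float)
    if np.any(np.diff(cadence) <= 0) or np.any(np.diff(time) <= 0):
        raise ValueError("grids must be strictly increasing")

    p_pasa = np.asarray(
        pasa_power(pasa, geometry, cadence[:, None], time[None, :]), float
    )
    p_pesa = _pesa_surface(pasa, pesa, geometry, cadence, time, peak_power)
    abs_diff = np.abs(p_pasa - p_pesa)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(p_pasa > 0, abs_diff / p_pasa, np.inf)
    # eps = inf is the trivial no-filter corridor and admits every cell,
    # including those where the reference prediction is non-positive
    mask = np.ones_like(rel, dtype=bool) if np.isinf(eps) else rel < eps
    return ConvergenceMap(
        cadence_grid_rpm=cadence,
        time_grid_s=time,
        p_pasa_W=p_pasa,
        p_pesa_W=p_pesa,
        abs_diff_W=abs_diff,
        rel_err=rel,
        corridor_mask=mask,
        eps=eps,
    )


def regress_predictions(
    pasa: PasaParams,
    pesa: PesaParams,
    geometry: CrankGeometry,
    cadence_rpm: float,
    time_grid_s: np.ndarray | None = None,
    peak_power: Callable[[np.ndarray], np.ndarray] | None = None,
) -> PredictionRegression:
    """OLS of the stroke-based on the time-based prediction at one cadence.

    A slope of 1 with zero intercept and R^2 = 1 indicates functional
    equivalence over the simulated span; slopes below 1 with positive
    intercepts are the signature of late-sprint divergence.
    """
    time = np.asarray(DEFAULT_TIME_GRID if time_grid_s is None else time_grid_s, float)
    if time.size < 3:
        raise ValueError("regress_predictions needs at least 3 time points")
    x = np.asarray(pasa_power(pasa, geometry, cadence_rpm, time), float)
    y = _pesa_surface(pasa, pesa, geometry, np.array([cadence_rpm]), time, peak_power)[0]
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) time-based predictions")
    res = sps.linregress(x, y)
    return PredictionRegression(
        cadence_rpm=float(cadence_rpm),
        slope=float(res.slope),
        intercept_W=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def phase_differences(
    pasa: PasaParams,
    pesa: PesaParams,
    geometry: CrankGeometry,
    cadence_rpm: float,
    phases: Sequence[tuple[float, float]],
    dt_s: float = 0.1,
    peak_power: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[float]:
    """Mean absolute power difference per sprint-phase window at one cadence.

    A single-instant window ``(t, t)`` yields ``|P_pasa(t) - P_pesa(t)|``.
    """
    out = []
    for t0, t1 in phases:
        if t1 < t0:
            raise ValueError(f"empty phase window ({t0}, {t1})")
        grid = np.array([t0]) if t1 == t0 else np.arange(t0, t1 + 1e-9, dt_s)
        x = np.asarray(pasa_power(pasa, geometry, cadence_rpm, grid), float)
        y = _pesa_surface(pasa, pesa, geometry, np.array([cadence_rpm]), grid, peak_power)[0]
        out.append(float(np.mean(np.abs(x - y))))
    return out
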