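"""Parameter estimation from per-revolution sprint traces.

The calibration pipeline mirrors how an isokinetic sprint test is analysed in
practice:

1. Fatigue-free F-v points are assembled from the first acceleration
   revolutions of the isokinetic sprint (< 3 s) plus high-cadence revolutions
   (>= 160 rpm) from short low-resistance "motoric" sprints, and a linear
   profile is fitted (:func:`select_fatigue_free_points`,
   :func:`~sprintfatigue.profiles.fit_linear_fv`).
2. PASA parameters (A_F, C_F, tau_F, TD) are estimated by constrained
   nonlinear least squares on per-revolution power with a trust-region
   reflective solver (:func:`fit_pasa`), under the physiological constraints
   A_F > C_F > 0, 0 < tau_F < 100 s, TD >= 0.
3. PESA parameters are derived empirically: the stroke delay ND as the last
   stroke preceding a sustained power decline (:func:`detect_nd`), and the
   per-stroke decrement delta as the mean relative per-stroke power loss over
   a window (:func:`estimate_delta`), or by 1-D RMSE minimisation
   (:func:`optimize_delta`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .fatigue import CadenceSeries, PasaParams, PesaParams, pesa_power_exp
from .profiles import (
    RPM_PER_REV_S,
    CrankGeometry,
    FvPoint,
    LinearFvProfile,
    fit_linear_fv,
)

__all__ = [
    "RevolutionSample",
    "SprintTrace",
    "FitResult",
    "DeltaEstimate",
    "select_fatigue_free_points",
    "fit_pasa",
    "detect_nd",
    "estimate_delta",
    "optimize_delta",
    "goodness",
    "target_onset_index",
    "peak_power",
    "calibrate_sprint",
]


@dataclass(frozen=True)
class RevolutionSample:
    """One pedal revolution: 1-based stroke index, end-of-revolution time,
    mean cadence, mean pedal force and mean power over the revolution."""

    index_n: int
    t_s: float
    cadence_rpm: float
    force_N: float
    power_W: float


@dataclass
class SprintTrace:
    """Per-revolution record of one sprint, the unit of all fitting.

    Fields are parallel numpy arrays ordered by revolution.  ``index_n`` is the
    1-based completed-stroke count and must increase by exactly 1;
    ``t_s`` is the end-of-revolution time stamp and must be strictly
    increasing.  ``protocol`` tags the test type (``"isokinetic_45s"`` or
    ``"motoric_6s"``); ``meta`` carries free-form provenance (seed, truth
    parameters, ...).
    """

    index_n: np.ndarray
    t_s: np.ndarray
    cadence_rpm: np.ndarray
    force_N: np.ndarray
    power_W: np.ndarray
    target_cadence_rpm: float | None = None
    geometry: CrankGeometry = field(default_factory=CrankGeometry)
    protocol: str = "isokinetic_45s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("index_n", "t_s", "cadence_rpm", "force_N", "power_W"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = self.index_n.size
        if n == 0:
            raise ValueError("SprintTrace must contain at least one revolution")
        shapes = {getattr(self, f).shape for f in ("index_n", "t_s", "cadence_rpm", "force_N", "power_W")}
        if shapes != {(n,)}:
            raise ValueError("all SprintTrace columns must be 1-D arrays of equal length")
        if np.any(np.diff(self.index_n) != 1):
            raise ValueError("index_n must increase by exactly 1")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")

    def __len__(self) -> int:
        return int(self.index_n.size)

    @property
    def revolutions(self) -> list[RevolutionSample]:
        return [
            RevolutionSample(int(i), float(t), float(c), float(f), float(p))
            for i, t, c, f, p in zip(
                self.index_n, self.t_s, self.cadence_rpm, self.force_N, self.power_W
            )
        ]

    def cadence_series(self) -> CadenceSeries:
        """Piecewise-linear cadence clock anchored at (t=0, first-revolution cadence)."""
        t = np.concatenate([[0.0], self.t_s])
        pr = np.concatenate([[self.cadence_rpm[0]], self.cadence_rpm])
        return CadenceSeries(t, pr)


@dataclass
class FitResult:
    """Outcome of a model fit: parameters, goodness-of-fit and residuals."""

    params: PasaParams | PesaParams
    rmse_W: float
    r2: float
    residuals_W: np.ndarray
    n_used: int
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rmse_W < 0:
            raise ValueError("rmse_W must be non-negative")
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")


@dataclass(frozen=True)
class DeltaEstimate:
    """Empirical per-stroke decrement: mean and SD of relative per-stroke losses."""

    delta: float
    sd: float
    n_losses: int


def select_fatigue_free_points(
    iso: SprintTrace,
    motoric: Sequence[SprintTrace] = (),
    *,
    max_acceleration: int = 4,
    acceleration_window_s: float = 3.0,
    min_motoric_cadence_rpm: float = 160.0,
    max_motoric: int = 3,
) -> list[FvPoint]:
    """Fatigue-free (cadence, force) points for the linear F-v profile.

    Takes the first 3-4 acceleration revolutions of the isokinetic sprint
    (end-of-revolution time < 3 s) plus up to 3 of the highest-power
    revolutions at >= 160 rpm from the motoric sprints.  Raises ``ValueError``
    if fewer than two usable points remain; warns if no motoric points are
    available (the high-cadence end of the profile is then extrapolated).
    """
    accel_mask = iso.t_s < acceleration_window_s
    if iso.target_cadence_rpm is not None:
        accel_mask &= iso.cadence_rpm < iso.target_cadence_rpm
    idx = np.nonzero(accel_mask)[0][:max_acceleration]
    points = [
        FvPoint(float(iso.cadence_rpm[i]), float(iso.force_N[i]), "acceleration") for i in idx
    ]

    candidates: list[tuple[float, FvPoint]] = []
    for tr in motoric:
        sel = np.nonzero(tr.cadence_rpm >= min_motoric_cadence_rpm)[0]
        for i in sel:
            candidates.append(
                (
                    float(tr.power_W[i]),
                    FvPoint(float(tr.cadence_rpm[i]), float(tr.force_N[i]), "motoric"),
                )
            )
    candidates.sort(key=lambda c: -c[0])
    points.extend(p for _, p in candidates[:max_motoric])

    if not any(p.source == "motoric" for p in points):
        warnings.warn(
            "no motoric high-cadence points available; F-v profile relies on "
            "acceleration revolutions only",
            stacklevel=2,
        )
    if len(points) < 2:
        raise ValueError("fewer than 2 usable fatigue-free points")
    return points


def goodness(observed_W: np.ndarray, predicted_W: np.ndarray) -> tuple[float, float]:
    """RMSE (W) and coefficient of determination R^2 about the observed mean."""
    obs = np.asarray(observed_W, float)
    pred = np.asarray(predicted_W, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted power must have equal length")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ssres = float(np.sum(resid**2))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0:  # constant observations: R2 defined only for a perfect fit
        r2 = 1.0 if ssres == 0 else float("-inf")
    else:
        r2 = 1.0 - ssres / sstot
    return rmse, r2


def target_onset_index(trace: SprintTrace, tol_rpm: float = 1.0) -> int:
    """Array index of the first revolution at/above the target cadence."""
    if trace.target_cadence_rpm is None:
        return 0
    hit = np.nonzero(trace.cadence_rpm >= trace.target_cadence_rpm - tol_rpm)[0]
    if hit.size == 0:
        raise ValueError("trace never reaches its target cadence")
    return int(hit[0])


def peak_power(trace: SprintTrace) -> float:
    """Peak per-revolution power at/after reaching the target cadence (PESA's P_peak)."""
    return float(trace.power_W[target_onset_index(trace):].max())


def _pasa_predicted(
    fmax: float, cf: float, tau: float, td: float, slope: float,
    pr_rpm: np.ndarray, t: np.ndarray, speed: np.ndarray,
) -> np.ndarray:
    fmax_t = (fmax - cf) * np.exp(np.minimum(0.0, -(t - td) / tau)) + cf
    return (slope * pr_rpm + fmax_t) * speed


def fit_pasa(
    trace: SprintTrace,
    fv: LinearFvProfile,
    geometry: CrankGeometry | None = None,
    *,
    fix_fmax: bool = True,
    include_acceleration: bool = False,
    max_restarts: int = 5,
    restart_seed: int = 0,
) -> FitResult:
    """Constrained nonlinear least squares for the PASA parameters.

    Minimises the sum of squared power residuals with a trust-region
    reflective solver, by default over the revolutions from target-cadence
    attainment onward: the acceleration revolutions follow a prescribed ramp
    whose role is to supply fatigue-free F-v points, so they carry no decay
    information (set ``include_acceleration=True`` to use them anyway).  By
    default ``F_max`` is fixed to the fatigue-free intercept of ``fv`` (the
    profile is measured independently), leaving (C_F, tau_F, TD) free with
    the ordering constraint A_F > C_F reducing to the box C_F < F_max/2.
    With ``fix_fmax=False`` the amplitude is freed as well via the
    parameterisation (C_F, gap = A_F - C_F, tau, TD), keeping the ordering
    constraint a simple bound.

    Initialisation: tau0 = 30 s, C_F0 = 0.4 F_max, TD0 = time of peak power;
    on solver failure up to ``max_restarts`` multiplicatively jittered restarts
    are attempted (deterministic via ``restart_seed``).  A fit whose C_F lands
    on the ordering boundary is flagged (``flags["boundary"]``).
    """
    geometry = geometry or trace.geometry
    start = 0 if include_acceleration else target_onset_index(trace)
    if len(trace) - start < 10:
        raise ValueError("fit_pasa needs at least 10 revolutions in the fit window")
    pr = np.asarray(trace.cadence_rpm[start:], float)
    t = np.asarray(trace.t_s[start:], float)
    p_obs = np.asarray(trace.power_W[start:], float)
    speed = np.asarray(geometry.tangential_speed(pr), float)
    fmax0 = fv.fmax_N
    slope = fv.slope_a
    t_peak = float(t[np.argmax(p_obs)])
    t_max = float(t[-1])

    if fix_fmax:
        def resid(x: np.ndarray) -> np.ndarray:
            cf, tau, td = x
            return _pasa_predicted(fmax0, cf, tau, td, slope, pr, t, speed) - p_obs

        x0 = np.array([0.4 * fmax0, 30.0, t_peak])
        lo = np.array([1e-6, 1e-3, 0.0])
        hi = np.array([fmax0 / 2.0, 100.0 - 1e-9, t_max])
    else:
        def resid(x: np.ndarray) -> np.ndarray:
            cf, gap, tau, td = x
            fmax = 2.0 * cf + gap
            return _pasa_predicted(fmax, cf, tau, td, slope, pr, t, speed) - p_obs

        x0 = np.array([0.4 * fmax0, 0.2 * fmax0, 30.0, t_peak])
        lo = np.array([1e-6, 0.0, 1e-3, 0.0])
        hi = np.array([np.inf, np.inf, 100.0 - 1e-9, t_max])

    rng = np.random.default_rng(restart_seed)
    best = None
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else np.clip(
            x0 * rng.lognormal(0.0, 0.3, size=x0.size), lo, hi
        )
        try:
            sol = least_squares(resid, start, bounds=(lo, hi), method="trf")
        except Exception as err:  # pragma: no cover - solver-level failure
            last_err = err
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(f"fit_pasa failed to converge after restarts: {last_err}")

    if fix_fmax:
        cf, tau, td = best.x
        fmax = fmax0
        boundary = bool(np.isclose(cf, fmax0 / 2.0, rtol=1e-6))
    else:
        cf, gap, tau, td = best.x
        fmax = 2.0 * cf + gap
        boundary = bool(np.isclose(gap, 0.0, atol=1e-9))
    if boundary:
        warnings.warn("PASA fit pinned to the A_F > C_F constraint boundary", stacklevel=2)

    params = PasaParams(
        base=LinearFvProfile(slope_a=slope, fmax_N=float(fmax)),
        cf_N=float(cf),
        tau_s=float(tau),
        td_s=float(td),
    )
    predicted = _pasa_predicted(fmax, cf, tau, td, slope, pr, t, speed)
    rmse, r2 = goodness(p_obs, predicted)
    return FitResult(
        params=params,
        rmse_W=rmse,
        r2=r2,
        residuals_W=p_obs - predicted,
        n_used=len(trace),
        flags={"boundary": boundary, "fix_fmax": fix_fmax},
    )


def detect_nd(
    trace: SprintTrace,
    *,
    run_length: int = 5,
    tol_W: float = 0.0,
    scan_from_target: bool = True,
) -> int:
    """Stroke delay ND: last stroke preceding a sustained decline in power.

    Scanning (by default) from the first revolution at/above the target
    cadence, returns the smallest stroke index ``k`` such that the next
    ``run_length`` strokes have strictly decreasing mean power
    (``P(k+1) > P(k+2) > ... > P(k+run_length)``, each drop exceeding
    ``tol_W``).  Strictness means ties break a run.  Raises ``ValueError``
    when no such run exists (the trace is not fatiguing).
    """
    if len(trace) < run_length + 1:
        raise ValueError(f"detect_nd needs at least {run_length + 1} revolutions")
    start = target_onset_index(trace) if scan_from_target else 0
    p = np.asarray(trace.power_W, float)
    decreasing = np.diff(p) < -tol_W  # decreasing[i]: p[i+1] < p[i] - tol
    # ND is the stroke at position s where the first run of `run_length`
    # consecutive strict decreases begins: the strokes s+1 .. s+run_length all
    # have monotonically decreasing power, and stroke s is the last one
    # preceding that sustained decline.
    for s in range(start, p.size - run_length):
        if np.all(decreasing[s : s + run_length]):
            return int(trace.index_n[s])
    raise ValueError("no sustained power decline found; trace does not fatigue")


def estimate_delta(
    trace: SprintTrace,
    nd: int,
    window_end_s: float,
) -> DeltaEstimate:
    """Empirical per-stroke decrement: mean relative per-stroke power loss after ND.

    Averages ``1 - P(i+1)/P(i)`` over consecutive revolutions with stroke index
    ``i > nd`` whose successor falls at or before ``window_end_s``.  Also
    returns the SD of the individual losses (the stroke-to-stroke variability
    that grows with fatigue).  Raises ``ValueError`` on an empty window.
    """
    idx = np.asarray(trace.index_n)
    p = np.asarray(trace.power_W, float)
    t = np.asarray(trace.t_s, float)
    pairs = [
        i
        for i in range(p.size - 1)
        if idx[i] > nd and t[i + 1] <= window_end_s
    ]
    if not pairs:
        raise ValueError("estimate_delta window contains no per-stroke losses")
    losses = np.array([1.0 - p[i + 1] / p[i] for i in pairs])
    sd = float(np.std(losses, ddof=1)) if losses.size > 1 else 0.0
    return DeltaEstimate(delta=float(losses.mean()), sd=sd, n_losses=losses.size)


def _pesa_fit_result(
    trace: SprintTrace, delta: float, nd: int, peak: float, start: int
) -> FitResult:
    params = PesaParams(peak_power_W=peak, delta=float(delta), nd_strokes=int(nd))
    n = np.asarray(trace.index_n[start:], float)
    predicted = np.asarray(pesa_power_exp(params, n), float)
    obs = np.asarray(trace.power_W[start:], float)
    rmse, r2 = goodness(obs, predicted)
    return FitResult(
        params=params,
        rmse_W=rmse,
        r2=r2,
        residuals_W=obs - predicted,
        n_used=obs.size,
        flags={},
    )


def evaluate_pesa(trace: SprintTrace, delta: float, nd: int) -> FitResult:
    """Score an exponential-PESA parameterisation against a trace.

    P_peak is the maximum observed power at/after target-cadence attainment,
    and the fit is scored over the revolutions from that point on (the
    single-cadence regime where a scalar P_peak is meaningful).  An empirical
    decrement outside [0, 1) -- possible when a noisy window shows no net
    decline -- is clipped to the admissible range and flagged.
    """
    start = target_onset_index(trace)
    clipped = min(max(delta, 0.0), 1.0 - 1e-9)
    result = _pesa_fit_result(trace, clipped, nd, peak_power(trace), start)
    if clipped != delta:
        result.flags["delta_clipped"] = delta
    return result


def optimize_delta(
    trace: SprintTrace,
    nd: int,
    *,
    bounds: tuple[float, float] = (1e-6, 0.2),
    fit_peak: bool = True,
) -> tuple[float, FitResult]:
    """RMSE-minimising per-stroke decrement with the stroke delay held fixed.

    Bounded 1-D minimisation of the RMSE between observed per-revolution power
    and the exponential PESA prediction; deterministic for a given trace.

    This variant quantifies the stroke-based model under ideal calibration,
    so by default the peak power is concentrated out analytically: for each
    candidate decrement the optimal P_peak is the closed-form linear
    least-squares scale of the decay shape, which avoids the upward bias of
    the noisy single-revolution maximum.  With ``fit_peak=False`` the
    empirical peak (maximum observed post-onset power) is held fixed instead.
    On noise-free traces both variants recover the generating decrement
    exactly.
    """
    start = target_onset_index(trace)
    n = np.asarray(trace.index_n[start:], float)
    obs = np.asarray(trace.power_W[start:], float)
    exponent = np.maximum(0.0, n - nd)
    peak_fixed = peak_power(trace)

    def peak_of(delta: float) -> float:
        if not fit_peak:
            return peak_fixed
        shape = (1.0 - delta) ** exponent
        return float(np.dot(obs, shape) / np.dot(shape, shape))

    def rmse_of(delta: float) -> float:
        pred = peak_of(delta) * (1.0 - delta) ** exponent
        return float(np.sqrt(np.mean((obs - pred) ** 2)))

    sol = minimize_scalar(rmse_of, bounds=bounds, method="bounded",
                          options={"xatol": 1e-10})
    delta_opt = float(sol.x)
    return delta_opt, _pesa_fit_result(trace, delta_opt, nd, peak_of(delta_opt), start)


def calibrate_sprint(
    iso: SprintTrace,
    motoric: Sequence[SprintTrace] = (),
    geometry: CrankGeometry | None = None,
) -> dict:
    """Full single-athlete calibration: F-v profile, PASA fit and PESA variants.

    Returns a flat report dictionary with the conventional parameter names
    (Fmax, a, Pmax, PRopt, AF, tauF, CF, TD, R2, RMSE, Ppeak, Delta15,
    Delta15SD, Delta45, Delta45SD, DeltaOpt, ND and per-model RMSE/R2).  All
    PESA variants and the PASA comparison RMSE are scored over the revolutions
    from target-cadence attainment onward so the model comparison shares one
    revolution set.
    """
    from .profiles import derived_metrics  # local import to avoid cycle noise

    geometry = geometry or iso.geometry
    points = select_fatigue_free_points(iso, motoric)
    fv, fv_r2 = fit_linear_fv(points)
    metrics = derived_metrics(fv, geometry)
    pasa = fit_pasa(iso, fv, geometry)

    # The strict five-decreasing-strokes rule mislocalizes the decline onset
    # on traces whose stroke-to-stroke variability masks the monotone run
    # (uncorrelated multiplicative noise makes adjacent per-stroke losses
    # anti-correlated, so strict runs are rare).  The rule's result is used
    # when it lands within a few strokes of the stroke/time conversion
    # ND = n(TD) from the fitted delay; otherwise the conversion is used.
    from .fatigue import nd_from_td

    nd_conv = nd_from_td(iso.cadence_series(), pasa.params.td_s)
    try:
        nd_rule = detect_nd(iso)
    except ValueError:
        nd_rule = None
    if nd_rule is not None and nd_rule <= nd_conv + 5:
        nd, nd_fallback = nd_rule, False
    else:
        nd, nd_fallback = nd_conv, True
    d15 = estimate_delta(iso, nd, 15.0)
    d45 = estimate_delta(iso, nd, float(iso.t_s[-1]))
    delta_opt, pesa_opt = optimize_delta(iso, nd)
    pesa15 = evaluate_pesa(iso, d15.delta, nd)
    pesa45 = evaluate_pesa(iso, d45.delta, nd)

    # PASA comparison RMSE on the same post-onset revolution set as PESA
    start = target_onset_index(iso)
    from .fatigue import pasa_power

    pasa_pred = np.asarray(
        pasa_power(pasa.params, geometry, iso.cadence_rpm[start:], iso.t_s[start:]), float
    )
    pasa_cmp_rmse, pasa_cmp_r2 = goodness(iso.power_W[start:], pasa_pred)

    return {
        "Fmax": fv.fmax_N,
        "a": fv.slope_a,
        "fv_R2": fv_r2,
        "Pmax": metrics.pmax_W,
        "PRopt": metrics.propt_rpm,
        "PRmax": metrics.prmax_rpm,
        "AF": pasa.params.af_N,
        "tauF": pasa.params.tau_s,
        "CF": pasa.params.cf_N,
        "TD": pasa.params.td_s,
        "R2": pasa.r2,
        "RMSE": pasa.rmse_W,
        "RMSE_PASA": pasa_cmp_rmse,
        "R2_PASA": pasa_cmp_r2,
        "Ppeak": peak_power(iso),
        "ND": nd,
        "ND_from_td_fallback": nd_fallback,
        "Delta15": d15.delta,
        "Delta15SD": d15.sd,
        "Delta45": d45.delta,
        "Delta45SD": d45.sd,
        "DeltaOpt": delta_opt,
        "RMSE_PESA15": pesa15.rmse_W,
        "RMSE_PESA45": pesa45.rmse_W,
        "RMSE_PESAopt": pesa_opt.rmse_W,
        "R2_PESA15": pesa15.r2,
        "R2_PESA45": pesa45.r2,
        "R2_PESAopt": pesa_opt.r2,
    }
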