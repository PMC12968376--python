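"""Synthetic per-revolution sprint traces with the structure the pipeline assumes.

The generator emulates the study conditions the models were designed for: a
45 s maximal isokinetic sprint at 135 rpm with a stationary start and an
acceleration phase of roughly 2.5-3 s, preceded by two 6 s low-resistance
"motoric" sprints that supply fatigue-free force-velocity points at >= 160
rpm.  Athlete parameters are drawn from truncated normal distributions whose
means and SDs match the published elite track-sprint cohort (overall: F_max
1207 +/- 245 N, a -4.53 +/- 0.76 N/rpm, tau_F 38 +/- 12 s, C_F 483 +/- 129 N,
TD 2.55 +/- 0.53 s; sex-specific baselines where a sex is given), subject to
the physiological constraints A_F > C_F > 0, 0 < tau_F < 100, TD >= 0 and an
optimal cadence in 100-160 rpm.  Parameters are drawn independently
(marginal SDs only; real F_max and tau_F may covary).

Power decline follows either the time-based (PASA) or the stroke-based
exponential (PESA) truth model; stroke-to-stroke noise is multiplicative
lognormal with mean 1 and configurable coefficient of variation (default
0.03), optionally growing with elapsed time to emulate the larger
stroke-to-stroke variability seen late in real sprints.  All randomness flows
from a single seed through ``numpy.random.SeedSequence`` spawning, and every
generated trace records its seed and truth parameters in ``meta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .calibration import SprintTrace
from .fatigue import (
    PasaParams,
    PesaParams,
    pasa_force,
    pasa_per_stroke_decrement,
    pasa_power,
    pesa_power_exp,
)
from .profiles import RPM_PER_REV_S, CrankGeometry, LinearFvProfile, linear_force, linear_power

__all__ = [
    "AthleteSpec",
    "ProtocolSpec",
    "NoiseSpec",
    "POPULATION",
    "sample_athlete",
    "generate_sprint",
    "generate_motoric",
    "generate_cohort",
    "to_raw_samples",
]

#: Population parameter distributions (mean, sd) for athlete sampling.
#: "all" pools both sexes; sex-specific baselines differ mainly in F_max and
#: slope, fatigue kinetics being largely sex-invariant.
POPULATION: dict[str, dict[str, tuple[float, float]]] = {
    "all": {
        "fmax_N": (1207.0, 245.0),
        "slope_a": (-4.53, 0.76),
        "tau_s": (38.0, 12.0),
        "cf_N": (483.0, 129.0),
        "td_s": (2.55, 0.53),
    },
    "male": {
        "fmax_N": (1389.0, 157.0),
        "slope_a": (-4.98, 0.63),
        "tau_s": (39.1, 9.2),
        "cf_N": (495.0, 151.0),
        "td_s": (2.55, 0.53),
    },
    "female": {
        "fmax_N": (1026.0, 164.0),
        "slope_a": (-4.07, 0.62),
        "tau_s": (36.5, 15.5),
        "cf_N": (470.0, 117.0),
        "td_s": (2.55, 0.53),
    },
}


@dataclass(frozen=True)
class AthleteSpec:
    """Ground-truth parameters of one synthetic athlete."""

    fv: LinearFvProfile
    pasa: PasaParams
    pesa: PesaParams
    sex: str = "all"
    geometry: CrankGeometry = field(default_factory=CrankGeometry)


@dataclass(frozen=True)
class ProtocolSpec:
    """Sprint protocol: target cadence, duration and the prescribed acceleration ramp.

    The ramp prescribes per-revolution mean cadences as fractions of the
    target; with the default fractions the target is reached within ~2.9 s,
    leaving 3-4 acceleration revolutions below 3 s for the fatigue-free F-v
    profile.  The acceleration phase is prescribed, not simulated -- those
    revolutions only serve as F-v points.
    """

    target_cadence_rpm: float = 135.0
    duration_s: float = 45.0
    accel_fractions: tuple[float, ...] = (0.35, 0.65, 0.85, 0.96)
    motoric_duration_s: float = 6.0
    motoric_fractions: tuple[float, ...] = (0.40, 0.55, 0.68, 0.78, 0.86, 0.91, 0.94)

    def __post_init__(self) -> None:
        accel_span = sum(RPM_PER_REV_S / (f * self.target_cadence_rpm) for f in self.accel_fractions)
        if self.duration_s <= accel_span:
            raise ValueError("duration_s must exceed the acceleration span")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative per-revolution noise: lognormal, mean 1, given CV.

    ``fatigue_growth`` linearly inflates the CV toward the end of the sprint
    (cv(t) = cv * (1 + fatigue_growth * t/duration)), emulating the increase
    of stroke-to-stroke variability with fatigue.
    """

    cv: float = 0.03
    fatigue_growth: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf, tries: int = 1000) -> float:
    for _ in range(tries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("truncated-normal sampling failed")


def sample_athlete(
    seed: int | np.random.Generator,
    sex: Literal["all", "male", "female"] = "all",
    protocol: ProtocolSpec | None = None,
    geometry: CrankGeometry | None = None,
    max_tries: int = 200,
) -> AthleteSpec:
    """Draw one athlete from the population distributions, respecting constraints.

    Parameter sets violating A_F > C_F > 0, 0 < tau_F < 100 or an optimal
    cadence outside 100-160 rpm are resampled (bounded retries).  The
    stroke-based truth is derived from the time-based one: delta is the
    per-stroke decrement of tau_F at the protocol cadence, ND the completed
    strokes during TD at that cadence, and P_peak the fatigue-free power at
    the target cadence -- keeping the two truth families comparable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    protocol = protocol or ProtocolSpec()
    geometry = geometry or CrankGeometry()
    pop = POPULATION[sex]
    # tau is drawn up front so its marginal tracks the population
    # distribution; the joint-constraint screening below redraws the other
    # parameters (marginal SDs come without correlations, so some joint draws
    # are incompatible with an athlete finishing the sprint).  tau itself is
    # redrawn only when no compatible partner parameters exist at all, which
    # concerns the rare fast-decay tail.
    tau = _truncated_normal(rng, *pop["tau_s"], lo=1.0, hi=99.0)
    for attempt in range(max_tries):
        if attempt > 0 and attempt % 50 == 0:
            tau = _truncated_normal(rng, *pop["tau_s"], lo=1.0, hi=99.0)
        fmax = _truncated_normal(rng, *pop["fmax_N"], lo=300.0)
        slope = _truncated_normal(rng, *pop["slope_a"], hi=-0.5)
        cf = _truncated_normal(rng, *pop["cf_N"], lo=50.0)
        td = _truncated_normal(rng, *pop["td_s"], lo=0.3)
        propt = -fmax / (2.0 * slope)
        if not (cf < fmax / 2.0 and 100.0 <= propt <= 160.0):
            continue
        fv = LinearFvProfile(slope_a=slope, fmax_N=fmax)
        pasa = PasaParams(base=fv, cf_N=cf, tau_s=tau, td_s=td)
        # the athlete must sustain physiologically meaningful power at the
        # target cadence through task termination (isokinetic sprints end by
        # time, not by collapse; the sustainable-force asymptote keeps
        # end-of-sprint power well above zero): require >= 5% of the
        # fatigue-free force, ~70 W at 135 rpm for the cohort mean
        f_end = pasa_force(pasa, protocol.target_cadence_rpm, protocol.duration_s)
        f_free = float(linear_force(fv, protocol.target_cadence_rpm))
        if f_end < 0.05 * f_free:
            continue
        pr_rev_s = protocol.target_cadence_rpm / RPM_PER_REV_S
        delta = pasa_per_stroke_decrement(pasa, pr_rev_s)
        nd = math.floor(pr_rev_s * td)
        peak = float(linear_power(fv, geometry, protocol.target_cadence_rpm))
        pesa = PesaParams(peak_power_W=peak, delta=delta, nd_strokes=nd)
        return AthleteSpec(fv=fv, pasa=pasa, pesa=pesa, sex=sex, geometry=geometry)
    raise RuntimeError("sample_athlete: constraint satisfaction failed after retries")


def _revolution_grid(protocol: ProtocolSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-revolution cadences and end-of-revolution times for the isokinetic sprint."""
    cadences = [f * protocol.target_cadence_rpm for f in protocol.accel_fractions]
    t = sum(RPM_PER_REV_S / c for c in cadences)
    iso_dur = RPM_PER_REV_S / protocol.target_cadence_rpm
    while t + iso_dur <= protocol.duration_s + 1e-9:
        cadences.append(protocol.target_cadence_rpm)
        t += iso_dur
    cadence = np.array(cadences)
    times = np.cumsum(RPM_PER_REV_S / cadence)
    return cadence, times


def _apply_noise(
    power: np.ndarray, times: np.ndarray, duration: float,
    noise: NoiseSpec, rng: np.random.Generator,
) -> np.ndarray:
    if noise.cv == 0:
        return power
    cv_t = noise.cv * (1.0 + noise.fatigue_growth * times / duration)
    sigma = np.sqrt(np.log1p(cv_t**2))
    factors = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma)
    return power * factors


def generate_sprint(
    athlete: AthleteSpec,
    protocol: ProtocolSpec | None = None,
    noise: NoiseSpec | None = None,
    truth: Literal["pasa", "pesa"] = "pasa",
    seed: int | np.random.Generator = 0,
) -> SprintTrace:
    """One isokinetic sprint trace governed by the chosen truth model.

    Time stamps are end-of-revolution (cumulative revolution durations).
    Acceleration revolutions carry fatigue-free forces read off the linear
    F-v profile at the ramp cadences -- their analytical role is to supply
    F-v points, not fatigue information.  Isokinetic revolutions follow the
    truth model: the time-based form at each revolution's time stamp (PASA)
    or the exponential stroke decay at integer stroke counts (PESA).  The
    same multiplicative noise factor scales force and power, preserving
    ``P = F * 2*pi*r*PR``; power is clamped at zero.
    """
    protocol = protocol or ProtocolSpec()
    noise = noise or NoiseSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geometry = athlete.geometry

    cadence, times = _revolution_grid(protocol)
    n_accel = len(protocol.accel_fractions)
    index = np.arange(1, cadence.size + 1)

    if truth == "pasa":
        power = np.asarray(pasa_power(athlete.pasa, geometry, cadence, times), float)
    elif truth == "pesa":
        power = np.asarray(pesa_power_exp(athlete.pesa, index), float)
    else:
        raise ValueError(f"unknown truth model {truth!r}")
    power[:n_accel] = np.asarray(linear_power(athlete.fv, geometry, cadence[:n_accel]), float)

    power = np.maximum(0.0, _apply_noise(power, times, protocol.duration_s, noise, rng))
    speed = np.asarray(geometry.tangential_speed(cadence), float)
    force = power / speed
    return SprintTrace(
        index_n=index,
        t_s=times,
        cadence_rpm=cadence,
        force_N=force,
        power_W=power,
        target_cadence_rpm=protocol.target_cadence_rpm,
        geometry=geometry,
        protocol="isokinetic_45s",
        meta={"truth": truth, "noise_cv": noise.cv},
    )


def generate_motoric(
    athlete: AthleteSpec,
    seed: int | np.random.Generator = 0,
    protocol: ProtocolSpec | None = None,
    noise: NoiseSpec | None = None,
) -> SprintTrace:
    """One 6 s low-resistance sprint supplying fatigue-free high-cadence F-v points.

    Per-revolution cadences ramp toward ~94% of the athlete's PR_max (well
    above 160 rpm for elite profiles) and forces sit on the fatigue-free line
    plus multiplicative noise.
    """
    protocol = protocol or ProtocolSpec()
    noise = noise or NoiseSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geometry = athlete.geometry

    prmax = athlete.fv.prmax_rpm
    cadences = [f * prmax for f in protocol.motoric_fractions]
    times = list(np.cumsum([RPM_PER_REV_S / c for c in cadences]))
    top = protocol.motoric_fractions[-1] * prmax
    while times[-1] + RPM_PER_REV_S / top <= protocol.motoric_duration_s:
        cadences.append(top)
        times.append(times[-1] + RPM_PER_REV_S / top)
    cadence = np.array(cadences)
    t = np.array(times)
    power = np.asarray(linear_power(athlete.fv, geometry, cadence), float)
    power = np.maximum(0.0, _apply_noise(power, t, protocol.motoric_duration_s, noise, rng))
    force = power / np.asarray(geometry.tangential_speed(cadence), float)
    return SprintTrace(
        index_n=np.arange(1, cadence.size + 1),
        t_s=t,
        cadence_rpm=cadence,
        force_N=force,
        power_W=power,
        target_cadence_rpm=None,
        geometry=geometry,
        protocol="motoric_6s",
        meta={"noise_cv": noise.cv},
    )


def generate_cohort(
    n: int = 12,
    seed: int = 0,
    sex_split: tuple[int, int] | None = None,
    truth: Literal["pasa", "pesa"] = "pasa",
    protocol: ProtocolSpec | None = None,
    noise: NoiseSpec | None = None,
) -> list[tuple[AthleteSpec, dict]]:
    """A cohort of athletes, each with one isokinetic and two motoric traces.

    ``sex_split = (n_female, n_male)`` must sum to ``n``; ``None`` samples from
    the pooled population.  Deterministic per master seed: each athlete gets
    an independent child seed via ``SeedSequence`` spawning.
    """
    if n < 2:
        raise ValueError("generate_cohort needs n >= 2")
    if sex_split is not None and sum(sex_split) != n:
        raise ValueError(f"sex_split {sex_split} must sum to n={n}")
    sexes = (
        ["female"] * sex_split[0] + ["male"] * sex_split[1]
        if sex_split is not None
        else ["all"] * n
    )
    protocol = protocol or ProtocolSpec()
    noise = noise or NoiseSpec()
    out = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n)):
        rng = np.random.default_rng(child)
        athlete = sample_athlete(rng, sex=sexes[i], protocol=protocol)
        iso = generate_sprint(athlete, protocol, noise, truth=truth, seed=rng)
        motoric = [generate_motoric(athlete, rng, protocol, noise) for _ in range(2)]
        iso.meta["athlete"] = i
        out.append((athlete, {"isokinetic": iso, "motoric": motoric}))
    return out


def to_raw_samples(trace: SprintTrace, fs_hz: float = 200.0):
    """Emit 200 Hz torque/angular-velocity samples, constant within each revolution.

    A testing helper for the raw-sample aggregator: angular velocity and
    torque are held at each revolution's mean, so aggregating the emitted
    series reproduces the per-revolution values (up to sample quantisation).
    Returns a :class:`~sprintfatigue.io.RawSampleSeries`.
    """
    from .io import RawSampleSeries

    dt = 1.0 / fs_hz
    t_edges = np.concatenate([[0.0], np.asarray(trace.t_s, float)])
    t = np.arange(0.0, t_edges[-1], dt)
    rev_of_sample = np.clip(np.searchsorted(t_edges, t, side="right") - 1, 0, len(trace) - 1)
    omega = 2.0 * math.pi * np.asarray(trace.cadence_rpm, float)[rev_of_sample] / RPM_PER_REV_S
    torque = np.asarray(trace.power_W, float)[rev_of_sample] / omega
    return RawSampleSeries(time_s=t, torque_Nm=torque, angular_velocity_rad_s=omega)
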