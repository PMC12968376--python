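"""Trace file format and raw 200 Hz sample aggregation.

The canonical per-revolution trace format is a comma-separated UTF-8 text file
with '.' decimals, ``#``-prefixed ``key: value`` metadata header lines and the
columns ``rev_index, t_s, cadence_rpm, force_N, power_W``.  Time stamps are
end-of-revolution; revolution indices are 1-based completed-stroke counts.
"""

from __future__ import annotations

import io as _stdio
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import SprintTrace
from .profiles import RPM_PER_REV_S, CrankGeometry

__all__ = ["RawSampleSeries", "aggregate_revolutions", "read_trace", "write_trace"]

_COLUMNS = ["rev_index", "t_s", "cadence_rpm", "force_N", "power_W"]


@dataclass(frozen=True)
class RawSampleSeries:
    """Uniformly sampled crank torque and angular velocity (typically 200 Hz)."""

    time_s: np.ndarray
    torque_Nm: np.ndarray
    angular_velocity_rad_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, float)
        if t.size < 2:
            raise ValueError("RawSampleSeries needs at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        if np.any(np.asarray(self.angular_velocity_rad_s, float) < 0):
            raise ValueError("angular velocity must be non-negative")

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(np.diff(self.time_s[:2])[0])


def aggregate_revolutions(
    raw: RawSampleSeries,
    geometry: CrankGeometry | None = None,
    target_cadence_rpm: float | None = None,
) -> SprintTrace:
    """Average raw samples per pedal revolution.

    Revolution boundaries sit at every 2*pi of the integrated angular
    velocity (trapezoidal cumulative angle, linearly interpolated between
    samples).  Per revolution: cadence = 60/duration (rpm), mean power is the
    time average of ``torque * omega`` and mean pedal force is
    ``power / (2*pi*r * cadence_rev_s)``.
    """
    geometry = geometry or CrankGeometry()
    t = np.asarray(raw.time_s, float)
    omega = np.asarray(raw.angular_velocity_rad_s, float)
    power_inst = np.asarray(raw.torque_Nm, float) * omega

    dt = np.diff(t)
    angle = np.concatenate([[0.0], np.cumsum(dt * (omega[:-1] + omega[1:]) / 2.0)])
    if np.any(np.diff(angle) < 0):
        raise ValueError("cumulative crank angle must be non-decreasing")
    n_rev = int(angle[-1] // (2.0 * math.pi))
    if n_rev < 1:
        raise ValueError("raw series spans less than one full revolution")

    # boundary times where the cumulative angle crosses each 2*pi multiple
    targets = 2.0 * math.pi * np.arange(0, n_rev + 1)
    bounds = np.interp(targets, angle, t)

    # cumulative time-integral of instantaneous power for fast window means
    cum_energy = np.concatenate([[0.0], np.cumsum(dt * (power_inst[:-1] + power_inst[1:]) / 2.0)])

    def energy_at(tq: np.ndarray) -> np.ndarray:
        return np.interp(tq, t, cum_energy)

    durations = np.diff(bounds)
    cadence_rpm = RPM_PER_REV_S / durations
    mean_power = np.diff(energy_at(bounds)) / durations
    speed = np.asarray(geometry.tangential_speed(cadence_rpm), float)
    force = mean_power / speed
    return SprintTrace(
        index_n=np.arange(1, n_rev + 1),
        t_s=bounds[1:],
        cadence_rpm=cadence_rpm,
        force_N=force,
        power_W=mean_power,
        target_cadence_rpm=target_cadence_rpm,
        geometry=geometry,
        protocol="isokinetic_45s",
        meta={"aggregated_from_fs_hz": raw.fs_hz},
    )


def write_trace(trace: SprintTrace, path: str | Path) -> None:
    """Write a trace in the canonical delimited format (lossless round trip)."""
    path = Path(path)
    meta = {
        "protocol": trace.protocol,
        "crank_length_m": trace.geometry.crank_length_m,
    }
    if trace.target_cadence_rpm is not None:
        meta["target_cadence_rpm"] = trace.target_cadence_rpm
    for key, value in trace.meta.items():
        if isinstance(value, (str, int, float, bool)):
            meta[f"meta_{key}"] = value
    buf = _stdio.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}: {value}\n")
    df = pd.DataFrame(
        {
            "rev_index": trace.index_n,
            "t_s": trace.t_s,
            "cadence_rpm": trace.cadence_rpm,
            "force_N": trace.force_N,
            "power_W": trace.power_W,
        }
    )
    df.to_csv(buf, index=False, float_format="%.10g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if text in ("True", "False"):
        return text == "True"
    return text


def read_trace(path: str | Path, strict_columns: bool = False) -> SprintTrace:
    """Read a trace written by :func:`write_trace`.

    Raises ``ValueError`` on missing required columns or unsorted times.
    With ``strict_columns`` unexpected extra columns are rejected instead of
    ignored.
    """
    path = Path(path)
    meta: dict = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = _parse_scalar(value.strip())
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_stdio.StringIO("\n".join(lines[body_start:])))
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} missing columns: {missing}")
    extra = [c for c in df.columns if c not in _COLUMNS]
    if extra and strict_columns:
        raise ValueError(f"trace file {path} has unexpected columns: {extra}")

    geometry = CrankGeometry(crank_length_m=float(meta.pop("crank_length_m", 0.17)))
    protocol = str(meta.pop("protocol", "isokinetic_45s"))
    target = meta.pop("target_cadence_rpm", None)
    user_meta = {k[len("meta_"):]: v for k, v in meta.items() if k.startswith("meta_")}
    return SprintTrace(
        index_n=df["rev_index"].to_numpy(int),
        t_s=df["t_s"].to_numpy(float),
        cadence_rpm=df["cadence_rpm"].to_numpy(float),
        force_N=df["force_N"].to_numpy(float),
        power_W=df["power_W"].to_numpy(float),
        target_cadence_rpm=None if target is None else float(target),
        geometry=geometry,
        protocol=protocol,
        meta=user_meta,
    )
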