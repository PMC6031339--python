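"""Linear thermal-time model and degree-minute accumulation.

Developmental rate in poikilotherm embryos is, to good approximation,
linear in temperature within the thermal tolerance range: r = a*T + b.
The x-intercept T0 = -b/a is the developmental zero -- the temperature at
which developmental velocity extrapolates to zero.  Time spent at
temperature T therefore advances development in proportion to (T - T0),
and progress is naturally measured in *degree-minutes* above T0.  A run
of D real minutes at constant T is equivalent to

    D_ref = D * (T - T0) / (T_ref - T0)

minutes at the reference temperature T_ref at which a staging series is
defined (18 degC for Ciona).  This module holds the three-parameter model
(T0, T_ref, sensor offset), the timestamped temperature trace, and the
integration machinery that turns a trace into adjusted minutes.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from ._exceptions import ConfigurationError, TraceValidationError

__all__ = [
    "SENSOR_MIN_C",
    "SENSOR_MAX_C",
    "ThermalModel",
    "TemperatureTrace",
    "ThermalTimeState",
    "calibrate_trace",
    "accumulate_degree_minutes",
    "cumulative_degree_minutes",
    "adjusted_minutes",
    "equivalent_duration",
    "duration_to_reach",
    "constant_trace",
]

#: Physical measurement range of the DS18B20-class digital sensor, degC.
SENSOR_MIN_C = -55.0
SENSOR_MAX_C = 125.0

_RULES = ("left-hold", "trapezoid")


@dataclass(frozen=True)
class ThermalModel:
    """Parameters of the linear clamped thermal-time model.

    Parameters
    ----------
    t0 : float
        Developmental zero temperature (degC).  Below this temperature the
        model assigns zero developmental velocity.
    t_ref : float
        Reference temperature (degC) at which adjusted time is expressed;
        must exceed ``t0``.
    offset : float
        Additive sensor calibration (degC), determined e.g. against an
        ice/water bath; added to every raw reading before any computation.
        Default 0.  Magnitudes above 2 degC trigger a warning (a sensor
        that far off is suspect) but are not rejected.
    """

    t0: float = 7.5
    t_ref: float = 18.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t0", "t_ref", "offset"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if not self.t_ref > self.t0:
            raise ConfigurationError(
                f"t_ref ({self.t_ref} degC) must exceed t0 ({self.t0} degC): "
                "the conversion divisor t_ref - t0 must be positive"
            )
        if abs(self.offset) > 2.0:
            warnings.warn(
                f"sensor offset {self.offset:+.2f} degC exceeds 2 degC; "
                "check the sensor calibration",
                stacklevel=2,
            )

    @property
    def divisor(self) -> float:
        """The conversion divisor t_ref - t0 (degC), strictly positive."""
        return self.t_ref - self.t0


@dataclass(frozen=True)
class TemperatureTrace:
    """A timestamped record of raw temperature readings.

    ``times`` are seconds since run start (strictly increasing, first value
    >= 0); ``temps`` are raw sensor readings in degC, each within the
    sensor's physical range [-55, 125].
    """

    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if times.ndim != 1 or temps.ndim != 1:
            raise TraceValidationError("times and temps must be 1-D sequences")
        if times.size != temps.size:
            raise TraceValidationError(
                f"length mismatch: {times.size} times vs {temps.size} temps"
            )
        if times.size < 1:
            raise TraceValidationError("trace must contain at least one sample")
        if not np.all(np.isfinite(times)) or times[0] < 0:
            raise TraceValidationError("times must be finite and start at >= 0 s")
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            i = int(bad[0]) + 1
            raise TraceValidationError(
                f"times must be strictly increasing; first violation at "
                f"sample index {i} (t={times[i]!r} after t={times[i - 1]!r})"
            )
        if not np.all(np.isfinite(temps)):
            i = int(np.flatnonzero(~np.isfinite(temps))[0])
            raise TraceValidationError(f"non-finite temperature at sample index {i}")
        out = (temps < SENSOR_MIN_C) | (temps > SENSOR_MAX_C)
        if np.any(out):
            i = int(np.flatnonzero(out)[0])
            raise TraceValidationError(
                f"temperature {temps[i]} degC at sample index {i} outside the "
                f"sensor range [{SENSOR_MIN_C}, {SENSOR_MAX_C}] degC"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def split_at(self, index: int) -> tuple["TemperatureTrace", "TemperatureTrace"]:
        """Split at an interior sample, which belongs to both halves, so the
        two integrals add up to the whole."""
        if not 0 < index < len(self) - 1:
            raise ValueError("split index must be interior")
        return (
            TemperatureTrace(self.times[: index + 1], self.temps[: index + 1]),
            TemperatureTrace(self.times[index:], self.temps[index:]),
        )


@dataclass(frozen=True)
class ThermalTimeState:
    """Accumulated thermal-time summary of a run.

    ``degree_minutes`` is cumulative effective temperature (degC*min above
    t0); ``adjusted_min`` is that divided by (t_ref - t0), i.e. the
    equivalent minutes at the reference temperature; ``elapsed_min`` is
    real time; ``mean_temp`` is the time-weighted mean calibrated
    temperature.
    """

    degree_minutes: float
    elapsed_min: float
    adjusted_min: float
    mean_temp: float


def calibrate_trace(trace: TemperatureTrace, model: ThermalModel) -> TemperatureTrace:
    """Apply the model's additive sensor offset to every reading.

    Times are unchanged.  With ``offset == 0`` this returns an equal trace.
    """
    if model.offset == 0.0:
        return trace
    return replace(trace, temps=trace.temps + model.offset)


def _effective(temps_cal: np.ndarray, t0: float, clamp: bool) -> np.ndarray:
    eff = temps_cal - t0
    if clamp:
        eff = np.maximum(eff, 0.0)
    return eff


def accumulate_degree_minutes(
    trace: TemperatureTrace,
    model: ThermalModel,
    rule: str = "left-hold",
    clamp_below_t0: bool = True,
) -> ThermalTimeState:
    """Integrate effective degree-minutes over a temperature trace.

    The default ``left-hold`` rule holds each reading until the next poll,
    matching a sampler that polls once per interval:

        degree_minutes = sum_i max(T_i - t0, 0) * dt_i / 60

    ``trapezoid`` instead averages the clamped integrand at the two ends of
    each interval.  Samples at or below t0 contribute nothing (the model's
    developmental velocity is zero there) unless ``clamp_below_t0=False``,
    which accumulates signed degree-minutes for strict device-comparison
    purposes.

    A single-sample trace spans zero time and yields the all-zero state
    (with a warning); its mean temperature is the lone calibrated reading.
    """
    if rule not in _RULES:
        raise ConfigurationError(f"unknown integration rule {rule!r}; choose from {_RULES}")
    cal = calibrate_trace(trace, model)
    if len(cal) == 1:
        warnings.warn(
            "single-sample trace spans zero time; returning the zero state",
            stacklevel=2,
        )
        return ThermalTimeState(0.0, 0.0, 0.0, float(cal.temps[0]))

    dt_min = np.diff(cal.times) / 60.0
    eff = _effective(cal.temps, model.t0, clamp_below_t0)
    if rule == "left-hold":
        dm = float(np.dot(eff[:-1], dt_min))
        mean_temp = float(np.dot(cal.temps[:-1], dt_min) / dt_min.sum())
    else:
        mid = 0.5 * (eff[:-1] + eff[1:])
        dm = float(np.dot(mid, dt_min))
        mean_temp = float(
            np.dot(0.5 * (cal.temps[:-1] + cal.temps[1:]), dt_min) / dt_min.sum()
        )
    elapsed_min = float(dt_min.sum())
    return ThermalTimeState(
        degree_minutes=dm,
        elapsed_min=elapsed_min,
        adjusted_min=dm / model.divisor,
        mean_temp=mean_temp,
    )


def cumulative_degree_minutes(
    trace: TemperatureTrace,
    model: ThermalModel,
    rule: str = "left-hold",
    clamp_below_t0: bool = True,
) -> np.ndarray:
    """Running degree-minute total at each sample time (first value 0)."""
    if rule not in _RULES:
        raise ConfigurationError(f"unknown integration rule {rule!r}; choose from {_RULES}")
    cal = calibrate_trace(trace, model)
    if len(cal) == 1:
        return np.zeros(1)
    dt_min = np.diff(cal.times) / 60.0
    eff = _effective(cal.temps, model.t0, clamp_below_t0)
    if rule == "left-hold":
        steps = eff[:-1] * dt_min
    else:
        steps = 0.5 * (eff[:-1] + eff[1:]) * dt_min
    out = np.empty(len(cal))
    out[0] = 0.0
    np.cumsum(steps, out=out[1:])
    return out


def adjusted_minutes(
    degree_minutes: Union[float, ThermalTimeState], model: ThermalModel
) -> float:
    """Convert accumulated degree-minutes to minutes at the reference
    temperature by dividing by (t_ref - t0)."""
    if isinstance(degree_minutes, ThermalTimeState):
        degree_minutes = degree_minutes.degree_minutes
    return float(degree_minutes) / model.divisor


def equivalent_duration(duration: float, temp: float, model: ThermalModel) -> float:
    """Reference-temperature equivalent of ``duration`` real minutes spent
    at a constant temperature: D_ref = D * (T - t0) / (t_ref - t0).

    Raises for ``temp <= t0`` -- no development occurs below the
    developmental zero, so there is no finite equivalent.
    """
    if temp <= model.t0:
        raise ConfigurationError(
            f"no development below developmental zero: T={temp} degC <= t0={model.t0} degC"
        )
    return float(duration) * (temp - model.t0) / model.divisor


def duration_to_reach(target_adjusted: float, temp: float, model: ThermalModel) -> float:
    """Real minutes at constant ``temp`` needed to accumulate
    ``target_adjusted`` reference-temperature minutes (inverse of
    :func:`equivalent_duration`); used to plan fixation times."""
    if temp <= model.t0:
        raise ConfigurationError(
            f"no development below developmental zero: T={temp} degC <= t0={model.t0} degC"
        )
    if target_adjusted < 0:
        raise ConfigurationError("target adjusted time must be non-negative")
    return float(target_adjusted) * model.divisor / (temp - model.t0)


def constant_trace(
    temp: float, duration_s: float, interval_s: float = 1.0, start_s: float = 0.0
) -> TemperatureTrace:
    """Convenience constructor: a constant-temperature trace sampled every
    ``interval_s`` seconds, endpoints included."""
    n = int(round(duration_s / interval_s))
    times = start_s + np.arange(n + 1) * interval_s
    return TemperatureTrace(times, np.full(n + 1, float(temp)))
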