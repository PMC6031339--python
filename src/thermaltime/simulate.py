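"""Synthetic temperature trajectories and in-silico validation cohorts.

Real incubators and benchtops do not hold temperature: heaters and coolers
cycle, doors open, probes drift.  This module generates temperature traces
with those features (constant, sinusoid, square-wave incubator cycling,
step excursions, Gaussian sensor noise and 12-bit quantization), simulates
when an embryo with a given thermal budget reaches its landmark under such
a trace, and recreates the device's wet-lab validation design in silico:
sibling cohorts reared at different temperatures, fixed at chosen adjusted
minutes, and scored for whether each embryo is past the landmark.

The landmark model: an embryo reaches the landmark when its accumulated
degree-minutes above the true developmental zero first equal its thermal
budget K.  Embryo-to-embryo variability is multiplicative noise on K --
the simplest mechanism consistent with siblings dividing over a window of
adjusted (not real) time.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, TraceTooShortError
from .core import TemperatureTrace, ThermalModel, cumulative_degree_minutes

__all__ = [
    "TraceProfile",
    "CohortSpec",
    "ValidationResult",
    "generate_trace",
    "simulate_landmark",
    "run_validation_experiment",
]

_KINDS = ("constant", "sinusoid", "incubator-cycle", "excursion")

#: Resolution of a 12-bit DS18B20-class sensor, degC.
DS18B20_STEP = 0.0625


@dataclass(frozen=True)
class TraceProfile:
    """Recipe for one synthetic temperature trajectory.

    ``kind`` selects the base signal: ``constant`` (base_temp throughout),
    ``sinusoid`` (base + amplitude*sin(2*pi*t/period)), ``incubator-cycle``
    (square wave, +amplitude for the first half-period then -amplitude), or
    ``excursion`` (constant base; deviations come only from ``excursions``).
    ``excursions`` -- (start_s, duration_s, delta_c) windows -- are added on
    top of any kind.  Gaussian sensor noise (sd in degC) and quantization to
    the nearest ``quantization_step`` are applied last, in that order.
    """

    kind: str
    base_temp: float
    total_duration: float
    sample_interval: float = 1.0
    amplitude: float = 0.0
    period: float = 3600.0
    excursions: Sequence[tuple[float, float, float]] = ()
    sensor_noise_sd: float = 0.0
    quantization_step: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown trace kind {self.kind!r}; choose from {_KINDS}"
            )
        if self.sample_interval <= 0:
            raise ConfigurationError("sample_interval must be > 0")
        if self.total_duration < self.sample_interval:
            raise ConfigurationError("total_duration must be >= sample_interval")
        if self.amplitude < 0 or self.sensor_noise_sd < 0 or self.quantization_step < 0:
            raise ConfigurationError(
                "amplitude, sensor_noise_sd and quantization_step must be >= 0"
            )
        if self.kind in ("sinusoid", "incubator-cycle") and self.period <= 0:
            raise ConfigurationError("period must be > 0 for periodic kinds")


def generate_trace(profile: TraceProfile) -> TemperatureTrace:
    """Deterministically (given ``profile.seed``) realize a profile as a
    :class:`TemperatureTrace`.  Endpoints are included: 600 s at 1 Hz gives
    601 samples."""
    dt = profile.sample_interval
    n = int(np.floor(profile.total_duration / dt + 1e-9))
    t = np.arange(n + 1) * dt
    if profile.kind == "sinusoid":
        temps = profile.base_temp + profile.amplitude * np.sin(2 * np.pi * t / profile.period)
    elif profile.kind == "incubator-cycle":
        phase = np.mod(t, profile.period)
        temps = profile.base_temp + np.where(
            phase < 0.5 * profile.period, profile.amplitude, -profile.amplitude
        )
    else:  # constant, excursion
        temps = np.full(t.shape, float(profile.base_temp))
    for start, duration, delta in profile.excursions:
        temps = temps + np.where((t >= start) & (t < start + duration), delta, 0.0)
    if profile.sensor_noise_sd > 0:
        rng = np.random.default_rng(profile.seed)
        temps = temps + rng.normal(0.0, profile.sensor_noise_sd, temps.shape)
    if profile.quantization_step > 0:
        temps = np.round(temps / profile.quantization_step) * profile.quantization_step
    # keep pathological noise draws inside the sensor's physical range
    temps = np.clip(temps, -55.0, 125.0)
    return TemperatureTrace(t, temps)


def simulate_landmark(
    trace: TemperatureTrace, true_t0: float, k_embryo: float
) -> float:
    """Real time (minutes) at which cumulative degree-minutes above
    ``true_t0`` first reach the embryo's thermal budget ``k_embryo``.

    Uses the left-hold accumulation rule; the crossing time is linearly
    interpolated within the bracketing sample interval.  Raises
    :class:`TraceTooShortError` (reporting the shortfall) if the trace ends
    before the budget is met.
    """
    if k_embryo < 0:
        raise ConfigurationError("thermal budget must be >= 0")
    # t_ref is irrelevant here; any value above t0 satisfies the model check
    model = ThermalModel(t0=true_t0, t_ref=true_t0 + 1.0, offset=0.0)
    cum = cumulative_degree_minutes(trace, model, rule="left-hold")
    if cum[-1] < k_embryo:
        raise TraceTooShortError(
            f"trace too short: accumulated {cum[-1]:.2f} degC*min of the "
            f"{k_embryo:.2f} degC*min budget (shortfall "
            f"{k_embryo - cum[-1]:.2f} degC*min)"
        )
    i = int(np.searchsorted(cum, k_embryo, side="left"))
    if i == 0:
        return float(trace.times[0]) / 60.0
    # within [t_{i-1}, t_i] accumulation is linear at eff/60 degC*min per s
    dt = trace.times[i] - trace.times[i - 1]
    step = cum[i] - cum[i - 1]
    frac = 0.0 if step == 0 else (k_embryo - cum[i - 1]) / step
    return float(trace.times[i - 1] + frac * dt) / 60.0


@dataclass(frozen=True)
class CohortSpec:
    """Design of an in-silico staging-validation experiment.

    One :class:`TraceProfile` per rearing condition; every embryo draws a
    thermal budget K * (1 + eps), eps ~ N(0, landmark_noise_cv), reaches
    the landmark when its accumulated degree-minutes (above ``true_t0``)
    meet that budget, and is scored past/not-past at each fixation point
    (given in adjusted minutes; exactly at a fixation point counts as
    past).  ``model`` is the timer configuration used to convert to
    adjusted minutes; it defaults to (t0=true_t0, t_ref=18) -- a perfectly
    calibrated device.
    """

    profiles: Mapping[str, TraceProfile]
    true_t0: float = 7.5
    true_k: float = 4200.0
    landmark_noise_cv: float = 0.0
    n_embryos: int = 16
    fixation_points: Sequence[float] = (390.0, 400.0, 410.0)
    seed: Optional[int] = None
    model: Optional[ThermalModel] = None

    def __post_init__(self) -> None:
        if self.true_k <= 0:
            raise ConfigurationError("true_k must be > 0")
        if self.n_embryos < 1:
            raise ConfigurationError("n_embryos must be >= 1")
        if self.landmark_noise_cv < 0:
            raise ConfigurationError("landmark_noise_cv must be >= 0")
        fp = tuple(self.fixation_points)
        if any(b <= a for a, b in zip(fp, fp[1:])):
            raise ConfigurationError("fixation_points must be strictly increasing")

    def timer_model(self) -> ThermalModel:
        return self.model if self.model is not None else ThermalModel(t0=self.true_t0, t_ref=18.0)


@dataclass
class ValidationResult:
    """Tables produced by :func:`run_validation_experiment`.

    ``landmarks``: one row per embryo -- condition, embryo_id, real_min,
    adjusted_min, plus the condition's time-weighted mean temperature.
    ``fractions``: one row per (condition, fixation point) with the
    fraction of embryos already past the landmark.
    """

    landmarks: pd.DataFrame
    fractions: pd.DataFrame

    def condition_means(self) -> pd.DataFrame:
        return self.landmarks.groupby("condition", sort=False)[
            ["real_min", "adjusted_min"]
        ].mean()


def run_validation_experiment(spec: CohortSpec) -> ValidationResult:
    """Simulate the full multi-temperature fixation experiment.

    For each condition: realize the temperature trace, draw per-embryo
    thermal budgets, find each embryo's real landmark time, read the
    timer's adjusted minutes at that moment, and score past/not-past at
    each fixation point.  Deterministic given ``spec.seed`` (condition
    trace seeds are derived from it when a profile does not set its own).
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.timer_model()
    landmark_rows = []
    fraction_rows = []
    for condition, profile in spec.profiles.items():
        if profile.seed is None and (
            profile.sensor_noise_sd > 0 or profile.quantization_step > 0
        ):
            profile = replace(profile, seed=int(rng.integers(2**31)))
        trace = generate_trace(profile)
        # timer-side cumulative degree-minutes (calibrated trace, device t0)
        cum_dev = cumulative_degree_minutes(trace, model)
        eff_dev = np.maximum(trace.temps + model.offset - model.t0, 0.0)
        dt_min = np.diff(trace.times) / 60.0
        mean_temp = float(np.dot(trace.temps[:-1] + model.offset, dt_min) / dt_min.sum())
        if spec.landmark_noise_cv > 0:
            budgets = spec.true_k * (1.0 + rng.normal(0.0, spec.landmark_noise_cv, spec.n_embryos))
            budgets = np.maximum(budgets, 1e-9)
        else:
            budgets = np.full(spec.n_embryos, spec.true_k)
        adjusted = np.empty(spec.n_embryos)
        for e, k in enumerate(budgets):
            real_min = simulate_landmark(trace, spec.true_t0, float(k))
            t_cross = real_min * 60.0
            i = int(np.searchsorted(trace.times, t_cross, side="right")) - 1
            i = min(i, len(trace) - 2)
            dm = cum_dev[i] + eff_dev[i] * (t_cross - trace.times[i]) / 60.0
            adjusted[e] = dm / model.divisor
            landmark_rows.append(
                {
                    "condition": condition,
                    "embryo_id": e,
                    "real_min": real_min,
                    "adjusted_min": adjusted[e],
                    "mean_temp_c": mean_temp,
                }
            )
        for fp in spec.fixation_points:
            fraction_rows.append(
                {
                    "condition": condition,
                    "fixation_adj_min": float(fp),
                    "fraction_past": float(np.mean(adjusted <= fp)),
                }
            )
    return ValidationResult(pd.DataFrame(landmark_rows), pd.DataFrame(fraction_rows))
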