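"""Faithful emulation of the timer firmware's polling loop.

The physical instrument polls its temperature probe once per second and
keeps its cumulative tally as an *integer* number of degree-milliseconds
above t0 (integer arithmetic on a microcontroller).  This module replays
that loop in software: per polling interval it adds
floor(max(T - t0, 0) * dt_ms) degree-milliseconds (truncation being the
conservative reading of integer accumulation), tracks elapsed
milliseconds, and derives the four displayed quantities -- current
temperature, running mean temperature, elapsed minutes and adjusted
minutes.  A reset (the button pressed at fertilization) zeroes all
accumulators mid-stream; subsequent values are independent of anything
before the reset.

The float pipeline in :mod:`thermaltime.core` is the reference; the
integer path agrees with it to better than 1e-3 relative on runs of ten
minutes or more, which is the contract this emulator is tested against.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .core import TemperatureTrace, ThermalModel

__all__ = ["DeviceState", "emulate_device"]


@dataclass(frozen=True)
class DeviceState:
    """Snapshot of the device's accumulators at one polling instant."""

    time_s: float
    degree_ms: int
    elapsed_ms: int
    current_temp: float
    mean_temp: float

    def adjusted_min(self, model: ThermalModel) -> float:
        """Adjusted minutes before display rounding."""
        return self.degree_ms / (60000.0 * model.divisor)

    def elapsed_min(self) -> float:
        return self.elapsed_ms / 60000.0

    def display(self, model: ThermalModel) -> tuple[float, float, float, float]:
        """(current temp, mean temp, elapsed min, adjusted min) rounded to
        the display's precision (0.1 degC, 0.1 min)."""
        return (
            round(self.current_temp, 1),
            round(self.mean_temp, 1),
            round(self.elapsed_min(), 1),
            round(self.adjusted_min(model), 1),
        )


def emulate_device(
    trace: TemperatureTrace,
    model: ThermalModel,
    reset_at_s: Optional[float] = None,
) -> list[DeviceState]:
    """Replay the polling loop over ``trace`` and return one
    :class:`DeviceState` per sample.

    Each interval's contribution is computed from the reading at the start
    of the interval (sample-and-hold, like the firmware).  If
    ``reset_at_s`` is given, all accumulators are zeroed at the first
    sample whose time is >= that value.
    """
    degree_ms = 0
    elapsed_ms = 0
    temp_dt_sum = 0.0  # degC * ms, for the running mean
    states: list[DeviceState] = []
    t0 = model.t0
    did_reset = reset_at_s is None
    prev_time = None
    prev_temp = None
    for time_s, raw in zip(trace.times, trace.temps):
        temp = raw + model.offset
        if prev_time is not None:
            dt_ms = int(round((time_s - prev_time) * 1000.0))
            contrib = prev_temp - t0
            if contrib > 0:
                degree_ms += math.floor(contrib * dt_ms)
            elapsed_ms += dt_ms
            temp_dt_sum += prev_temp * dt_ms
        if not did_reset and time_s >= reset_at_s:
            degree_ms = 0
            elapsed_ms = 0
            temp_dt_sum = 0.0
            did_reset = True
        mean_temp = temp if elapsed_ms == 0 else temp_dt_sum / elapsed_ms
        states.append(
            DeviceState(
                time_s=float(time_s),
                degree_ms=degree_ms,
                elapsed_ms=elapsed_ms,
                current_temp=float(temp),
                mean_temp=float(mean_temp),
            )
        )
        prev_time = time_s
        prev_temp = temp
    return states
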