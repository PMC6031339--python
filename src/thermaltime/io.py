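"""CSV readers/writers and run configuration.

Three small text formats, all UTF-8 with ``#`` comment lines:

* temperature log -- header ``time_s,temp_c`` (float seconds from run
  start) or ``timestamp_iso,temp_c`` (ISO-8601 timestamps, converted to
  seconds from the first row);
* rate table -- header ``temp_c,duration_min``, one row per landmark
  observation;
* staging series -- header ``stage_label,ordinal,onset_adjusted_min``,
  optional ``#total=<minutes>`` comment for the full staged window.

Parsing uses the stdlib csv module so malformed rows can be reported with
their line numbers.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterator, Optional, Sequence, TextIO, Union

import numpy as np

from ._exceptions import ConfigurationError, TableFormatError
from .core import (
    TemperatureTrace,
    ThermalModel,
    accumulate_degree_minutes,
    calibrate_trace,
)
from .estimate import RateObservation
from .staging import StageAnchor, StagingSeries

__all__ = [
    "RunConfig",
    "read_temperature_log",
    "write_temperature_log",
    "read_rate_table",
    "write_rate_table",
    "read_staging_series",
    "write_staging_series",
    "read_config",
    "summarize_run",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class RunConfig:
    """Timer configuration: the three device parameters plus the two
    library-side integration switches."""

    t0_c: float = 7.5
    tref_c: float = 18.0
    offset_c: float = 0.0
    integration_rule: str = "left-hold"
    clamp_below_t0: bool = True

    def __post_init__(self) -> None:
        if self.integration_rule not in ("left-hold", "trapezoid"):
            raise ConfigurationError(
                f"unknown integration rule {self.integration_rule!r}"
            )
        # delegates the tref > t0 check
        self.thermal_model()

    def thermal_model(self) -> ThermalModel:
        return ThermalModel(t0=self.t0_c, t_ref=self.tref_c, offset=self.offset_c)


def _data_rows(fh: TextIO) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank rows."""
    for lineno, row in enumerate(csv.reader(fh), start=1):
        if not row or not "".join(row).strip():
            continue
        if row[0].lstrip().startswith("#"):
            continue
        yield lineno, [f.strip() for f in row]


def _parse_float(value: str, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise TableFormatError(
            f"line {lineno}: cannot parse {what} from {value!r}"
        ) from None


def read_temperature_log(path: PathLike) -> TemperatureTrace:
    """Read a temperature log CSV into a validated trace.

    Accepts either the ``time_s,temp_c`` or the ``timestamp_iso,temp_c``
    dialect; out-of-order timestamps are an error naming the line.
    """
    times: list[float] = []
    temps: list[float] = []
    iso_origin: Optional[datetime] = None
    header: Optional[list[str]] = None
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in _data_rows(fh):
            if header is None:
                header = [h.lower() for h in row]
                if header not in (["time_s", "temp_c"], ["timestamp_iso", "temp_c"]):
                    raise TableFormatError(
                        f"line {lineno}: expected header 'time_s,temp_c' or "
                        f"'timestamp_iso,temp_c', got {','.join(row)!r}"
                    )
                continue
            if len(row) != 2:
                raise TableFormatError(f"line {lineno}: expected 2 fields, got {len(row)}")
            if header[0] == "time_s":
                t = _parse_float(row[0], lineno, "time_s")
            else:
                try:
                    stamp = datetime.fromisoformat(row[0])
                except ValueError:
                    raise TableFormatError(
                        f"line {lineno}: cannot parse ISO-8601 timestamp {row[0]!r}"
                    ) from None
                if iso_origin is None:
                    iso_origin = stamp
                t = (stamp - iso_origin).total_seconds()
            if times and t <= times[-1]:
                raise TableFormatError(
                    f"line {lineno}: time {t} s is not after the previous sample "
                    f"({times[-1]} s); log must be strictly increasing in time"
                )
            times.append(t)
            temps.append(_parse_float(row[1], lineno, "temp_c"))
    if header is None or not times:
        raise TableFormatError(f"{path}: no temperature samples found")
    return TemperatureTrace(np.array(times), np.array(temps))


def write_temperature_log(trace: TemperatureTrace, path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "temp_c"])
        for t, c in zip(trace.times, trace.temps):
            w.writerow([repr(float(t)), repr(float(c))])


def read_rate_table(path: PathLike) -> list[RateObservation]:
    """Read (temperature, time-to-landmark) observations; rate = 1/duration
    is derived on construction."""
    obs: list[RateObservation] = []
    header = None
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in _data_rows(fh):
            if header is None:
                header = [h.lower() for h in row]
                if header != ["temp_c", "duration_min"]:
                    raise TableFormatError(
                        f"line {lineno}: expected header 'temp_c,duration_min', "
                        f"got {','.join(row)!r}"
                    )
                continue
            if len(row) != 2:
                raise TableFormatError(f"line {lineno}: expected 2 fields, got {len(row)}")
            temp = _parse_float(row[0], lineno, "temp_c")
            duration = _parse_float(row[1], lineno, "duration_min")
            if duration <= 0:
                raise TableFormatError(f"line {lineno}: non-positive duration {duration}")
            obs.append(RateObservation(temp=temp, duration=duration))
    if not obs:
        raise TableFormatError(f"{path}: no observations")
    return obs


def write_rate_table(observations: Sequence[RateObservation], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["temp_c", "duration_min"])
        for o in observations:
            w.writerow([repr(float(o.temp)), repr(float(o.duration))])


def read_staging_series(path: PathLike) -> StagingSeries:
    anchors: list[StageAnchor] = []
    total: Optional[float] = None
    header = None
    with open(path, encoding="utf-8") as fh:
        text_lines = fh.read().splitlines()
    for lineno, line in enumerate(text_lines, start=1):
        stripped = line.strip()
        if stripped.startswith("#total="):
            total = _parse_float(stripped.split("=", 1)[1], lineno, "total_adjusted_min")
    import io as _io

    with _io.StringIO("\n".join(text_lines)) as fh:
        for lineno, row in _data_rows(fh):
            if header is None:
                header = [h.lower() for h in row]
                if header != ["stage_label", "ordinal", "onset_adjusted_min"]:
                    raise TableFormatError(
                        f"line {lineno}: expected header "
                        f"'stage_label,ordinal,onset_adjusted_min', got {','.join(row)!r}"
                    )
                continue
            if len(row) != 3:
                raise TableFormatError(f"line {lineno}: expected 3 fields, got {len(row)}")
            anchors.append(
                StageAnchor(
                    label=row[0],
                    ordinal=_parse_float(row[1], lineno, "ordinal"),
                    onset_adjusted_min=_parse_float(row[2], lineno, "onset_adjusted_min"),
                )
            )
    if len(anchors) < 2:
        raise TableFormatError(f"{path}: staging series needs >= 2 anchors")
    if total is None:
        total = anchors[-1].onset_adjusted_min
    return StagingSeries(anchors=anchors, total_adjusted_min=total)


def write_staging_series(series: StagingSeries, path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"#total={repr(float(series.total_adjusted_min))}\n")
        w = csv.writer(fh)
        w.writerow(["stage_label", "ordinal", "onset_adjusted_min"])
        for a in series.anchors:
            w.writerow([a.label, repr(float(a.ordinal)), repr(float(a.onset_adjusted_min))])


_CONFIG_KEYS = {"t0_c", "tref_c", "offset_c", "integration_rule", "clamp_below_t0"}


def read_config(path: PathLike) -> RunConfig:
    """Read a run configuration from a ``key=value`` file (or JSON if the
    file starts with ``{``).  Unknown keys are an error; missing keys take
    the device defaults (t0 7.5, t_ref 18.0, offset 0)."""
    text = Path(path).read_text(encoding="utf-8")
    values: dict = {}
    if text.lstrip().startswith("{"):
        values = json.loads(text)
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "=" not in stripped:
                raise TableFormatError(f"line {lineno}: expected key=value, got {line!r}")
            key, _, value = stripped.partition("=")
            values[key.strip()] = value.strip()
    unknown = set(values) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("t0_c", "tref_c", "offset_c"):
        if key in values:
            kwargs[key] = float(values[key])
    if "integration_rule" in values:
        kwargs["integration_rule"] = str(values["integration_rule"])
    if "clamp_below_t0" in values:
        v = values["clamp_below_t0"]
        kwargs["clamp_below_t0"] = (
            v if isinstance(v, bool) else str(v).lower() in ("1", "true", "yes")
        )
    return RunConfig(**kwargs)


def summarize_run(trace: TemperatureTrace, config: RunConfig) -> dict:
    """The displayed quantities for a run: current (last calibrated)
    temperature, time-weighted mean temperature, elapsed minutes, adjusted
    minutes, plus the configuration echo."""
    model = config.thermal_model()
    state = accumulate_degree_minutes(
        trace, model, rule=config.integration_rule, clamp_below_t0=config.clamp_below_t0
    )
    current = float(calibrate_trace(trace, model).temps[-1])
    return {
        "current_temp_c": current,
        "mean_temp_c": state.mean_temp,
        "elapsed_min": state.elapsed_min,
        "adjusted_min": state.adjusted_min,
        "degree_minutes": state.degree_minutes,
        "n_samples": len(trace),
        "t0_c": config.t0_c,
        "tref_c": config.tref_c,
        "offset_c": config.offset_c,
        "integration_rule": config.integration_rule,
    }
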