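"""Mapping adjusted time onto a discrete embryonic staging series.

A staging series is an ordered set of named stages, each with a known
onset time at the reference temperature.  Given a running total of
adjusted minutes, two convenient readouts are:

* a continuous stage value ("Stage 3.35"), obtained by linear
  interpolation of the stage ordinal between the bracketing onsets; and
* percent of normal development ("17%"), the adjusted time as a fraction
  of the staged window.

Interpolation is linear in adjusted time, consistent with the thermal-time
premise that development advances uniformly in degree-minutes.  Stage
intervals are half-open [onset_i, onset_{i+1}); queries at or beyond the
final onset return the final ordinal (staging beyond the series is
undefined biology, so no extrapolation), and queries before the first
onset return ``None`` as a pre-series sentinel.

The package ships no canonical stage table -- onset times belong to the
organism's published staging series -- so users supply a CSV with header
``stage_label,ordinal,onset_adjusted_min`` and an optional ``#total=``
comment giving the full-window duration.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._exceptions import ConfigurationError

__all__ = ["StageAnchor", "StagingSeries", "continuous_stage", "percent_development"]


@dataclass(frozen=True)
class StageAnchor:
    """One stage: its label, numeric ordinal, and onset in adjusted minutes."""

    label: str
    ordinal: float
    onset_adjusted_min: float

    def __post_init__(self) -> None:
        if self.onset_adjusted_min < 0:
            raise ConfigurationError(
                f"stage {self.label!r}: onset must be >= 0 adjusted min"
            )


@dataclass(frozen=True)
class StagingSeries:
    """Ordered stage anchors plus the total adjusted duration of the staged
    window (used for the percent-development readout)."""

    anchors: Sequence[StageAnchor]
    total_adjusted_min: float

    def __post_init__(self) -> None:
        anchors = tuple(self.anchors)
        object.__setattr__(self, "anchors", anchors)
        if len(anchors) < 2:
            raise ConfigurationError("staging series needs >= 2 anchors")
        onsets = [a.onset_adjusted_min for a in anchors]
        ordinals = [a.ordinal for a in anchors]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ConfigurationError("anchor onset times must be strictly increasing")
        if any(b <= a for a, b in zip(ordinals, ordinals[1:])):
            raise ConfigurationError("anchor ordinals must be strictly increasing")
        if self.total_adjusted_min < onsets[-1]:
            raise ConfigurationError(
                "total_adjusted_min must be >= the last anchor onset"
            )

    @property
    def onsets(self) -> np.ndarray:
        return np.array([a.onset_adjusted_min for a in self.anchors])

    @property
    def ordinals(self) -> np.ndarray:
        return np.array([a.ordinal for a in self.anchors])

    @classmethod
    def from_csv(cls, path) -> "StagingSeries":
        from .io import read_staging_series

        return read_staging_series(path)


def continuous_stage(adjusted_min: float, series: StagingSeries) -> Optional[float]:
    """Continuous stage value at ``adjusted_min``, or ``None`` before the
    first anchor's onset.

    Linear interpolation of ordinal between the bracketing onsets; exactly
    the anchor's ordinal at its onset; the final ordinal at or beyond the
    final onset.
    """
    onsets = series.onsets
    ordinals = series.ordinals
    if adjusted_min < onsets[0]:
        return None
    if adjusted_min >= onsets[-1]:
        return float(ordinals[-1])
    return float(np.interp(adjusted_min, onsets, ordinals))


def invert_continuous_stage(stage: float, series: StagingSeries) -> float:
    """Adjusted minutes at which ``stage`` is reached (inverse of
    :func:`continuous_stage` on [first ordinal, last ordinal])."""
    ordinals = series.ordinals
    if not ordinals[0] <= stage <= ordinals[-1]:
        raise ConfigurationError(
            f"stage {stage} outside the series range [{ordinals[0]}, {ordinals[-1]}]"
        )
    return float(np.interp(stage, ordinals, series.onsets))


def percent_development(adjusted_min: float, series: StagingSeries) -> float:
    """100 * adjusted_min / total window, capped at 100."""
    if series.total_adjusted_min <= 0:
        raise ConfigurationError("total_adjusted_min must be positive")
    if adjusted_min < 0:
        raise ConfigurationError("adjusted_min must be >= 0")
    return min(100.0, 100.0 * adjusted_min / series.total_adjusted_min)
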