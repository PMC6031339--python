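"""Estimation of the developmental zero temperature T0 and thermal constant K.

Growing embryos at several temperatures and timing a fixed landmark gives
pairs (T, D).  Developmental rate is the reciprocal r = 1/D, and under the
linear model r = a*T + b.  Ordinary least squares of rate on temperature
yields the developmental zero T0 = -b/a (the x-intercept) and the thermal
constant K = 1/a (degree-minutes above T0 needed to reach the landmark).

The regression is deliberately of *rate* on temperature, not duration on
temperature: the two give different estimators under noise, and the linear
law holds on the rate scale.  Replicates at the same temperature enter as
independent observations.  Uncertainty on the x-intercept ratio -b/a is
quantified by a nonparametric case-resampling bootstrap; the ratio's
sampling distribution is heavy-tailed when the slope is small, which makes
the delta method unreliable here.

Exposed both as plain functions (:func:`estimate_t0`,
:func:`bootstrap_t0_ci`, :func:`thermal_constant`) and as a model/results
pair (:class:`DevelopmentalRateModel` -> :class:`T0Results`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._exceptions import (
    ConfigurationError,
    DegenerateDesignError,
    NonPositiveSlopeError,
    UnstableDesignError,
)

__all__ = [
    "RateObservation",
    "T0Estimate",
    "BootstrapCI",
    "estimate_t0",
    "bootstrap_t0_ci",
    "thermal_constant",
    "DevelopmentalRateModel",
    "T0Results",
]


@dataclass(frozen=True)
class RateObservation:
    """One (rearing temperature, time-to-landmark) observation.

    ``rate`` is the derived developmental rate 1/duration (per minute).
    """

    temp: float
    duration: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.temp):
            raise ConfigurationError(f"temperature must be finite, got {self.temp!r}")
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ConfigurationError(
                f"non-positive duration: {self.duration!r} (landmark times must be > 0 min)"
            )

    @property
    def rate(self) -> float:
        return 1.0 / self.duration


@dataclass(frozen=True)
class T0Estimate:
    """Fitted rate-vs-temperature line and derived thermal parameters."""

    slope_a: float
    intercept_b: float
    t0_hat: float
    k_hat: float
    r_squared: float
    n_obs: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: Optional[float] = None
    n_boot: Optional[int] = None
    n_discarded: Optional[int] = None


class BootstrapCI(NamedTuple):
    ci_low: float
    ci_high: float
    n_discarded: int
    n_boot: int


def _as_arrays(observations: Sequence[RateObservation]) -> tuple[np.ndarray, np.ndarray]:
    temps = np.array([o.temp for o in observations], dtype=float)
    rates = np.array([o.rate for o in observations], dtype=float)
    return temps, rates


def estimate_t0(observations: Sequence[RateObservation]) -> T0Estimate:
    """OLS of rate on temperature; returns slope, intercept, T0 = -b/a,
    K = 1/a and R-squared.

    Raises
    ------
    DegenerateDesignError
        Fewer than two observations or fewer than two distinct temperatures.
    NonPositiveSlopeError
        Fitted slope <= 0: development does not speed up with temperature in
        these data, so no developmental zero exists in the model's range.
    """
    if len(observations) < 2:
        raise DegenerateDesignError(
            f"degenerate design: need >= 2 observations, got {len(observations)}"
        )
    temps, rates = _as_arrays(observations)
    if np.unique(temps).size < 2:
        raise DegenerateDesignError(
            "degenerate design: need observations at >= 2 distinct temperatures"
        )
    fit = sm.OLS(rates, sm.add_constant(temps)).fit()
    b, a = float(fit.params[0]), float(fit.params[1])
    if a <= 0:
        raise NonPositiveSlopeError(
            f"non-positive slope: no developmental zero in model range (a={a:.3g})"
        )
    return T0Estimate(
        slope_a=a,
        intercept_b=b,
        t0_hat=-b / a,
        k_hat=1.0 / a,
        r_squared=float(fit.rsquared),
        n_obs=len(observations),
    )


def _batch_ols_t0(temps: np.ndarray, rates: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Closed-form per-row OLS x-intercepts for resample index matrix ``idx``
    (shape n_draws x n).  Rows with <2 distinct temperatures or slope <= 0
    come back NaN."""
    t = temps[idx]
    r = rates[idx]
    t_bar = t.mean(axis=1)
    r_bar = r.mean(axis=1)
    s_tt = (t * t).mean(axis=1) - t_bar**2
    s_tr = (t * r).mean(axis=1) - t_bar * r_bar
    with np.errstate(divide="ignore", invalid="ignore"):
        a = s_tr / s_tt
        b = r_bar - a * t_bar
        t0 = -b / a
    t0[~((s_tt > 0) & (a > 0))] = np.nan
    return t0


def bootstrap_t0_ci(
    observations: Sequence[RateObservation],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> BootstrapCI:
    """Percentile bootstrap interval for T0 by case resampling.

    Resamples that are degenerate (fewer than two distinct temperatures) or
    give a non-positive slope are discarded and redrawn; the discard count
    is reported.  If more than half of all draws are discarded the design
    is declared unstable and an error is raised.
    """
    if len(observations) < 3:
        raise DegenerateDesignError(
            f"bootstrap needs >= 3 observations, got {len(observations)}"
        )
    if n_boot < 100:
        raise ConfigurationError(f"n_boot must be >= 100, got {n_boot}")
    if not 0 < level < 1:
        raise ConfigurationError(f"level must be in (0, 1), got {level}")
    temps, rates = _as_arrays(observations)
    if np.unique(temps).size < 2:
        raise DegenerateDesignError(
            "degenerate design: need observations at >= 2 distinct temperatures"
        )
    rng = np.random.default_rng(seed)
    n = len(observations)
    collected: list[np.ndarray] = []
    n_kept = 0
    n_drawn = 0
    n_discarded = 0
    while n_kept < n_boot:
        need = n_boot - n_kept
        idx = rng.integers(0, n, size=(need, n))
        t0s = _batch_ols_t0(temps, rates, idx)
        ok = t0s[np.isfinite(t0s)]
        n_drawn += need
        n_discarded += need - ok.size
        n_kept += ok.size
        collected.append(ok)
        if n_drawn >= n_boot and n_discarded > 0.5 * n_drawn:
            raise UnstableDesignError(
                f"unstable design: {n_discarded}/{n_drawn} bootstrap resamples "
                "were degenerate or had non-positive slope"
            )
    t0s = np.concatenate(collected)[:n_boot]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(t0s, [alpha, 1.0 - alpha])
    return BootstrapCI(float(lo), float(hi), n_discarded, n_boot)


def thermal_constant(duration: float, temp: float, t0: float) -> float:
    """Thermal constant K = D * (T - t0): the degree-minutes above the
    developmental zero accumulated in reaching the landmark."""
    if temp <= t0:
        raise ConfigurationError(
            f"no development below developmental zero: T={temp} degC <= t0={t0} degC"
        )
    if duration <= 0:
        raise ConfigurationError(f"duration must be > 0, got {duration}")
    return float(duration) * (temp - t0)


class DevelopmentalRateModel:
    """Linear developmental-rate model r = a*T + b built from
    (temperature, time-to-landmark) observations.

    Examples
    --------
    >>> obs = [RateObservation(18.0, 400.0), RateObservation(21.1, 308.8235)]
    >>> res = DevelopmentalRateModel(obs).fit(bootstrap=False)
    >>> round(res.t0_hat, 3)
    7.5
    """

    def __init__(self, observations: Sequence[RateObservation]):
        self.observations = list(observations)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        temp_col: str = "temp_c",
        duration_col: str = "duration_min",
    ) -> "DevelopmentalRateModel":
        obs = [
            RateObservation(float(t), float(d))
            for t, d in zip(data[temp_col], data[duration_col])
        ]
        return cls(obs)

    @classmethod
    def from_csv(cls, path) -> "DevelopmentalRateModel":
        from .io import read_rate_table

        return cls(read_rate_table(path))

    def fit(
        self,
        bootstrap: bool = True,
        n_boot: int = 1000,
        seed: Optional[int] = None,
        level: float = 0.95,
    ) -> "T0Results":
        est = estimate_t0(self.observations)
        if bootstrap and len(self.observations) >= 3:
            ci = bootstrap_t0_ci(self.observations, n_boot=n_boot, seed=seed, level=level)
            est = T0Estimate(
                slope_a=est.slope_a,
                intercept_b=est.intercept_b,
                t0_hat=est.t0_hat,
                k_hat=est.k_hat,
                r_squared=est.r_squared,
                n_obs=est.n_obs,
                ci_low=ci.ci_low,
                ci_high=ci.ci_high,
                ci_level=level,
                n_boot=ci.n_boot,
                n_discarded=ci.n_discarded,
            )
        return T0Results(self, est)


class T0Results:
    """Results wrapper carrying the point estimates, bootstrap interval and
    a human-readable summary table."""

    def __init__(self, model: DevelopmentalRateModel, estimate: T0Estimate):
        self.model = model
        self.estimate = estimate

    def __getattr__(self, name):
        # delegate t0_hat, k_hat, slope_a, ... to the estimate dataclass
        try:
            return getattr(self.estimate, name)
        except AttributeError:
            raise AttributeError(name) from None

    def to_dict(self) -> dict:
        d = {
            "slope_a_per_degC_min": self.estimate.slope_a,
            "intercept_b_per_min": self.estimate.intercept_b,
            "t0_c": self.estimate.t0_hat,
            "k_deg_min": self.estimate.k_hat,
            "r_squared": self.estimate.r_squared,
            "n_obs": self.estimate.n_obs,
        }
        if self.estimate.ci_low is not None:
            d.update(
                t0_ci_low_c=self.estimate.ci_low,
                t0_ci_high_c=self.estimate.ci_high,
                ci_level=self.estimate.ci_level,
                n_boot=self.estimate.n_boot,
                n_boot_discarded=self.estimate.n_discarded,
            )
        return d

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Developmental rate model: r = a*T + b (OLS of rate on temperature)",
            f"  n observations       {e.n_obs}",
            f"  slope a              {e.slope_a:.6g} /(degC*min)",
            f"  intercept b          {e.intercept_b:.6g} /min",
            f"  R-squared            {e.r_squared:.4f}",
            f"  T0 (= -b/a)          {e.t0_hat:.3f} degC",
            f"  K  (= 1/a)           {e.k_hat:.1f} degC*min",
        ]
        if e.ci_low is not None:
            lines.append(
                f"  T0 {100 * e.ci_level:.0f}% bootstrap CI "
                f"[{e.ci_low:.3f}, {e.ci_high:.3f}] degC "
                f"({e.n_boot} resamples, {e.n_discarded} discarded)"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<T0Results t0_hat={self.estimate.t0_hat:.3f} degC>"
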