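import numpy as np
import pytest

from thermaltime import ThermalModel, TemperatureTrace


@pytest.fixture
def ciona_model() -> ThermalModel:
    """Default device configuration: t0 7.5 degC, t_ref 18 degC."""
    return ThermalModel(t0=7.5, t_ref=18.0, offset=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180517)


def make_trace(times, temps) -> TemperatureTrace:
    return TemperatureTrace(np.asarray(times, float), np.asarray(temps, float))


@pytest.fixture
def segment_trace() -> TemperatureTrace:
    """30 min at 18.0 degC then 30 min at 21.0 degC, minute sampling."""
    times = np.arange(0, 3601, 60.0)
    temps = np.where(times < 1800, 18.0, 21.0)
    return TemperatureTrace(times, temps)
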