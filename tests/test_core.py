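"""Unit and property tests for the thermal-time core: calibration,
degree-minute integration and the constant-temperature closed forms."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermaltime import (
    ConfigurationError,
    TemperatureTrace,
    ThermalModel,
    TraceValidationError,
    accumulate_degree_minutes,
    adjusted_minutes,
    calibrate_trace,
    constant_trace,
    cumulative_degree_minutes,
    duration_to_reach,
    equivalent_duration,
)
from conftest import make_trace


class TestThermalModel:
    def test_divisor_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            ThermalModel(t0=18.0, t_ref=18.0)
        with pytest.raises(ConfigurationError):
            ThermalModel(t0=20.0, t_ref=18.0)

    def test_large_offset_warns_but_is_accepted(self):
        with pytest.warns(UserWarning, match="offset"):
            m = ThermalModel(offset=3.0)
        assert m.offset == 3.0

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            ThermalModel(t0=float("nan"))


class TestTraceValidation:
    def test_nonincreasing_times_error_names_index(self):
        with pytest.raises(TraceValidationError, match="index 2"):
            make_trace([0, 1, 1, 2], [18, 18, 18, 18])

    def test_length_mismatch(self):
        with pytest.raises(TraceValidationError, match="mismatch"):
            make_trace([0, 1], [18.0])

    def test_out_of_sensor_range(self):
        with pytest.raises(TraceValidationError, match="sensor range"):
            make_trace([0, 1], [18.0, 130.0])


class TestCalibration:
    @pytest.mark.parametrize(
        "temps, offset, expected",
        [
            ([18.2, 18.2], -0.2, [18.0, 18.0]),
            ([18.2, 18.2], 0.0, [18.2, 18.2]),
            ([0.3], -0.3, [0.0]),  # ice-bath calibration scenario
        ],
    )
    def test_additive_offset(self, temps, offset, expected):
        model = ThermalModel(t0=-10.0, t_ref=18.0, offset=offset)
        trace = make_trace(np.arange(len(temps)), temps)
        cal = calibrate_trace(trace, model)
        np.testing.assert_allclose(cal.temps, expected, atol=1e-12)
        np.testing.assert_array_equal(cal.times, trace.times)


class TestAccumulation:
    def test_constant_hour_at_18(self, ciona_model):
        state = accumulate_degree_minutes(constant_trace(18.0, 3600, 60.0), ciona_model)
        assert state.degree_minutes == pytest.approx(630.0, rel=1e-12)
        assert state.adjusted_min == pytest.approx(60.0, rel=1e-12)
        assert state.elapsed_min == pytest.approx(60.0)
        assert state.mean_temp == pytest.approx(18.0)

    def test_constant_at_t0_accumulates_nothing(self, ciona_model):
        state = accumulate_degree_minutes(constant_trace(7.5, 7200), ciona_model)
        assert state.degree_minutes == 0.0
        assert state.adjusted_min == 0.0

    def test_two_segment_trace(self, ciona_model, segment_trace):
        # (10.5 + 13.5) degC * 30 min each, left-hold
        state = accumulate_degree_minutes(segment_trace, ciona_model)
        assert state.degree_minutes == pytest.approx(720.0, rel=1e-12)
        assert state.mean_temp == pytest.approx(19.5)

    def test_single_sample_yields_zero_state_with_warning(self, ciona_model):
        trace = make_trace([0.0], [18.0])
        with pytest.warns(UserWarning, match="single-sample"):
            state = accumulate_degree_minutes(trace, ciona_model)
        assert state.degree_minutes == 0.0
        assert state.elapsed_min == 0.0
        assert state.mean_temp == 18.0

    def test_samples_below_t0_contribute_zero(self, ciona_model):
        cold = make_trace([0, 600, 1200], [2.0, 5.0, 18.0])
        state = accumulate_degree_minutes(cold, ciona_model)
        assert state.degree_minutes == 0.0  # left-hold: only pre-final samples count

    def test_unclamped_mode_accumulates_signed(self, ciona_model):
        cold = constant_trace(5.5, 600)  # 2 degC below t0 for 10 min
        state = accumulate_degree_minutes(cold, ciona_model, clamp_below_t0=False)
        assert state.degree_minutes == pytest.approx(-20.0, rel=1e-9)

    def test_offset_applied_before_integration(self):
        model = ThermalModel(t0=7.5, t_ref=18.0, offset=-0.5)
        state = accumulate_degree_minutes(constant_trace(18.5, 3600), model)
        assert state.degree_minutes == pytest.approx(630.0, rel=1e-9)
        assert state.mean_temp == pytest.approx(18.0)

    def test_trapezoid_averages_interval_ends(self, ciona_model):
        trace = make_trace([0, 60], [18.0, 21.0])
        lh = accumulate_degree_minutes(trace, ciona_model, rule="left-hold")
        tz = accumulate_degree_minutes(trace, ciona_model, rule="trapezoid")
        assert lh.degree_minutes == pytest.approx(10.5, rel=1e-12)
        assert tz.degree_minutes == pytest.approx(12.0, rel=1e-12)

    def test_unknown_rule_rejected(self, ciona_model, segment_trace):
        with pytest.raises(ConfigurationError, match="rule"):
            accumulate_degree_minutes(segment_trace, ciona_model, rule="simpson")


class TestClosedForms:
    def test_adjusted_minutes_examples(self, ciona_model):
        assert adjusted_minutes(630.0, ciona_model) == pytest.approx(60.0, rel=1e-12)
        assert adjusted_minutes(0.0, ciona_model) == 0.0
        # the landmark thermal budget: 4200 degC*min <-> 400 adjusted min
        assert adjusted_minutes(4200.0, ciona_model) == pytest.approx(400.0, rel=1e-12)

    @pytest.mark.parametrize(
        "duration, temp",
        [(400.0, 18.0), (4200.0 / 13.6, 21.1), (4200.0 / 12.6, 20.1)],
    )
    def test_equivalent_duration_returns_400_on_model_line(self, ciona_model, duration, temp):
        assert equivalent_duration(duration, temp, ciona_model) == pytest.approx(400.0, rel=1e-9)

    def test_equivalent_duration_matches_hand_rounded_example(self, ciona_model):
        # 308.8235 * 13.6 / 10.5, input printed to 4 decimals
        assert equivalent_duration(308.8235, 21.1, ciona_model) == pytest.approx(400.0, abs=5e-4)

    def test_duration_to_reach_examples(self, ciona_model):
        assert duration_to_reach(400.0, 18.0, ciona_model) == pytest.approx(400.0, rel=1e-12)
        assert duration_to_reach(400.0, 21.1, ciona_model) == pytest.approx(
            400.0 * 10.5 / 13.6, rel=1e-12
        )
        assert duration_to_reach(0.0, 12.0, ciona_model) == 0.0

    def test_no_development_at_or_below_t0(self, ciona_model):
        for temp in (7.5, 5.0):
            with pytest.raises(ConfigurationError, match="developmental zero"):
                equivalent_duration(100.0, temp, ciona_model)
            with pytest.raises(ConfigurationError, match="developmental zero"):
                duration_to_reach(100.0, temp, ciona_model)


class TestIntegrationProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(10.0, 25.0), min_size=4, max_size=30),
        st.integers(1, 28),
    )
    def test_additivity_of_split_traces(self, temps, split):
        model = ThermalModel()
        times = np.arange(len(temps)) * 30.0
        trace = TemperatureTrace(times, np.array(temps))
        split = min(split, len(temps) - 2)
        left, right = trace.split_at(split)
        whole = accumulate_degree_minutes(trace, model).degree_minutes
        parts = (
            accumulate_degree_minutes(left, model).degree_minutes
            + accumulate_degree_minutes(right, model).degree_minutes
        )
        assert parts == pytest.approx(whole, rel=1e-9, abs=1e-12)

    def test_segment_permutation_invariance(self, ciona_model, rng):
        # left-hold degree-minutes depend only on the multiset of
        # (temperature, interval) segments, not their order
        segs = [(float(t), float(d)) for t, d in zip(rng.uniform(10, 24, 12), rng.uniform(10, 600, 12))]

        def dm_of(order):
            times = np.concatenate([[0.0], np.cumsum([d for _, d in order])])
            temps = np.array([t for t, _ in order] + [order[-1][0]])
            return accumulate_degree_minutes(
                TemperatureTrace(times, temps), ciona_model
            ).degree_minutes

        base = dm_of(segs)
        perm = [segs[i] for i in rng.permutation(len(segs))]
        assert dm_of(perm) == pytest.approx(base, rel=1e-9)

    def test_identity_at_reference_temperature(self, ciona_model):
        state = accumulate_degree_minutes(constant_trace(18.0, 5400), ciona_model)
        assert state.adjusted_min == pytest.approx(state.elapsed_min, rel=1e-9)

    def test_prefix_monotonicity(self, rng, ciona_model):
        temps = rng.uniform(2.0, 25.0, 500)  # some samples below t0
        trace = TemperatureTrace(np.arange(500.0), temps)
        cum = cumulative_degree_minutes(trace, ciona_model)
        assert np.all(np.diff(cum) >= 0)

    def test_left_hold_convergence_is_first_order(self, ciona_model):
        # 0.1 degC sinusoid, duration NOT a whole number of periods so the
        # leading O(h) error term does not cancel
        base, amp, period, total = 18.0, 0.1, 600.0, 1000.0

        def left_hold_error(dt):
            t = np.arange(0, total + dt / 2, dt)
            temps = base + amp * np.sin(2 * np.pi * t / period)
            dm = accumulate_degree_minutes(
                TemperatureTrace(t, temps), ciona_model
            ).degree_minutes
            exact = (base - 7.5) * total / 60.0 + amp * (
                period / (2 * np.pi) * (1 - np.cos(2 * np.pi * total / period))
            ) / 60.0
            return abs(dm - exact)

        ratio = left_hold_error(2.0) / left_hold_error(1.0)
        assert 1.5 <= ratio <= 2.5

    def test_trapezoid_convergence_is_second_order(self, ciona_model):
        base, amp, period, total = 18.0, 0.1, 600.0, 1000.0

        def trap_error(dt):
            t = np.arange(0, total + dt / 2, dt)
            temps = base + amp * np.sin(2 * np.pi * t / period)
            dm = accumulate_degree_minutes(
                TemperatureTrace(t, temps), ciona_model, rule="trapezoid"
            ).degree_minutes
            exact = (base - 7.5) * total / 60.0 + amp * (
                period / (2 * np.pi) * (1 - np.cos(2 * np.pi * total / period))
            ) / 60.0
            return abs(dm - exact)

        ratio = trap_error(2.0) / trap_error(1.0)
        assert 3.0 <= ratio <= 5.0

    def test_closed_form_agrees_with_integration(self, ciona_model):
        duration_min = 123.4
        temp = 20.7
        trace = make_trace([0.0, duration_min * 60.0], [temp, temp])
        state = accumulate_degree_minutes(trace, ciona_model)
        assert state.adjusted_min == pytest.approx(
            equivalent_duration(duration_min, temp, ciona_model), rel=1e-9
        )
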