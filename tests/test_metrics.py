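import numpy as np
import pytest

from stenovoice.fixtures import FixtureSpec, make_flow_waveform
from stenovoice.metrics import (
    NonOscillatingError,
    PhaseAveragedCycle,
    area_ratio,
    detect_cycles,
    flow_resistance,
    fundamental_frequency,
    mfdr,
    open_quotient,
    phase_average,
    skewness_quotient,
)


def make_cycle(values, period=1.0 / 201.0):
    values = np.asarray(values, dtype=float)
    return PhaseAveragedCycle(
        phases=np.arange(len(values)) / len(values),
        values=values,
        period=period,
        n_cycles_used=1,
    )


class TestDetectCycles:
    def test_sine_period_and_count(self):
        t = np.arange(0, 0.1, 1e-5)
        boundaries = detect_cycles(t, np.sin(2 * np.pi * 100 * t),
                                   discard_initial=2)
        periods = np.diff(boundaries)
        np.testing.assert_allclose(periods, 0.01, rtol=1e-6)
        assert len(boundaries) - 1 >= 6

    def test_constant_signal_rejected(self):
        t = np.linspace(0, 1, 1000)
        with pytest.raises(NonOscillatingError):
            detect_cycles(t, np.full_like(t, 3.7))

    def test_too_few_cycles_rejected(self):
        t = np.linspace(0, 0.02, 2000)  # two cycles at 100 Hz
        with pytest.raises(NonOscillatingError):
            detect_cycles(t, np.sin(2 * np.pi * 100 * t), discard_initial=2)


class TestPhaseAverage:
    def test_identical_cycles_recovered(self):
        spec = FixtureSpec(noise_std=0.0)
        t, q = make_flow_waveform(spec)
        boundaries = detect_cycles(t, q, discard_initial=2)
        cycle = phase_average(t, q, boundaries, n_phases=1000)
        # averaging identical cycles returns one cycle up to interpolation
        single = phase_average(t, q, boundaries[:2], n_phases=1000)
        np.testing.assert_allclose(cycle.values, single.values,
                                   atol=1e-3 * q.max())

    def test_idempotent_on_own_output(self):
        spec = FixtureSpec()
        t, q = make_flow_waveform(spec)
        boundaries = detect_cycles(t, q, discard_initial=2)
        cycle = phase_average(t, q, boundaries, n_phases=500)
        t2 = cycle.phases * cycle.period
        again = phase_average(t2, cycle.values,
                              np.array([0.0, cycle.period]), n_phases=500)
        np.testing.assert_allclose(again.values, cycle.values, rtol=1e-9,
                                   atol=1e-12)

    def test_opposite_cycles_cancel(self):
        # grid chosen so every phase sample falls on a data point
        t = np.arange(4000) / 2000.0
        v = np.where(t < 1.0, np.sin(2 * np.pi * t), -np.sin(2 * np.pi * t))
        cycle = phase_average(t, v, np.array([0.0, 1.0, 2.0]), n_phases=100)
        np.testing.assert_allclose(cycle.values, 0.0, atol=1e-12)

    def test_noise_shrinks_as_sqrt_n_cycles(self, rng):
        # Monte Carlo: per-phase residual std of averaged white noise is
        # sigma / sqrt(n_cycles)
        sigma, n_cycles, n_phases = 0.3, 25, 50
        t = np.arange(0, n_cycles, 1.0 / 200)
        boundaries = np.arange(n_cycles + 1, dtype=float)
        clean = np.sin(2 * np.pi * t)
        resid = []
        for _ in range(100):
            noisy = clean + rng.normal(0, sigma, size=len(t))
            cyc = phase_average(t, noisy, boundaries, n_phases=n_phases)
            ref = phase_average(t, clean, boundaries, n_phases=n_phases)
            resid.append(cyc.values - ref.values)
        measured = np.std(np.concatenate(resid))
        assert measured == pytest.approx(sigma / np.sqrt(n_cycles), rel=0.15)

    def test_few_phases_rejected(self):
        with pytest.raises(ValueError):
            phase_average(np.arange(10.0), np.arange(10.0),
                          np.array([0.0, 5.0]), n_phases=1)


class TestSkewnessQuotient:
    def test_triangular_pulse(self):
        # rising 60% of the cycle, falling 40%, no closed phase -> 1.5
        phases = np.arange(1000) / 1000
        v = np.where(phases < 0.6, phases / 0.6, (1 - phases) / 0.4)
        assert skewness_quotient(make_cycle(v)) == pytest.approx(1.5, abs=0.01)

    def test_symmetric_pulse(self):
        phases = np.arange(1000) / 1000
        v = 1 - np.abs(phases - 0.5) * 2
        assert skewness_quotient(make_cycle(v)) == pytest.approx(1.0, abs=0.01)

    def test_recovers_planted_value(self):
        spec = FixtureSpec(tau_s=1.45, tau_o=0.67)
        t, q = make_flow_waveform(spec)
        boundaries = detect_cycles(t, q, discard_initial=2)
        cycle = phase_average(t, q, boundaries, n_phases=1000)
        assert skewness_quotient(cycle) == pytest.approx(1.45, abs=0.02)

    def test_flat_cycle_rejected(self):
        with pytest.raises(ValueError):
            skewness_quotient(make_cycle(np.ones(100)))


class TestOpenQuotient:
    def test_recovers_planted_value(self):
        spec = FixtureSpec(tau_o=0.67)
        t, a = make_flow_waveform(spec)
        boundaries = detect_cycles(t, a, discard_initial=2)
        cycle = phase_average(t, a, boundaries, n_phases=1000)
        assert open_quotient(cycle) == pytest.approx(0.67, abs=2e-3)

    def test_always_open_sinusoid_warns(self):
        phases = np.arange(1000) / 1000
        cycle = make_cycle(1.0 + 0.5 * np.sin(2 * np.pi * phases))
        with pytest.warns(RuntimeWarning, match="no closed phase"):
            assert open_quotient(cycle) == 1.0

    def test_half_wave_rectified_sine(self):
        # closed exactly half the cycle
        phases = np.arange(1000) / 1000
        cycle = make_cycle(np.maximum(np.sin(2 * np.pi * phases), 0.0))
        assert open_quotient(cycle) == pytest.approx(0.5, abs=2e-3)


class TestMFDR:
    def test_sinusoid_analytic_bound(self):
        f0 = 201.0
        q0 = 2.2e-4
        phases = np.arange(1000) / 1000
        cycle = make_cycle(q0 * np.sin(2 * np.pi * phases), period=1 / f0)
        assert mfdr(cycle) == pytest.approx(2 * np.pi * f0 * q0, rel=1e-4)

    def test_linear_ramp_slope(self):
        # descending ramp in the cycle interior with slope -s
        period = 0.005
        phases = np.arange(1000) / 1000
        v = np.where(phases < 0.5, phases, 1.0 - phases)  # up then down
        cycle = make_cycle(v, period=period)
        # v falls from 0.5 to 0 over half the cycle: slope 1/period
        assert mfdr(cycle) == pytest.approx(1.0 / period, rel=1e-3)

    def test_amplitude_scaling(self):
        phases = np.arange(1000) / 1000
        v = np.sin(2 * np.pi * phases)
        assert mfdr(make_cycle(3 * v)) == pytest.approx(3 * mfdr(make_cycle(v)))

    def test_non_negative_for_rising_cycle(self):
        phases = np.arange(1000) / 1000
        assert mfdr(make_cycle(phases)) >= 0.0


class TestFlowResistance:
    def test_printed_driving_pressure_over_mean_flow(self):
        t = np.linspace(0, 0.05, 500)
        r = flow_resistance(t, np.full_like(t, 800.0), np.full_like(t, 1.13e-4))
        assert r == pytest.approx(800.0 / 1.13e-4, rel=1e-12)
        assert r == pytest.approx(7.08e6, rel=1e-3)

    def test_zero_pressure_drop(self):
        t = np.linspace(0, 0.05, 500)
        assert flow_resistance(t, np.zeros_like(t), np.ones_like(t)) == 0.0

    def test_halves_when_flow_doubles(self):
        t = np.linspace(0, 0.05, 500)
        dp = np.full_like(t, 640.0)
        q = np.full_like(t, 1e-4)
        assert flow_resistance(t, dp, 2 * q) == pytest.approx(
            flow_resistance(t, dp, q) / 2)

    def test_zero_flow_rejected(self):
        t = np.linspace(0, 0.05, 500)
        with pytest.raises(ValueError):
            flow_resistance(t, np.ones_like(t), np.zeros_like(t))


class TestAreaRatio:
    def test_equal_areas(self):
        t = np.linspace(0, 1, 100)
        assert area_ratio(t, np.full_like(t, 1e-5), 1e-5) == pytest.approx(1.0)

    def test_double_glottal_area(self):
        t = np.linspace(0, 1, 100)
        assert area_ratio(t, np.full_like(t, 1e-5), 5e-6) == pytest.approx(2.0)

    def test_nonpositive_sgs_area_rejected(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            area_ratio(t, np.ones_like(t), 0.0)


class TestFundamentalFrequency:
    def test_pure_tone(self):
        t = np.arange(0, 0.1, 1e-5)
        f0 = fundamental_frequency(t, np.sin(2 * np.pi * 201 * t))
        assert f0 == pytest.approx(201.0, rel=1e-3)

    def test_harmonic_sum_returns_fundamental(self):
        t = np.arange(0, 0.1, 1e-5)
        x = np.sin(2 * np.pi * 100 * t) + 0.2 * np.sin(2 * np.pi * 200 * t)
        assert fundamental_frequency(t, x) == pytest.approx(100.0, rel=1e-3)

    def test_aperiodic_input_flags_disagreement(self):
        # the mean-crossing rate tracks the fast weak tone while the
        # spectral peak sits at the slow strong one
        t = np.arange(0, 0.2, 1e-5)
        x = np.sin(2 * np.pi * 50 * t) + 0.9 * np.sin(2 * np.pi * 260 * t)
        with pytest.warns(RuntimeWarning, match="disagrees"):
            fundamental_frequency(t, x)

    def test_constant_rejected(self):
        t = np.linspace(0, 1, 1000)
        with pytest.raises(NonOscillatingError):
            fundamental_frequency(t, np.ones_like(t))
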