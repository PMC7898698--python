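"""Contractile metrics against closed-form and brute-force oracles."""

import numpy as np
import pytest

from myoxi import (ForceTrace, ForceVelocityModel, LengthTrace,
                   MuscleGeometry, WorkLoopTrace, decline_correction,
                   fatigue_index, fit_force_velocity, force_frequency,
                   shortening_velocity, specific_force, twitch_metrics,
                   twitch_tetanus_ratio, workloop_power)
from myoxi.mechanics import MechanicsError
from myoxi.synthetic import hill_velocity
from myoxi.traces import G_TO_N


# ----------------------------------------------------------------------
# Twitch metrics
# ----------------------------------------------------------------------

class TestTwitchMetrics:
    def test_triangle_pulse(self):
        # symmetric triangle peaking at 20 ms: TTP 20 ms, HRT 10 ms
        fs = 10_000.0
        t = np.arange(-0.05, 0.08, 1 / fs)
        f = np.interp(t, [0.0, 0.020, 0.060], [0.0, 1.0, -1.0])
        f = np.clip(f, 0, None)
        tr = ForceTrace(t, f, "N", stimulus_onsets=[0.0])
        m = twitch_metrics(tr)
        assert m.ttp_ms == pytest.approx(20.0, abs=0.2)
        assert m.hrt_ms == pytest.approx(10.0, abs=0.2)
        assert m.peak == pytest.approx(1.0, rel=0.01)

    def test_biexponential_half_relaxation_vs_bisection(self):
        from scipy.optimize import brentq

        tau_r, tau_d = 0.008, 0.045
        fs = 10_000.0
        t = np.arange(-0.05, 0.5, 1 / fs)
        f = np.where(t >= 0, np.exp(-t / tau_d) - np.exp(-t / tau_r), 0.0)
        tr = ForceTrace(t, f, "N", stimulus_onsets=[0.0])
        m = twitch_metrics(tr)
        tp = np.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)
        fp = np.exp(-tp / tau_d) - np.exp(-tp / tau_r)
        hrt_exact = brentq(
            lambda dt: np.exp(-(tp + dt) / tau_d)
            - np.exp(-(tp + dt) / tau_r) - 0.5 * fp, 1e-9, 1.0)
        assert m.hrt_ms == pytest.approx(hrt_exact * 1e3, abs=1e3 / fs)

    def test_never_relaxing_trace_rejected(self):
        t = np.arange(-0.01, 0.1, 1e-4)
        f = np.where(t >= 0, 1.0 - np.exp(-t / 0.005), 0.0)  # plateau
        tr = ForceTrace(t, f, "N", stimulus_onsets=[0.0])
        with pytest.raises(MechanicsError):
            twitch_metrics(tr)


# ----------------------------------------------------------------------
# Specific force
# ----------------------------------------------------------------------

class TestSpecificForce:
    def test_unit_csa(self):
        geom = MuscleGeometry(wet_mass=1.06, l0=1.0)
        assert geom.csa_cm2 == pytest.approx(1.0)
        assert specific_force(2.5, geom) == pytest.approx(2.5)

    def test_hand_arithmetic(self):
        # mass 0.2 g, L0 2 cm: CSA = 0.2/(2*1.06) = 0.094340 cm^2
        geom = MuscleGeometry(wet_mass=0.2, l0=2.0)
        assert geom.csa_cm2 == pytest.approx(0.094340, abs=1e-6)
        assert specific_force(1.0, geom) == pytest.approx(10.600, abs=1e-3)

    def test_linearity(self):
        geom = MuscleGeometry(wet_mass=0.15, l0=1.7)
        assert specific_force(2.0, geom) \
            == pytest.approx(2 * specific_force(1.0, geom))

    def test_gram_force_conversion(self):
        geom = MuscleGeometry(wet_mass=1.06, l0=1.0)
        assert specific_force(1000.0, geom, unit="g") \
            == pytest.approx(9.80665)

    def test_zero_mass_rejected(self):
        with pytest.raises(MechanicsError):
            MuscleGeometry(wet_mass=0.0, l0=1.0)


# ----------------------------------------------------------------------
# Force-frequency
# ----------------------------------------------------------------------

def _pulse_trace(peak, fs=10_000.0):
    t = np.arange(-0.02, 0.3, 1 / fs)
    f = peak * np.exp(-0.5 * ((t - 0.15) / 0.02) ** 2)
    return ForceTrace(t, f, "N", stimulus_onsets=[0.0])


class TestForceFrequency:
    def test_curve_sorted_and_peak(self):
        traces = {50: _pulse_trace(3.0), 1: _pulse_trace(0.5),
                  150: _pulse_trace(4.0), 15: _pulse_trace(1.5)}
        curve, p0 = force_frequency(traces)
        assert list(curve["freq_hz"]) == [1, 15, 50, 150]
        assert np.all(np.diff(curve["peak_force"]) > 0)
        assert p0 == pytest.approx(4.0, rel=1e-6)

    def test_sigmoid_half_frequency_recovered(self):
        f50, n = 40.0, 2.5
        freqs = [1, 15, 30, 50, 80, 120, 150]
        traces = {fq: _pulse_trace(fq ** n / (fq ** n + f50 ** n) + 0.02)
                  for fq in freqs}
        curve, _ = force_frequency(traces)
        # interpolate the frequency at half-maximal force
        half = curve["peak_force"].max() / 2
        est = np.interp(half, curve["peak_force"], curve["freq_hz"])
        assert est == pytest.approx(f50, rel=0.05)

    def test_twitch_tetanus_ratio(self):
        traces = {1: _pulse_trace(0.64), 150: _pulse_trace(4.0)}
        curve, _ = force_frequency(traces)
        assert twitch_tetanus_ratio(curve) == pytest.approx(0.16, rel=1e-6)

    def test_single_frequency_rejected(self):
        with pytest.raises(MechanicsError):
            force_frequency({50: _pulse_trace(1.0)})


# ----------------------------------------------------------------------
# Shortening velocity
# ----------------------------------------------------------------------

class TestShorteningVelocity:
    def test_pure_ramp(self):
        fs = 10_000.0
        t = np.arange(0, 0.3, 1 / fs)
        l0_cm = 2.0
        v = 0.5  # L0/s shortening
        L = np.where(t < 0.05, 20.0, 20.0 - v * 20.0 * (t - 0.05))
        tr = LengthTrace(t, L, l0_cm=l0_cm, release_time=0.05)
        assert shortening_velocity(tr) == pytest.approx(0.5, rel=1e-6)

    def test_flat_length_zero_velocity(self):
        t = np.arange(0, 0.2, 1e-4)
        tr = LengthTrace(t, np.full_like(t, 15.0), l0_cm=1.5,
                         release_time=0.05)
        assert shortening_velocity(tr) == 0.0

    def test_exponential_transient_slope_at_window(self):
        # L(t) decays exponentially; the estimate must match the analytic
        # slope near the start of the analysis window within 5%
        fs = 10_000.0
        t = np.arange(0, 0.4, 1 / fs)
        tau = 0.5
        t0 = 0.05
        L = np.where(t < t0, 10.0, 10.0 * np.exp(-(t - t0) / tau))
        tr = LengthTrace(t, L, l0_cm=1.0, release_time=t0)
        v = shortening_velocity(tr)
        t_win = t0 + 0.010
        analytic = 10.0 * np.exp(-(t_win - t0) / tau) / tau / 10.0
        assert v == pytest.approx(analytic, rel=0.05)

    def test_requires_khz_sampling(self):
        t = np.arange(0, 1.0, 1 / 200.0)
        tr = LengthTrace(t, 10 - t, l0_cm=1.0, release_time=0.1)
        with pytest.raises(MechanicsError):
            shortening_velocity(tr)


# ----------------------------------------------------------------------
# Force-velocity fit
# ----------------------------------------------------------------------

class TestForceVelocityFit:
    def test_linear_data_power_ratio_quarter(self):
        f = np.linspace(0.05, 0.8, 8)
        vmax = 1.8
        res = ForceVelocityModel(f, vmax * (1 - f)).fit()
        assert res.vmax == pytest.approx(vmax, rel=1e-4)
        assert res.power_ratio == pytest.approx(0.25, abs=1e-4)

    @pytest.mark.parametrize("curvature", [0.15, 0.25, 0.4])
    def test_hill_data_recovered_vs_grid_oracle(self, curvature):
        vmax = 2.2
        f = np.array([0.8, 0.65, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        v = hill_velocity(f, vmax, curvature)
        res = ForceVelocityModel(f, v).fit()
        assert res.vmax == pytest.approx(vmax, rel=0.02)
        # brute-force grid oracle for peak power of the generating curve
        fg = np.linspace(0, 1, 10_001)
        wmax_true = np.max(fg * hill_velocity(fg, vmax, curvature))
        assert res.wmax_norm == pytest.approx(wmax_true, rel=0.02)

    def test_power_ratio_decreases_with_curvature(self):
        f = np.array([0.8, 0.65, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        ratios = []
        for c in (0.5, 0.25, 0.1):  # smaller a/P0 = more curved
            res = ForceVelocityModel(f, hill_velocity(f, 2.0, c)).fit()
            ratios.append(res.power_ratio)
        assert ratios[0] > ratios[1] > ratios[2]

    def test_hill_form_is_nested(self):
        f = np.array([0.8, 0.6, 0.4, 0.2, 0.05])
        v = hill_velocity(f, 1.5, 0.3)
        res = ForceVelocityModel(f, v).fit(form="hill")
        assert res.params[2] == 0.0
        assert res.vmax == pytest.approx(1.5, rel=0.02)

    def test_wmax_bounds_observed_power(self):
        rng = np.random.default_rng(0)
        f = np.linspace(0.05, 0.8, 10)
        v = hill_velocity(f, 2.0, 0.25) * (1 + rng.normal(0, 0.02, 10))
        res = ForceVelocityModel(f, v).fit()
        assert res.wmax_norm >= 0.98 * np.max(f * v)

    def test_functional_wrapper_normalises_by_p0(self):
        p0 = 1.5  # N
        pts = [(p0 * f, hill_velocity(f, 2.0, 0.25))
               for f in (0.8, 0.6, 0.4, 0.2, 0.05)]
        res = fit_force_velocity(pts, p0=p0)
        assert res.vmax == pytest.approx(2.0, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(MechanicsError):
            ForceVelocityModel([0.5, 0.3], [1.0, 1.5])


# ----------------------------------------------------------------------
# Work loops
# ----------------------------------------------------------------------

class TestWorkloopPower:
    def _loop(self, force_fn, cycle_freq=2.0, n_cycles=3, l0_cm=2.0):
        fs = 1000.0 * cycle_freq
        t = np.arange(int(n_cycles * fs / cycle_freq)) / fs
        L = 20.0 * (1 + 0.065 * np.sin(2 * np.pi * cycle_freq * t))
        dL = 20.0 * 0.065 * 2 * np.pi * cycle_freq \
            * np.cos(2 * np.pi * cycle_freq * t)
        return WorkLoopTrace(t, force_fn(t, L, dL), L, cycle_freq, l0_cm)

    def test_elastic_loop_zero_work(self):
        wl = self._loop(lambda t, L, dL: 3.0 * (L - 20.0))
        res = workloop_power(wl, mass_g=0.2)
        assert abs(res.net_work_j) < 1e-9

    def test_constant_force_during_shortening(self):
        F0, eps, l0_m = 2.0, 0.065, 0.02
        wl = self._loop(lambda t, L, dL: np.where(dL < 0, F0, 0.0))
        res = workloop_power(wl, mass_g=0.2)
        assert res.net_work_j == pytest.approx(F0 * 2 * eps * l0_m, rel=1e-4)

    def test_power_normalisation(self):
        F0 = 2.0
        wl = self._loop(lambda t, L, dL: np.where(dL < 0, F0, 0.0),
                        cycle_freq=4.0)
        res = workloop_power(wl, mass_g=100.0)
        assert res.net_power_w_per_kg == pytest.approx(
            res.net_work_j * 4.0 / 0.1, rel=1e-12)

    def test_non_integer_cycles_rejected(self):
        fs = 2000.0
        t = np.arange(int(1.5 * fs / 2.0)) / fs  # 1.5 cycles at 2 Hz
        L = 20.0 * (1 + 0.065 * np.sin(2 * np.pi * 2.0 * t))
        wl = WorkLoopTrace(t, np.ones_like(t), L, 2.0, 2.0)
        with pytest.raises(MechanicsError):
            workloop_power(wl, mass_g=0.2)


# ----------------------------------------------------------------------
# Decline correction and fatigue
# ----------------------------------------------------------------------

class TestDeclineCorrection:
    def test_equal_references_no_correction(self):
        out = decline_correction([(5.0, 2.0)], [(0.0, 1.5), (10.0, 1.5)])
        assert out[0][1] == pytest.approx(2.0)

    def test_midpoint_interpolation(self):
        out = decline_correction([(5.0, 1.0)], [(0.0, 1.0), (10.0, 0.8)])
        assert out[0][1] == pytest.approx(1.0 / 0.9)

    def test_random_schedule_matches_hand_oracle(self):
        rng = np.random.default_rng(7)
        ref_t = np.sort(rng.uniform(0, 100, 6))
        ref_v = rng.uniform(0.5, 1.5, 6)
        trials = [(rng.uniform(ref_t[0], ref_t[-1]), rng.uniform(1, 3))
                  for _ in range(10)]
        out = decline_correction(trials, list(zip(ref_t, ref_v)))
        for (t, v), (_, corrected) in zip(trials, out):
            frac = np.interp(t, ref_t, ref_v / ref_v[0])
            assert corrected == pytest.approx(v / frac, abs=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(MechanicsError):
            decline_correction([(1.0, 1.0)], [(0.0, 1.0), (5.0, 0.0)])


def _twitch_train(amps, freq=10.0, fs=2000.0, pre=0.5):
    times = pre + np.arange(len(amps)) / freq
    t = np.arange(0, times[-1] + 0.2, 1 / fs)
    f = np.zeros_like(t)
    for onset, amp in zip(times, amps):
        idx = (t >= onset) & (t < onset + 0.06)
        f[idx] += amp * np.sin(np.pi * (t[idx] - onset) / 0.06) ** 2
    return ForceTrace(t, f, "N", stimulus_onsets=[pre], sampling_rate=fs)


class TestFatigueIndex:
    def test_constant_amplitude_is_100(self):
        fi = fatigue_index(_twitch_train(np.ones(20)))
        assert fi == pytest.approx(100.0, rel=1e-6)

    def test_exponential_decay_to_half(self):
        n = 30
        amps = 0.5 ** (np.arange(n) / (n - 1))  # exactly halves by the end
        fi = fatigue_index(_twitch_train(amps))
        expected = 100 * amps[-5:].mean() / amps[:5].mean()
        assert fi == pytest.approx(expected, rel=0.01)

    def test_three_minute_protocol_matches_peak_oracle(self):
        # 10 Hz for 3 min; amplitudes decline linearly to 45%
        n = 1800
        amps = np.linspace(1.0, 0.45, n)
        tr = _twitch_train(amps, fs=1000.0)
        fi = fatigue_index(tr)
        expected = 100 * amps[-5:].mean() / amps[:5].mean()
        assert fi == pytest.approx(expected, rel=0.01)

    def test_too_few_twitches_rejected(self):
        with pytest.raises(MechanicsError):
            fatigue_index(_twitch_train(np.ones(6)))


# ----------------------------------------------------------------------
# Unit coherence
# ----------------------------------------------------------------------

def test_dimensionless_outputs_unit_invariant():
    amps = np.linspace(1.0, 0.6, 20)
    tr_n = _twitch_train(amps)
    tr_g = ForceTrace(tr_n.time, tr_n.force / G_TO_N, "g",
                      stimulus_onsets=tr_n.stimulus_onsets,
                      sampling_rate=tr_n.sampling_rate)
    assert fatigue_index(tr_n) == pytest.approx(fatigue_index(tr_g),
                                                rel=1e-12)
    curve_n, _ = force_frequency({1: _pulse_trace(0.4),
                                  150: _pulse_trace(2.5)})
    traces_g = {1: ForceTrace(_pulse_trace(0.4).time,
                              _pulse_trace(0.4).force / G_TO_N, "g",
                              stimulus_onsets=[0.0]),
                150: ForceTrace(_pulse_trace(2.5).time,
                                _pulse_trace(2.5).force / G_TO_N, "g",
                                stimulus_onsets=[0.0])}
    curve_g, _ = force_frequency(traces_g)
    assert twitch_tetanus_ratio(curve_n) \
        == pytest.approx(twitch_tetanus_ratio(curve_g), rel=1e-12)
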