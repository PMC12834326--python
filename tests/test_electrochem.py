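"""Potentiostat arithmetic, waveform generation, oxygen calibration, and
CPA post-processing."""

import numpy as np
import pytest

from dcemu.core import TimeSeries
from dcemu.electrochem import (
    WaveformSpec, cpa_point_value, fit_o2_calibration, generate_waveform,
    mix_o2_concentration, potentiostat_current, process_invivo_cpa,
    state_conditioned_cpa_means,
)
from dcemu.event_detection import HypnogramEpoch


class TestPotentiostatCurrent:
    def test_equal_potentials_zero_current(self):
        assert potentiostat_current(1.2, 1.2, 1e4) == 0.0

    def test_ohms_law(self):
        # 1 mV across 10 kOhm -> 100 nA
        assert potentiostat_current(1e-3, 0.0, 1e4) == pytest.approx(100e-9)

    def test_antisymmetry(self):
        assert potentiostat_current(0.3, 0.1, 5e3) == \
            -potentiostat_current(0.1, 0.3, 5e3)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            potentiostat_current(1.0, 0.0, 0.0)


class TestWaveforms:
    def test_cpa_holds_bias(self):
        ts = generate_waveform(WaveformSpec("cpa", 2.0, 1000.0,
                                            {"hold_v": -0.65}))
        assert np.all(ts.values == -0.65)

    def test_fscv_triangle_closed_form(self):
        # v 0->1 at 100 V/s: period 20 ms; at 5 ms the ramp reads 0.5 V
        spec = WaveformSpec("fscv", 0.1, 10000.0,
                            {"v_min": 0.0, "v_max": 1.0,
                             "scan_rate_v_per_s": 100.0})
        ts = generate_waveform(spec)
        assert ts.values[int(0.005 * 10000)] == pytest.approx(0.5)
        assert ts.values.max() <= 1.0 and ts.values.min() >= 0.0

    def test_sine_dc_mean_over_whole_periods(self):
        spec = WaveformSpec("sine_dc", 2.0, 1000.0,
                            {"dc_v": -0.2, "amp_v": 0.1, "freq_hz": 10.0})
        ts = generate_waveform(spec)
        assert np.mean(ts.values) == pytest.approx(-0.2, abs=1e-6)

    @pytest.mark.parametrize("kind,params,period", [
        ("fscv", {"v_min": 0.0, "v_max": 1.0, "scan_rate_v_per_s": 100.0}, 0.02),
        ("ltpv", {"base_v": 0.0, "pulse_v": 0.5, "pulse_s": 0.01,
                  "period_s": 0.05}, 0.05),
        ("sine_dc", {"dc_v": 0.0, "amp_v": 0.2, "freq_hz": 20.0}, 0.05),
    ])
    def test_periodicity(self, kind, params, period):
        ts = generate_waveform(WaveformSpec(kind, 0.5, 10000.0, params))
        shift = int(round(period * 10000))
        assert np.max(np.abs(ts.values[shift:] - ts.values[:-shift])) < 1e-12

    def test_dpv_staircase_with_pulses(self):
        spec = WaveformSpec("dpv", 1.0, 1000.0,
                            {"start_v": 0.0, "end_v": 0.5, "step_v": 0.05,
                             "pulse_amp_v": 0.025, "pulse_s": 0.02,
                             "period_s": 0.1})
        ts = generate_waveform(spec)
        assert ts.values[0] == 0.0
        assert ts.values[int(0.15 * 1000)] == pytest.approx(0.05)   # tread 2
        assert ts.values[int(0.19 * 1000)] == pytest.approx(0.075)  # + pulse

    def test_invalid_spec_field_named(self):
        with pytest.raises(ValueError, match="v_min"):
            WaveformSpec("fscv", 1.0, 1000.0,
                         {"v_min": 1.0, "v_max": 0.0, "scan_rate_v_per_s": 10.0})
        with pytest.raises(ValueError, match="missing"):
            WaveformSpec("cpa", 1.0, 1000.0, {})


class TestCpaPointValue:
    def test_constant_trace(self):
        ts = TimeSeries(np.full(300000, 50.0), 1000.0, units="nA")
        assert cpa_point_value(ts) == pytest.approx(50.0)

    def test_early_transient_excluded(self):
        # large mixing transient in the first 60 s, flat 30 nA after
        x = np.full(300000, 30.0)
        x[:60000] += 500.0 * np.exp(-np.arange(60000) / 10000)
        ts = TimeSeries(x, 1000.0, units="nA")
        assert cpa_point_value(ts) == pytest.approx(30.0, abs=0.01)

    def test_linear_ramp_centred_mean(self):
        # a + b t over [0, T] -> a + b T/2
        a, b, T = 5.0, 0.02, 300.0
        t = np.arange(int(T * 1000)) / 1000.0
        ts = TimeSeries(a + b * t, 1000.0)
        assert cpa_point_value(ts) == pytest.approx(a + b * T / 2, rel=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="80"):
            cpa_point_value(TimeSeries(np.zeros(1000), 1000.0))


class TestMixO2:
    def test_no_dilution(self):
        assert mix_o2_concentration(10.0, 0.0) == pytest.approx(0.23)

    def test_equal_volumes_halve(self):
        assert mix_o2_concentration(5.0, 5.0) == pytest.approx(0.115)

    def test_cumulative_additions_match_mass_balance(self):
        # adding N2-saturated stock stepwise == brute-force mole tracking
        c_sat, v0 = 0.23, 100.0
        added = [10.0, 25.0, 40.0]
        moles, vol = c_sat * v0, v0
        for dv in added:
            vol += dv
            c_direct = mix_o2_concentration(v0, vol - v0, c_sat)
            assert c_direct == pytest.approx(moles / vol)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            mix_o2_concentration(-1.0, 5.0)


class TestO2Calibration:
    def line_points(self, conc, slope=100.0, intercept=5.0, noise=None, rng=None):
        cur = slope * conc + intercept
        if noise:
            cur = cur + rng.normal(0, noise, len(conc))
        return list(zip(conc, cur))

    def test_noiseless_exact_recovery(self):
        conc = np.linspace(0.09, 0.23, 8)
        res = fit_o2_calibration(self.line_points(conc))
        assert res.slope_na_per_mm == pytest.approx(100.0, rel=1e-9)
        assert res.intercept_na == pytest.approx(5.0, rel=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_monte_carlo_slope(self, rng):
        # sigma = 1 nA, 10 points, 200 replicates: mean slope within 5%
        conc = np.linspace(0.09, 0.23, 10)
        slopes = [fit_o2_calibration(
            self.line_points(conc, noise=1.0, rng=rng)).slope_na_per_mm
            for _ in range(200)]
        assert np.mean(slopes) == pytest.approx(100.0, rel=0.05)

    def test_out_of_range_points_excluded(self):
        conc = np.linspace(0.09, 0.23, 8)
        base = fit_o2_calibration(self.line_points(conc))
        spiked = self.line_points(conc) + [(0.5, 999.0)]
        res = fit_o2_calibration(spiked)
        assert res.slope_na_per_mm == base.slope_na_per_mm
        assert res.n_points == base.n_points

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_o2_calibration([(0.1, 10.0), (0.2, 20.0), (0.5, 50.0)])


class TestProcessInvivoCpa:
    def test_constant_preserved_at_20hz(self):
        ts = TimeSeries(np.full(100000, 42.0), 1000.0, units="nA")
        out = process_invivo_cpa(ts)
        assert out.fs_hz == 20.0
        assert np.allclose(out.values, 42.0)

    def test_output_length_arithmetic(self):
        # 1000 s at 1 kHz -> 20,000 samples at 20 Hz
        ts = TimeSeries(np.zeros(1000000), 1000.0)
        assert process_invivo_cpa(ts).n == 20000

    def test_10hz_interference_removed(self):
        t = np.arange(100000) / 1000.0
        ts = TimeSeries(50.0 + 2.0 * np.sin(2 * np.pi * 10 * t), 1000.0)
        out = process_invivo_cpa(ts)
        core = out.values[100:-100]
        assert np.max(np.abs(core - 50.0)) < 0.01 * 2.0

    def test_other_rate_warns_and_scales(self):
        with pytest.warns(UserWarning, match="1000"):
            out = process_invivo_cpa(TimeSeries(np.zeros(10000), 500.0))
        assert out.fs_hz == pytest.approx(20.0)


class TestStateConditionedMeans:
    def hyp(self):
        return [HypnogramEpoch(0, 100, "NREM"), HypnogramEpoch(100, 150, "REM"),
                HypnogramEpoch(150, 300, "NREM"), HypnogramEpoch(300, 400, "WAKE")]

    def test_constant_current_all_states_equal(self):
        cpa = TimeSeries(np.full(400 * 100, 7.0), 100.0, units="nA")
        means = state_conditioned_cpa_means(cpa, self.hyp())
        assert set(means) == {"NREM", "REM", "WAKE"}
        for mean, _ in means.values():
            assert mean == pytest.approx(7.0)

    def test_rem_elevation_recovered(self):
        x = np.zeros(400 * 100)
        x[100 * 100:150 * 100] = 2.0   # REM bout sits 2 nA above baseline
        cpa = TimeSeries(x, 100.0, units="nA")
        means = state_conditioned_cpa_means(cpa, self.hyp())
        assert means["REM"][0] - means["NREM"][0] == pytest.approx(2.0)

    def test_bout_near_event_excluded(self):
        cpa = TimeSeries(np.zeros(400 * 100), 100.0)
        # SD at 120-160 s: margin +-60 s touches both the REM bout and the
        # neighbouring NREM bouts
        means = state_conditioned_cpa_means(cpa, self.hyp(),
                                            exclusion_events=[(120.0, 160.0)])
        assert "REM" not in means
        assert means["WAKE"][1] == 1
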