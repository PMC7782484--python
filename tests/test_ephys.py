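"""AP detection, waveform features, rheobase, I-f, passive properties, PSCs."""

import numpy as np
import pytest

from aisquant import ephys
from aisquant.ephys import (Sweep, SweepSet, ap_amplitude_halfwidth,
                            current_threshold, detect_aps, detect_pscs,
                            if_curve, passive_properties, phase_plane,
                            series_resistance, voltage_threshold)
from aisquant.synthetic import (PSCModelParams, SpikeModelParams,
                                gen_psc_trace, gen_step_protocol_traces)

FS = 50_000.0
DT = 1.0 / FS


def _piecewise_linear_trace(knots_ms, knots_mV, fs=FS):
    t = np.arange(0.0, knots_ms[-1] + 1e-9, 1e3 / fs)
    return t * 1e-3, np.interp(t, knots_ms, knots_mV)


class TestDetectAPs:
    def test_flat_trace_detects_nothing(self):
        t = np.arange(0, 0.1, DT)
        assert len(detect_aps(t, np.full_like(t, -80.0))) == 0

    def test_subthreshold_charging_detects_nothing(self):
        t = np.arange(0, 0.1, DT)
        v = -80.0 + 25.0 * (1 - np.exp(-t / 5e-3))
        assert len(detect_aps(t, v)) == 0

    def test_generated_spikes_found_at_truth_times(self, default_spike_params):
        fi = {0.0: 0, 50.0: 0, 100.0: 0, 150.0: 8}
        ss, truth = gen_step_protocol_traces(
            default_spike_params, {"kind": "long", "n_steps": 4}, seed=0,
            f_of_i=fi)
        peaks = detect_aps(ss.time_s, ss.sweeps[3].signal)
        true_times = truth["spike_times_s"][3]
        assert len(peaks) == 4  # 8 Hz * 0.5 s
        assert np.allclose(np.sort(peaks), np.sort(true_times), atol=2 * DT)


class TestVoltageThreshold:
    def test_piecewise_linear_criterion_crossing(self):
        """Rise at 40 V/s to -55 mV, then at 60 V/s: centered differences
        reach 50 V/s exactly at the slope break, so threshold = -55 mV."""
        t, v = _piecewise_linear_trace(
            [0.0, 0.5, 1.5, 2.0, 4.0], [-75.0, -55.0, 5.0, 5.0, -75.0])
        thr = voltage_threshold(t, v, 1.5e-3, search_window_ms=1.6)
        assert thr == pytest.approx(-55.0, abs=0.01)

    def test_stylized_ap_threshold_exact(self, default_spike_params):
        ss, truth = gen_step_protocol_traces(default_spike_params,
                                             {"kind": "short"}, seed=0)
        feats = ephys.extract_ap_features(ss)
        assert feats.v_threshold_mV == pytest.approx(
            truth["v_threshold_mV"], abs=0.5)

    def test_slow_trace_raises(self):
        t, v = _piecewise_linear_trace([0.0, 10.0, 20.0], [-80.0, 0.0, -80.0])
        # 8 V/s rise never reaches the 50 V/s criterion
        with pytest.raises(ValueError, match="50"):
            voltage_threshold(t, v, 10e-3, search_window_ms=12.0)

    def test_offset_equivariance(self):
        t, v = _piecewise_linear_trace(
            [0.0, 0.5, 1.5, 2.0, 4.0], [-75.0, -55.0, 5.0, 5.0, -75.0])
        thr0 = voltage_threshold(t, v, 1.5e-3, search_window_ms=1.6)
        thr1 = voltage_threshold(t + 0.5, v, 1.5e-3 + 0.5,
                                 search_window_ms=1.6)
        thr2 = voltage_threshold(t, v + 7.0, 1.5e-3, search_window_ms=1.6)
        assert thr1 == pytest.approx(thr0, abs=1e-9)
        assert thr2 == pytest.approx(thr0 + 7.0, abs=1e-9)


class TestAmplitudeHalfWidth:
    def test_triangular_ap_hand_arithmetic(self):
        """Linear rise 80 mV in 1 ms, linear decay in 2 ms: amplitude 80,
        half-width = 0.5 + 1.0 = 1.5 ms."""
        t, v = _piecewise_linear_trace([0.0, 1.0, 3.0], [-50.0, 30.0, -50.0])
        amp, hw = ap_amplitude_halfwidth(t, v, 1e-3, -50.0)
        assert amp == pytest.approx(80.0, abs=0.05)
        assert hw == pytest.approx(1.5, abs=0.01)

    def test_stylized_ap_half_width_within_one_sample(self,
                                                      default_spike_params):
        ss, truth = gen_step_protocol_traces(default_spike_params,
                                             {"kind": "short"}, seed=0)
        feats = ephys.extract_ap_features(ss)
        assert feats.half_width_ms == pytest.approx(
            truth["half_width_ms"], abs=1e3 * DT)
        assert feats.amplitude_mV == pytest.approx(
            truth["amplitude_mV"], abs=0.5)

    def test_degenerate_peak_raises(self):
        t, v = _piecewise_linear_trace([0.0, 1.0, 2.0], [-50.0, -50.0, -50.0])
        with pytest.raises(ValueError, match="degenerate"):
            ap_amplitude_halfwidth(t, v, 1e-3, -50.0)

    def test_missing_falling_crossing_raises(self):
        t, v = _piecewise_linear_trace([0.0, 1.0, 3.0], [-50.0, 30.0, 25.0])
        with pytest.raises(ValueError, match="re-cross"):
            ap_amplitude_halfwidth(t, v, 1e-3, -50.0)


class TestPhasePlane:
    def test_biphasic_rise_rates_recovered(self, default_spike_params):
        ss, truth = gen_step_protocol_traces(default_spike_params,
                                             {"kind": "short"}, seed=0)
        feats = ephys.extract_ap_features(ss)
        r1, r2 = truth["rise_rates_Vps"]
        assert feats.phase_peak1_Vps == pytest.approx(r1, rel=0.05)
        assert feats.phase_peak2_Vps == pytest.approx(r2, rel=0.05)
        assert feats.phase_resolved

    def test_triangular_ap_reports_constant_slope_unresolved(self):
        t, v = _piecewise_linear_trace([0.0, 1.0, 3.0], [-50.0, 30.0, -50.0])
        p1, p2, _, resolved = phase_plane(t, v, 1e-3)
        assert not resolved
        assert p1 == p2 == pytest.approx(80.0, rel=0.05)  # 80 mV / 1 ms


class TestCurrentThreshold:
    def _sweepset(self, amps, spiking):
        t = np.arange(0, 0.1, DT)
        sweeps = []
        for a, s in zip(amps, spiking):
            v = np.full_like(t, -80.0)
            if s:
                i0 = int(0.05 / DT)
                seg = int(0.002 / DT)
                v[i0:i0 + seg] = np.linspace(-80, 30, seg)
                v[i0 + seg:i0 + 2 * seg] = np.linspace(30, -80, seg)
            sweeps.append(Sweep(v, float(a), 0.04, 0.02))
        return SweepSet(time_s=t, sweeps=sweeps)

    def test_monotone_spiking_returns_first_step(self):
        ss = self._sweepset([130, 140, 150, 160, 170],
                            [False, False, True, True, True])
        assert current_threshold(ss) == 150.0

    def test_unreliable_single_spike_rejected(self):
        ss = self._sweepset([120, 130, 140, 150],
                            [True, False, False, False])
        with pytest.raises(ValueError, match="non-monotone"):
            current_threshold(ss)

    def test_no_spikes_raises(self):
        ss = self._sweepset([100, 110, 120], [False, False, False])
        with pytest.raises(ValueError, match="undefined"):
            current_threshold(ss)

    def test_generator_rheobase_on_grid(self, default_spike_params):
        ss, truth = gen_step_protocol_traces(default_spike_params,
                                             {"kind": "short"}, seed=0)
        assert current_threshold(ss) == truth["rheobase_on_grid_pA"] == 150.0

    @pytest.mark.parametrize("rheo", [185.0, 145.0, 105.0])
    def test_threshold_monotone_in_rheobase(self, rheo):
        p = SpikeModelParams(rheobase_pA=rheo)
        ss, _ = gen_step_protocol_traces(p, {"kind": "short"}, seed=0)
        # grid ceiling of the true rheobase on the 10 pA protocol grid
        assert current_threshold(ss) == 10.0 * np.ceil(rheo / 10.0)


class TestIFCurve:
    def test_worked_example_slopes(self):
        """I = 0..250 pA, f = [0,0,5,10,20,20] Hz: interior slopes
        [0.05, 0.1, 0.15, 0.1] Hz/pA, max 0.15 at 150 pA (1 s steps so
        every frequency is an integral spike count)."""
        p = SpikeModelParams(rheobase_pA=95.0)
        fi = {0.0: 0, 50.0: 0, 100.0: 5, 150.0: 10, 200.0: 20, 250.0: 20}
        ss, _ = gen_step_protocol_traces(
            p, {"kind": "long", "n_steps": 6, "duration_ms": 1000.0},
            seed=0, f_of_i=fi)
        c = if_curve(ss)
        assert np.allclose(c.frequencies_Hz, [0, 0, 5, 10, 20, 20])
        assert c.f_prime_max_HzperpA == pytest.approx(0.15)
        assert c.i_at_f_prime_max_pA == 150.0

    def test_constant_frequency_zero_slope_first_interior(self):
        p = SpikeModelParams(rheobase_pA=10.0)
        fi = {0.0: 4, 50.0: 4, 100.0: 4, 150.0: 4}
        ss, _ = gen_step_protocol_traces(p, {"kind": "long", "n_steps": 4},
                                         seed=0, f_of_i=fi)
        c = if_curve(ss)
        assert c.f_prime_max_HzperpA == 0.0
        assert c.i_at_f_prime_max_pA == 50.0

    def test_too_few_steps_raises(self):
        p = SpikeModelParams()
        ss, _ = gen_step_protocol_traces(p, {"kind": "long", "n_steps": 2},
                                         seed=0, f_of_i={0.0: 0, 50.0: 0})
        with pytest.raises(ValueError, match="3"):
            if_curve(ss)


class TestPassiveProperties:
    def test_ohmic_cell_input_resistance(self):
        """V = RMP + 0.3 mV/pA * I -> R_N = 300 MOhm."""
        t = np.arange(0, 0.5, DT)
        sweeps = []
        for i_pA in [-100, -50, 0, 50, 100]:
            v = np.full_like(t, -80.0)
            on, off = int(0.05 / DT), int(0.45 / DT)
            v[on:off] = -80.0 + 0.3 * i_pA
            sweeps.append(Sweep(v, float(i_pA), 0.05, 0.4))
        ss = SweepSet(time_s=t, sweeps=sweeps)
        pp = passive_properties(ss)
        assert pp.r_n_MOhm == pytest.approx(300.0, rel=1e-6)
        assert pp.rmp_mV == pytest.approx(-80.0, abs=1e-9)

    def test_series_resistance_ohms_law(self):
        """-10 mV step with a -500 pA transient peak -> R_s = 20 MOhm."""
        i = np.zeros(1000)
        i[500:520] = -500.0 * np.exp(-np.arange(20) / 5.0)
        assert series_resistance(-10.0, i) == pytest.approx(20.0)

    def test_high_series_resistance_flagged_excluded(self):
        t = np.arange(0, 0.5, DT)
        sweeps = []
        for i_pA in [-100, -50, 0, 50]:
            v = np.full_like(t, -80.0)
            v[int(0.05 / DT):int(0.45 / DT)] = -80.0 + 0.3 * i_pA
            sweeps.append(Sweep(v, float(i_pA), 0.05, 0.4))
        ss = SweepSet(time_s=t, sweeps=sweeps)
        rs_trace = np.zeros(1000)
        rs_trace[500] = -10.0 / 35.0 * 1000.0  # peak for R_s = 35 MOhm
        pp = passive_properties(ss, rs_step_mV=-10.0,
                                rs_current_trace_pA=rs_trace)
        assert pp.r_s_MOhm == pytest.approx(35.0)
        assert pp.r_s_excluded

    def test_spiking_sweeps_excluded_from_fit(self, default_spike_params):
        ss, _ = gen_step_protocol_traces(
            default_spike_params, {"kind": "long", "n_steps": 5}, seed=0,
            f_of_i={0.0: 0, 50.0: 0, 100.0: 0, 150.0: 4, 200.0: 10})
        pp = passive_properties(ss)
        # steady state of a 500 ms step at tau = 5 ms is fully charged
        assert pp.r_n_MOhm == pytest.approx(
            default_spike_params.r_n_MOhm, rel=0.01)


class TestFeatureRecoveryProperty:
    def test_random_params_recovered_within_tolerance(self):
        """Across random spike parameter draws, extracted threshold,
        amplitude and half-width match construction values within
        (0.5 mV, 0.5 mV, 1 sample) on noiseless 50 kHz traces."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            p = SpikeModelParams(
                rheobase_pA=float(rng.uniform(80, 250)),
                v_rest_mV=float(rng.uniform(-85, -75)),
                v_thr_true_mV=float(rng.uniform(-55, -45)),
                ap_peak_mV=float(rng.uniform(30, 45)),
                rise_rates_Vps=(float(rng.uniform(80, 200)),
                                float(rng.uniform(300, 500))),
                half_width_true_ms=float(rng.uniform(0.8, 1.6)))
            ss, truth = gen_step_protocol_traces(
                p, {"kind": "short", "n_steps": 30}, seed=0)
            feats = ephys.extract_ap_features(ss)
            assert feats.v_threshold_mV == pytest.approx(
                truth["v_threshold_mV"], abs=0.5)
            assert feats.amplitude_mV == pytest.approx(
                truth["amplitude_mV"], abs=0.5)
            assert feats.half_width_ms == pytest.approx(
                truth["half_width_ms"], abs=1e3 * DT)


class TestPSCDetection:
    def test_noiseless_trace_fully_recovered(self):
        p = PSCModelParams(rate_Hz=0.5, duration_s=30.0, noise_sd_pA=0.0,
                           sample_rate_Hz=10_000.0)
        t, i_pA, ev = gen_psc_trace(p, seed=4)
        s = detect_pscs(t, i_pA, duration_s=30.0)
        assert len(s.events) == len(ev)
        assert np.allclose(np.sort(s.events.amplitude_pA),
                           np.sort(ev.amplitude_pA), rtol=0.02)

    def test_recall_and_false_positives_at_snr5(self):
        """SNR 5 (20 pA events, 4 pA noise): recall >= 0.9 and <= 2 false
        positives on matched pure-noise segments, averaged over seeds."""
        p = PSCModelParams(rate_Hz=0.8, duration_s=30.0,
                           amplitude_mean_pA=20.0, noise_sd_pA=4.0,
                           sample_rate_Hz=10_000.0)
        recalls, fps = [], []
        for seed in range(10):
            t, i_pA, ev = gen_psc_trace(p, seed=seed)
            s = detect_pscs(t, i_pA, duration_s=30.0)
            det = s.events.time_s.values
            hit = sum(np.any(np.abs(det - te) < 5e-3) for te in ev.time_s)
            recalls.append(hit / max(1, len(ev)))
            noise = PSCModelParams(rate_Hz=0.0, duration_s=30.0,
                                   noise_sd_pA=4.0, sample_rate_Hz=10_000.0)
            tn, xn, _ = gen_psc_trace(noise, seed=100 + seed)
            fps.append(len(detect_pscs(tn, xn, duration_s=30.0).events))
        assert np.mean(recalls) >= 0.9
        assert np.mean(fps) <= 2.0

    def test_frequency_is_count_over_duration(self):
        p = PSCModelParams(rate_Hz=0.5, duration_s=30.0, noise_sd_pA=0.0,
                           sample_rate_Hz=10_000.0)
        t, i_pA, ev = gen_psc_trace(p, seed=4)
        s = detect_pscs(t, i_pA, duration_s=30.0)
        assert s.frequency_Hz == pytest.approx(len(s.events) / 30.0)

    def test_bad_duration_raises(self):
        t = np.arange(0, 1.0, 1e-4)
        with pytest.raises(ValueError, match="duration"):
            detect_pscs(t, np.zeros_like(t), duration_s=0.0)
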