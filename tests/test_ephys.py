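"""Action-potential detection and membrane-feature extraction."""

import numpy as np
import pytest

from axoregen import ephys
from axoregen.ephys import CurrentStepProtocol, VoltageTrace
from axoregen.synthetic import gen_voltage_trace, spike_template, template_fwhm


def flat_trace(vm=-60.0, dur_ms=3000.0, khz=20.0, protocol=None):
    n = int(dur_ms * khz) + 1
    t = np.arange(n) / khz
    return VoltageTrace(t_ms=t, vm_mV=np.full(n, vm), sampling_khz=khz,
                        protocol=protocol)


def oracle_detect(trace, accel_thr=20.0, gate=0.0, window_ms=10.0):
    """Independent exhaustive scan: second difference + gate, no shortcuts."""
    v, dt = trace.vm_mV, trace.dt_ms
    w = int(round(window_ms / dt))
    onsets = []
    i = 1
    while i < v.size - 1:
        acc = (v[i + 1] - 2 * v[i] + v[i - 1]) / dt**2
        if acc > accel_thr and v[i:i + w + 1].max() >= gate:
            onsets.append(trace.t_ms[i])
            j = i + int(np.argmax(v[i:i + w + 1] >= gate))
            while j < v.size and v[j] >= v[i]:
                j += 1
            i = j
        i += 1
    return onsets


class TestDetection:
    def test_flat_trace_no_events(self):
        assert ephys.detect_action_potentials(flat_trace()) == []

    def test_planted_spikes_recovered_at_onsets(self):
        trace, gt = gen_voltage_trace(3, protocol=CurrentStepProtocol.compact(),
                                      seed=1)
        events = ephys.detect_action_potentials(trace)
        planted = gt.labels["trace"]["spike_times_ms"]
        assert len(events) == 3
        for ev, t0 in zip(events, planted):
            assert abs(ev.threshold_time_ms - t0) <= 0.2

    def test_matches_exhaustive_oracle_scan(self):
        for seed in range(5):
            trace, _ = gen_voltage_trace(4, protocol=CurrentStepProtocol.compact(),
                                         seed=seed, noise_sd=0.0)
            events = ephys.detect_action_potentials(trace)
            oracle = oracle_detect(trace)
            assert [e.threshold_time_ms for e in events] == pytest.approx(oracle)

    def test_subthreshold_hump_rejected_by_gate(self):
        # fast deflection peaking at -20 mV: high acceleration, fails 0 mV gate
        tr = flat_trace(vm=-60.0, dur_ms=500.0)
        tmpl = spike_template(np.arange(0, 50, tr.dt_ms))
        i0 = 4000
        tr.vm_mV[i0:i0 + tmpl.size] += 40.0 * tmpl
        assert tr.vm_mV.max() < -10.0
        assert ephys.detect_action_potentials(tr) == []

    def test_distractors_not_detected(self):
        trace, gt = gen_voltage_trace(2, seed=3, n_distractors=2)
        events = ephys.detect_action_potentials(trace)
        assert len(events) == 2

    def test_gate_monotonicity_under_positive_shift(self):
        trace, _ = gen_voltage_trace(3, protocol=CurrentStepProtocol.compact(),
                                     seed=4, spike_peak_mv=5.0)
        n0 = len(ephys.detect_action_potentials(trace))
        shifted = VoltageTrace(t_ms=trace.t_ms, vm_mV=trace.vm_mV + 10.0,
                               sampling_khz=trace.sampling_khz,
                               protocol=trace.protocol)
        assert len(ephys.detect_action_potentials(shifted)) >= n0

    def test_coarse_sampling_rejected(self):
        with pytest.raises(ValueError, match=">= 10 kHz"):
            ephys.detect_action_potentials(flat_trace(khz=5.0))

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            VoltageTrace(t_ms=np.array([]), vm_mV=np.array([]), sampling_khz=20.0)


class TestSpikeFeatures:
    def test_frequency_five_spikes(self):
        trace, _ = gen_voltage_trace(5, protocol=CurrentStepProtocol.compact(),
                                     seed=2)
        events, freq = ephys.measure_spike_features(trace)
        assert len(events) == 5
        assert freq == pytest.approx(6.25)  # 5 APs / 0.8 s

    def test_amplitude_is_peak_minus_threshold(self):
        # template riding a -40 mV baseline, scaled to peak at +20 mV
        tr = flat_trace(vm=-40.0, dur_ms=500.0)
        tmpl = spike_template(np.arange(0, 60, tr.dt_ms))
        tr.vm_mV[4000:4000 + tmpl.size] += (60.0 / tmpl.max()) * tmpl
        ev = ephys.detect_action_potentials(tr)[0]
        assert ev.threshold_vm_mV == pytest.approx(-40.0, abs=0.5)
        assert ev.amplitude_mV == pytest.approx(60.0, abs=0.5)

    def test_width_matches_template_fwhm(self):
        trace, gt = gen_voltage_trace(3, protocol=CurrentStepProtocol.compact(),
                                      seed=5)
        events = ephys.detect_action_potentials(trace)
        fwhm = gt.labels["trace"]["width_ms"]
        for ev in events:
            assert ev.width_ms == pytest.approx(fwhm, abs=0.1)

    def test_width_time_rescaling_invariance(self):
        # doubling the sampling rate changes width by less than one sample
        widths = []
        for khz in (20.0, 40.0):
            trace, _ = gen_voltage_trace(1, protocol=CurrentStepProtocol.compact(),
                                         seed=6, sampling_khz=khz)
            ev = ephys.detect_action_potentials(trace)[0]
            widths.append(ev.width_ms)
        assert abs(widths[0] - widths[1]) < 1.0 / 20.0


class TestPassiveProperties:
    def test_ohms_law_hand_case(self):
        # baseline -60 mV, -20 pA step settling to -62 mV -> 100 MOhm
        proto = CurrentStepProtocol([ephys.CurrentStep(200.0, 800.0, -20.0)])
        tr = flat_trace(vm=-60.0, dur_ms=1500.0, protocol=proto)
        mask = (tr.t_ms >= 200.0) & (tr.t_ms < 1000.0)
        tr.vm_mV[mask] = -62.0
        props = ephys.measure_passive_properties(tr)
        assert props.resting_mv == pytest.approx(-60.0)
        assert props.input_resistance_MOhm == pytest.approx(100.0)

    def test_resting_is_baseline_mean(self):
        trace, _ = gen_voltage_trace(0, protocol=CurrentStepProtocol.compact(),
                                     seed=7, resting_mv=-55.0)
        props = ephys.measure_passive_properties(trace)
        assert props.resting_mv == pytest.approx(-55.0)

    def test_planted_resistance_recovered_through_rc_settling(self):
        trace, _ = gen_voltage_trace(0, protocol=CurrentStepProtocol.compact(),
                                     seed=8, input_resistance_mohm=150.0,
                                     tau_membrane_ms=20.0)
        props = ephys.measure_passive_properties(trace)
        assert props.input_resistance_MOhm == pytest.approx(150.0, abs=1.0)

    def test_no_hyperpolarizing_step_flagged(self):
        proto = CurrentStepProtocol([ephys.CurrentStep(300.0, 800.0, 200.0)])
        tr = flat_trace(vm=-60.0, dur_ms=1500.0, protocol=proto)
        props = ephys.measure_passive_properties(tr)
        assert props.input_resistance_MOhm is None
        assert any("input resistance" in f for f in props.flags)

    def test_fires_ap_flag(self):
        silent, _ = gen_voltage_trace(0, protocol=CurrentStepProtocol.compact(),
                                      seed=9)
        firing, _ = gen_voltage_trace(2, protocol=CurrentStepProtocol.compact(),
                                      seed=9)
        assert not ephys.measure_passive_properties(silent).fires_ap
        assert ephys.measure_passive_properties(firing).fires_ap


class TestSpontaneousActivity:
    def test_silent_trace(self):
        trace, _ = gen_voltage_trace(0, protocol=None, duration_ms=121_000,
                                     seed=10)
        assert ephys.assess_spontaneous_activity(trace) is False

    def test_one_planted_ap(self):
        trace, _ = gen_voltage_trace(1, protocol=None, duration_ms=121_000,
                                     seed=11)
        assert ephys.assess_spontaneous_activity(trace) is True

    def test_short_recording_rejected(self):
        trace, _ = gen_voltage_trace(0, protocol=None, duration_ms=30_000,
                                     seed=12)
        with pytest.raises(ValueError, match="shorter"):
            ephys.assess_spontaneous_activity(trace)

    def test_no_false_positives_in_noise(self):
        # 2 mV membrane noise never reaches the 0 mV gate from -65 mV
        for seed in range(20):
            trace, _ = gen_voltage_trace(0, protocol=None, duration_ms=121_000,
                                         noise_sd=2.0, seed=seed)
            assert ephys.assess_spontaneous_activity(trace) is False


def test_detection_count_equals_planted_over_seeds():
    rng = np.random.default_rng(0)
    for seed in range(30):
        n = int(rng.integers(0, 11))
        trace, gt = gen_voltage_trace(n, protocol=CurrentStepProtocol.compact(),
                                      seed=seed)
        events = ephys.detect_action_potentials(trace)
        assert len(events) == n == len(gt.labels["trace"]["spike_times_ms"])
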