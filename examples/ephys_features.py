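"""Extract action-potential and passive-membrane features from a synthetic
current-clamp recording.

A trace with five planted spikes rides the 200 pA step of the standard
alternating protocol; detection uses the 20 mV/ms^2 acceleration criterion
confirmed at the 0 mV gate.
"""

from axoregen import ephys
from axoregen.synthetic import gen_voltage_trace

trace, truth = gen_voltage_trace(
    n_spikes=5, protocol=ephys.CurrentStepProtocol.compact(),
    resting_mv=-65.0, input_resistance_mohm=150.0, seed=42)

events, frequency = ephys.measure_spike_features(trace)
passive = ephys.measure_passive_properties(trace)

print(f"planted spikes : {len(truth.labels['trace']['spike_times_ms'])}")
print(f"detected spikes: {len(events)}")
print(f"spike frequency: {frequency:.2f} Hz  (APs / 0.8 s injection)")
print(f"mean amplitude : {sum(e.amplitude_mV for e in events)/len(events):.1f} mV"
      " (threshold point to peak)")
print(f"mean width     : {sum(e.width_ms for e in events)/len(events):.2f} ms"
      " (half-maximal upstroke to repolarization)")
print(f"resting Vm     : {passive.resting_mv:.1f} mV")
print(f"input resistance: {passive.input_resistance_MOhm:.0f} MOhm"
      " (hyperpolarizing-step Ohm's law)")
# The detected count, amplitude and width match the planted template exactly
# because the trace is noise-free: this is the package's closed-loop check.
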