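"""Action-potential and passive-membrane feature extraction from current-clamp traces.

The recording protocol applies 800 ms negative and positive current steps in an
alternating manner, increasing by 20 pA. Spike events are classified as action
potentials when the membrane-potential acceleration (discrete second
derivative) exceeds 20 mV/ms^2 and the potential subsequently reaches 0 mV.
Spike features (threshold, amplitude, half-maximal width, frequency) are taken
from the response to the 200 pA step; passive properties (resting potential,
input resistance) come from the pre-stimulus baseline and the hyperpolarizing
steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import savgol_filter

__all__ = [
    "CurrentStep",
    "CurrentStepProtocol",
    "VoltageTrace",
    "SpikeEvent",
    "PassiveProperties",
    "detect_action_potentials",
    "measure_spike_features",
    "measure_passive_properties",
    "assess_spontaneous_activity",
]

ACCEL_THRESHOLD_MV_MS2 = 20.0  # classification rule for AP acceleration
AMPLITUDE_GATE_MV = 0.0        # an AP must reach 0 mV
CONFIRM_WINDOW_MS = 10.0       # window after threshold crossing to reach the gate


@dataclass(frozen=True)
class CurrentStep:
    onset_ms: float
    duration_ms: float
    amplitude_pA: float


@dataclass
class CurrentStepProtocol:
    """Ordered current steps: 800 ms, alternating sign, 20 pA increments."""

    steps: list[CurrentStep]

    @classmethod
    def standard(cls, max_pa: float = 200.0, step_pa: float = 20.0,
                 start_ms: float = 200.0, duration_ms: float = 800.0,
                 gap_ms: float = 200.0) -> "CurrentStepProtocol":
        steps = []
        onset = start_ms
        amp = step_pa
        while amp <= max_pa + 1e-9:
            for sign in (-1.0, 1.0):
                steps.append(CurrentStep(onset, duration_ms, sign * amp))
                onset += duration_ms + gap_ms
            amp += step_pa
        return cls(steps)

    @classmethod
    def compact(cls, spike_step_pa: float = 200.0, hyper_step_pa: float = -20.0,
                start_ms: float = 200.0, duration_ms: float = 800.0,
                gap_ms: float = 200.0) -> "CurrentStepProtocol":
        """Minimal protocol (one negative, one positive step) for quick runs."""
        return cls([
            CurrentStep(start_ms, duration_ms, hyper_step_pa),
            CurrentStep(start_ms + duration_ms + gap_ms, duration_ms, spike_step_pa),
        ])

    @property
    def end_ms(self) -> float:
        if not self.steps:
            return 0.0
        return max(s.onset_ms + s.duration_ms for s in self.steps)

    def step_with_amplitude(self, amplitude_pA: float) -> CurrentStep:
        for s in self.steps:
            if abs(s.amplitude_pA - amplitude_pA) < 1e-9:
                return s
        raise ValueError(f"no {amplitude_pA} pA step in protocol")

    def negative_steps(self) -> list[CurrentStep]:
        return [s for s in sorted(self.steps, key=lambda s: s.onset_ms)
                if s.amplitude_pA < 0]

    def positive_steps(self) -> list[CurrentStep]:
        return [s for s in sorted(self.steps, key=lambda s: s.onset_ms)
                if s.amplitude_pA > 0]


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential, optionally with its protocol."""

    t_ms: np.ndarray
    vm_mV: np.ndarray
    sampling_khz: float
    protocol: CurrentStepProtocol | None = None
    trace_id: str = "trace"

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.vm_mV = np.asarray(self.vm_mV, dtype=float)
        if self.t_ms.size != self.vm_mV.size:
            raise ValueError("t_ms and vm_mV must have equal length")
        if self.t_ms.size == 0:
            raise ValueError("empty trace")
        if not np.all(np.isfinite(self.vm_mV)):
            raise ValueError("non-finite membrane potential values")

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_khz

    def check_uniform(self, rtol: float = 1e-3):
        if self.t_ms.size < 3:
            raise ValueError("trace too short")
        dt = np.diff(self.t_ms)
        if np.any(np.abs(dt - self.dt_ms) > rtol * self.dt_ms):
            raise ValueError("non-uniform sampling beyond tolerance")


@dataclass
class SpikeEvent:
    threshold_time_ms: float
    threshold_vm_mV: float
    peak_vm_mV: float
    amplitude_mV: float
    width_ms: float | None = None
    flags: list[str] = field(default_factory=list)
    onset_index: int = -1
    peak_index: int = -1
    release_index: int = -1


@dataclass
class PassiveProperties:
    resting_mv: float
    input_resistance_MOhm: float | None
    spike_frequency_Hz: float | None
    fires_ap: bool
    spontaneous: bool | None = None
    flags: list[str] = field(default_factory=list)


def _acceleration(vm: np.ndarray, dt_ms: float, smooth: bool) -> np.ndarray:
    """Discrete central second difference of Vm in mV/ms^2 (optionally Savitzky-Golay)."""
    v = savgol_filter(vm, 5, 2) if smooth else vm
    acc = np.zeros_like(v)
    acc[1:-1] = (v[2:] - 2.0 * v[1:-1] + v[:-2]) / dt_ms**2
    return acc


def detect_action_potentials(trace: VoltageTrace,
                             accel_threshold: float = ACCEL_THRESHOLD_MV_MS2,
                             amplitude_gate: float = AMPLITUDE_GATE_MV,
                             confirm_window_ms: float = CONFIRM_WINDOW_MS,
                             smooth: bool = False) -> list[SpikeEvent]:
    """Detect APs: acceleration over the threshold, confirmed by reaching the gate.

    An event begins at the first sample whose second difference exceeds
    ``accel_threshold`` and is confirmed only if Vm reaches ``amplitude_gate``
    within ``confirm_window_ms``. After confirmation, scanning resumes once Vm
    falls back below the event's threshold voltage, so multi-crossing upstrokes
    are not double-counted.
    """
    if trace.sampling_khz < 10.0:
        raise ValueError("sampling rate must be >= 10 kHz")
    trace.check_uniform()
    vm = trace.vm_mV
    dt = trace.dt_ms
    acc = _acceleration(vm, dt, smooth)
    window = max(1, int(round(confirm_window_ms / dt)))
    candidates = np.nonzero(acc > accel_threshold)[0]
    if candidates.size:
        # cheap superset prefilter: drop candidates whose forward window
        # cannot reach the gate (exact per-candidate check happens below)
        w_eff = window + (window % 2)
        fwd_max = maximum_filter1d(vm, size=w_eff + 1, mode="nearest")
        idx = np.clip(candidates + w_eff // 2, 0, vm.size - 1)
        candidates = candidates[fwd_max[idx] >= amplitude_gate]
    events: list[SpikeEvent] = []
    resume = 0
    for i in candidates:
        if i < resume:
            continue
        hi = min(vm.size, i + window + 1)
        seg = vm[i:hi]
        gate_hits = np.nonzero(seg >= amplitude_gate)[0]
        if gate_hits.size == 0:
            continue
        thr_vm = vm[i]
        # follow the spike until Vm repolarizes below its own threshold
        j = i + gate_hits[0]
        release = vm.size - 1
        below = np.nonzero(vm[j:] < thr_vm)[0]
        if below.size:
            release = j + below[0]
        peak_rel = int(np.argmax(vm[i:release + 1]))
        peak_idx = i + peak_rel
        ev = SpikeEvent(
            threshold_time_ms=float(trace.t_ms[i]),
            threshold_vm_mV=float(thr_vm),
            peak_vm_mV=float(vm[peak_idx]),
            amplitude_mV=float(vm[peak_idx] - thr_vm),
            onset_index=int(i),
            peak_index=int(peak_idx),
            release_index=int(release),
        )
        ev.width_ms = _half_width(trace, ev)
        if ev.width_ms is None:
            ev.flags.append("width undefined")
        events.append(ev)
        resume = release + 1
    return events


def _half_width(trace: VoltageTrace, ev: SpikeEvent) -> float | None:
    """Width from half-maximal amplitude on the upstroke to the same voltage on
    repolarization, with linear interpolation between samples."""
    vm, t = trace.vm_mV, trace.t_ms
    half_v = ev.threshold_vm_mV + 0.5 * ev.amplitude_mV
    i, pk = ev.onset_index, ev.peak_index
    up = None
    for a in range(i, pk):
        if vm[a] < half_v <= vm[a + 1]:
            frac = (half_v - vm[a]) / (vm[a + 1] - vm[a])
            up = t[a] + frac * (t[a + 1] - t[a])
            break
    if up is None:
        if vm[i] >= half_v:
            up = t[i]
        else:
            return None
    # search the repolarizing phase (allow running past release a little)
    stop = min(vm.size - 1, max(ev.release_index, pk + 1) + 1)
    down = None
    for a in range(pk, stop):
        if vm[a] >= half_v > vm[a + 1]:
            frac = (vm[a] - half_v) / (vm[a] - vm[a + 1])
            down = t[a] + frac * (t[a + 1] - t[a])
            break
    if down is None:
        return None
    return float(down - up)


def measure_spike_features(trace: VoltageTrace,
                           events: list[SpikeEvent] | None = None,
                           response_step_pa: float = 200.0,
                           ) -> tuple[list[SpikeEvent], float]:
    """Spike features from the response to the stated current step (default 200 pA).

    Returns the events occurring during that step (with widths filled) and the
    spike frequency, the number of APs divided by the current injection time.
    """
    if trace.protocol is None:
        raise ValueError("trace has no protocol; spike features need the 200 pA step")
    step = trace.protocol.step_with_amplitude(response_step_pa)
    if events is None:
        events = detect_action_potentials(trace)
    in_step = [e for e in events
               if step.onset_ms <= e.threshold_time_ms < step.onset_ms + step.duration_ms]
    freq = len(in_step) / (step.duration_ms / 1000.0)
    return in_step, freq


def measure_passive_properties(trace: VoltageTrace,
                               baseline_ms: float = 200.0,
                               steady_ms: float = 100.0) -> PassiveProperties:
    """Resting potential, input resistance, and excitability flags.

    Resting potential is the mean over the baseline window immediately before
    the first step ('before applying any current'); input resistance is
    |dV_ss| / |I| using the smallest-magnitude of the first three negative
    steps, with dV_ss the mean of the final ``steady_ms`` of the step minus
    baseline.
    """
    if trace.protocol is None or not trace.protocol.steps:
        raise ValueError("passive properties need a step protocol")
    first_onset = min(s.onset_ms for s in trace.protocol.steps)
    if first_onset < baseline_ms:
        raise ValueError("need a pre-stimulus baseline of at least "
                         f"{baseline_ms} ms before the first step")
    t = trace.t_ms
    base_mask = (t >= first_onset - baseline_ms) & (t < first_onset)
    resting = float(trace.vm_mV[base_mask].mean())

    flags = []
    neg = trace.protocol.negative_steps()[:3]
    if not neg:
        r_in = None
        flags.append("no hyperpolarizing step: input resistance undefined")
    else:
        step = min(neg, key=lambda s: abs(s.amplitude_pA))
        off = step.onset_ms + step.duration_ms
        mask = (t >= off - steady_ms) & (t < off)
        dv = float(trace.vm_mV[mask].mean()) - resting
        # mV / pA = GOhm; report MOhm
        r_in = abs(dv) / abs(step.amplitude_pA) * 1000.0

    events = detect_action_potentials(trace)
    pos = trace.protocol.positive_steps()
    fires = any(
        s.onset_ms <= e.threshold_time_ms < s.onset_ms + s.duration_ms
        for e in events for s in pos)

    freq = None
    try:
        _, freq = measure_spike_features(trace, events)
    except ValueError:
        flags.append("no 200 pA step: spike frequency undefined")
    return PassiveProperties(resting_mv=resting, input_resistance_MOhm=r_in,
                             spike_frequency_Hz=freq, fires_ap=fires, flags=flags)


def assess_spontaneous_activity(trace: VoltageTrace,
                                min_duration_s: float = 120.0) -> bool:
    """True iff the zero-current recording contains any action potential.

    Positive spontaneous activity means the neuron produced APs within two
    minutes without current injection; the same detection rule is applied.
    """
    duration_s = (trace.t_ms[-1] - trace.t_ms[0]) / 1000.0
    if duration_s < min_duration_s - 1e-9:
        raise ValueError(f"recording shorter than {min_duration_s} s")
    if trace.protocol is not None and any(s.amplitude_pA != 0 for s in trace.protocol.steps):
        raise ValueError("spontaneous activity requires a zero-current recording")
    return len(detect_action_potentials(trace)) >= 1
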