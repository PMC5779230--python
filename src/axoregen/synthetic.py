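"""Seeded synthetic-data generators with embedded ground truth.

Every generator emulates the statistical structure of the corresponding
measurement: spike trains riding on 800 ms current steps, vesicle tracks with
planted direction classes under the 2 um rule, axotomy time courses with
log-normally distributed retraction and stochastic regeneration initiation,
polarized neurite intensity profiles, and FPKM matrices over DIV 1/4/8/16/24
with six replicates and planted increasing/decreasing genes. The planted
parameters are returned as a :class:`GroundTruth` so every downstream
measurement stage can be verified by parameter recovery; for noise-free
settings the recovery is exact by construction.

All generators are pure functions of their arguments (including the seed):
identical calls return bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .axotomy import AxotomyParams, AxotomyTimecourse
from .ephys import CurrentStepProtocol, VoltageTrace
from .kymograph import KymographImage, VesicleTrack, REGION_LENGTH_UM
from .polarity import NeuriteIntensityProfile
from .trends import ExpressionMatrix, TIMEPOINTS_DIV

import pandas as pd

__all__ = [
    "GroundTruth",
    "SimConfig",
    "run_simconfig",
    "spike_template",
    "template_fwhm",
    "gen_voltage_trace",
    "gen_vesicle_tracks",
    "gen_parallel_tracks",
    "render_kymograph",
    "gen_axotomy_timecourse",
    "gen_axotomy_cohort",
    "gen_expression_matrix",
    "gen_intensity_profiles",
]


@dataclass
class GroundTruth:
    """Planted class/parameter per generated object id (the test oracle)."""

    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        def _check(v):
            if isinstance(v, dict):
                for x in v.values():
                    _check(x)
            elif isinstance(v, (list, tuple, np.ndarray)):
                for x in v:
                    _check(x)
            elif isinstance(v, (int, float, np.floating, np.integer)):
                if not np.isfinite(v):
                    raise ValueError("planted values must be finite")
        _check(self.labels)


@dataclass(frozen=True)
class SimConfig:
    """A generator call: name, keyword parameters, and the seed."""

    generator: str
    params: dict
    seed: int = 0


_GENERATORS = {}


def _register(fn):
    _GENERATORS[fn.__name__.removeprefix("gen_")] = fn
    return fn


def run_simconfig(cfg: SimConfig):
    if cfg.generator not in _GENERATORS:
        raise ValueError(f"unknown generator {cfg.generator!r}; "
                         f"known: {sorted(_GENERATORS)}")
    return _GENERATORS[cfg.generator](seed=cfg.seed, **cfg.params)


# ---------------------------------------------------------------------------
# voltage traces


def spike_template(t_ms, tau_rise_ms: float = 0.3, tau_decay_ms: float = 1.1,
                   ahp_mv_per_unit: float = 0.06, tau_ahp_ms: float = 10.0):
    """Spike waveform: difference of exponentials normalized to unit peak,
    with a slow afterhyperpolarization so the trace undershoots its threshold.

    The waveform starts with a slope discontinuity at t = 0, so the discrete
    second difference of any trace containing it is large exactly at onset.
    """
    t = np.asarray(t_ms, dtype=float)
    tr, td = tau_rise_ms, tau_decay_ms
    if not td > tr > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    t_pk = tr * td / (td - tr) * math.log(td / tr)
    peak = math.exp(-t_pk / td) - math.exp(-t_pk / tr)
    doe = np.where(t >= 0, np.exp(-np.minimum(t, 700 * td) / td)
                   - np.exp(-np.minimum(t, 700 * tr) / tr), 0.0) / peak
    ahp = np.where(t >= 0, np.exp(-t / tau_ahp_ms) - np.exp(-t / td), 0.0)
    ahp_peak_t = td * tau_ahp_ms / (tau_ahp_ms - td) * math.log(tau_ahp_ms / td)
    ahp /= math.exp(-ahp_peak_t / tau_ahp_ms) - math.exp(-ahp_peak_t / td)
    return doe - ahp_mv_per_unit * ahp


def template_fwhm(tau_rise_ms: float = 0.3, tau_decay_ms: float = 1.1,
                  **kwargs) -> float:
    """Full width at half maximum of the spike template, by root finding.

    The half level is half of the template's actual peak (the
    afterhyperpolarization term pulls the peak slightly below the normalized
    difference-of-exponentials maximum)."""
    grid = np.arange(0.0, 6.0 * tau_decay_ms, 1e-4)
    vals = spike_template(grid, tau_rise_ms, tau_decay_ms, **kwargs)
    i_pk = int(np.argmax(vals))
    half = 0.5 * vals[i_pk]
    t_pk = grid[i_pk]

    def f(t):
        return float(spike_template(np.array([t]), tau_rise_ms, tau_decay_ms,
                                    **kwargs)[0]) - half

    left = brentq(f, 1e-9, t_pk)
    right = brentq(f, t_pk, t_pk + 30 * tau_decay_ms)
    return right - left


def _rc_response(t, onset, duration, amp_pa, r_mohm, tau_ms):
    """Passive membrane response to one current step, in mV."""
    dv = amp_pa * r_mohm * 1e-3
    rise = np.clip(t - onset, 0, None)
    on = dv * (1 - np.exp(-rise / tau_ms)) * (t >= onset)
    fall = np.clip(t - (onset + duration), 0, None)
    off = -dv * (1 - np.exp(-fall / tau_ms)) * (t >= onset + duration)
    return on + off


@_register
def gen_voltage_trace(n_spikes: int,
                      protocol: CurrentStepProtocol | None = None,
                      resting_mv: float = -65.0,
                      noise_sd: float = 0.0,
                      sampling_khz: float = 20.0,
                      seed: int = 0,
                      input_resistance_mohm: float = 150.0,
                      tau_membrane_ms: float = 20.0,
                      spike_peak_mv: float = 20.0,
                      tau_rise_ms: float = 0.3,
                      tau_decay_ms: float = 1.1,
                      n_distractors: int = 0,
                      distractor_peak_mv: float = -20.0,
                      spike_step_pa: float = 200.0,
                      duration_ms: float | None = None,
                      trace_id: str = "trace",
                      ) -> tuple[VoltageTrace, GroundTruth]:
    """One current-clamp trace with ``n_spikes`` planted APs and ground truth.

    Planted spikes ride on the depolarizing ``spike_step_pa`` step (or are
    spread over the whole recording when ``protocol`` is explicitly absent,
    emulating a spontaneous recording). Distractor deflections peak below
    -10 mV so they fail the 0 mV amplitude gate despite fast acceleration.
    """
    if sampling_khz < 10.0:
        raise ValueError("sampling rate must be >= 10 kHz")
    dt = 1.0 / sampling_khz
    if tau_rise_ms < 2.0 * dt:
        raise ValueError(
            f"sampling too coarse to resolve the spike template "
            f"(tau_rise {tau_rise_ms} ms < 2 samples at {sampling_khz} kHz)")
    if n_spikes < 0:
        raise ValueError("n_spikes must be >= 0")
    rng = np.random.default_rng(seed)
    spontaneous = protocol is None and duration_ms is not None
    if protocol is None and duration_ms is None:
        protocol = CurrentStepProtocol.standard(max_pa=max(spike_step_pa, 40.0))
    if spontaneous:
        total_ms = duration_ms
    else:
        total_ms = protocol.end_ms + 200.0
    n = int(round(total_ms / dt)) + 1
    t = np.arange(n) * dt
    vm = np.full(n, resting_mv)
    if not spontaneous:
        for s in protocol.steps:
            vm += _rc_response(t, s.onset_ms, s.duration_ms, s.amplitude_pA,
                               input_resistance_mohm, tau_membrane_ms)

    min_sep_ms = 25.0
    if spontaneous:
        lo, hi = 50.0, total_ms - 50.0
    else:
        if n_spikes > 0:
            step = protocol.step_with_amplitude(spike_step_pa)
            lo = step.onset_ms + 5.0 * tau_membrane_ms
            hi = step.onset_ms + step.duration_ms - 30.0
        else:
            lo = hi = 0.0
    spike_times = []
    if n_spikes > 0:
        span = hi - lo - (n_spikes - 1) * min_sep_ms
        if span <= 0:
            raise ValueError(f"cannot place {n_spikes} spikes {min_sep_ms} ms apart")
        u = np.sort(rng.uniform(0, span, size=n_spikes))
        times = lo + u + np.arange(n_spikes) * min_sep_ms
        spike_times = [round(x / dt) * dt for x in times]

    tmpl_kwargs = dict(tau_rise_ms=tau_rise_ms, tau_decay_ms=tau_decay_ms)
    support = np.arange(0, int(round(80.0 / dt))) * dt
    tmpl = spike_template(support, **tmpl_kwargs)
    thresholds, amplitudes = [], []
    for st in spike_times:
        i0 = int(round(st / dt))
        base = vm[i0]
        amp = spike_peak_mv - base
        if amp <= 0:
            raise ValueError("spike peak below local baseline; raise spike_peak_mv")
        hi_i = min(n, i0 + support.size)
        vm[i0:hi_i] += amp * tmpl[: hi_i - i0]
        thresholds.append(float(base))
        amplitudes.append(float(vm[i0:hi_i].max() - base))

    distractor_times = []
    if n_distractors > 0 and not spontaneous:
        gaps = []
        steps = sorted(protocol.steps, key=lambda s: s.onset_ms)
        for a, b in zip(steps, steps[1:]):
            gap_lo = a.onset_ms + a.duration_ms + 150.0
            gap_hi = b.onset_ms - 10.0
            if gap_hi > gap_lo:
                gaps.append((gap_lo, gap_hi))
        if len(gaps) < n_distractors:
            raise ValueError("not enough inter-step gaps for distractors")
        pick = rng.choice(len(gaps), size=n_distractors, replace=False)
        for gi in sorted(pick):
            gt_ms = round(rng.uniform(*gaps[gi]) / dt) * dt
            i0 = int(round(gt_ms / dt))
            amp = distractor_peak_mv - vm[i0]
            if amp <= 0:
                raise ValueError("distractor peak below baseline")
            hi_i = min(n, i0 + support.size)
            vm[i0:hi_i] += amp * tmpl[: hi_i - i0]
            distractor_times.append(float(gt_ms))

    if noise_sd > 0:
        vm = vm + rng.normal(0.0, noise_sd, size=n)

    trace = VoltageTrace(t_ms=t, vm_mV=vm, sampling_khz=sampling_khz,
                         protocol=None if spontaneous else protocol,
                         trace_id=trace_id)
    gt = GroundTruth(labels={trace_id: {
        "spike_times_ms": [float(x) for x in spike_times],
        "threshold_vm_mv": thresholds,
        "amplitude_mv": amplitudes,
        "width_ms": template_fwhm(**tmpl_kwargs),
        "distractor_times_ms": distractor_times,
        "resting_mv": resting_mv,
        "input_resistance_mohm": input_resistance_mohm,
    }})
    return trace, gt


# ---------------------------------------------------------------------------
# vesicle tracks and kymographs


def largest_remainder_counts(fractions: dict, n: int) -> dict:
    """Deterministic integer allocation of n items to classes by largest remainders."""
    keys = list(fractions)
    raw = np.array([fractions[k] * n for k in keys], dtype=float)
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = n - base.sum()
    order = np.argsort(-rem, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


TRACK_SAMPLES = 181  # 1 frame/s for 3 min


def _directional_positions(rng, sign: int, n_runs: int, speed_range,
                           run_net_range=(4.0, 10.0)) -> np.ndarray:
    p = np.zeros(TRACK_SAMPLES)
    margin = 0.5
    total_net = 0.0
    runs = []
    for _ in range(n_runs):
        net = rng.uniform(*run_net_range)
        speed = rng.uniform(*speed_range)
        runs.append((net, speed))
        total_net += net
    total_net = min(total_net, REGION_LENGTH_UM - 2 * margin - 1.0)
    if sign > 0:
        p0 = rng.uniform(margin, REGION_LENGTH_UM - margin - total_net - 0.5)
    else:
        p0 = rng.uniform(margin + total_net + 0.5, REGION_LENGTH_UM - margin)
    pos = p0
    cursor = 0
    p[:] = p0
    budget = total_net
    for net, speed in runs:
        net = min(net, budget)
        if net < 4.0:
            net = min(4.0, budget)
        n_steps = max(1, int(math.ceil(net / speed)))
        start = cursor + rng.integers(0, max(1, (TRACK_SAMPLES - cursor
                                                 - n_steps) // max(1, n_runs)))
        step = net / n_steps
        for i in range(n_steps):
            idx = start + i + 1
            if idx >= TRACK_SAMPLES:
                break
            pos += sign * step
            p[idx:] = pos
        cursor = start + n_steps
        budget -= net
        if cursor >= TRACK_SAMPLES - 2:
            break
    return p


def _bidirectional_positions(rng, speed_range) -> np.ndarray:
    p = np.zeros(TRACK_SAMPLES)
    n1 = rng.uniform(4.0, 8.0)
    n2 = rng.uniform(4.0, 8.0)
    first = 1 if rng.random() < 0.5 else -1
    lo_need = n1 if first < 0 else n2 - min(n1, n2)
    p0 = rng.uniform(max(1.0, 1.0 + max(n1, n2)),
                     REGION_LENGTH_UM - 1.0 - max(n1, n2))
    del lo_need
    pos = p0
    p[:] = p0
    cursor = rng.integers(1, 40)
    for sign, net in ((first, n1), (-first, n2)):
        speed = rng.uniform(*speed_range)
        n_steps = max(1, int(math.ceil(net / speed)))
        step = net / n_steps
        for i in range(n_steps):
            idx = cursor + i
            if idx >= TRACK_SAMPLES:
                break
            pos += sign * step
            p[idx:] = pos
        cursor += n_steps + int(rng.integers(2, 30))
        if cursor >= TRACK_SAMPLES - 2:
            break
    return p


def _stationary_positions(rng, excursion_um: float = 0.8) -> np.ndarray:
    p0 = rng.uniform(2.0, REGION_LENGTH_UM - 2.0)
    steps = rng.normal(0.0, 0.05, size=TRACK_SAMPLES - 1)
    walk = np.concatenate([[0.0], np.cumsum(steps)])
    # reflect the walk into the +-excursion band
    walk = excursion_um * (2 * np.abs(walk / (2 * excursion_um)
                                      - np.floor(walk / (2 * excursion_um) + 0.5)))
    walk = walk - walk[0]
    return p0 + walk


@_register
def gen_vesicle_tracks(n_tracks: int,
                       fractions: dict,
                       speed_um_s: tuple = (0.3, 1.5),
                       pause_prob: float = 0.3,
                       seed: int = 0,
                       noise_sd_um: float = 0.0,
                       compartment: str = "axon",
                       ) -> tuple[list[VesicleTrack], GroundTruth]:
    """Tracks with planted direction classes (181 positions at 1 Hz, 30 um).

    Class counts follow largest-remainder rounding of ``fractions``.
    Anterograde/retrograde tracks contain one or two contiguous monotone runs
    of net >= 4 um in their class direction only; bidirectional tracks run
    both ways; stationary tracks stay within a sub-2 um excursion band.
    ``pause_prob`` shapes how late runs may start (runs are processive).
    """
    expected = {"anterograde", "retrograde", "bidirectional", "stationary"}
    if set(fractions) - expected:
        raise ValueError(f"unknown classes: {set(fractions) - expected}")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total}")
    if not (speed_um_s[0] > 0 and speed_um_s[1] >= speed_um_s[0]):
        raise ValueError("speeds must be positive")
    counts = largest_remainder_counts(
        {k: fractions.get(k, 0.0) for k in
         ["anterograde", "retrograde", "bidirectional", "stationary"]}, n_tracks)
    rng = np.random.default_rng(seed)
    t = np.arange(TRACK_SAMPLES, dtype=float)
    tracks, labels = [], {}
    i = 0
    for cls in ["anterograde", "retrograde", "bidirectional", "stationary"]:
        for _ in range(counts[cls]):
            n_runs = 1 if rng.random() < 1.0 - pause_prob else 2
            if cls == "anterograde":
                p = _directional_positions(rng, +1, n_runs, speed_um_s)
            elif cls == "retrograde":
                p = _directional_positions(rng, -1, n_runs, speed_um_s)
            elif cls == "bidirectional":
                p = _bidirectional_positions(rng, speed_um_s)
            else:
                p = _stationary_positions(rng)
            if noise_sd_um > 0:
                p = p + rng.normal(0.0, noise_sd_um, size=p.size)
            tid = f"track{i:04d}"
            tracks.append(VesicleTrack(track_id=tid, t_s=t, positions_um=p,
                                       compartment=compartment))
            labels[tid] = cls
            i += 1
    return tracks, GroundTruth(labels=labels)


def gen_parallel_tracks(n_tracks: int = 10,
                        speed_um_s: float = 0.05,
                        spacing_um: float = 2.0,
                        seed: int = 0) -> tuple[list[VesicleTrack], GroundTruth]:
    """Equal-speed, staggered-start tracks that never cross (tracker validation)."""
    rng = np.random.default_rng(seed)
    t = np.arange(TRACK_SAMPLES, dtype=float)
    tracks, labels = [], {}
    for i in range(n_tracks):
        p0 = 0.5 + i * spacing_um + rng.uniform(0, 0.3 * spacing_um)
        p = p0 + speed_um_s * t
        if p[-1] > REGION_LENGTH_UM - 0.5:
            raise ValueError("tracks leave the region; lower speed or spacing")
        tid = f"ptrack{i:02d}"
        tracks.append(VesicleTrack(track_id=tid, t_s=t, positions_um=p))
        labels[tid] = "anterograde" if speed_um_s * (TRACK_SAMPLES - 1) > 2 else "stationary"
    return tracks, GroundTruth(labels=labels)


@_register
def render_kymograph(tracks: list[VesicleTrack],
                     pixel_um: float = 0.2,
                     psf_sigma_px: float = 2.0,
                     snr: float = 10.0,
                     seed: int = 0,
                     amplitude: float = 1.0) -> KymographImage:
    """Render tracks into a kymograph: one Gaussian spot per vesicle per row,
    rows = frames, cols = ceil(30 um / pixel_um), plus additive noise at the
    requested SNR (amplitude / noise sd). Intensities are clipped at zero."""
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    n_rows = TRACK_SAMPLES
    n_cols = int(math.ceil(REGION_LENGTH_UM / pixel_um))
    img = np.zeros((n_rows, n_cols))
    cols = np.arange(n_cols)
    for tr in tracks:
        frames = np.round(tr.t_s).astype(int)
        for f, pos in zip(frames, tr.positions_um):
            if not 0 <= f < n_rows:
                continue
            x = pos / pixel_um
            img[f] += amplitude * np.exp(-0.5 * ((cols - x) / psf_sigma_px) ** 2)
    if snr and np.isfinite(snr):
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, amplitude / snr, size=img.shape)
    return KymographImage(pixels=np.clip(img, 0.0, None), pixel_um=pixel_um)


# ---------------------------------------------------------------------------
# axotomy time courses


def _frame_times(rng, duration_hr: float, frame_min_range) -> np.ndarray:
    lo, hi = frame_min_range
    if not (20.0 - 1e-9 <= lo <= hi <= 30.0 + 1e-9):
        raise ValueError("frame interval must lie in [20, 30] min")
    times = [0.0]
    while times[-1] < duration_hr:
        times.append(times[-1] + rng.uniform(lo, hi) / 60.0)
    return np.asarray(times)


@_register
def gen_axotomy_timecourse(outcome: str,
                           axotomy_um: float,
                           retraction_um: float | None = None,
                           retract_log10_mean: float = 2.0,
                           retract_log10_sd: float = 0.15,
                           bulb_time_hr: float | None = None,
                           retract_speed_um_hr: float | None = None,
                           init_delay_hr: float = 2.0,
                           elong_um_hr: float = 30.0,
                           gc_area_um2: float = 40.0,
                           bulb_area_um2: float = 25.0,
                           frame_min_range: tuple = (20.0, 30.0),
                           duration_hr: float | None = None,
                           death_time_hr: float = 5.0,
                           branch_point_um: float | None = None,
                           ectopic_offset_um: float | None = None,
                           noise_sd_um: float = 0.0,
                           seed: int = 0,
                           cell_id: str = "cell",
                           div: int | None = None,
                           substrate: str | None = None,
                           params: AxotomyParams | None = None,
                           ) -> tuple[AxotomyTimecourse, GroundTruth]:
    """One post-axotomy tip trajectory with a planted outcome and factors.

    The tip retracts linearly from the cut to the bulb position, dwells, and
    (for regeneration) elongates linearly from the initiation time. Planted
    bulb and initiation times are snapped onto the jittered frame grid so the
    trajectory encodes exactly the recorded ground truth. The mean retraction
    speed must exceed the bulb-stabilization threshold per frame, otherwise
    the planted bulb time is not representable and an error is raised.
    """
    allowed = {"death", "branch_loss", "regeneration", "ectopic", "no_regeneration"}
    if outcome not in allowed:
        raise ValueError(f"outcome must be one of {sorted(allowed)}")
    params = params or AxotomyParams()
    rng = np.random.default_rng(seed)

    if outcome == "branch_loss":
        if branch_point_um is None:
            branch_point_um = rng.uniform(0.30, 0.60) * axotomy_um
        retraction_um = axotomy_um - branch_point_um
    elif retraction_um is None:
        for _ in range(200):
            retraction_um = 10.0 ** rng.normal(retract_log10_mean, retract_log10_sd)
            if retraction_um < 0.6 * axotomy_um:
                break
        else:
            raise ValueError("could not draw a retraction below the cut distance")
    if retraction_um >= axotomy_um:
        raise ValueError(
            f"retraction ({retraction_um:.0f} um) exceeds axotomy distance "
            f"({axotomy_um:.0f} um)")
    if bulb_time_hr is None:
        speed = retract_speed_um_hr or rng.uniform(40.0, 100.0)
        # long retractions retract faster so the bulb forms inside the window
        speed = max(speed, retraction_um / 6.0)
        bulb_time_hr = retraction_um / speed
    elif bulb_time_hr > 9.0:
        raise ValueError("inconsistent parameters: planted bulb time past the "
                         "10 hr analysis window")

    if duration_hr is None:
        duration_hr = max(10.5, bulb_time_hr + init_delay_hr + 2.7)
    t = _frame_times(rng, duration_hr, frame_min_range)

    # snap planted times onto the frame grid
    bulb_idx = max(1, int(np.argmin(np.abs(t - bulb_time_hr))))
    t_bulb = t[bulb_idx]
    speed = retraction_um / t_bulb
    min_gap = float(np.diff(t[: bulb_idx + 1]).min())
    if speed * min_gap <= params.delta_stab_um:
        raise ValueError(
            f"inconsistent parameters: retraction speed {speed:.1f} um/hr cannot "
            f"encode the planted bulb time (needs > "
            f"{params.delta_stab_um / min_gap:.1f} um/hr)")

    bulb_pos = axotomy_um - retraction_um
    p = np.where(t <= t_bulb, axotomy_um - speed * t, bulb_pos)
    area = np.full(t.size, bulb_area_um2, dtype=float)
    flags: list[tuple] = []
    labels = {"outcome": outcome, "axotomy_um": float(axotomy_um),
              "retraction_um": float(retraction_um),
              "bulb_time_hr": float(t_bulb)}

    if outcome == "death":
        d_idx = int(np.argmin(np.abs(t - death_time_hr)))
        flags.append((float(t[d_idx]), "disintegration", None))
        p = p.copy()
        p[d_idx:] = p[d_idx]
        labels["death_time_hr"] = float(t[d_idx])
    elif outcome == "branch_loss":
        labels["branch_point_um"] = float(branch_point_um)
    elif outcome == "regeneration":
        init_idx = int(np.argmin(np.abs(t - (t_bulb + init_delay_hr))))
        init_idx = max(init_idx, bulb_idx + 1)
        t_init = t[init_idx]
        if t_init > 9.0:
            raise ValueError("planted initiation too late for the 10 hr window")
        p = np.where(t >= t_init, bulb_pos + elong_um_hr * (t - t_init), p)
        area = np.where(t >= t_init - 1e-9, gc_area_um2, area)
        labels.update({"init_delay_hr": float(t_init - t_bulb),
                       "init_time_abs_hr": float(t_init),
                       "elong_um_hr": float(elong_um_hr),
                       "regen_length_um": float(2.0 * elong_um_hr),
                       "gc_area_um2": float(gc_area_um2)})
    elif outcome == "ectopic":
        if ectopic_offset_um is None:
            ectopic_offset_um = rng.uniform(-80.0, 80.0)
        bt = t_bulb + rng.uniform(1.0, 4.0)
        b_idx = int(np.argmin(np.abs(t - bt)))
        flags.append((float(t[b_idx]), "new_branch",
                      float(bulb_pos + ectopic_offset_um)))
        labels["ectopic_position_um"] = float(bulb_pos + ectopic_offset_um)

    if noise_sd_um > 0:
        p = p + rng.normal(0.0, noise_sd_um, size=p.size)

    if outcome == "branch_loss":
        branch_points = [float(branch_point_um)]
    else:
        branch_points = [float(max(10.0, bulb_pos - 150.0))]

    tc = AxotomyTimecourse(cell_id=cell_id, axotomy_um=axotomy_um, t_hr=t,
                           tip_position_um=p, tip_area_um2=area, flags=flags,
                           div=div, substrate=substrate,
                           branch_points_um=branch_points)
    return tc, GroundTruth(labels={cell_id: labels})


def gen_axotomy_cohort(n_cells: int,
                       outcome_fractions: dict | None = None,
                       axotomy_range_um: tuple = (300.0, 1500.0),
                       retract_log10_mean: float = 2.0,
                       retract_log10_sd: float = 0.15,
                       div: int | None = None,
                       substrate: str | None = None,
                       seed: int = 0,
                       cell_prefix: str = "cell",
                       allocation: str = "largest_remainder",
                       **cell_kwargs,
                       ) -> tuple[list[AxotomyTimecourse], GroundTruth]:
    """A cohort of time courses with planted outcomes.

    ``allocation`` is 'largest_remainder' (deterministic, exact class counts)
    or 'multinomial' (each cell draws its outcome independently, so cohort
    counts fluctuate like a real experiment).
    """
    outcome_fractions = outcome_fractions or {
        "death": 0.15, "branch_loss": 0.10, "regeneration": 0.40,
        "ectopic": 0.10, "no_regeneration": 0.25}
    total = sum(outcome_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("outcome fractions must sum to 1")
    root = np.random.default_rng(seed)
    order = ["death", "branch_loss", "regeneration", "ectopic", "no_regeneration"]
    if allocation == "largest_remainder":
        counts = largest_remainder_counts(outcome_fractions, n_cells)
    elif allocation == "multinomial":
        draw = root.multinomial(n_cells, [outcome_fractions.get(o, 0.0) for o in order])
        counts = dict(zip(order, draw.tolist()))
    else:
        raise ValueError(f"unknown allocation {allocation!r}")
    seeds = root.integers(0, 2**31 - 1, size=n_cells)
    cohort, labels = [], {}
    i = 0
    for outcome in order:
        for _ in range(counts.get(outcome, 0)):
            cid = f"{cell_prefix}{i:04d}"
            local = np.random.default_rng(seeds[i])
            axo = local.uniform(*axotomy_range_um)
            tc, gt = gen_axotomy_timecourse(
                outcome, axo, retract_log10_mean=retract_log10_mean,
                retract_log10_sd=retract_log10_sd,
                init_delay_hr=float(local.uniform(1.0, 3.5)),
                elong_um_hr=float(local.uniform(20.0, 60.0)),
                gc_area_um2=float(local.uniform(20.0, 60.0)),
                seed=int(seeds[i]), cell_id=cid, div=div, substrate=substrate,
                **cell_kwargs)
            cohort.append(tc)
            labels[cid] = gt.labels[cid]
            i += 1
    return cohort, GroundTruth(labels=labels)


# ---------------------------------------------------------------------------
# expression matrices


@_register
def gen_expression_matrix(n_genes: int,
                          n_increasing: int,
                          n_decreasing: int,
                          fold: float = 5.0,
                          cv: float = 0.1,
                          floor_fpkm: float = 10.0,
                          seed: int = 0,
                          base_range: tuple = (4.0, 12.0),
                          flat_mix: tuple = (0.6, 0.2, 0.2),
                          cv_noisy: float = 1.5,
                          timepoints=TIMEPOINTS_DIV,
                          n_reps: int = 6,
                          ) -> tuple[ExpressionMatrix, GroundTruth]:
    """FPKM matrix over the culture timepoints with planted trending genes.

    Trending genes ramp geometrically between ``base`` and ``base * fold``
    across timepoints (monotone in the group means by construction). Flat
    genes come in three flavors mixed by ``flat_mix``: plain constant genes,
    low-expressed ramps (max mean below the 10 FPKM floor), and high-variance
    constant genes. Values are mean * lognormal(1, cv) per sample.
    """
    if n_increasing + n_decreasing > n_genes:
        raise ValueError("more trending genes than genes")
    if fold <= 3.0:
        raise ValueError("planted trending genes need fold > 3")
    rng = np.random.default_rng(seed)
    T = len(timepoints)
    n_flat = n_genes - n_increasing - n_decreasing
    flat_counts = largest_remainder_counts(
        {"plain": flat_mix[0], "low": flat_mix[1], "noisy": flat_mix[2]}, n_flat)

    genes, truth, mean_rows, cv_rows = [], {}, [], []
    i = 0

    def add(name_cls, means, gene_cv):
        nonlocal i
        gid = f"g{i:05d}"
        genes.append(gid)
        truth[gid] = name_cls if name_cls in ("increasing", "decreasing") else "flat"
        mean_rows.append(means)
        cv_rows.append(gene_cv)
        i += 1

    for _ in range(n_increasing):
        base = rng.uniform(*base_range)
        add("increasing", base * fold ** (np.arange(T) / (T - 1)), cv)
    for _ in range(n_decreasing):
        base = rng.uniform(*base_range)
        add("decreasing", base * fold ** ((T - 1 - np.arange(T)) / (T - 1)), cv)
    for _ in range(flat_counts["plain"]):
        add("flat", np.full(T, rng.uniform(1.0, 40.0)), cv)
    for _ in range(flat_counts["low"]):
        top = rng.uniform(2.0, 0.8 * floor_fpkm)
        f = rng.uniform(3.5, 6.0)
        add("flat", (top / f) * f ** (np.arange(T) / (T - 1)), cv)
    for _ in range(flat_counts["noisy"]):
        add("flat", np.full(T, rng.uniform(15.0, 40.0)), cv_noisy)

    means = np.asarray(mean_rows)                      # (G, T)
    cvs = np.asarray(cv_rows)[:, None, None]           # (G, 1, 1)
    sigma = np.sqrt(np.log1p(cvs**2))
    noise = rng.normal(size=(len(genes), T, n_reps))
    values = means[:, :, None] * np.exp(sigma * noise - sigma**2 / 2.0)

    sample_ids = [f"DIV{d}_r{r+1}" for d in timepoints for r in range(n_reps)]
    fpkm = pd.DataFrame(values.reshape(len(genes), T * n_reps),
                        index=genes, columns=sample_ids)
    sample_map = pd.DataFrame({
        "sample_id": sample_ids,
        "div": [d for d in timepoints for _ in range(n_reps)],
        "replicate": [r + 1 for _ in timepoints for r in range(n_reps)]})
    return ExpressionMatrix(fpkm=fpkm, sample_map=sample_map), GroundTruth(labels=truth)


# ---------------------------------------------------------------------------
# intensity profiles


@_register
def gen_intensity_profiles(axon_dendrite_ratio: float = 2.0,
                           background: float = 10.0,
                           noise_sd: float = 0.0,
                           n_dendrites: int = 4,
                           lengths_um: dict | None = None,
                           seed: int = 0,
                           dendrite_raw_mean: float = 30.0,
                           distal_400_ratio: float = 1.0,
                           distal_800_ratio: float = 1.0,
                           cell_body_raw: float = 60.0,
                           dim_dendrite_scale: float = 0.2,
                           cell_id: str = "cell",
                           ) -> tuple[list[NeuriteIntensityProfile], dict, GroundTruth]:
    """Polarized profiles for one cell: one long axon, >= 3 bright dendrites
    (plus dimmer extras), paired backgrounds, and a cell-body measurement.

    The planted axon/dendrite ratio applies to background-corrected 0-100 um
    signals. Returns (profiles, cell_body dict, ground truth).
    """
    if n_dendrites < 3:
        raise ValueError("need at least 3 dendrites (brightest-three rule)")
    lengths = {"axon": 900.0, "dendrite": 150.0, **(lengths_um or {})}
    if lengths["axon"] < 850.0:
        raise ValueError("axon must reach the 750-850 um window")
    if lengths["dendrite"] < 100.0:
        raise ValueError("dendrites must cover the 0-100 um window")
    rng = np.random.default_rng(seed)
    dendrite_corr = dendrite_raw_mean - background
    if dendrite_corr <= 0:
        raise ValueError("dendrite signal must exceed background")
    axon_corr = axon_dendrite_ratio * dendrite_corr

    def profile(nid, kind, length, level_fn, regions):
        x = np.arange(0.0, length + 0.5, 1.0)
        y = level_fn(x) + (rng.normal(0.0, noise_sd, x.size) if noise_sd > 0 else 0.0)
        return NeuriteIntensityProfile(cell_id=cell_id, neurite_id=nid, kind=kind,
                                       arclength_um=x, intensity=np.clip(y, 0, None),
                                       region_backgrounds=regions)

    def axon_level(x):
        y = np.full(x.size, background + 0.5 * axon_corr)
        y[x < 100.0] = background + axon_corr
        y[(x >= 350.0) & (x < 450.0)] = background + distal_400_ratio * axon_corr
        y[(x >= 750.0) & (x < 850.0)] = background + distal_800_ratio * axon_corr
        return y

    profiles = [profile("axon0", "axon", lengths["axon"], axon_level,
                        {"stem": background, "distal_400": background,
                         "distal_800": background})]
    for d in range(n_dendrites):
        level = dendrite_corr if d < 3 else dim_dendrite_scale * dendrite_corr
        profiles.append(profile(
            f"dend{d}", "dendrite", lengths["dendrite"],
            lambda x, lv=level: np.full(x.size, background + lv),
            {"stem": background}))
    cell_body = {"intensity": cell_body_raw, "background": background}
    gt = GroundTruth(labels={cell_id: {
        "axon_dendrite_ratio": float(axon_dendrite_ratio),
        "axon_stem_signal": float(axon_corr),
        "dendrite_signal": float(dendrite_corr),
        "cell_body_signal": float(cell_body_raw - background),
        "distal_400_ratio": float(distal_400_ratio),
        "distal_800_ratio": float(distal_800_ratio),
        "bright_dendrites": [f"dend{d}" for d in range(3)],
    }})
    return profiles, cell_body, gt
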