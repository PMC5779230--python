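"""Vesicle transport quantification from kymographs.

A kymograph stacks one row per frame (1 frame/s for 3 min) over a 30 um
neurite region, so moving vesicles appear as diagonal ridges. Tracks are
segmented into maximal monotone runs; runs moving in one direction for more
than 2 um count as movements, and a track is anterograde, retrograde,
bidirectional, or stationary according to which movement directions it
contains. Per-cell transport reports the direction fractions and the mean
velocity over all movements of each direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "VesicleTrack",
    "Movement",
    "TransportSummary",
    "KymographImage",
    "trace_tracks",
    "segment_movements",
    "classify_track",
    "summarize_transport",
    "match_tracks",
    "MOVEMENT_THRESHOLD_UM",
]

MOVEMENT_THRESHOLD_UM = 2.0      # 'moving only in one direction for more than 2 um'
REGION_LENGTH_UM = 30.0
FRAME_INTERVAL_S = 1.0


@dataclass
class VesicleTrack:
    track_id: str
    t_s: np.ndarray
    positions_um: np.ndarray       # positive = away from the soma
    compartment: str = "axon"      # axon | dendrite
    region_length_um: float = REGION_LENGTH_UM

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.t_s.size != self.positions_um.size:
            raise ValueError("time and position arrays must match")
        if self.t_s.size and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class Movement:
    start_s: float
    end_s: float
    direction: str                 # anterograde | retrograde
    net_displacement_um: float

    @property
    def speed_um_s(self) -> float:
        return self.net_displacement_um / (self.end_s - self.start_s)


@dataclass
class TransportSummary:
    n_tracks: int
    fractions: dict
    mean_anterograde_velocity_um_s: float | None
    mean_retrograde_velocity_um_s: float | None


@dataclass
class KymographImage:
    pixels: np.ndarray             # rows = frames, cols = distance
    pixel_um: float
    frame_interval_s: float = FRAME_INTERVAL_S

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("kymograph must be a 2-D image")
        if np.any(self.pixels < 0):
            raise ValueError("kymograph intensities must be nonnegative")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")


# ---------------------------------------------------------------------------
# movement segmentation and classification


def segment_movements(track: VesicleTrack,
                      reversal_tolerance_um: float = 0.2,
                      threshold_um: float = MOVEMENT_THRESHOLD_UM,
                      inclusive: bool = False) -> list[Movement]:
    """Partition a track into maximal monotone runs and keep those over 2 um.

    Reversals smaller than ``reversal_tolerance_um`` (localization jitter) do
    not break a run. Net displacement, not path length, is compared with the
    threshold; the comparison is strict by default ('more than 2 um').
    """
    p = track.positions_um
    t = track.t_s
    if p.size < 2:
        return []
    runs: list[tuple[int, int]] = []
    direction = 0
    lo_i = hi_i = 0
    lo = hi = p[0]
    start = 0
    ext_i = 0
    for i in range(1, p.size):
        x = p[i]
        if direction == 0:
            # anchor at the latest extremum so a leading pause is not part of
            # the first run
            if x >= hi:
                hi, hi_i = x, i
            if x <= lo:
                lo, lo_i = x, i
            if hi - lo > reversal_tolerance_um:
                if hi_i >= lo_i:
                    direction, start, ext_i = 1, lo_i, hi_i
                else:
                    direction, start, ext_i = -1, hi_i, lo_i
        elif direction == 1:
            if x > p[ext_i]:
                ext_i = i
            elif p[ext_i] - x > reversal_tolerance_um:
                runs.append((start, ext_i))
                direction, start = -1, ext_i
                ext_i = i
        else:
            if x < p[ext_i]:
                ext_i = i
            elif x - p[ext_i] > reversal_tolerance_um:
                runs.append((start, ext_i))
                direction, start = 1, ext_i
                ext_i = i
    if direction != 0:
        runs.append((start, ext_i))
    movements = []
    for a, b in runs:
        net = p[b] - p[a]
        keep = abs(net) >= threshold_um if inclusive else abs(net) > threshold_um
        if keep and b > a:
            movements.append(Movement(
                start_s=float(t[a]), end_s=float(t[b]),
                direction="anterograde" if net > 0 else "retrograde",
                net_displacement_um=float(abs(net))))
    return movements


def classify_track(track: VesicleTrack, **segment_kwargs) -> str:
    """anterograde | retrograde | bidirectional | stationary per the 2 um rule."""
    moves = segment_movements(track, **segment_kwargs)
    has_a = any(m.direction == "anterograde" for m in moves)
    has_r = any(m.direction == "retrograde" for m in moves)
    if has_a and has_r:
        return "bidirectional"
    if has_a:
        return "anterograde"
    if has_r:
        return "retrograde"
    return "stationary"


def summarize_transport(tracks: list[VesicleTrack], **segment_kwargs) -> TransportSummary:
    """Direction fractions over tracks and per-direction mean movement velocity.

    The cell's anterograde (retrograde) velocity is the mean speed over every
    anterograde (retrograde) movement across all of the cell's tracks; it is
    absent when no movement of that direction exists.
    """
    if not tracks:
        raise ValueError("summarize_transport needs at least one track")
    counts = {"anterograde": 0, "retrograde": 0, "bidirectional": 0, "stationary": 0}
    speeds = {"anterograde": [], "retrograde": []}
    for tr in tracks:
        moves = segment_movements(tr, **segment_kwargs)
        for m in moves:
            speeds[m.direction].append(m.speed_um_s)
        counts[classify_track(tr, **segment_kwargs)] += 1
    n = len(tracks)
    fractions = {k: v / n for k, v in counts.items()}
    mean_a = float(np.mean(speeds["anterograde"])) if speeds["anterograde"] else None
    mean_r = float(np.mean(speeds["retrograde"])) if speeds["retrograde"] else None
    return TransportSummary(n_tracks=n, fractions=fractions,
                            mean_anterograde_velocity_um_s=mean_a,
                            mean_retrograde_velocity_um_s=mean_r)


def match_tracks(planted: list[VesicleTrack], recovered: list[VesicleTrack],
                 min_overlap: float = 0.9) -> dict:
    """Match planted tracks to recovered ones (validation helper).

    A planted track counts as recovered when some recovered track overlaps it
    in time on >= ``min_overlap`` of its samples; the match minimizes the mean
    absolute position error over the common frames. Returns the recovery
    fraction and the mean position error (um) over matched tracks.
    """
    errors = []
    n_matched = 0
    for t in planted:
        best = None
        for r in recovered:
            common, ti, ri = np.intersect1d(t.t_s, r.t_s, return_indices=True)
            if common.size < min_overlap * t.t_s.size:
                continue
            err = float(np.abs(t.positions_um[ti] - r.positions_um[ri]).mean())
            if best is None or err < best:
                best = err
        if best is not None:
            n_matched += 1
            errors.append(best)
    return {"recovered_fraction": n_matched / len(planted) if planted else 0.0,
            "mean_position_error_um": float(np.mean(errors)) if errors else None}


# ---------------------------------------------------------------------------
# image -> tracks


def _subpixel_peak(row: np.ndarray, idx: int) -> float:
    """Refine a peak position; Gaussian (log-parabolic) interpolation when the
    three samples are positive, plain parabolic otherwise."""
    if idx <= 0 or idx >= row.size - 1:
        return float(idx)
    a, b, c = row[idx - 1], row[idx], row[idx + 1]
    if a > 0 and b > 0 and c > 0:
        la, lb, lc = np.log(a), np.log(b), np.log(c)
        den = la - 2 * lb + lc
        if den < 0:
            return float(idx + 0.5 * (la - lc) / den)
    den = a - 2 * b + c
    if den < 0:
        return float(idx + 0.5 * (a - c) / den)
    return float(idx)


def trace_tracks(image: KymographImage,
                 min_intensity: float = 0.5,
                 max_step_px: float = 5.0,
                 max_gap_frames: int = 2,
                 min_duration_s: float = 10.0,
                 smooth_sigma_px: float = 1.0,
                 min_separation_px: int = 3) -> list[VesicleTrack]:
    """Build tracks from per-row intensity peaks by nearest-neighbour linking.

    Rows are lightly Gaussian-smoothed before peak finding (smoothing a
    Gaussian spot leaves its center unchanged). Each frame's local maxima
    above ``min_intensity`` are linked to the nearest active track within
    ``max_step_px`` (scaled by any bridged gap); ambiguous claims go to the
    nearest detection and the losing track ends, so crossing tracks are split
    rather than guessed. Tracks shorter than ``min_duration_s`` are discarded.
    """
    img = image.pixels
    if img.size == 0:
        return []
    n_frames = img.shape[0]
    active: list[dict] = []
    finished: list[dict] = []
    for f in range(n_frames):
        row = gaussian_filter1d(img[f], smooth_sigma_px) if smooth_sigma_px > 0 \
            else img[f]
        peaks, _ = find_peaks(row, height=min_intensity,
                              distance=max(1, min_separation_px))
        detections = [_subpixel_peak(row, p) for p in peaks]
        # retire tracks whose gap exceeded the allowance
        still = []
        for tr in active:
            if f - tr["frames"][-1] > max_gap_frames + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        # candidate links sorted by distance, greedy assignment
        links = []
        for ti, tr in enumerate(active):
            gap = f - tr["frames"][-1]
            allow = max_step_px * gap
            for di, d in enumerate(detections):
                dist = abs(d - tr["positions"][-1])
                if dist <= allow:
                    links.append((dist, ti, di))
        links.sort()
        used_t, used_d = set(), set()
        for dist, ti, di in links:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            active[ti]["frames"].append(f)
            active[ti]["positions"].append(detections[di])
        for di, d in enumerate(detections):
            if di not in used_d:
                active.append({"frames": [f], "positions": [d]})
    finished.extend(active)
    tracks = []
    for i, tr in enumerate(sorted(finished, key=lambda x: (x["frames"][0], x["positions"][0]))):
        t = np.asarray(tr["frames"], dtype=float) * image.frame_interval_s
        if t[-1] - t[0] < min_duration_s:
            continue
        pos = np.asarray(tr["positions"]) * image.pixel_um
        tracks.append(VesicleTrack(track_id=f"trk{i:03d}", t_s=t, positions_um=pos))
    return tracks
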