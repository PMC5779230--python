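"""Compartment-specific fluorescence and polarity ratios.

Each measured region is corrected by subtracting the intensity of a paired
adjacent control region (non-specific staining). The axon stem signal is the
corrected 0-100 um axon region; the dendrite signal averages the corrected
0-100 um regions of the three brightest dendrites; distal axon windows sit at
350-450 um and 750-850 um from the cell body. Polarity is summarized as
axon/dendrite, axon/cell-body, dendrite/cell-body and distal/stem ratios.

Windows are half-open [a, b) in um of traced arclength from the soma edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuriteIntensityProfile",
    "PolaritySummary",
    "corrected_intensity",
    "compute_compartment_signals",
    "compute_polarity_ratios",
    "AXON_STEM_WINDOW",
    "AXON_400_WINDOW",
    "AXON_800_WINDOW",
]

AXON_STEM_WINDOW = (0.0, 100.0)
DENDRITE_WINDOW = (0.0, 100.0)
AXON_400_WINDOW = (350.0, 450.0)
AXON_800_WINDOW = (750.0, 850.0)
N_BRIGHTEST_DENDRITES = 3


@dataclass
class NeuriteIntensityProfile:
    """Fluorescence vs arclength for one neurite, with per-region backgrounds.

    ``region_backgrounds`` maps region names ('stem', 'distal_400',
    'distal_800') to the paired adjacent-background intensity chosen for that
    region; backgrounds are supplied, not estimated.
    """

    cell_id: str
    neurite_id: str
    kind: str  # axon | dendrite
    arclength_um: np.ndarray
    intensity: np.ndarray
    region_backgrounds: dict = field(default_factory=dict)

    def __post_init__(self):
        self.arclength_um = np.asarray(self.arclength_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.kind not in ("axon", "dendrite"):
            raise ValueError(f"kind must be axon or dendrite, got {self.kind!r}")
        if self.arclength_um.size != self.intensity.size:
            raise ValueError("arclength and intensity must match")
        if np.any(self.arclength_um < 0) or np.any(np.diff(self.arclength_um) <= 0):
            raise ValueError("arclength must be nonnegative and increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def length_um(self) -> float:
        return float(self.arclength_um[-1])


@dataclass
class PolaritySummary:
    cell_id: str
    axon_stem_signal: float | None = None
    dendrite_signal: float | None = None
    cell_body_signal: float | None = None
    axon_400_signal: float | None = None
    axon_800_signal: float | None = None
    axon_dendrite_ratio: float | None = None
    axon_cell_body_ratio: float | None = None
    dendrite_cell_body_ratio: float | None = None
    distal_stem_ratio_400: float | None = None
    distal_stem_ratio_800: float | None = None
    flags: list[str] = field(default_factory=list)


def corrected_intensity(profile: NeuriteIntensityProfile,
                        window_um: tuple,
                        background: float | None = None,
                        region: str = "stem") -> tuple[float, list[str]]:
    """Mean intensity over the half-open window minus the paired background.

    Negative corrected intensities are permitted but flagged. The profile must
    cover the window.
    """
    a, b = window_um
    if profile.length_um < b - 1e-9:
        raise ValueError(
            f"window {a}-{b} um outside profile extent ({profile.length_um:.1f} um) "
            f"for {profile.neurite_id}")
    if background is None:
        if region not in profile.region_backgrounds:
            raise ValueError(f"no background supplied for region {region!r} "
                             f"of {profile.neurite_id}")
        background = profile.region_backgrounds[region]
    mask = (profile.arclength_um >= a) & (profile.arclength_um < b)
    if not mask.any():
        raise ValueError(f"no samples in window {a}-{b} um")
    value = float(profile.intensity[mask].mean()) - float(background)
    flags = []
    if value < 0:
        flags.append(f"negative corrected intensity ({value:.3g}) in "
                     f"{profile.neurite_id} {region}")
    return value, flags


def compute_compartment_signals(profiles: list[NeuriteIntensityProfile],
                                cell_body_intensity: float | None = None,
                                cell_body_background: float = 0.0
                                ) -> PolaritySummary:
    """Axon stem, dendrite (brightest three), cell body and distal signals.

    Requires exactly one axon profile (cells with more than one axon are
    excluded upstream) and at least three dendrite profiles. Dendrites are
    ranked by corrected 0-100 um intensity, ties broken toward the lowest
    neurite id.
    """
    axons = [p for p in profiles if p.kind == "axon"]
    dendrites = [p for p in profiles if p.kind == "dendrite"]
    if len(axons) != 1:
        raise ValueError(f"need exactly one axon profile, got {len(axons)}")
    if len(dendrites) < N_BRIGHTEST_DENDRITES:
        raise ValueError(f"need >= {N_BRIGHTEST_DENDRITES} dendrite profiles, "
                         f"got {len(dendrites)}")
    axon = axons[0]
    cell_id = axon.cell_id
    summary = PolaritySummary(cell_id=cell_id)
    stem, flags = corrected_intensity(axon, AXON_STEM_WINDOW, region="stem")
    summary.axon_stem_signal = stem
    summary.flags.extend(flags)

    dvals = []
    for d in dendrites:
        v, fl = corrected_intensity(d, DENDRITE_WINDOW, region="stem")
        summary.flags.extend(fl)
        dvals.append((v, d.neurite_id))
    dvals.sort(key=lambda t: (-t[0], t[1]))
    top = dvals[:N_BRIGHTEST_DENDRITES]
    summary.dendrite_signal = float(np.mean([v for v, _ in top]))

    for window, attr in ((AXON_400_WINDOW, "axon_400_signal"),
                         (AXON_800_WINDOW, "axon_800_signal")):
        region = "distal_400" if attr == "axon_400_signal" else "distal_800"
        if axon.length_um >= window[1]:
            v, fl = corrected_intensity(axon, window, region=region)
            setattr(summary, attr, v)
            summary.flags.extend(fl)
        else:
            summary.flags.append(f"axon too short for {window[0]}-{window[1]} um window")
    if cell_body_intensity is not None:
        summary.cell_body_signal = float(cell_body_intensity) - float(cell_body_background)
        if summary.cell_body_signal < 0:
            summary.flags.append("negative corrected cell body signal")
    return summary


def _ratio(num, den):
    if num is None or den is None or den <= 0:
        return None
    return num / den


def compute_polarity_ratios(summary: PolaritySummary) -> PolaritySummary:
    """Fill the polarity ratios; ratios with non-positive denominators are
    left undefined and flagged."""
    summary.axon_dendrite_ratio = _ratio(summary.axon_stem_signal, summary.dendrite_signal)
    summary.axon_cell_body_ratio = _ratio(summary.axon_stem_signal, summary.cell_body_signal)
    summary.dendrite_cell_body_ratio = _ratio(summary.dendrite_signal, summary.cell_body_signal)
    summary.distal_stem_ratio_400 = _ratio(summary.axon_400_signal, summary.axon_stem_signal)
    summary.distal_stem_ratio_800 = _ratio(summary.axon_800_signal, summary.axon_stem_signal)
    for name in ("axon_dendrite_ratio", "axon_cell_body_ratio",
                 "dendrite_cell_body_ratio", "distal_stem_ratio_400",
                 "distal_stem_ratio_800"):
        if getattr(summary, name) is None:
            summary.flags.append(f"{name} undefined (missing or non-positive denominator)")
    return summary
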