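# Methods

This note documents the models, rules and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the underlying measurement conventions left room.

## Action-potential detection and ephys features

A current-clamp recording applies 800 ms negative and positive steps in an
alternating manner, increasing by 20 pA. Detection classifies as an AP any
event whose discrete central second difference of Vm exceeds 20 mV/ms² and
whose potential reaches 0 mV within a 10 ms confirmation window. Choices:

- *Acceleration* is computed on the raw trace (no smoothing by default; an
  optional 5-point Savitzky–Golay switch exists). The criterion has the units
  of a second derivative and no filter is part of its definition.
- *Confirmation window* 10 ms: longer than any physiological upstroke, short
  enough not to pair a crossing with a later unrelated peak.
- *Refractory handling*: after confirming an event, scanning resumes once Vm
  falls back below that event's threshold voltage, so a multi-crossing
  upstroke yields one event.
- *Threshold voltage* is Vm at the first acceleration crossing; amplitude is
  peak minus threshold; width runs from the half-maximal-amplitude voltage on
  the upstroke to the same voltage on repolarization, with linear
  interpolation between samples. A spike that never repolarizes below
  half-max within the trace gets a flagged, undefined width rather than an
  error.
- *Passive properties*: resting potential is the mean over the 200 ms
  immediately preceding the first step ("before any current" without
  consuming the whole recording); input resistance uses the
  smallest-magnitude of the first three negative steps (staying in the linear
  regime), with ΔV taken as the mean of the final 100 ms of the step minus
  baseline. Spontaneous activity applies the same AP rule to a ≥ 2 min
  zero-current recording. Membrane capacitance is out of scope.

The synthetic spike is a difference of exponentials (rise 0.3 ms, decay
1.1 ms, peak +20 mV by default) minus a small, slow afterhyperpolarization
(6% of peak, 10 ms) — the simplest waveform whose second derivative, peak and
half-width are controllable, whose onset kink guarantees a large on-sample
second difference, and whose undershoot lets the detector's refractory rule
terminate. `template_fwhm` computes the waveform's exact half-width by root
finding and is the oracle for width recovery (tested to ±0.1 ms). Distractor
deflections use the same waveform scaled to peak at −20 mV: they pass the
acceleration criterion and fail the 0 mV gate.

## Kymograph transport

Tracks sample one position per second for 3 min inside a 30 µm region,
positive direction away from the soma. Segmentation partitions a track into
maximal monotone runs anchored at the latest extremum, ignoring reversals
smaller than 0.2 µm (localization jitter); runs whose **net displacement**
(not path length) exceeds 2 µm strictly become movements with
speed = net / duration. The class rule: anterograde iff ≥ 1 anterograde and 0
retrograde movements, retrograde symmetric, bidirectional iff both,
stationary otherwise — the fourth class names the sub-2 µm vesicles so the
fractions sum to 1. Whether "more than 2 µm" is strict is configurable
(`inclusive=`); strict is the default. Mirror symmetry (negating positions
swaps the direction classes exactly) is enforced by construction and tested.

The tracker is deliberately simple: per-row local maxima (after light
Gaussian row smoothing, which leaves a Gaussian spot's center unchanged) with
sub-pixel refinement (log-parabolic where valid, parabolic otherwise), linked
frame-to-frame by nearest neighbour within a gate, bridging gaps of ≤ 2
frames; ambiguous claims end the losing track, so crossing tracks split
rather than guess; fragments shorter than 10 s are dropped. It targets
rendered synthetic kymographs, not raw movies.

Generated directional tracks plant contiguous monotone runs of net ≥ 4 µm at
0.3–1.5 µm/s — comfortably above the 2 µm rule so 0.1 µm position noise
cannot demote a class — while stationary tracks stay inside a ±0.8 µm
reflected band. Speeds and the one-or-two-run structure are what vesicle
kymographs of recycling-endosome markers look like; the renderer (Gaussian
spots, additive noise at a stated SNR) does not attempt photorealism,
photobleaching, or intensity-based identity.

## Axotomy scoring

Cut distances lie in 250–2000 µm from the axon stem; frames arrive every
20–30 min (timestamps explicit, nothing assumes uniform spacing) and the
first 10 hr are analysed. Scoring rules and their parameters:

- *Death*: a disintegration/cell-disruption flag at t ≤ 10 hr; excluded from
  factor computation, as is branch loss.
- *Bulb stabilization*: the first frame from which the next k_stab = 2
  inter-frame position changes are each below δ_stab = 10 µm. A positional
  criterion is the only trajectory-level proxy for the morphological bulb;
  both parameters are configurable. Retraction distance is the cut distance
  minus the stabilized position, so retraction + bulb position = cut distance
  exactly.
- *Branch loss*: the stabilized tip lies within 10 µm of the nearest proximal
  branch point.
- *Steady extension*: the earliest frame t\* after the bulb where the first
  step advances, no step retreats beyond 2 µm, and the cumulative gain stays
  at or above v_min = 10 µm/hr at every frame of the following ≥ 1 hr window.
  The minimum rate excludes ordinary bulb motility (bulbs are usually
  motile); the first-step condition pins t\* to the actual start and makes
  noise-free recovery exact. Initiation time is t\* minus the bulb time.
- *Ectopic growth*: failing steady extension, a new-branch flag within 100 µm
  of the bulb.
- *Regeneration length*: advancing (monotone) segments summed over the 2 hr
  after initiation, with interpolated endpoints — path length along the
  recorded trajectory, consistent with "length of axon that extended".
- *Growth cone area*: mean of the tip areas at the frames nearest 20, 40 and
  60 min after initiation (frames are 20–30 min apart, so nearest-frame
  matching is the honest default; interpolation is available).
- *Categorization*: long retraction is ≥ 70 µm (inclusive on the long side);
  retraction is analysed on the log10 scale; the proximal/distal cut boundary
  defaults to 500 µm and is an artifact default, configurable and recorded in
  output metadata, because no universal numeric boundary exists for rodent
  neurons. Overall regeneration counts regeneration and ectopic growth.

The mixture model fits 1- and 2-component normal mixtures to log10 distances
by EM with five quantile-seeded restarts per k, an SD floor of 1e-3, and BIC
selection; the reported boundary is the posterior-equality point between the
component means (closed-form root of the log-density difference), mapped back
to µm. A degenerate all-equal sample returns k = 1 at the floor with a
warning.

The generator retracts linearly to the bulb, dwells, and elongates linearly
after initiation. Planted bulb and initiation times are snapped onto the
jittered frame grid and the snapped values recorded as ground truth: exact
length recovery and one-frame time recovery are only well-posed when the
planted event is representable on the sampled grid. Parameter sets whose mean
retraction speed cannot exceed δ_stab per minimum frame interval, or whose
bulb would form after 9 hr, are rejected as inconsistent rather than silently
producing unrecoverable truth. Cohort defaults draw log10 retraction from
N(2.0, 0.15) and retraction speeds of 40–100 µm/hr, giving bulb times of
roughly 1–2.5 hr — the regime reported for maturing cortical neurons.
Inter-frame positional measurement noise is exposed as a parameter
(`noise_sd_um`, default 0) rather than fixed, since no value is established.

## Polarity

All windows are half-open [a, b) in µm of traced arclength from the soma
edge (avoiding an off-by-one at 100 µm). Each measured region subtracts a
*supplied* paired adjacent background — region selection avoids nearby
structures and is inherently manual, so no automatic background estimation is
attempted. The dendrite signal averages the corrected 0–100 µm intensity of
the three brightest dendrites, ranked by **corrected** intensity (consistent
with every other reported quantity), ties broken toward the lowest neurite
id. Cells must have exactly one axon (multi-axon cells are excluded upstream)
and at least three dendrites. Negative corrected intensities are permitted
but flagged; ratios with non-positive denominators are undefined and flagged.
The cell body value is a supplied scalar with its own background — soma
segmentation is out of scope.

## Expression trends

"Highest/lowest FPKM value" is read as the highest/lowest *timepoint group
mean*: the significance criterion tests between the highest and lowest
groups, which only makes sense group-wise. The FDR procedure is
Benjamini–Hochberg (the field default where only "FDR adjusted" is stated);
Welch's t is applied per gene between the argmax and argmin timepoints (ties
broken toward the earlier timepoint, deterministically); fold uses a 0.01
pseudocount against silent genes while the > 10 FPKM floor is evaluated on
raw means. The classifier never assumes monotonicity — it compares extreme
timepoints only — even though the generator's trending genes are monotone
geometric ramps. Generated flat genes come in three flavors (plain constant,
low-expressed ramps under the floor, high-variance constant) so specificity
is exercised against each failure mode of the rule; high-variance genes are
the one flavor that occasionally defeats it, because choosing the extreme
groups post hoc inflates the t statistic.

## Statistics harness

- `t_test_auto`: variance equality gated by a two-sided F-ratio test at
  α = 0.05 (the convention is recorded in `method_path` so analyses are
  auditable); equal → Student, unequal → Welch with Welch–Satterthwaite df.
  Zero-variance degeneracies use the p = 1 / p = 0 conventions, flagged.
- `anova_posthoc`: one-way ANOVA; in auto mode Bartlett's test at α = 0.05 is
  the only variance-homogeneity gate and routes to Games–Howell when
  violated, otherwise Dunnett versus a named control or Bonferroni-adjusted
  pairwise Student's t.
- `games_howell`: per pair, Welch SE and df (floored at 2 to keep the
  integral defined), range statistic q = |Δm|·√2/SE, and p from a
  studentized-range CDF evaluated in-package by Gauss–Legendre quadrature of
  the scale-mixture double integral (160 inner × 80 outer nodes, chi quantile
  outer bounds at 1e-12). The implementation agrees with
  `scipy.stats.studentized_range` to ~1e-4 and with Monte-Carlo quantiles to
  < 0.005, and its family-wise error under the null sits inside the 99%
  binomial band of α = 0.05 at 10,000 simulations.
- Dunnett's comparisons delegate to `scipy.stats.dunnett` (seeded); writing a
  second multivariate-t integrator would duplicate a maintained one without
  changing the surface.
- `fisher_exact_p`: two-sided p by hypergeometric point-probability
  enumeration — the sum of all tables with the observed margins whose
  probability does not exceed the observed table's (with a 1e-9 relative
  guard against ties lost to rounding). Verified against
  `scipy.stats.fisher_exact` for every 2×2 table with total n ≤ 40. r×c
  tables get a Monte-Carlo permutation p and are flagged. Bonferroni uses
  min(1, m·p) across the submitted tables.
- `kruskal_wallis`: tie-corrected H with the chi-square approximation; an
  exact permutation p (full enumeration over rank assignments) is available
  for total n ≤ 12.
- Sidedness is two-sided throughout; no one-sided convention is stated
  anywhere upstream.
- The two-way ANOVA used once for vesicle-movement data is a thin delegation
  to statsmodels.

## Orchestration and determinism

Every generator and the full pipeline are pure functions of their parameters
and seed. `run_full_analysis` derives per-stage seeds from the global seed by
CRC-32 of `"{seed}:{stage}"` (stable across platforms, < 2³¹), writes every
output as CSV/JSON/TIFF with unit-bearing column names, and records a
manifest of parameters, seeds and SHA-256 checksums; reruns with an identical
config are byte-identical. Distances are µm, axotomy times hr, ephys times
ms, intensities arbitrary units.

## Problem sizes

The default verification sizes are 100 traces (0–10 spikes each), 1,000
tracks per noise condition, 10 rendered tracks at SNR 10, 500 axotomy cells,
100 mixture seeds at n = 300, 1,000 genes × 30 samples, exhaustive 2×2
enumeration to n = 40, 10,000-replicate null simulations (two groups of 20
for the t-test, three of 25 for Kruskal–Wallis — where the chi-square
approximation is accurate — and four of 10 for the Games–Howell family), and
100 cohort
seeds at n = 50/group for the Fisher power check — sizes at which every
recovery property is measured with comfortable margin on a single CPU.

## What passing tests do and do not show

The generators plant the statistical structure the measurements are defined
on: log-normal retraction with a biphasic log10 mixture at intermediate
maturity, direction-biased processive transport, monotone expression ramps,
polarized intensity profiles. They do not emulate segmentation error from
real images, photobleaching, baseline drift or electrode artifacts in
recordings, crossing vesicle identities, or FPKM estimation noise beyond
log-normal dispersion. Closed-loop recovery therefore validates the
*rules* — that the implementations compute exactly the quantities defined
above, with calibrated statistics — not the upstream image- and
signal-extraction steps that produce such inputs from raw microscopy, which
are out of scope by design.
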