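"""Laser-axotomy outcome scoring and regeneration factors.

After axotomy a neuron either dies (axon disintegration or cell disruption
within 10 hr), loses the cut branch back to the nearest branch point, or forms
a retraction bulb. Bulb-forming neurons then regenerate, grow an ectopic
branch near the bulb, or fail to regenerate. From each tip trajectory the six
regeneration factors are computed: retraction distance, bulb formation time,
regeneration ratio (at cohort level), regeneration initiation time,
regeneration length, and growth cone area.

Retraction distances are log-normally distributed; at intermediate maturity
the log10 distances are biphasic, so a 1- vs 2-component normal mixture is
fitted by EM and selected by BIC, with the short/long boundary at 70 um
(inclusive on the long side).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "AxotomyTimecourse",
    "RegenerationRecord",
    "MixtureFit",
    "AxotomyParams",
    "classify_initial_response",
    "measure_retraction",
    "detect_regeneration",
    "measure_regrowth",
    "categorize_record",
    "analyze_timecourse",
    "fit_retraction_mixture",
    "summarize_cohort",
    "LONG_RETRACTION_UM",
    "ECTOPIC_RADIUS_UM",
]

LONG_RETRACTION_UM = 70.0     # long retraction: >= 70 um
ECTOPIC_RADIUS_UM = 100.0     # new branch within 100 um of the bulb
ANALYSIS_WINDOW_HR = 10.0     # the first 10 hr are used for analysis
AXOTOMY_RANGE_UM = (250.0, 2000.0)


@dataclass
class AxotomyTimecourse:
    """Tip trajectory after a cut at a known distance from the axon stem.

    Frames arrive every 20-30 min; timestamps are stored explicitly and no
    stage assumes uniform spacing. ``flags`` holds (t_hr, kind, position_um)
    events with kind in {disintegration, cell_disruption, new_branch}.
    """

    cell_id: str
    axotomy_um: float
    t_hr: np.ndarray
    tip_position_um: np.ndarray
    tip_area_um2: np.ndarray | None = None
    flags: list[tuple] = field(default_factory=list)
    div: int | None = None
    substrate: str | None = None
    branch_points_um: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.t_hr = np.asarray(self.t_hr, dtype=float)
        self.tip_position_um = np.asarray(self.tip_position_um, dtype=float)
        if self.tip_area_um2 is not None:
            self.tip_area_um2 = np.asarray(self.tip_area_um2, dtype=float)
        if np.any(np.diff(self.t_hr) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not (AXOTOMY_RANGE_UM[0] <= self.axotomy_um <= AXOTOMY_RANGE_UM[1]):
            raise ValueError(
                f"axotomy distance {self.axotomy_um} um outside "
                f"{AXOTOMY_RANGE_UM[0]}-{AXOTOMY_RANGE_UM[1]} um")

    def check_coverage(self, min_hr: float = ANALYSIS_WINDOW_HR):
        if self.t_hr[-1] < min_hr - 1e-9:
            raise ValueError(f"trajectory must cover at least {min_hr} hr")


@dataclass
class RegenerationRecord:
    cell_id: str
    axotomy_um: float
    div: int | None = None
    substrate: str | None = None
    initial_response: str | None = None   # death | branch_loss | bulb_formation
    outcome: str | None = None            # regeneration | ectopic | none | excluded
    retraction_um: float | None = None
    log10_retraction: float | None = None
    bulb_time_hr: float | None = None
    init_time_hr: float | None = None
    regen_length_um: float | None = None
    gc_area_um2: float | None = None
    retraction_class: str | None = None   # short | long
    axotomy_class: str | None = None      # proximal | distal
    overall_regenerated: bool | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class AxotomyParams:
    """Tunable trajectory-analysis thresholds (all distances um, times hr)."""

    delta_stab_um: float = 10.0    # bulb: tip moved less than this per frame ...
    k_stab: int = 2                # ... for this many consecutive intervals
    v_min_um_hr: float = 10.0      # steady extension: minimum net rate
    window_hr: float = 1.0         # ... sustained over at least 1 hr
    backstep_tol_um: float = 2.0   # per-frame retreat tolerated during extension
    branch_tol_um: float = 10.0    # tip-to-branch-point distance calling branch loss
    proximal_cut_um: float = 500.0 # proximal/distal axotomy boundary (artifact default)
    ectopic_radius_um: float = ECTOPIC_RADIUS_UM


# ---------------------------------------------------------------------------
# per-cell scoring


def classify_initial_response(tc: AxotomyTimecourse,
                              params: AxotomyParams | None = None) -> tuple[str, list[str]]:
    """death | branch_loss | bulb_formation within the 10 hr analysis window.

    Death: a disintegration/cell-disruption flag at t <= 10 hr. Branch loss:
    the tip retracts to within tolerance of the nearest proximal branch point
    (no bulb). Otherwise the stabilized tip is a retraction bulb.
    """
    params = params or AxotomyParams()
    tc.check_coverage()
    notes: list[str] = []
    for t, kind, _pos in tc.flags:
        if kind in ("disintegration", "cell_disruption") and t <= ANALYSIS_WINDOW_HR:
            return "death", notes
    stab = _find_stabilization(tc, params)
    if stab is None:
        notes.append("no stabilization within 10 hr: bulb undetected")
        return "bulb_formation", notes + ["excluded"]
    _, stable_pos = stab
    proximal = [b for b in tc.branch_points_um if b <= tc.axotomy_um]
    if proximal:
        nearest = min(proximal, key=lambda b: abs(stable_pos - b))
        if abs(stable_pos - nearest) <= params.branch_tol_um:
            return "branch_loss", notes
    elif stable_pos <= params.branch_tol_um:
        notes.append("tip retracted to soma region with no branch-point list: ambiguous")
    return "bulb_formation", notes


def _find_stabilization(tc: AxotomyTimecourse,
                        params: AxotomyParams) -> tuple[int, float] | None:
    """First frame index from which the next k_stab inter-frame position
    changes are all below delta_stab, within the analysis window."""
    p = tc.tip_position_um
    t = tc.t_hr
    dmoves = np.abs(np.diff(p))
    k = params.k_stab
    for i in range(dmoves.size - k + 1):
        if t[i] > ANALYSIS_WINDOW_HR:
            break
        if np.all(dmoves[i:i + k] < params.delta_stab_um):
            return i, float(p[i])
    return None


def measure_retraction(tc: AxotomyTimecourse,
                       params: AxotomyParams | None = None
                       ) -> tuple[float | None, float | None, list[str]]:
    """(retraction_um, bulb_time_hr): axon length lost to the initial bulb and
    the time from axotomy to bulb formation."""
    params = params or AxotomyParams()
    stab = _find_stabilization(tc, params)
    if stab is None:
        return None, None, ["bulb undetected within 10 hr"]
    i, pos = stab
    retraction = tc.axotomy_um - pos
    return float(retraction), float(tc.t_hr[i]), []


def detect_regeneration(tc: AxotomyTimecourse, bulb_time_hr: float,
                        params: AxotomyParams | None = None
                        ) -> tuple[str, float | None, list[str]]:
    """Outcome after bulb formation and the regeneration initiation time.

    Scans frames after the bulb for the earliest start of a steady extension:
    the first step advances, no step retreats beyond the backstep tolerance,
    and the cumulative gain stays at or above v_min um/hr at every frame of
    the following >= 1 hr window. Failing that, a new-branch flag within
    100 um of the bulb is ectopic growth; otherwise no regeneration.
    """
    params = params or AxotomyParams()
    t, p = tc.t_hr, tc.tip_position_um
    bulb_idx = int(np.searchsorted(t, bulb_time_hr - 1e-9))
    bulb_pos = p[bulb_idx]
    notes: list[str] = []
    for k in range(bulb_idx, t.size - 1):
        if t[k] > ANALYSIS_WINDOW_HR:
            break
        # window end: first frame at least window_hr later
        m = int(np.searchsorted(t, t[k] + params.window_hr - 1e-9))
        if m >= t.size:
            if p[t.size - 1] - p[k] > 0:
                notes.append("extension started but trajectory truncated "
                             "before 1 hr of persistence: indeterminate")
            break
        steps = np.diff(p[k:m + 1])
        # extension starts AT t*: the first step must itself advance
        if steps[0] <= 0 or np.any(steps <= -params.backstep_tol_um):
            continue
        # the tip keeps gaining at >= v_min throughout the window
        gains = p[k + 1:m + 1] - p[k]
        dts = t[k + 1:m + 1] - t[k]
        if np.all(gains >= params.v_min_um_hr * dts):
            init_abs = float(t[k])
            return "regeneration", init_abs - float(bulb_time_hr), notes
    for ft, kind, pos in tc.flags:
        if kind == "new_branch" and pos is not None and \
                abs(pos - bulb_pos) <= params.ectopic_radius_um and ft <= ANALYSIS_WINDOW_HR:
            return "ectopic", None, notes
    return "none", None, notes


def measure_regrowth(tc: AxotomyTimecourse, init_time_abs_hr: float,
                     params: AxotomyParams | None = None
                     ) -> tuple[float | None, float | None, list[str]]:
    """Regeneration length over the 2 hr after initiation and mean growth cone
    area at 20/40/60 min after initiation (nearest frames)."""
    params = params or AxotomyParams()
    t, p = tc.t_hr, tc.tip_position_um
    t_end = init_time_abs_hr + 2.0
    notes: list[str] = []
    if t[-1] < t_end - 1e-9:
        return None, None, ["trajectory does not cover init + 2 hr"]
    mask = (t >= init_time_abs_hr - 1e-9) & (t <= t_end + 1e-9)
    seg_t = t[mask]
    seg_p = p[mask]
    # interpolated endpoints so the window is exactly 2 hr
    p_start = float(np.interp(init_time_abs_hr, t, p))
    p_end = float(np.interp(t_end, t, p))
    path_t = np.concatenate([[init_time_abs_hr], seg_t, [t_end]])
    path_p = np.concatenate([[p_start], seg_p, [p_end]])
    order = np.argsort(path_t)
    path_p = path_p[order]
    # path length: advancing (monotone) segments summed
    steps = np.diff(path_p)
    regen_length = float(steps[steps > 0].sum())
    gc = None
    if tc.tip_area_um2 is not None:
        probes = []
        for minutes in (20.0, 40.0, 60.0):
            target = init_time_abs_hr + minutes / 60.0
            idx = int(np.argmin(np.abs(t - target)))
            probes.append(tc.tip_area_um2[idx])
        gc = float(np.mean(probes))
    else:
        notes.append("no tip-area channel: growth cone area absent")
    return regen_length, gc, notes


def categorize_record(rec: RegenerationRecord,
                      proximal_cut_um: float = 500.0) -> RegenerationRecord:
    """Fill retraction class (70 um boundary, inclusive on the long side),
    log10 retraction, proximal/distal axotomy class, and the overall
    regeneration score (regeneration or ectopic growth)."""
    if rec.retraction_um is not None:
        if rec.retraction_um <= 0:
            rec.flags.append("non-positive retraction: log10 undefined")
            rec.log10_retraction = None
        else:
            rec.log10_retraction = math.log10(rec.retraction_um)
        rec.retraction_class = ("long" if rec.retraction_um >= LONG_RETRACTION_UM
                                else "short")
    rec.axotomy_class = "distal" if rec.axotomy_um >= proximal_cut_um else "proximal"
    if rec.outcome is not None and rec.outcome != "excluded":
        rec.overall_regenerated = rec.outcome in ("regeneration", "ectopic")
    return rec


def analyze_timecourse(tc: AxotomyTimecourse,
                       params: AxotomyParams | None = None) -> RegenerationRecord:
    """Full per-cell scoring: initial response, six factors, categorization."""
    params = params or AxotomyParams()
    rec = RegenerationRecord(cell_id=tc.cell_id, axotomy_um=tc.axotomy_um,
                             div=tc.div, substrate=tc.substrate)
    response, notes = classify_initial_response(tc, params)
    rec.initial_response = response
    rec.flags.extend(notes)
    if response in ("death", "branch_loss") or "excluded" in notes:
        rec.outcome = "excluded"
        return categorize_record(rec, params.proximal_cut_um)
    retraction, bulb_time, notes = measure_retraction(tc, params)
    rec.flags.extend(notes)
    rec.retraction_um = retraction
    rec.bulb_time_hr = bulb_time
    if bulb_time is None:
        rec.outcome = "excluded"
        return categorize_record(rec, params.proximal_cut_um)
    outcome, init_time, notes = detect_regeneration(tc, bulb_time, params)
    rec.flags.extend(notes)
    rec.outcome = outcome
    rec.init_time_hr = init_time
    if outcome == "regeneration":
        length, gc, notes = measure_regrowth(tc, bulb_time + init_time, params)
        rec.flags.extend(notes)
        rec.regen_length_um = length
        rec.gc_area_um2 = gc
    return categorize_record(rec, params.proximal_cut_um)


# ---------------------------------------------------------------------------
# retraction-distance mixture model


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: dict
    boundary_um: float | None
    fits: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _em_1d(x: np.ndarray, mu0: np.ndarray, sd0: np.ndarray, w0: np.ndarray,
           sd_floor: float, max_iter: int = 500, tol: float = 1e-9):
    """EM for a 1-D Gaussian mixture; returns (w, mu, sd, loglik)."""
    w, mu, sd = w0.copy(), mu0.copy(), np.maximum(sd0, sd_floor)
    n = x.size
    ll_old = -np.inf
    for _ in range(max_iter):
        log_comp = (np.log(w)[None, :]
                    - 0.5 * math.log(2 * math.pi) - np.log(sd)[None, :]
                    - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2)
        m = log_comp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(log_comp - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return w, mu, sd, ll


def _posterior_boundary(w, mu, sd) -> float | None:
    """log10 value where the two components' posteriors are equal, between means."""
    (w1, w2), (m1, m2), (s1, s2) = w, mu, sd
    if m1 > m2:
        w1, w2, m1, m2, s1, s2 = w2, w1, m2, m1, s2, s1
    a = 0.5 * (1 / s1**2 - 1 / s2**2)
    b = m2 / s2**2 - m1 / s1**2
    c = (0.5 * (m1**2 / s1**2 - m2**2 / s2**2)
         + math.log(w1 / s1) - math.log(w2 / s2))
    if abs(a) < 1e-14:
        if abs(b) < 1e-14:
            return None
        x = -c / b
        return x if m1 <= x <= m2 else None
    disc = b * b - 4 * a * c
    if disc < 0:
        return None
    roots = [(-b + s * math.sqrt(disc)) / (2 * a) for s in (1.0, -1.0)]
    inside = [r for r in roots if m1 - 1e-12 <= r <= m2 + 1e-12]
    return inside[0] if inside else None


def fit_retraction_mixture(log10_distances, k_max: int = 2, restarts: int = 5,
                           seed: int = 0, sd_floor: float = 1e-3) -> MixtureFit:
    """EM fits of 1- and 2-component normal mixtures on log10 distances.

    Each k runs ``restarts`` quantile-seeded initializations; the best
    log-likelihood wins. BIC selects k; for k = 2 the posterior-equality point
    between the component means is reported in um (the data-driven short/long
    boundary).
    """
    x = np.asarray(log10_distances, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite log10 distances")
    flags = []
    rng = np.random.default_rng(seed)
    overall_sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if overall_sd == 0.0:
        flags.append("degenerate sample (all values equal): k=1 with sd at floor")
        warnings.warn(flags[-1])
        fit1 = MixtureFit(k=1, weights=np.array([1.0]), means=np.array([x[0]]),
                          sds=np.array([sd_floor]), log_likelihood=float("nan"),
                          bic={1: float("inf")}, boundary_um=None, flags=flags)
        return fit1

    results = {}
    base_pairs = [(0.25, 0.75), (0.10, 0.90), (0.33, 0.66), (0.20, 0.80), (0.40, 0.60)]
    for k in range(1, k_max + 1):
        best = None
        for r in range(restarts):
            if k == 1:
                mu0 = np.array([x.mean()])
                sd0 = np.array([overall_sd])
                w0 = np.array([1.0])
            else:
                if r < len(base_pairs):
                    qa, qb = base_pairs[r]
                else:
                    qa = rng.uniform(0.05, 0.45)
                    qb = rng.uniform(0.55, 0.95)
                mu0 = np.quantile(x, [qa, qb])
                sd0 = np.full(k, max(overall_sd / 2, sd_floor))
                w0 = np.full(k, 1.0 / k)
            w, mu, sd, ll = _em_1d(x, mu0, sd0, w0, sd_floor)
            if best is None or ll > best[3]:
                best = (w, mu, sd, ll)
            if k == 1:
                break
        n_params = 2 * k + (k - 1)
        bic = -2.0 * best[3] + n_params * math.log(x.size)
        results[k] = (*best, bic)

    bics = {k: results[k][4] for k in results}
    k_best = min(bics, key=bics.get)
    w, mu, sd, ll, _ = results[k_best]
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    boundary = None
    if k_best == 2:
        b = _posterior_boundary(w, mu, sd)
        boundary = 10.0 ** b if b is not None else None
    return MixtureFit(k=k_best, weights=w, means=mu, sds=sd, log_likelihood=ll,
                      bic=bics, boundary_um=boundary,
                      fits={k: {"weights": results[k][0][np.argsort(results[k][1])].tolist(),
                                "means": np.sort(results[k][1]).tolist(),
                                "sds": results[k][2][np.argsort(results[k][1])].tolist(),
                                "log_likelihood": results[k][3],
                                "bic": results[k][4]} for k in results},
                      flags=flags)


# ---------------------------------------------------------------------------
# cohort summaries


_FACTORS = ["log10_retraction", "bulb_time_hr", "init_time_hr",
            "regen_length_um", "gc_area_um2"]


def summarize_cohort(records: list[RegenerationRecord],
                     grouping: tuple = ("div", "retraction_class", "axotomy_class"),
                     run_tests: bool = True) -> dict:
    """Per-group regeneration ratios and factor descriptives, with the
    appropriate between-group tests.

    The regeneration ratio is regenerated neurons (including ectopic growth)
    over all neurons that formed a retraction bulb. Ratios are compared by
    Fisher's exact test with Bonferroni correction across group pairs;
    continuous factors by variance-gated t-test (2 groups) or one-way ANOVA
    with Bartlett-routed post hoc (>= 3 groups).
    """
    rows = []
    for r in records:
        rows.append({"cell_id": r.cell_id, "div": r.div,
                     "substrate": r.substrate,
                     "retraction_class": r.retraction_class,
                     "axotomy_class": r.axotomy_class,
                     "initial_response": r.initial_response,
                     "outcome": r.outcome,
                     "overall_regenerated": r.overall_regenerated,
                     "retraction_um": r.retraction_um,
                     **{f: getattr(r, f) for f in _FACTORS}})
    df = pd.DataFrame(rows)
    bulb = df[(df["initial_response"] == "bulb_formation")
              & (df["outcome"] != "excluded")].copy()
    if bulb.empty:
        raise ValueError("no bulb-forming neurons in cohort")
    keys = [g for g in grouping if g in bulb.columns and bulb[g].notna().any()]
    if not keys:
        keys = ["div"]
    grouped = bulb.groupby(keys, dropna=False, observed=True)
    table = []
    counts = {}
    for name, sub in grouped:
        name = name if isinstance(name, tuple) else (name,)
        n_bulb = len(sub)
        n_regen = int(sub["overall_regenerated"].eq(True).sum())
        row = {k: v for k, v in zip(keys, name)}
        row.update({"n_bulb": n_bulb, "n_regenerated": n_regen,
                    "regeneration_ratio": n_regen / n_bulb if n_bulb else None})
        for f in _FACTORS:
            vals = sub[f].dropna().to_numpy(dtype=float)
            row[f"{f}_mean"] = float(vals.mean()) if vals.size else None
            row[f"{f}_sem"] = (float(vals.std(ddof=1) / math.sqrt(vals.size))
                               if vals.size > 1 else None)
        table.append(row)
        counts[name] = (n_regen, n_bulb - n_regen)
    summary = pd.DataFrame(table)
    tests = {}
    if run_tests and len(counts) >= 2:
        import itertools as _it
        names = list(counts)
        tables = []
        labels = []
        for a, b in _it.combinations(names, 2):
            tables.append(np.array([counts[a], counts[b]]))
            labels.append((a, b))
        fisher = _stats.fisher_exact_bonferroni(tables)
        tests["regeneration_ratio"] = [
            {"groups": [list(map(str, l[0])), list(map(str, l[1]))],
             "p": t.p, "adjusted_p": t.adjusted_p}
            for l, t in zip(labels, fisher)]
        for f in _FACTORS:
            groups = {}
            for name, sub in grouped:
                name = name if isinstance(name, tuple) else (name,)
                vals = sub[f].dropna().to_numpy(dtype=float)
                if vals.size >= 2:
                    groups[str(name)] = vals
            if len(groups) < 2:
                continue
            if len(groups) == 2:
                a, b = groups.values()
                res = _stats.t_test_auto(a, b)
                tests[f] = [{"test": res.test_name, "statistic": res.statistic,
                             "p": res.p, "method_path": res.method_path}]
            else:
                res = _stats.anova_posthoc(groups, posthoc="auto")
                tests[f] = [{"test": r.test_name, "groups": r.groups,
                             "statistic": r.statistic, "p": r.p,
                             "adjusted_p": r.adjusted_p,
                             "method_path": r.method_path} for r in res]
    return {"summary": summary, "tests": tests,
            "n_records": len(records), "n_bulb_forming": int(len(bulb))}
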