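"""Statistical decision logic for grouped neuronal data.

Implements the test-selection rules used throughout the analyses: variance-gated
t-tests, one-way ANOVA with Bartlett-routed post hocs (Bonferroni pairwise,
Dunnett versus control, or Games-Howell when variance homogeneity is violated),
Fisher's exact test with Bonferroni correction for regeneration ratios,
Kruskal-Wallis for patch-clamp features, Benjamini-Hochberg FDR adjustment,
and the log10 transform applied to retraction distances.

The Games-Howell procedure evaluates p-values from the studentized range
distribution computed by direct numerical integration (Gauss-Legendre
quadrature over the range statistic's double integral), so its calibration can
be checked independently of any library implementation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats as sps
from scipy.special import gammaln, ndtr

__all__ = [
    "TestResult",
    "ContingencyTable",
    "t_test_auto",
    "anova_posthoc",
    "games_howell",
    "fisher_exact_p",
    "fisher_exact_bonferroni",
    "kruskal_wallis",
    "bh_adjust",
    "log10_transform",
    "two_way_anova",
    "studentized_range_cdf",
    "studentized_range_sf",
]


@dataclass
class TestResult:
    """One statistical comparison, with an audit trail of the branch taken."""

    test_name: str
    statistic: float
    df: float | tuple | None
    p: float
    adjusted_p: float | None = None
    groups: tuple | None = None
    method_path: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")
        if self.adjusted_p is not None and self.adjusted_p < self.p - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


@dataclass
class ContingencyTable:
    counts: np.ndarray
    label: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if np.any(self.counts < 0) or not np.all(
            np.equal(np.mod(self.counts, 1), 0)
        ):
            raise ValueError("counts must be nonnegative integers")
        self.counts = self.counts.astype(np.int64)
        if np.any(self.counts.sum(axis=0) == 0) or np.any(self.counts.sum(axis=1) == 0):
            raise ValueError("row and column sums must be positive")


# ---------------------------------------------------------------------------
# elementary transforms


def log10_transform(values) -> np.ndarray:
    """Element-wise log10, rejecting non-positive entries by index."""
    values = np.asarray(values, dtype=float)
    bad = np.nonzero(~(values > 0))[0]
    if bad.size:
        raise ValueError(
            f"log10 transform requires positive values; offending indices: {bad.tolist()}"
        )
    return np.log10(values)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards, cap at 1
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# two-sample comparisons


def _as_sample(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    return x


def t_test_auto(a, b) -> TestResult:
    """Two-sample t-test, Student's or Welch's depending on the variance.

    Variance equality is assessed by a two-sided F-ratio test at alpha = 0.05;
    the branch taken is recorded in ``method_path``.
    """
    a, b = _as_sample(a), _as_sample(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    path = []
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult("student_t", 0.0, a.size + b.size - 2, 1.0,
                              method_path=["zero-variance: equal means -> p=1"])
        return TestResult("student_t", math.inf, a.size + b.size - 2, 0.0,
                          method_path=["zero-variance: unequal means -> p=0"],
                          flags=["degenerate"])
    if va == 0.0 or vb == 0.0:
        f_p = 0.0
    else:
        f_stat = va / vb
        fd = sps.f(a.size - 1, b.size - 1)
        f_p = 2.0 * min(fd.sf(f_stat), fd.cdf(f_stat))
        f_p = min(1.0, f_p)
    if f_p < 0.05:
        path.append(f"F-ratio p={f_p:.4g} < 0.05 -> Welch")
        t, p = sps.ttest_ind(a, b, equal_var=False)
        df = _welch_df(va, vb, a.size, b.size)
        name = "welch_t"
    else:
        path.append(f"F-ratio p={f_p:.4g} >= 0.05 -> Student")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
        name = "student_t"
    return TestResult(name, float(t), float(df), float(p), method_path=path)


def _welch_df(va, vb, na, nb) -> float:
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    if den == 0:
        return na + nb - 2
    return num / den


# ---------------------------------------------------------------------------
# studentized range distribution (numerical integration)

_Z_NODES, _Z_WEIGHTS = leggauss(160)
_S_NODES, _S_WEIGHTS = leggauss(80)
_Z_LIM = 9.0


def _range_cdf_normal(u, k):
    """P(range of k iid N(0,1) <= u) for u >= 0, vectorized over u."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    z = _Z_NODES * _Z_LIM
    w = _Z_WEIGHTS * _Z_LIM
    phi = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    diff = ndtr(z[None, :]) - ndtr(z[None, :] - u[:, None])
    integrand = phi[None, :] * np.clip(diff, 0.0, 1.0) ** (k - 1)
    return np.clip(k * integrand @ w, 0.0, 1.0)


def studentized_range_cdf(q, k: int, df: float) -> float:
    """CDF of the studentized range for k groups and df error degrees of freedom.

    Evaluated by Gauss-Legendre quadrature of the scale-mixture integral
    P(Q<=q) = E_s[ P(range <= q s) ] with s = sqrt(chi2_df / df).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if q <= 0:
        return 0.0
    if not np.isfinite(df):
        return float(_range_cdf_normal(q, k)[0])
    df = float(df)
    lo = sps.chi.ppf(1e-12, df) / math.sqrt(df)
    hi = sps.chi.ppf(1.0 - 1e-12, df) / math.sqrt(df)
    s = 0.5 * (hi - lo) * _S_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _S_WEIGHTS
    # density of s = chi_df / sqrt(df)
    log_dens = (
        (1.0 - df / 2.0) * math.log(2.0)
        - gammaln(df / 2.0)
        + df * 0.5 * math.log(df)
        + (df - 1.0) * np.log(s)
        - df * s * s / 2.0
    )
    dens = np.exp(log_dens)
    inner = _range_cdf_normal(q * s, k)
    return float(np.clip(np.sum(w * dens * inner), 0.0, 1.0))


def studentized_range_sf(q, k: int, df: float) -> float:
    return 1.0 - studentized_range_cdf(q, k, df)


# ---------------------------------------------------------------------------
# multi-group comparisons


def _group_dict(groups) -> dict:
    if isinstance(groups, dict):
        return {name: _as_sample(v) for name, v in groups.items()}
    return {i: _as_sample(v) for i, v in enumerate(groups)}


def games_howell(groups, df_floor: float = 2.0) -> list[TestResult]:
    """Games-Howell pairwise comparisons (unequal-variance post hoc).

    For each pair: Welch standard error, Welch-Satterthwaite df, range
    statistic q = |dm| * sqrt(2) / SE, p from the studentized range
    distribution with k groups and that df.
    """
    g = _group_dict(groups)
    if len(g) < 2:
        raise ValueError("need >= 2 groups")
    k = len(g)
    results = []
    for (na_, a), (nb_, b) in itertools.combinations(g.items(), 2):
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / a.size + vb / b.size
        flags = []
        if se2 == 0.0:
            p = 1.0 if a.mean() == b.mean() else 0.0
            results.append(TestResult("games_howell", math.inf if p == 0 else 0.0,
                                      df_floor, p, groups=(na_, nb_),
                                      flags=["zero-variance pair"]))
            continue
        df = _welch_df(va, vb, a.size, b.size)
        if df < df_floor:
            df = df_floor
            flags.append("df floored")
        q = abs(a.mean() - b.mean()) * math.sqrt(2.0) / math.sqrt(se2)
        p = studentized_range_sf(q, k, df)
        results.append(TestResult("games_howell", q, df, p, groups=(na_, nb_),
                                  method_path=[f"k={k}"], flags=flags))
    return results


def anova_posthoc(groups, posthoc: str = "auto", control_group=None,
                  alpha_variance: float = 0.05, rng=None) -> list[TestResult]:
    """One-way ANOVA followed by the requested (or Bartlett-routed) post hoc.

    In ``auto`` mode Bartlett's test at ``alpha_variance`` routes to
    Games-Howell when variance homogeneity is violated, otherwise to Dunnett
    versus ``control_group`` when one is given, else to Bonferroni-adjusted
    pairwise Student's t-tests.
    """
    g = _group_dict(groups)
    names = list(g)
    if len(g) < 2:
        raise ValueError("need >= 2 groups")
    if posthoc not in ("auto", "bonferroni", "dunnett", "games_howell"):
        raise ValueError(f"unknown posthoc: {posthoc}")
    if posthoc == "dunnett" and control_group is None:
        raise ValueError("dunnett post hoc requires control_group")
    values = list(g.values())
    if all(v.var(ddof=1) == 0 for v in values) and len({v.mean() for v in values}) == 1:
        omnibus = TestResult("one_way_anova", 0.0,
                             (len(g) - 1, sum(v.size for v in values) - len(g)), 1.0,
                             method_path=["all groups identical"])
        results = [omnibus]
        for a, b in itertools.combinations(names, 2):
            results.append(TestResult("bonferroni_t", 0.0, None, 1.0, adjusted_p=1.0,
                                      groups=(a, b)))
        return results
    f_stat, f_p = sps.f_oneway(*values)
    path = []
    omnibus = TestResult(
        "one_way_anova", float(f_stat),
        (len(g) - 1, sum(v.size for v in values) - len(g)), float(f_p),
        method_path=path)
    chosen = posthoc
    if posthoc == "auto":
        bart_stat, bart_p = sps.bartlett(*values)
        if bart_p < alpha_variance:
            chosen = "games_howell"
            path.append(f"Bartlett p={bart_p:.4g} < {alpha_variance} -> Games-Howell")
        else:
            chosen = "dunnett" if control_group is not None else "bonferroni"
            path.append(f"Bartlett p={bart_p:.4g} >= {alpha_variance} -> {chosen}")
    results = [omnibus]
    if len(g) < 3 and chosen in ("bonferroni", "dunnett"):
        chosen = "bonferroni"
    if chosen == "games_howell":
        results.extend(games_howell(g))
    elif chosen == "dunnett":
        if control_group not in g:
            raise ValueError(f"control group {control_group!r} not among groups")
        control = g[control_group]
        others = [n for n in names if n != control_group]
        res = sps.dunnett(*[g[n] for n in others], control=control,
                          rng=np.random.default_rng(0) if rng is None else rng)
        for name, stat, p in zip(others, np.atleast_1d(res.statistic),
                                 np.atleast_1d(res.pvalue)):
            results.append(TestResult("dunnett", float(stat), None, float(p),
                                      adjusted_p=float(p),
                                      groups=(name, control_group),
                                      method_path=["scipy multivariate-t"]))
    else:  # bonferroni pairwise Student's t
        pairs = list(itertools.combinations(names, 2))
        m = len(pairs)
        for a, b in pairs:
            xa, xb = g[a], g[b]
            if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
                p = 1.0 if xa.mean() == xb.mean() else 0.0
                t = 0.0 if p == 1.0 else math.inf
            else:
                t, p = sps.ttest_ind(xa, xb, equal_var=True)
            results.append(TestResult("bonferroni_t", float(t),
                                      xa.size + xb.size - 2, float(p),
                                      adjusted_p=min(1.0, float(p) * m),
                                      groups=(a, b)))
    return results


# ---------------------------------------------------------------------------
# exact and rank-based tests


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by point-probability enumeration.

    Sums the hypergeometric probabilities of all tables (with the observed
    margins) whose probability does not exceed the observed table's.
    """
    t = ContingencyTable(table).counts if not isinstance(table, ContingencyTable) else table.counts
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_p handles 2x2 tables; use the Monte-Carlo path for r x c")
    a = t[0, 0]
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = r1 + r2
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(1.0, p)


def _rxc_montecarlo_p(t: np.ndarray, n_sims: int, rng) -> float:
    """Monte-Carlo two-sided p for an r x c table, fixed margins, point-probability ordering."""
    rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
    log_fact = gammaln(np.arange(int(t.sum()) + 2))

    def neg_stat(tab):
        return float(log_fact[tab + 1].sum())  # larger => less probable table

    obs = neg_stat(t)
    hits = 0
    for _ in range(n_sims):
        perm = rng.permutation(cols)
        tab = np.zeros_like(t)
        np.add.at(tab, (rows, perm), 1)
        if neg_stat(tab) >= obs - 1e-9:
            hits += 1
    return (hits + 1) / (n_sims + 1)


def fisher_exact_bonferroni(tables, n_sims: int = 10000, rng=None) -> list[TestResult]:
    """Fisher's exact test per table with Bonferroni correction across tables.

    2x2 tables get the exact enumeration p; larger tables fall back to a
    Monte-Carlo permutation p and are flagged.
    """
    tabs = [t if isinstance(t, ContingencyTable) else ContingencyTable(t) for t in tables]
    m = len(tabs)
    if m == 0:
        raise ValueError("no tables given")
    rng = np.random.default_rng(0) if rng is None else rng
    results = []
    for tab in tabs:
        if tab.counts.shape == (2, 2):
            p = fisher_exact_p(tab)
            flags = []
            name = "fisher_exact"
        else:
            p = _rxc_montecarlo_p(tab.counts, n_sims, rng)
            flags = ["monte_carlo"]
            name = "fisher_exact_mc"
        results.append(TestResult(name, math.nan, None, p,
                                  adjusted_p=min(1.0, m * p),
                                  groups=(tab.label,) if tab.label else None,
                                  method_path=[f"bonferroni m={m}"], flags=flags))
    return results


def _kw_h(ranks_by_group, n_total, tie_term) -> float:
    s = sum(r.sum() ** 2 / r.size for r in ranks_by_group)
    h = 12.0 / (n_total * (n_total + 1)) * s - 3.0 * (n_total + 1)
    if tie_term > 0:
        h /= 1.0 - tie_term
    return h


def kruskal_wallis(groups, exact: bool | None = None) -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    p comes from the chi-square approximation (df = k-1); for total n <= 12 an
    exact permutation p is available (``exact=True``) and is enumerated over
    all assignments of the pooled ranks to groups.
    """
    g = _group_dict(groups)
    values = list(g.values())
    if len(values) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, len(values) - 1, 1.0,
                          method_path=["all values identical"])
    h, p = sps.kruskal(*values)
    path = ["chi-square approximation"]
    if exact:
        n = pooled.size
        if n > 12:
            raise ValueError("exact permutation p restricted to total n <= 12")
        ranks = sps.rankdata(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts).sum()) / (n**3 - n))
        sizes = [v.size for v in values]
        h_obs = _kw_h(np.split(ranks, np.cumsum(sizes))[:-1], n, tie_term)

        total = 0
        ge = 0
        idx = np.arange(n)

        def recurse(remaining, gi, chosen):
            nonlocal total, ge
            if gi == len(sizes) - 1:
                grouped = chosen + [remaining]
                hval = _kw_h([ranks[list(c)] for c in grouped], n, tie_term)
                total += 1
                if hval >= h_obs - 1e-12:
                    ge += 1
                return
            for comb in itertools.combinations(remaining, sizes[gi]):
                rest = [i for i in remaining if i not in set(comb)]
                recurse(rest, gi + 1, chosen + [list(comb)])

        recurse(list(idx), 0, [])
        p = ge / total
        path = [f"exact permutation over {total} assignments"]
        h = h_obs
    return TestResult("kruskal_wallis", float(h), len(values) - 1, float(p),
                      method_path=path)


def two_way_anova(values, factor_a, factor_b) -> dict:
    """Thin two-way ANOVA delegation (used once, for vesicle movement data)."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "a": list(factor_a), "b": list(factor_b)})
    model = ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {row: {"F": float(table.loc[row, "F"]), "p": float(table.loc[row, "PR(>F)"])}
            for row in table.index if row != "Residual"}
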