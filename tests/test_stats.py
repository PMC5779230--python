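"""Statistics harness: decision logic, exact tests, and calibration."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from axoregen import stats as st


class TestLog10Transform:
    def test_values(self):
        np.testing.assert_allclose(st.log10_transform([100, 1, 10]), [2.0, 0.0, 1.0])

    def test_nonpositive_rejected_with_index(self):
        with pytest.raises(ValueError, match=r"indices: \[1\]"):
            st.log10_transform([5.0, 0.0, 2.0])


class TestBHAdjust:
    def test_step_up_hand_computation(self):
        # ranked p*m/i = [.04,.04,.04,.04] after the monotone pass
        np.testing.assert_allclose(st.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert st.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(st.bh_adjust(p), expected, atol=1e-12)

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=20)
        adj = st.bh_adjust(p)
        p2 = p.copy()
        p2[7] = min(1.0, p2[7] + 0.2)
        adj2 = st.bh_adjust(p2)
        assert np.all(adj2 >= adj - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.bh_adjust([0.5, 1.2])


class TestTTestAuto:
    def test_identical_samples(self):
        r = st.t_test_auto([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_equal_variance_takes_student_branch(self):
        r = st.t_test_auto([1, 2, 3], [11, 12, 13])
        assert r.test_name == "student_t"
        assert "Student" in r.method_path[0]

    def test_unequal_variance_takes_welch_branch(self):
        rng = np.random.default_rng(3)
        r = st.t_test_auto(rng.normal(0, 1, 30), rng.normal(0, 10, 30))
        assert r.test_name == "welch_t"

    def test_welch_equals_student_under_equal_variance_and_n(self):
        # exact algebraic identity when sample variances and sizes coincide
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 2.5  # same sample variance
        t_w, _ = sps.ttest_ind(a, b, equal_var=False)
        t_s, _ = sps.ttest_ind(a, b, equal_var=True)
        assert abs(t_w - t_s) < 1e-12

    def test_zero_variance_conventions(self):
        same = st.t_test_auto([2.0, 2.0], [2.0, 2.0])
        assert same.p == 1.0
        diff = st.t_test_auto([2.0, 2.0], [3.0, 3.0])
        assert diff.p == 0.0 and "degenerate" in diff.flags

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(5)
        rej = sum(st.t_test_auto(rng.normal(size=20), rng.normal(size=20)).p < 0.05
                  for _ in range(2000))
        assert 0.035 <= rej / 2000 <= 0.065


class TestStudentizedRange:
    @pytest.mark.parametrize("q,k,df", [(2.0, 3, 10), (3.5, 4, 30), (4.0, 5, 120),
                                        (1.0, 3, 5), (6.0, 4, 8)])
    def test_matches_scipy(self, q, k, df):
        ours = st.studentized_range_cdf(q, k, df)
        ref = sps.studentized_range.cdf(q, k, df)
        assert ours == pytest.approx(ref, abs=2e-4)

    def test_infinite_df_is_normal_range(self):
        ours = st.studentized_range_cdf(3.0, 3, math.inf)
        ref = sps.studentized_range.cdf(3.0, 3, 1e7)
        assert ours == pytest.approx(ref, abs=5e-4)

    def test_monte_carlo_quantiles(self):
        # CDF at empirical 0.90/0.95 quantiles of simulated ranges
        rng = np.random.default_rng(7)
        k, df, n = 4, 10, 200_000
        z = rng.standard_normal((n, k))
        s = np.sqrt(rng.chisquare(df, size=n) / df)
        qs = (z.max(axis=1) - z.min(axis=1)) / s
        for level in (0.90, 0.95):
            q_emp = np.quantile(qs, level)
            assert st.studentized_range_cdf(q_emp, k, df) == pytest.approx(level, abs=0.005)


class TestGamesHowell:
    def test_equal_mean_groups_p_near_one(self):
        r = st.games_howell({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert r[0].p > 0.999

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        groups = {"a": rng.normal(0, 1, 12), "b": rng.normal(1, 3, 9),
                  "c": rng.normal(0.5, 0.5, 15)}
        df = pd.DataFrame([(g, v) for g, vs in groups.items() for v in vs],
                          columns=["g", "y"])
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        ours = {tuple(sorted(r.groups)): r.p for r in st.games_howell(groups)}
        for _, row in ref.iterrows():
            key = tuple(sorted((row["A"], row["B"])))
            assert ours[key] == pytest.approx(row["pval"], abs=1e-3)

    def test_balanced_equal_variance_agrees_with_tukey(self):
        # in the balanced homoscedastic limit Games-Howell ~ Tukey HSD
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(9)
        base = rng.normal(0, 1.0, 50)
        # shifted copies: identical sample variances, so the pairwise Welch SE
        # equals the pooled SE and only the df conventions differ (negligibly
        # at this n)
        vals = [base + m for m in (0.0, 0.4, 0.8)]
        labels = np.repeat(["a", "b", "c"], 50)
        tukey = pairwise_tukeyhsd(np.concatenate(vals), labels)
        ours = st.games_howell(dict(zip("abc", vals)))
        for r, p_ref in zip(ours, tukey.pvalues):
            assert r.p == pytest.approx(p_ref, abs=0.01)

    def test_fwer_calibration_quick(self):
        rng = np.random.default_rng(10)
        n_rej = sum(
            any(r.p < 0.05 for r in
                st.games_howell([rng.normal(size=10) for _ in range(4)]))
            for _ in range(500))
        assert 0.02 <= n_rej / 500 <= 0.09


class TestAnovaPosthoc:
    def test_identical_groups(self):
        res = st.anova_posthoc({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res[0].p == pytest.approx(1.0)
        assert all(r.p == pytest.approx(1.0) for r in res[1:])

    def test_variance_violation_routes_to_games_howell(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(50):
            groups = [rng.normal(size=15), rng.normal(size=15),
                      rng.normal(scale=5.0, size=15)]
            res = st.anova_posthoc(groups, posthoc="auto")
            hits += res[1].test_name == "games_howell"
        assert hits >= 49

    def test_dunnett_needs_control(self):
        with pytest.raises(ValueError, match="control"):
            st.anova_posthoc({"a": [1, 2], "b": [3, 4], "c": [5, 6]},
                             posthoc="dunnett")

    def test_dunnett_vs_control(self):
        rng = np.random.default_rng(0)
        groups = {"ctrl": rng.normal(0, 1, 15), "t1": rng.normal(3, 1, 15),
                  "t2": rng.normal(0, 1, 15)}
        res = st.anova_posthoc(groups, posthoc="dunnett", control_group="ctrl")
        by_pair = {r.groups[0]: r for r in res[1:]}
        assert by_pair["t1"].p < 0.001
        assert by_pair["t2"].p > 0.05

    def test_power_for_planted_shift(self):
        rng = np.random.default_rng(12)
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            groups = [rng.normal(size=15), rng.normal(size=15),
                      rng.normal(loc=2.0, size=15)]
            res = st.anova_posthoc(groups, posthoc="bonferroni")
            shifted = [r for r in res[1:] if 2 in r.groups]
            hits += any(r.adjusted_p < 0.05 for r in shifted)
        assert hits / n_sims >= 0.90

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(13)
        res = st.anova_posthoc([rng.normal(size=8) for _ in range(4)],
                               posthoc="bonferroni")
        for r in res[1:]:
            assert r.adjusted_p >= r.p


class TestFisherExact:
    def test_balanced_table(self):
        assert st.fisher_exact_p([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        assert st.fisher_exact_p([[10, 0], [0, 10]]) == pytest.approx(
            2.0 / math.comb(20, 10), rel=1e-12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            t = rng.integers(1, 15, size=(2, 2))
            ours = st.fisher_exact_p(t)
            ref = sps.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_bonferroni_adjustment(self):
        t = [[8, 2], [3, 7]]
        res = st.fisher_exact_bonferroni([t, t, t])
        p = st.fisher_exact_p(t)
        for r in res:
            assert r.adjusted_p == pytest.approx(min(1.0, 3 * p))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            st.fisher_exact_bonferroni([[[1.5, 2], [3, 4]]])

    def test_rxc_monte_carlo_flagged(self):
        res = st.fisher_exact_bonferroni([[[5, 1, 1], [1, 5, 1], [1, 1, 5]]],
                                         n_sims=2000, rng=np.random.default_rng(0))
        assert "monte_carlo" in res[0].flags
        assert res[0].p < 0.05


class TestKruskalWallis:
    def test_identical_values(self):
        r = st.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_exact_permutation_matches_brute_force(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        r = st.kruskal_wallis(groups, exact=True)
        # independent brute force over all label permutations
        pooled = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ranks = sps.rankdata(pooled)
        n = 6

        def h_of(assign):
            h = 0.0
            for g in range(3):
                r_g = ranks[[i for i, a in enumerate(assign) if a == g]]
                h += r_g.sum() ** 2 / 2
            return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

        obs = h_of([0, 0, 1, 1, 2, 2])
        count = total = 0
        for perm in set(itertools.permutations([0, 0, 1, 1, 2, 2])):
            total += 1
            count += h_of(perm) >= obs - 1e-12
        assert r.statistic == pytest.approx(obs)
        assert r.p == pytest.approx(count / total)

    def test_chi2_path_matches_scipy(self):
        rng = np.random.default_rng(15)
        groups = [rng.normal(size=12) for _ in range(3)]
        r = st.kruskal_wallis(groups)
        h, p = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(h)
        assert r.p == pytest.approx(p)


def test_two_way_anova_detects_main_effect():
    rng = np.random.default_rng(16)
    a = np.repeat(["x", "y"], 40)
    b = np.tile(np.repeat(["u", "v"], 20), 2)
    y = rng.normal(size=80) + (a == "y") * 2.0
    res = st.two_way_anova(y, a, b)
    assert res["C(a)"]["p"] < 1e-6
    assert res["C(b)"]["p"] > 0.01
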