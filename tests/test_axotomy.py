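"""Axotomy outcome scoring, regeneration factors, and the retraction mixture."""

import math
import warnings

import numpy as np
import pytest

from axoregen import axotomy as ax
from axoregen.axotomy import AxotomyTimecourse, RegenerationRecord
from axoregen.synthetic import gen_axotomy_cohort, gen_axotomy_timecourse


def timecourse(positions, dt_hr=0.5, axotomy_um=800.0, flags=(), areas=None,
               branch_points=(300.0,)):
    t = np.arange(len(positions)) * dt_hr
    return AxotomyTimecourse(cell_id="c", axotomy_um=axotomy_um, t_hr=t,
                             tip_position_um=np.asarray(positions, dtype=float),
                             tip_area_um2=None if areas is None else np.asarray(areas),
                             flags=list(flags),
                             branch_points_um=list(branch_points))


def bulb_then(positions_after, axotomy_um=800.0, bulb_pos=650.0, **kw):
    """Trajectory retracting 800 -> bulb_pos by t=2 hr, then as given."""
    pre = [800.0, 762.5, 725.0, 687.5, bulb_pos]
    return timecourse(pre + list(positions_after), axotomy_um=axotomy_um, **kw)


class TestInitialResponse:
    def test_disintegration_flag_is_death(self):
        tc = bulb_then([650.0] * 17, flags=[(6.0, "disintegration", None)])
        assert ax.classify_initial_response(tc)[0] == "death"

    def test_flag_after_window_not_death(self):
        tc = bulb_then([650.0] * 18, flags=[(10.6, "disintegration", None)])
        assert ax.classify_initial_response(tc)[0] == "bulb_formation"

    def test_retraction_to_branch_point_is_branch_loss(self):
        p = np.concatenate([np.linspace(800, 300, 11), np.full(11, 300.0)])
        tc = timecourse(p, branch_points=(300.0,))
        assert ax.classify_initial_response(tc)[0] == "branch_loss"

    def test_stabilizing_away_from_branch_point_is_bulb(self):
        tc = bulb_then([650.0] * 17)
        assert ax.classify_initial_response(tc)[0] == "bulb_formation"

    def test_short_coverage_rejected(self):
        with pytest.raises(ValueError, match="10"):
            ax.classify_initial_response(timecourse([800, 700, 650]))


class TestRetraction:
    def test_hand_case(self):
        tc = bulb_then([650.0] * 17)
        retraction, bulb_time, _ = ax.measure_retraction(tc)
        assert retraction == pytest.approx(150.0)
        assert bulb_time == pytest.approx(2.0)

    def test_no_stabilization_flagged(self):
        p = np.linspace(800, 300, 22)  # keeps moving for 10.5 hr
        retraction, bulb_time, notes = ax.measure_retraction(timecourse(p))
        assert retraction is None and bulb_time is None
        assert any("undetected" in n for n in notes)

    def test_noisy_recovery_mean_error(self):
        errs = []
        for seed in range(100):
            tc, gt = gen_axotomy_timecourse(
                "no_regeneration", 900.0, retraction_um=150.0,
                retract_speed_um_hr=75.0, noise_sd_um=5.0, seed=seed)
            r, _, _ = ax.measure_retraction(tc)
            errs.append(abs(r - gt.labels["cell"]["retraction_um"]))
        assert np.mean(errs) < 10.0

    def test_conservation_retraction_plus_bulb_position(self):
        tc, _ = gen_axotomy_timecourse("no_regeneration", 700.0,
                                       retraction_um=120.0, seed=1)
        retraction, bulb_time, _ = ax.measure_retraction(tc)
        i = int(np.searchsorted(tc.t_hr, bulb_time - 1e-9))
        assert retraction + tc.tip_position_um[i] == pytest.approx(700.0)


class TestRegenerationDetection:
    def test_steady_advance_after_bulb(self):
        # bulb at 2.0 hr, advance 20 um/frame from 4.0 hr
        after = [650.0] * 4 + [650.0 + 20.0 * k for k in range(1, 14)]
        tc = bulb_then(after)
        outcome, init_time, _ = ax.detect_regeneration(tc, 2.0)
        assert outcome == "regeneration"
        assert init_time == pytest.approx(2.0)

    def test_new_branch_near_bulb_is_ectopic(self):
        tc = bulb_then([650.0] * 17, flags=[(5.0, "new_branch", 590.0)])
        outcome, init_time, _ = ax.detect_regeneration(tc, 2.0)
        assert outcome == "ectopic" and init_time is None

    def test_new_branch_far_from_bulb_is_not_ectopic(self):
        tc = bulb_then([650.0] * 17, flags=[(5.0, "new_branch", 400.0)])
        assert ax.detect_regeneration(tc, 2.0)[0] == "none"

    def test_motile_bulb_is_none(self):
        rng = np.random.default_rng(3)
        after = 650.0 + 5.0 * np.sin(np.arange(17)) + rng.normal(0, 1, 17)
        tc = bulb_then(list(after))
        assert ax.detect_regeneration(tc, 2.0)[0] == "none"


class TestRegrowth:
    def test_linear_advance(self):
        after = [650.0 + 15.0 * k for k in range(1, 14)]  # 30 um/hr
        tc = bulb_then([650.0] * 2 + after)
        length, _, _ = ax.measure_regrowth(tc, 3.0)
        assert length == pytest.approx(60.0)

    def test_growth_cone_area_mean(self):
        # frames every 20 min; areas 10, 12, 14 at 20/40/60 min after init
        t = np.arange(0, 31) / 3.0
        p = np.where(t <= 1.0, 800.0 - 150.0 * t, 650.0)
        p = np.where(t >= 3.0, 650.0 + 30.0 * (t - 3.0), p)
        areas = np.full(t.size, 25.0)
        areas[np.argmin(np.abs(t - (3.0 + 1 / 3)))] = 10.0
        areas[np.argmin(np.abs(t - (3.0 + 2 / 3)))] = 12.0
        areas[np.argmin(np.abs(t - 4.0))] = 14.0
        tc = AxotomyTimecourse("c", 800.0, t, p, tip_area_um2=areas)
        _, gc, _ = ax.measure_regrowth(tc, 3.0)
        assert gc == pytest.approx(12.0)

    def test_planted_elongation_rate_recovered_with_noise(self):
        rates = []
        for seed in range(100):
            tc, gt = gen_axotomy_timecourse(
                "regeneration", 900.0, retraction_um=150.0, init_delay_hr=2.0,
                elong_um_hr=45.0, noise_sd_um=5.0, seed=seed)
            rec = ax.analyze_timecourse(tc)
            if rec.regen_length_um is not None:
                rates.append(rec.regen_length_um / 2.0)
        assert abs(np.mean(rates) - 45.0) / 45.0 < 0.10


class TestCategorize:
    def test_log10_retraction(self):
        rec = RegenerationRecord("c", 800.0, retraction_um=100.0,
                                 outcome="regeneration")
        rec = ax.categorize_record(rec)
        assert rec.log10_retraction == pytest.approx(2.0)

    @pytest.mark.parametrize("retraction,expected", [(69.9, "short"), (70.0, "long")])
    def test_short_long_boundary_inclusive(self, retraction, expected):
        rec = ax.categorize_record(
            RegenerationRecord("c", 800.0, retraction_um=retraction, outcome="none"))
        assert rec.retraction_class == expected

    def test_ectopic_counts_as_overall_regenerated(self):
        rec = ax.categorize_record(
            RegenerationRecord("c", 800.0, retraction_um=50.0, outcome="ectopic"))
        assert rec.overall_regenerated is True

    def test_proximal_distal_boundary(self):
        rec = ax.categorize_record(
            RegenerationRecord("c", 450.0, retraction_um=50.0, outcome="none"),
            proximal_cut_um=500.0)
        assert rec.axotomy_class == "proximal"


class TestMixtureFit:
    def test_unimodal_selects_k1(self):
        rng = np.random.default_rng(3)
        fit = ax.fit_retraction_mixture(rng.normal(2.16, 0.2, 500), seed=3)
        assert fit.k == 1
        assert fit.means[0] == pytest.approx(2.16, abs=0.03)

    def test_bimodal_selects_k2_and_recovers_means(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(1.5, 0.15, 150), rng.normal(2.2, 0.15, 150)])
        fit = ax.fit_retraction_mixture(x, seed=3)
        assert fit.k == 2
        assert fit.means[0] == pytest.approx(1.5, abs=0.1)
        assert fit.means[1] == pytest.approx(2.2, abs=0.1)
        assert fit.boundary_um is not None
        assert 10**1.5 < fit.boundary_um < 10**2.2

    def test_agrees_with_sklearn_em(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(1.5, 0.15, 200), rng.normal(2.2, 0.15, 200)])
        fit = ax.fit_retraction_mixture(x, seed=4)
        gm = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        np.testing.assert_allclose(np.sort(fit.means),
                                   np.sort(gm.means_.ravel()), atol=0.02)

    def test_degenerate_sample_floors_sd(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ax.fit_retraction_mixture(np.full(20, 1.7))
        assert fit.k == 1
        assert fit.sds[0] == pytest.approx(1e-3)
        assert fit.flags

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ax.fit_retraction_mixture([1.0, 2.0])

    def test_grid_search_oracle_agreement(self):
        # coarse grid over (mu1, mu2, w) with the ML sd per component serves
        # as an independent check on the EM optimum
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(1.5, 0.15, 150), rng.normal(2.2, 0.15, 150)])
        fit = ax.fit_retraction_mixture(x, seed=5)
        grid = np.linspace(1.2, 2.5, 27)
        best = (-np.inf, None, None)
        for m1 in grid:
            for m2 in grid:
                if m2 <= m1:
                    continue
                for w in (0.3, 0.4, 0.5, 0.6, 0.7):
                    ll = np.log(
                        w * np.exp(-0.5 * ((x - m1) / 0.15) ** 2)
                        + (1 - w) * np.exp(-0.5 * ((x - m2) / 0.15) ** 2)).sum()
                    if ll > best[0]:
                        best = (ll, m1, m2)
        assert fit.means[0] == pytest.approx(best[1], abs=0.06)
        assert fit.means[1] == pytest.approx(best[2], abs=0.06)


class TestCohort:
    def test_closed_loop_noise_free(self):
        cohort, gt = gen_axotomy_cohort(100, seed=2)
        frame_hr = 0.5
        for tc in cohort:
            g = gt.labels[tc.cell_id]
            rec = ax.analyze_timecourse(tc)
            planted = g["outcome"]
            if planted in ("death", "branch_loss"):
                assert rec.initial_response == planted
                continue
            assert rec.outcome == {"no_regeneration": "none"}.get(planted, planted)
            assert rec.retraction_um == pytest.approx(g["retraction_um"], abs=1e-9)
            assert abs(rec.bulb_time_hr - g["bulb_time_hr"]) <= frame_hr
            if planted == "regeneration":
                assert abs(rec.init_time_hr - g["init_delay_hr"]) <= frame_hr
                assert rec.regen_length_um == pytest.approx(g["regen_length_um"],
                                                            abs=1e-6)
                assert rec.gc_area_um2 == pytest.approx(g["gc_area_um2"])

    def test_initial_response_partitions_cohort(self):
        cohort, _ = gen_axotomy_cohort(60, seed=3)
        recs = [ax.analyze_timecourse(tc) for tc in cohort]
        assert all(r.initial_response in ("death", "branch_loss", "bulb_formation")
                   for r in recs)
        bulb = [r for r in recs if r.initial_response == "bulb_formation"]
        assert all(r.outcome in ("regeneration", "ectopic", "none", "excluded")
                   for r in bulb)

    def test_summary_ratio_includes_ectopic(self):
        records = []
        for i in range(10):
            outcome = ("regeneration" if i < 6 else
                       "ectopic" if i == 6 else "none")
            rec = RegenerationRecord(f"c{i}", 800.0, div=16,
                                     initial_response="bulb_formation",
                                     outcome=outcome, retraction_um=100.0,
                                     bulb_time_hr=2.0)
            records.append(ax.categorize_record(rec))
        out = ax.summarize_cohort(records, grouping=("div",))
        assert out["summary"]["regeneration_ratio"].iloc[0] == pytest.approx(0.7)

    def test_single_group_descriptives_only(self):
        records = [ax.categorize_record(RegenerationRecord(
            f"c{i}", 800.0, div=4, initial_response="bulb_formation",
            outcome="regeneration", retraction_um=50.0)) for i in range(5)]
        out = ax.summarize_cohort(records, grouping=("div",))
        assert out["tests"] == {}

    def test_planted_group_difference_detected_by_fisher(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            records = []
            for gi, p_reg in ((4, 0.6), (24, 0.1)):
                for i in range(50):
                    outcome = "regeneration" if rng.random() < p_reg else "none"
                    records.append(ax.categorize_record(RegenerationRecord(
                        f"d{gi}c{i}", 800.0, div=gi,
                        initial_response="bulb_formation", outcome=outcome,
                        retraction_um=100.0, bulb_time_hr=2.0)))
            out = ax.summarize_cohort(records, grouping=("div",))
            hits += out["tests"]["regeneration_ratio"][0]["p"] < 0.001
        assert hits >= 0.9 * n_seeds


def test_axotomy_distance_range_enforced():
    with pytest.raises(ValueError, match="axotomy distance"):
        AxotomyTimecourse("c", 100.0, np.array([0.0, 0.5]),
                          np.array([100.0, 90.0]))
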