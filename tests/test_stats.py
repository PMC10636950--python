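"""Response and survival statistics: oracles, invariants, full grid."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mpq.config import AnalysisConfig
from mpq.core import LesionMetrics, MpqError
from mpq.stats import (
    bh_adjust,
    cox_univariate,
    km_logrank_q3,
    mismatch_ratios,
    percent_change,
    run_full_analysis,
    spearman,
    wilcoxon_rank_sum,
)
from mpq.synth import CohortEffectSpec, make_cohort


class TestPercentChange:
    def test_basic_arithmetic(self):
        assert percent_change(2.0, 1.0) == pytest.approx(-50.0)

    def test_no_change_is_zero(self):
        assert percent_change(3.7, 3.7) == 0.0

    def test_zero_or_missing_baseline_gives_missing(self):
        assert percent_change(0.0, 1.0) is None
        assert percent_change(None, 1.0) is None
        assert percent_change(1.0, None) is None
        assert percent_change(np.nan, 1.0) is None


class TestMismatchRatios:
    def test_division(self):
        m = LesionMetrics(mrfdg=0.1, peak_ser=1.25, peak_pe=0.8, k1=0.1, suvmax=4.0)
        mismatch_ratios(m)
        assert m.mrfdg_peak_ser == pytest.approx(0.08)
        assert m.mrfdg_peak_pe == pytest.approx(0.125)
        assert m.mrfdg_k1 == pytest.approx(1.0)
        assert m.suvmax_peak_pe == pytest.approx(5.0)
        assert m.suvmax_peak_ser == pytest.approx(3.2)

    def test_zero_mrfdg_gives_zero_ratios(self):
        m = LesionMetrics(mrfdg=0.0, peak_ser=1.2, peak_pe=0.9, k1=0.1, suvmax=2.0)
        mismatch_ratios(m)
        assert m.mrfdg_peak_ser == 0.0 and m.mrfdg_peak_pe == 0.0 and m.mrfdg_k1 == 0.0

    def test_missing_denominator_propagates_only_there(self):
        m = LesionMetrics(mrfdg=0.1, peak_ser=1.25, peak_pe=None, k1=0.1, suvmax=4.0)
        mismatch_ratios(m)
        assert m.mrfdg_peak_pe is None and m.suvmax_peak_pe is None
        assert m.mrfdg_peak_ser == pytest.approx(0.08)


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        assert spearman(x, x**3).estimate == pytest.approx(1.0)
        assert spearman(x, -x).estimate == pytest.approx(-1.0)

    def test_matches_brute_force_rank_computation_with_ties(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 5, 10).astype(float)  # ties guaranteed
        y = rng.normal(size=10)
        r = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)  # average ranks
        expected = np.corrcoef(rx, ry)[0, 1]
        assert r.estimate == pytest.approx(expected, rel=1e-12)

    def test_constant_input_flagged(self):
        r = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert r.estimate is None and "constant" in r.note

    def test_pairwise_complete_deletion(self):
        r = spearman([1, 2, np.nan, 4, 5], [2, 4, 6, np.nan, 10])
        assert r.n == 3


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        r = wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0])
        assert r.p_raw == 1.0

    def test_exact_separated_groups(self):
        # fully separated 3-vs-3: 2 of C(6,3)=20 orderings as extreme
        r = wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.p_raw == pytest.approx(0.1)

    def test_exact_agrees_with_normal_approximation_moderate_n(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 9)
        b = rng.normal(0.5, 1, 9)
        exact = wilcoxon_rank_sum(a, b).p_raw  # n=18 <= 20, tie-free
        approx = sps.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert exact == pytest.approx(approx, abs=0.02)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_idempotent(self):
        p = np.array([0.001, 0.02, 0.04, 0.2, 0.9])
        once = bh_adjust(p)
        np.testing.assert_allclose(bh_adjust(once), bh_adjust(once))
        assert (bh_adjust(p) >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(MpqError):
            bh_adjust([0.5, 1.2])


class TestCox:
    # Frozen oracle from R survival::coxph (Efron ties) on this fixture.
    X = [-50.0, -40.0, -30.0, -20.0, -10.0, 0.0, 10.0, 20.0]
    T = [2.0, 3.0, 1.0, 4.0, 5.0, 6.0, 7.0, 8.0]
    E = [1, 0, 1, 1, 0, 1, 0, 1]

    def test_matches_r_coxph_oracle(self):
        r = cox_univariate(self.X, self.T, self.E, unit_percent=5.0)
        assert r.estimate == pytest.approx(0.6066929295, rel=1e-6)
        assert r.p_raw == pytest.approx(0.0913685107, rel=1e-5)

    def test_unit_rescaling_identity(self):
        per1 = cox_univariate(self.X, self.T, self.E, unit_percent=1.0)
        per5 = cox_univariate(self.X, self.T, self.E, unit_percent=5.0)
        assert np.log(per5.estimate) == pytest.approx(5.0 * np.log(per1.estimate), rel=1e-6)

    def test_no_events_flagged(self):
        r = cox_univariate([1.0, 2.0, 3.0], [1, 2, 3], [0, 0, 0])
        assert r.p_raw is None and "no events" in r.note

    def test_constant_covariate_flagged(self):
        r = cox_univariate([1.0, 1.0, 1.0], [1, 2, 3], [1, 0, 1])
        assert "constant" in r.note

    def test_planted_hazard_recovery(self):
        """Median fitted HR near a planted HR=1.04 per 5% at n=300."""
        hrs = []
        for seed in range(30):
            spec = CohortEffectSpec(
                n_responders=150, n_nonresponders=150,
                hazard_coefs={"mrfdg": np.log(1.04)},
                base_hazard_per_year=0.05, seed=seed,
            )
            df = make_cohort(spec)
            r = cox_univariate(
                df["pct_mrfdg_mid"], df["rfs_time_years"], df["rfs_event"]
            )
            hrs.append(r.estimate)
        assert 1.02 <= np.median(hrs) <= 1.06


class TestKaplanMeierLogrank:
    def km_inputs(self):
        # 8-subject hand fixture, frozen against R survival::survdiff/survfit:
        # group A times 1,2,3+,4 ; group B times 5,6+,7,8
        change = [-80.0, -70.0, -60.0, -55.0, -20.0, -10.0, -5.0, 0.0]
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        e = [1, 1, 0, 1, 1, 0, 1, 1]
        return change, t, e

    def test_hand_fixture_curves_and_statistic(self):
        # Q3 of 8 distinct values splits 6 vs 2 (linear interpolation);
        # chi-square and product-limit steps frozen from R survival.
        change, t, e = self.km_inputs()
        res = km_logrank_q3(change, t, e)
        assert res.test.estimate == pytest.approx(2.3381561433, rel=1e-6)
        assert res.test.p_raw == pytest.approx(0.1262388989, rel=1e-5)
        lo = res.curve_larger_decrease.set_index("time_years")["survival"]
        np.testing.assert_allclose(
            [lo.loc[1.0], lo.loc[2.0], lo.loc[4.0], lo.loc[5.0]],
            [5 / 6, 2 / 3, 4 / 9, 2 / 9],
        )
        hi = res.curve_smaller_decrease.set_index("time_years")["survival"]
        np.testing.assert_allclose([hi.loc[7.0], hi.loc[8.0]], [0.5, 0.0])

    def test_km_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(3.0, 40)
        e = np.ones(40, bool)
        change = np.concatenate([rng.normal(-50, 5, 30), rng.normal(0, 5, 10)])
        res = km_logrank_q3(change, t, e)
        lower = change <= np.percentile(change, 75)
        tl = np.sort(t[lower])
        curve = res.curve_larger_decrease.set_index("time_years")["survival"]
        for i, ti in enumerate(tl):
            assert curve.loc[ti] == pytest.approx(1.0 - (i + 1) / tl.size)

    def test_no_events_flagged(self):
        change = [-50.0, -40.0, -30.0, -20.0, -10.0, 0.0]
        res = km_logrank_q3(change, [1, 2, 3, 4, 5, 6], [0] * 6)
        assert res.test.p_raw is None
        assert "log-rank undefined" in res.test.note
        assert (res.curve_larger_decrease["survival"] == 1.0).all()

    def test_degenerate_split_flagged(self):
        res = km_logrank_q3([5.0] * 8, list(range(1, 9)), [1] * 8)
        assert "degenerate" in res.test.note


class TestFullAnalysis:
    def test_grid_on_default_cohort(self):
        df = make_cohort(CohortEffectSpec(seed=3))
        report = run_full_analysis(df)
        # 14 metrics x 2 timepoints for both analyses
        assert len(report.wilcoxon) == 28
        assert len(report.cox) == 28
        assert set(r.family for r in report.wilcoxon) == {"wilcoxon_mid", "wilcoxon_post"}
        for r in report.wilcoxon:
            if r.p_raw is not None:
                assert r.p_adjusted >= r.p_raw - 1e-12
        assert set(report.km) == set(AnalysisConfig().km_metrics)
        assert len(report.group_summary) == 28

    def test_single_patient_graceful(self):
        df = make_cohort(CohortEffectSpec(seed=3)).iloc[:1].copy()
        report = run_full_analysis(df)
        assert any("insufficient" in n for n in report.notes)
        assert all(r.p_raw is None for r in report.wilcoxon)

    def test_deterministic_given_cohort(self):
        df = make_cohort(CohortEffectSpec(seed=7))
        r1 = run_full_analysis(df).results_frame()
        r2 = run_full_analysis(df).results_frame()
        pd.testing.assert_frame_equal(r1, r2)

    def test_missing_outcome_columns_raise(self):
        with pytest.raises(MpqError, match="outcome column"):
            run_full_analysis(pd.DataFrame({"pct_adc_mid": [1.0, 2.0]}))
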