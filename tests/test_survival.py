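import numpy as np
import pytest
from scipy import stats

from synthaml import (compare_continuous, cox_hr, fisher_exact, km_estimate,
                      km_median_iqr, logistic_odds, logistic_or, logrank_test,
                      reverse_km_followup)

from conftest import km_product_limit_oracle, fisher_two_sided_oracle


class TestKaplanMeier:
    def test_five_events_toy(self):
        curve = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert curve.survival_at(3) == pytest.approx(0.4)
        assert curve.median() == 3

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert curve.survival_at(100) == 1.0
        assert np.isnan(curve.median())

    def test_single_event_drops_to_zero(self):
        curve = km_estimate([1.0], [1.0])
        assert curve.survival_at(1.0) == 0.0

    def test_matches_brute_force_product_limit_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 200)
            t = np.round(rng.exponential(10, n), 1)
            e = (rng.uniform(size=n) < 0.7).astype(float)
            if e.sum() == 0:
                continue
            curve = km_estimate(t, e)
            ot, os_ = km_product_limit_oracle(t, e)
            assert np.allclose(curve.event_times, ot)
            assert np.allclose(curve.survival, os_)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = np.round(rng.exponential(12, 300), 1)
        e = (rng.uniform(size=300) < 0.6).astype(float)
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = curve.survival_at(curve.event_times)
        theirs = kmf.survival_function_at_times(curve.event_times).to_numpy()
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_median_iqr_undefined_when_curve_plateaus(self):
        # 40% events, then censoring: survival never reaches 0.5
        t = [1, 1, 2, 3, 4, 5, 6, 7, 8, 9]
        e = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        med, q1, q3 = km_median_iqr(km_estimate(t, e))
        assert np.isnan(med) and np.isnan(q3)
        assert q1 == 2  # first time survival drops to <= 0.75


class TestReverseKM:
    def test_point_mass_censoring(self):
        med, lo, hi = reverse_km_followup([12, 12, 12], [0, 0, 0])
        assert med == 12

    def test_all_events_undefined(self):
        with pytest.warns(UserWarning, match="no censored"):
            med, lo, hi = reverse_km_followup([1, 2, 3], [1, 1, 1])
        assert np.isnan(med)

    def test_matches_flipped_indicator_oracle_on_fixture(self, fixture_cohort):
        t, e = fixture_cohort.survival("os")
        med, lo, hi = reverse_km_followup(t, e)
        ot, os_ = km_product_limit_oracle(t, 1 - e)
        brute_med = ot[os_ <= 0.5][0]
        assert med == pytest.approx(brute_med)
        # censoring is entry-window uniform on [48, 132]: median ~ 90
        assert 85 <= med <= 95
        assert lo <= med <= hi


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        g = ([1, 2, 3, 4], [1, 0, 1, 1])
        stat, p = logrank_test(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # A: events at 1, 2; B: censored at 1, event at 3
        # O-E = 1, V = 0.5 -> chi2 = 2
        stat, p = logrank_test(([1, 2], [1, 1]), ([1, 3], [0, 1]))
        assert stat == pytest.approx(2.0)
        assert p == pytest.approx(stats.chi2.sf(2, 1))

    def test_matches_lifelines_on_random_groups(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(2)
        ta = rng.exponential(10, 150)
        tb = rng.exponential(14, 120)
        ea = (rng.uniform(size=150) < 0.8).astype(float)
        eb = (rng.uniform(size=120) < 0.8).astype(float)
        stat, p = logrank_test((ta, ea), (tb, eb))
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_power_at_hazard_ratio_two(self):
        rng = np.random.default_rng(3)
        ta = rng.exponential(10, 5000)
        tb = rng.exponential(20, 5000)
        e = np.ones(5000)
        _, p = logrank_test((ta, e), (tb, e))
        assert p < 0.001


class TestCox:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(4)
        n = 8000
        t = rng.exponential(10, n)
        x = (rng.uniform(size=n) < 0.5).astype(float)
        est = cox_hr(t, np.ones(n), x)
        assert 0.9 <= est.point <= 1.1
        assert est.ci_low <= est.point <= est.ci_high

    def test_recovers_planted_log_hr(self):
        # unconfounded single-covariate Weibull PH fixture, true log-HR 0.7
        from synthaml import default_config, simulate_cohort

        cfg = default_config(seed=21, n=20000)
        cfg.latent_corr = np.eye(len(cfg.latent_names))
        cfg.os_model = {"shape": 0.9, "scale": 19.0, "cure_fraction": 0.0,
                        "coefs": {"TP53": 0.7}}
        cohort, _ = simulate_cohort(cfg, n=20000)
        t, e = cohort.survival("os")
        keep = cohort.df["TP53"].notna().to_numpy()
        est = cox_hr(cohort.df.loc[keep, "os_time"],
                     cohort.df.loc[keep, "os_event"],
                     cohort.df.loc[keep, "TP53"])
        assert np.log(est.point) == pytest.approx(0.7, abs=0.1)

    def test_matches_lifelines_breslow_direction(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 500
        x = (rng.uniform(size=n) < 0.4).astype(float)
        t = rng.exponential(10 * np.exp(-0.5 * x))
        e = np.ones(n)
        est = cox_hr(t, e, x)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}),
                                "t", "e")
        assert est.point == pytest.approx(float(np.exp(cph.params_["x"])),
                                          rel=0.02)

    def test_constant_covariate_raises_named_error(self):
        with pytest.raises(ValueError, match="marker_x"):
            cox_hr([1, 2, 3], [1, 1, 1], [1, 1, 1], name="marker_x")

    def test_agrees_with_logrank_significance_on_fixture(self, fixture_cohort):
        t, e = fixture_cohort.survival("os")
        x = fixture_cohort.df["TP53"].to_numpy(float)
        keep = np.isfinite(x)
        est = cox_hr(t[keep], e[keep], x[keep])
        _, p_lr = logrank_test((t[keep][x[keep] == 0], e[keep][x[keep] == 0]),
                               (t[keep][x[keep] == 1], e[keep][x[keep] == 1]))
        assert (est.p < 0.05) == (p_lr < 0.05)


class TestOddsAndOddsRatio:
    @pytest.mark.parametrize("s,f,odds,lo,hi", [
        (1135, 471, 2.41, 2.16, 2.68),  # CR odds, original cohort
        (1184, 422, 2.81, 2.51, 3.14),  # CR odds, first synthetic cohort
        (10, 10, 1.00, None, None),
    ])
    def test_odds_with_wald_ci(self, s, f, odds, lo, hi):
        est = logistic_odds(s, f)
        assert est.point == pytest.approx(odds, abs=0.005)
        if lo is not None:
            assert est.ci_low == pytest.approx(lo, abs=0.005)
            assert est.ci_high == pytest.approx(hi, abs=0.005)

    def test_ci_contains_point(self):
        est = logistic_odds(30, 17)
        assert est.ci_low <= est.point <= est.ci_high

    def test_zero_cell_warns(self):
        with pytest.warns(UserWarning, match="zero cell"):
            est = logistic_odds(5, 0)
        assert np.isnan(est.ci_low)

    def test_wald_ci_coverage_at_trial_size(self):
        # 2000 binomial replicates at n=1606, p=0.707: the 95% Wald CI for
        # the odds should cover the true odds 95% +/- 1.5% of the time
        rng = np.random.default_rng(6)
        n, p = 1606, 0.707
        true_odds = p / (1 - p)
        s = rng.binomial(n, p, size=2000)
        f = n - s
        logodds = np.log(s / f)
        se = np.sqrt(1 / s + 1 / f)
        z = stats.norm.ppf(0.975)
        cover = (np.log(true_odds) >= logodds - z * se) & \
                (np.log(true_odds) <= logodds + z * se)
        assert cover.mean() == pytest.approx(0.95, abs=0.015)

    def test_or_matches_logistic_regression(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = (rng.uniform(size=n) < 0.3).astype(float)
        py = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        y = (rng.uniform(size=n) < py).astype(float)
        est_2x2 = logistic_or(y, x)
        import statsmodels.api as sm

        res = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
        assert np.log(est_2x2.point) == pytest.approx(res.params[1], abs=1e-6)


class TestCompareContinuous:
    def test_identical_samples_p_near_one(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 100)
        name, stat, p = compare_continuous(a, a.copy())
        assert p >= 0.99

    def test_normal_samples_get_t_test_with_power(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 500)
        b = rng.normal(1, 1, 500)
        name, stat, p = compare_continuous(a, b)
        assert name == "t-test"
        assert p < 1e-10

    def test_lognormal_samples_get_wilcoxon(self):
        rng = np.random.default_rng(10)
        a = np.exp(rng.normal(0, 1, 500))
        b = np.exp(rng.normal(0, 1, 500))
        name, _, _ = compare_continuous(a, b)
        assert name == "wilcoxon-rank-sum"

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_continuous([1.0, 2.0], [1.0, 2.0, 3.0])


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ([[768, 838], [703, 903]], 0.023),  # sex, original vs first synthetic
        ([[768, 838], [781, 825]], 0.672),  # sex, original vs second synthetic
    ])
    def test_printed_sex_tables(self, table, expected):
        assert round(fisher_exact(table), 3) == expected

    def test_identical_rows_p_one(self):
        assert fisher_exact([[10, 20], [10, 20]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            tab = rng.integers(0, 40, size=(2, 2))
            if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                continue
            assert fisher_exact(tab) == pytest.approx(
                fisher_two_sided_oracle(tab), rel=1e-8)

    def test_symmetric_under_row_and_column_swaps(self):
        tab = np.array([[12, 5], [3, 20]])
        p = fisher_exact(tab)
        assert fisher_exact(tab[::-1]) == pytest.approx(p)
        assert fisher_exact(tab[:, ::-1]) == pytest.approx(p)
        assert fisher_exact(tab.T) == pytest.approx(p)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact([[0, 0], [5, 10]]) == 1.0
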