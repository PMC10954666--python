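import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synthaml import (RISK_MARKER_PANEL, alteration_frequencies,
                      baseline_table, classify_concordance,
                      concordance_matrix, cooccurrence_diff, outcome_table,
                      univariable_panel)

from conftest import make_cohort


class TestBaselineTable:
    def test_identity_comparison_has_no_significant_rows(self, fixture_cohort):
        tab = baseline_table(fixture_cohort, {"copy": fixture_cohort.copy()},
                             variables=["age", "wbc", "sex", "NPM1"])
        assert not tab["significant"].any()
        assert (tab["p"] >= 0.99).all()

    def test_printed_sex_counts_reproduce_significant_p(self):
        # 768 F / 838 M in one cohort vs 703 F / 903 M in the other
        sex_a = ["F"] * 768 + ["M"] * 838
        sex_b = ["F"] * 703 + ["M"] * 903
        a = make_cohort({"sex": ("categorical", sex_a)})
        b = make_cohort({"sex": ("categorical", sex_b)})
        tab = baseline_table(a, {"syn": b})
        p_female = tab[tab.level == "F"].iloc[0]["p"]
        assert round(p_female, 3) == 0.023
        assert tab[tab.level == "F"].iloc[0]["significant"]

    def test_planted_mean_shift_is_the_only_flagged_continuous_row(self, fixture_cohort):
        shifted = fixture_cohort.copy(label="shifted")
        sd = shifted.df["hb"].std()
        shifted.df["hb"] = shifted.df["hb"] + 2 * sd
        tab = baseline_table(fixture_cohort, {"shifted": shifted},
                             variables=["age", "wbc", "hb", "plt"])
        flagged = tab[tab["significant"]]["variable"].tolist()
        assert flagged == ["hb"]


class TestOutcomeTable:
    def test_cr_odds_row_matches_printed_original_cohort(self):
        cr = [1.0] * 1135 + [0.0] * 471
        rng = np.random.default_rng(0)
        n = len(cr)
        t = np.round(rng.exponential(17, n), 1)
        cohort = make_cohort({
            "cr": ("binary", cr),
            "efs_time": ("time", t * 0.6),
            "efs_event": ("event_indicator", np.ones(n)),
            "os_time": ("time", t),
            "os_event": ("event_indicator", np.ones(n)),
        }, endpoints={"cr": "cr", "efs": ("efs_time", "efs_event"),
                      "os": ("os_time", "os_event")})
        row = outcome_table(cohort, {}).iloc[0]
        assert row["cr_percent"] == pytest.approx(70.7, abs=0.05)
        assert row["cr_odds"] == pytest.approx(2.41, abs=0.005)
        assert row["cr_odds_ci_high"] == pytest.approx(2.68, abs=0.005)

    def test_cohort_versus_itself_hr_one_logrank_p_one(self, fixture_cohort):
        tab = outcome_table(fixture_cohort, {"copy": fixture_cohort.copy()})
        row = tab[tab.cohort == "copy"].iloc[0]
        assert row["os_hr"] == pytest.approx(1.0, abs=1e-6)
        assert row["os_logrank_p"] == pytest.approx(1.0)
        assert row["cr_fisher_p"] == pytest.approx(1.0)

    def test_planted_hazard_ratio_recovered(self):
        rng = np.random.default_rng(1)
        n = 20000
        base = rng.exponential(15, n)
        mk = lambda t: make_cohort({
            "cr": ("binary", (rng.uniform(size=n) < 0.7).astype(float)),
            "efs_time": ("time", t * 0.7),
            "efs_event": ("event_indicator", np.ones(n)),
            "os_time": ("time", t),
            "os_event": ("event_indicator", np.ones(n)),
        }, endpoints={"cr": "cr", "efs": ("efs_time", "efs_event"),
                      "os": ("os_time", "os_event")})
        orig = mk(base)
        syn = mk(rng.exponential(15, n) / 0.74)  # hazard 0.74x the original
        tab = outcome_table(orig, {"syn": syn})
        hr = tab[tab.cohort == "syn"].iloc[0]["os_hr"]
        assert hr == pytest.approx(0.74, abs=0.05)


class TestAlterationFrequencies:
    def test_identity_gives_p_one_everywhere(self, fixture_cohort):
        tab = alteration_frequencies(fixture_cohort,
                                     {"copy": fixture_cohort.copy()},
                                     alterations=["NPM1", "TP53", "ZRSR2"])
        assert (tab["copy_p"] == 1.0).all()
        assert not tab["copy_highly_significant"].any()

    def test_doubled_frequency_is_flagged(self, fixture_cohort):
        bumped = fixture_cohort.copy(label="bumped")
        col = bumped.df["TP53"].to_numpy(float)
        zeros = np.flatnonzero(col == 0)
        rng = np.random.default_rng(2)
        flip = rng.choice(zeros, int((col == 1).sum()), replace=False)
        col[flip] = 1.0
        bumped.df["TP53"] = col
        tab = alteration_frequencies(fixture_cohort, {"b": bumped},
                                     alterations=["NPM1", "TP53"])
        assert tab.set_index("alteration").loc["TP53", "b_highly_significant"]
        assert not tab.set_index("alteration").loc["NPM1", "b_highly_significant"]

    def test_percent_recomputes_from_counts(self, fixture_cohort):
        tab = alteration_frequencies(fixture_cohort, {},
                                     alterations=["NPM1", "DNMT3A"])
        for _, r in tab.iterrows():
            assert r["original_percent"] == pytest.approx(
                100 * r["original_count"] / fixture_cohort.n)


class TestCooccurrenceDiff:
    def test_identity_gives_zero_matrix(self, fixture_cohort):
        m = cooccurrence_diff(fixture_cohort, fixture_cohort.copy(),
                              alterations=["NPM1", "FLT3_ITD", "TP53"])
        assert np.allclose(m.to_numpy(), 0.0)

    def test_absent_pair_clamps_to_minus_100(self):
        both = make_cohort({"a": ("binary", [1.0, 1.0, 0.0, 0.0]),
                            "b": ("binary", [1.0, 1.0, 1.0, 0.0])})
        neither = make_cohort({"a": ("binary", [1.0, 0.0, 0.0, 0.0]),
                               "b": ("binary", [0.0, 1.0, 1.0, 0.0])})
        m = cooccurrence_diff(both, neither)
        assert m.loc["a", "b"] == -100.0

    def test_matches_brute_force_counting(self, fixture_cohort, synthetic_cohort):
        names = ["NPM1", "FLT3_ITD", "complex_karyotype"]
        m = cooccurrence_diff(fixture_cohort, synthetic_cohort, names)
        eps = 1.0 / fixture_cohort.n
        for a, b in itertools.combinations(names, 2):
            po = ((fixture_cohort.df[a] == 1) & (fixture_cohort.df[b] == 1)).mean()
            ps = ((synthetic_cohort.df[a] == 1) & (synthetic_cohort.df[b] == 1)).mean()
            exp = np.clip(100 * (ps - po) / max(po, eps), -100, 100)
            assert m.loc[a, b] == pytest.approx(exp)
            assert m.loc[b, a] == pytest.approx(exp)

    def test_entries_always_within_bounds(self, fixture_cohort, synthetic_cohort):
        m = cooccurrence_diff(fixture_cohort, synthetic_cohort)
        assert (m.to_numpy() >= -100).all() and (m.to_numpy() <= 100).all()


class TestUnivariablePanel:
    def test_panel_shape_and_kinds(self, fixture_cohort):
        panel = univariable_panel(fixture_cohort)
        assert len(panel) == len(RISK_MARKER_PANEL) * 3
        assert set(panel[panel.endpoint == "CR"]["kind"]) == {"odds_ratio"}
        assert set(panel[panel.endpoint == "OS"]["kind"]) == {"hazard_ratio"}

    def test_age_adverse_direction_recovered(self, big_cohort, big_truth):
        panel = univariable_panel(big_cohort, markers=["age"],
                                  endpoints=("os",))
        hr = panel.iloc[0]["estimate"]
        assert big_truth.true_log_hrs["age_z"] > 0
        assert hr > 1.0 and panel.iloc[0]["p"] < 0.05

    def test_null_marker_or_ci_covers_one(self):
        # 200 replicates of an outcome-independent binary marker at n=1606:
        # the Wald OR interval should cover 1 at close to the nominal rate
        rng = np.random.default_rng(3)
        n, reps = 1606, 200
        cover = 0
        z = stats.norm.ppf(0.975)
        for _ in range(reps):
            x = rng.uniform(size=n) < 0.25
            y = rng.uniform(size=n) < 0.7
            n11 = (x & y).sum(); n10 = (x & ~y).sum()
            n01 = (~x & y).sum(); n00 = (~x & ~y).sum()
            lo_r = np.log(n11 * n00 / (n10 * n01))
            se = np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
            cover += (lo_r - z * se <= 0 <= lo_r + z * se)
        assert cover / reps >= 0.93

    def test_absent_marker_raises_named_error(self, fixture_cohort):
        with pytest.raises(KeyError, match="NOT_A_GENE"):
            univariable_panel(fixture_cohort, markers=["NOT_A_GENE"])


class TestConcordance:
    def test_classification_exhaustive_over_all_flag_combinations(self):
        for d_r, d_s, s_r, s_s in itertools.product((-1, 1), (-1, 1),
                                                    (False, True), (False, True)):
            cls = classify_concordance(d_r, d_s, s_r, s_s)
            opposite = d_r != d_s
            if opposite and (s_r or s_s):
                assert cls == "inverse"
            elif not (s_r or s_s):
                assert cls == "concordant_nonsignificant"
            elif s_r and s_s:
                assert cls == "concordant_significant"
            else:
                assert cls == "significance_discordant"

    def test_panel_versus_itself_all_concordant(self, fixture_cohort):
        panel = univariable_panel(fixture_cohort)
        summary = concordance_matrix(panel, panel.copy())
        assert summary.inverse_count == 0
        assert "significance_discordant" not in summary.counts

    def test_one_flipped_significant_effect_is_one_inverse_cell(self, fixture_cohort):
        panel = univariable_panel(fixture_cohort)
        flipped = panel.copy()
        sig = flipped[(flipped.p < 0.05) & (flipped.estimate > 1)].index[0]
        flipped.loc[sig, "estimate"] = 1.0 / flipped.loc[sig, "estimate"]
        summary = concordance_matrix(panel, flipped)
        assert summary.inverse_count == 1

    def test_generator_sample_shows_zero_inverse_effects(self, fixture_cohort,
                                                         synthetic_cohort):
        real = univariable_panel(fixture_cohort)
        syn = univariable_panel(synthetic_cohort)
        summary = concordance_matrix(real, syn)
        assert summary.inverse_count == 0
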