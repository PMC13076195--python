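"""Group-level inference: ANCOVA/ANOVA/logistic, Holm, missingness checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habitdecay.asymptotic import AsymptoteOutcome
from habitdecay.gam import WeeklyRate
from habitdecay.inference import (
    adjusted_difference,
    ancova,
    ancova_log_days,
    anova_rate,
    build_outcome_table,
    holm_adjust,
    logistic_asymptote,
    missingness_check,
)
from habitdecay.preprocess import MagnitudeEndpoints, PersonSeries


def _series(pid, arm):
    return PersonSeries(pid, arm, np.arange(5), np.full(5, 2.0), 2.0)


class TestOutcomeTable:
    def _inputs(self):
        series = [_series("P1", "control"), _series("P2", "substitution+reward")]
        eps = {p: MagnitudeEndpoints(2.5, 1.5, "last-week-mean") for p in ("P1", "P2")}
        asym = {"P1": AsymptoteOutcome(True, 1, 20.0), "P2": AsymptoteOutcome(False, 0, math.nan)}
        rates = {"P1": WeeklyRate(-0.05, -0.02)}
        return series, eps, asym, rates

    def test_invalid_fit_scores_zero_keeps_others(self):
        series, eps, asym, rates = self._inputs()
        t = build_outcome_table(series, eps, asym, rates)
        row = t.set_index("participant_id").loc["P2"]
        assert row["reached95"] == 0 and math.isnan(row["t95_days"])
        assert row["final_srbai"] == 1.5
        assert row["strategy"] == "substitution" and row["reward"] == "yes"

    def test_missing_gam_leaves_rates_missing(self):
        series, eps, asym, rates = self._inputs()
        t = build_outcome_table(series, eps, asym, rates).set_index("participant_id")
        assert math.isnan(t.loc["P2", "week1_rate"])
        assert t.loc["P1", "week1_rate"] == -0.05

    def test_complete_participant_has_no_missing(self):
        series, eps, asym, rates = self._inputs()
        t = build_outcome_table(series, eps, asym, rates).set_index("participant_id")
        assert not t.loc["P1"].drop(["t95_days"]).isna().any()
        assert t.loc["P1", "t95_days"] == 20.0

    def test_duplicate_participant_errors(self):
        series = [_series("P1", "control"), _series("P1", "control")]
        with pytest.raises(ValueError):
            build_outcome_table(series, {}, {}, {})

    def test_control_rows_have_na_reward(self):
        series, eps, asym, rates = self._inputs()
        t = build_outcome_table(series, eps, asym, rates).set_index("participant_id")
        assert t.loc["P1", "strategy"] == "control" and t.loc["P1", "reward"] == "n/a"


class TestAncova:
    def test_orthogonal_covariate_leaves_group_means(self):
        # within-group constant outcome: covariate slope is exactly 0
        df = pd.DataFrame({
            "y": [1.0, 1.0, 2.0, 2.0],
            "g": ["a", "a", "b", "b"],
            "x": [-1.0, 1.0, -1.0, 1.0],
        })
        res = ancova(df, "y", ["g"], "x")
        means = res.adjusted_means.set_index("g")["mean"]
        assert means["a"] == pytest.approx(1.0, abs=1e-10)
        assert means["b"] == pytest.approx(2.0, abs=1e-10)

    def test_two_group_f_equals_squared_t(self, rng):
        df = pd.DataFrame({
            "y": np.r_[rng.normal(0, 1, 30), rng.normal(0.4, 1, 30)],
            "g": ["a"] * 30 + ["b"] * 30,
        })
        res = anova_rate(df, "y", ["g"])
        t, _ = stats.ttest_ind(df.loc[df.g == "a", "y"], df.loc[df.g == "b", "y"])
        assert res.effect("g").statistic == pytest.approx(t**2, abs=1e-10)

    def test_ges_equals_eta_squared_oneway(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 90) + np.repeat([0.0, 0.3, 0.6], 30),
            "g": np.repeat(["a", "b", "c"], 30),
        })
        res = anova_rate(df, "y", ["g"])
        grand = df["y"].mean()
        ss_b = sum(len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("g"))
        ss_t = ((df["y"] - grand) ** 2).sum()
        assert res.effect("g").ges == pytest.approx(ss_b / ss_t, abs=1e-10)

    def test_null_data_large_p(self):
        df = pd.DataFrame({"y": np.tile([1.0, 2.0, 3.0], 4),
                           "g": np.repeat(["a", "b"], 6)})
        res = anova_rate(df, "y", ["g"])
        assert res.effect("g").p > 0.9

    def test_zero_variance_covariate_matches_anova(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 40) + np.repeat([0.0, 0.5], 20),
            "g": np.repeat(["a", "b"], 20),
            "x": 1.0,
        })
        f_anova = anova_rate(df, "y", ["g"]).effect("g").statistic
        f_ancova = ancova(df, "y", ["g"], "x").effect("g").statistic
        assert f_ancova == pytest.approx(f_anova, abs=1e-8)

    def test_recovers_simulated_difference(self, rng):
        diffs = []
        for _ in range(30):
            df = pd.DataFrame({
                "y": np.r_[rng.normal(0, 1, 200), rng.normal(0.5, 1, 200)],
                "g": np.repeat(["a", "b"], 200),
                "x": rng.normal(0, 1, 400),
            })
            res = ancova(df, "y", ["g"], "x")
            est, _, _ = adjusted_difference(res, "g", "b", "a")
            diffs.append(est)
        assert abs(np.mean(diffs) - 0.5) < 0.15

    def test_factorial_interaction_detected(self, rng):
        # pure interaction of 1 sd: detected in > 80% of replicates
        hits = 0
        reps = 60
        for _ in range(reps):
            rows = []
            for s in ("inhibition", "substitution", "reduced-accessibility"):
                for r in ("no", "yes"):
                    shift = 0.5 if (s == "substitution") == (r == "yes") else -0.5
                    rows.append(pd.DataFrame({
                        "y": rng.normal(shift, 1.0, 44), "strategy": s, "reward": r}))
            df = pd.concat(rows, ignore_index=True)
            res = anova_rate(df, "y", ["strategy", "reward"])
            hits += res.effect("strategy:reward").p < 0.05
        assert hits / reps > 0.8

    def test_empty_level_errors(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError):
            anova_rate(df, "y", ["g"])


class TestLogistic:
    def test_balanced_probability_half(self):
        df = pd.DataFrame({"y": np.tile([0, 1], 20), "g": np.repeat(["a", "b"], 20)})
        res = logistic_asymptote(df, "y", ["g"], covariate=None)
        means = res.adjusted_means.set_index("g")
        assert means.loc["a", "mean"] == pytest.approx(0.5, abs=1e-6)
        # delta-method SE at p = 0.5 is exactly 0.25 x SE(linear predictor)
        eta_se = means.loc["a", "se"] / (0.5 * 0.5)
        ci_lo = 1 / (1 + math.exp(-(0.0 - stats.norm.ppf(0.975) * eta_se)))
        assert means.loc["a", "ci_lo"] == pytest.approx(ci_lo, abs=1e-6)

    def test_two_level_wald_z_reported(self, rng):
        y = np.r_[rng.binomial(1, 0.2, 100), rng.binomial(1, 0.5, 100)]
        df = pd.DataFrame({"y": y, "g": np.repeat(["a", "b"], 100)})
        res = logistic_asymptote(df, "y", ["g"], covariate=None)
        eff = res.effect("g")
        assert eff.stat_name == "z" and eff.p < 0.01

    def test_null_calibration(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame({"y": rng.binomial(1, 0.3, 160),
                               "g": np.repeat(["a", "b"], 80)})
            res = logistic_asymptote(df, "y", ["g"], covariate=None)
            hits += res.effect("g").p < 0.05
        assert abs(hits / reps - 0.05) < 0.035

    def test_complete_separation_flagged(self):
        df = pd.DataFrame({"y": [0] * 20 + [1] * 20, "g": ["a"] * 20 + ["b"] * 20})
        res = logistic_asymptote(df, "y", ["g"], covariate=None)
        assert not res.effect("g").estimable


class TestLogDays:
    def test_back_transform_identities(self, rng):
        df = pd.DataFrame({
            "t95_days": np.exp(rng.normal(2.0, 0.5, 120)),
            "g": np.repeat(["a", "b"], 60),
            "x": rng.normal(0, 1, 120),
        })
        res = ancova_log_days(df, "t95_days", ["g"], "x")
        m = res.adjusted_means
        np.testing.assert_allclose(m["mean"], np.exp(m["mean_log"]))
        np.testing.assert_allclose(m["se"], np.exp(m["mean_log"]) * m["se_log"])
        np.testing.assert_allclose(m["ci_lo"], np.exp(m["mean_log"] - stats.t.ppf(0.975, res.df_resid) * m["se_log"]), rtol=1e-10)

    def test_known_group_ratio_recovered(self, rng):
        ests = []
        for _ in range(20):
            df = pd.DataFrame({
                "t95_days": np.r_[np.exp(rng.normal(2.0, 0.4, 150)),
                                  np.exp(rng.normal(2.0 + math.log(2), 0.4, 150))],
                "g": np.repeat(["a", "b"], 150),
            })
            res = ancova_log_days(df, "t95_days", ["g"], covariate=None)
            m = res.adjusted_means.set_index("g")["mean"]
            ests.append(m["b"] / m["a"])
        assert abs(np.mean(ests) - 2.0) < 0.1

    def test_nonpositive_rows_excluded(self):
        df = pd.DataFrame({"t95_days": [10.0, 0.0, -1.0, 20.0, 15.0, 12.0],
                           "g": ["a", "a", "a", "a", "b", "b"],
                           "x": [1, 2, 3, 4, 5, 6.0]})
        res = ancova_log_days(df, "t95_days", ["g"], covariate=None)
        assert res.nobs == 4


class TestHolm:
    def test_study_family_smallest_adjusted(self):
        fam = [0.007, 0.039, 0.395, 0.655, 0.792, 0.846]
        adj = holm_adjust(fam, 6)
        assert adj[0] == pytest.approx(0.042)
        # step-down: second-smallest multiplied by 5, floor at previous
        assert adj[1] == pytest.approx(0.195)

    def test_all_ties(self):
        np.testing.assert_allclose(holm_adjust([0.01] * 6, 6), 0.06)

    def test_family_padding(self):
        # two observed p values in a declared family of 6
        adj = holm_adjust([0.007, 0.039], 6)
        assert adj[0] == pytest.approx(0.042)
        assert adj[1] == pytest.approx(0.195)

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 9))
            adj = holm_adjust(p)
            # brute force: adj_(i) = max_{j<=i} min(1, (m-j+1) p_(j))
            order = np.argsort(p)
            m = len(p)
            expected = np.empty(m)
            run = 0.0
            for j, idx in enumerate(order):
                run = max(run, min(1.0, (m - j) * p[idx]))
                expected[idx] = run
            np.testing.assert_allclose(adj, expected)
            np.testing.assert_allclose(adj, multipletests(p, method="holm")[1])
            assert (adj >= p - 1e-15).all()

    def test_bonferroni_dominance(self, rng):
        p = rng.uniform(0, 0.4, 6)
        adj = holm_adjust(p)
        bonf = np.minimum(p * 6, 1.0)
        assert adj[np.argmin(p)] == pytest.approx(bonf[np.argmin(p)])
        assert (adj <= bonf + 1e-15).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            holm_adjust([0.1, 0.2, 0.3], family_size=2)


class TestMissingness:
    def test_null_predictors_rarely_significant(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            df = pd.DataFrame({
                "miss": rng.binomial(1, 0.4, 200),
                "group": np.repeat(["control", "intervention"], 100),
                "intention": rng.normal(3, 0.7, 200),
            })
            res = missingness_check(df, "miss", ["C(group)", "intention"])
            hits += any(e.p < 0.05 for e in res.effects)
        # two independent null tests: familywise rate ~= 1 - 0.95^2
        assert abs(hits / reps - 0.0975) < 0.06

    def test_intention_driven_missingness_detected(self, rng):
        hits = 0
        reps = 40
        for _ in range(reps):
            intention = rng.normal(0, 1, 313)
            p = 1 / (1 + np.exp(-(-0.4 + 1.0 * intention)))
            df = pd.DataFrame({
                "miss": rng.binomial(1, p),
                "group": rng.choice(["control", "intervention"], 313),
                "intention": intention,
            })
            res = missingness_check(df, "miss", ["C(group)", "intention"])
            pint = [e.p for e in res.effects if "intention" in e.name][0]
            hits += pint < 0.05
        assert hits / reps > 0.8

    def test_constant_indicator_degenerate(self):
        df = pd.DataFrame({"miss": [0] * 10, "group": ["a", "b"] * 5})
        res = missingness_check(df, "miss", ["C(group)"])
        assert all(not e.estimable for e in res.effects)
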