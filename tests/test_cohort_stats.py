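"""Cohort statistics: fixture integrity, OLS/t/ANOVA/Tukey/NB/power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dnmsuite import cohort_stats


class TestLoadCohort:
    def test_packaged_fixture_shape_and_total(self, table1):
        assert len(table1) == 53
        assert table1["dnm_count"].sum() == 4344
        assert set(table1["method"]) == set(cohort_stats.METHODS)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("child_id,method,dnm_count,maternal_age,"
                     "paternal_age,fertility_status\n")
        with pytest.raises(ValueError):
            cohort_stats.load_cohort(p)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("child_id,method,dnm_count,maternal_age,"
                     "paternal_age,fertility_status\n"
                     "A,spontaneous,70,30,30,none\n"
                     "B,teleportation,70,30,30,none\n")
        with pytest.raises(ValueError, match="row 3"):
            cohort_stats.load_cohort(p)

    def test_mid_range_paternal_age_rejected(self, tmp_path):
        p = tmp_path / "mid.csv"
        p.write_text("child_id,method,dnm_count,maternal_age,"
                     "paternal_age,fertility_status\n"
                     "A,IVF,70,30,40,none\n")
        with pytest.raises(ValueError, match="age-group"):
            cohort_stats.load_cohort(p)


class TestGroupMeans:
    def test_published_group_means(self, table1):
        out = cohort_stats.group_means(table1)
        got = {(r.method, r.age_group): r.mean_rounded
               for r in out.itertuples()}
        assert got == {
            ("spontaneous", "<35"): 71, ("spontaneous", ">45"): 94,
            ("IVF", "<35"): 69, ("IVF", ">45"): 97,
            ("ICSI-TESE", "<35"): 70, ("ICSI-TESE", ">45"): 92,
        }

    def test_cohort_mean_rounds_to_82(self, table1):
        assert round(table1["dnm_count"].mean()) == 82

    def test_single_record_group_flags_sd(self):
        df = pd.DataFrame({"method": ["IVF"], "age_group": ["<35"],
                           "dnm_count": [70]})
        out = cohort_stats.group_means(df)
        assert out.loc[0, "mean"] == 70
        assert np.isnan(out.loc[0, "sd"])


class TestOlsRegression:
    def test_published_fit(self, table1):
        fit = cohort_stats.ols_regression(table1)
        assert fit.params["paternal_age"] == pytest.approx(1.09, abs=0.005)
        assert fit.bse["paternal_age"] == pytest.approx(0.19, abs=0.005)
        assert fit.tvalues["paternal_age"] == pytest.approx(5.636, abs=5e-4)
        assert fit.r_squared == pytest.approx(0.6113, abs=5e-5)
        assert fit.f_stat == pytest.approx(18.87, abs=0.005)
        assert fit.f_df == (4, 48)

    def test_f_r2_identity(self, table1):
        # F = (R^2/df1) / ((1-R^2)/df2) must hold internally
        fit = cohort_stats.ols_regression(table1)
        df1, df2 = fit.f_df
        implied = (fit.r_squared / df1) / ((1 - fit.r_squared) / df2)
        assert fit.f_stat == pytest.approx(implied, rel=1e-10)

    def test_exact_linear_fit(self):
        df = pd.DataFrame({"method": ["IVF"] * 6,
                           "paternal_age": [25, 28, 31, 46, 49, 52],
                           "maternal_age": [30] * 6})
        df["dnm_count"] = 10 + 2 * df["paternal_age"]
        fit = cohort_stats.ols_regression(
            df, formula="dnm_count ~ paternal_age")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.params["paternal_age"] == pytest.approx(2.0)

    def test_rank_deficiency_raises(self, table1):
        df = table1.copy()
        df["paternal_age_twice"] = df["paternal_age"]
        with pytest.raises(ValueError, match="rank-deficient"):
            cohort_stats.ols_regression(
                df, formula="dnm_count ~ paternal_age + paternal_age_twice")

    def test_matches_normal_equations_oracle(self):
        # brute-force (X'X)^-1 X'y on random small designs
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(10, 31))
            df = pd.DataFrame({
                "paternal_age": rng.uniform(20, 60, n),
                "maternal_age": rng.uniform(20, 45, n),
            })
            df["dnm_count"] = rng.normal(50 + df["paternal_age"], 5)
            fit = cohort_stats.ols_regression(
                df, formula="dnm_count ~ paternal_age + maternal_age")
            X = np.column_stack([np.ones(n), df["paternal_age"],
                                 df["maternal_age"]])
            beta = np.linalg.solve(X.T @ X, X.T @ df["dnm_count"])
            got = [fit.params["Intercept"], fit.params["paternal_age"],
                   fit.params["maternal_age"]]
            np.testing.assert_allclose(got, beta, atol=1e-8)


class TestTwoSampleT:
    def test_published_statistic(self, table1):
        res = cohort_stats.two_sample_t(table1)
        assert res.statistic == pytest.approx(-7.9, abs=0.05)
        assert res.df == 51  # 27 + 26 - 2
        assert res.pvalue < 1e-8

    def test_identical_groups_zero(self):
        df = pd.DataFrame({"age_group": ["<35"] * 3 + [">45"] * 3,
                           "dnm_count": [70, 80, 90, 70, 80, 90]})
        assert cohort_stats.two_sample_t(df).statistic == pytest.approx(0.0)

    def test_textbook_example(self):
        # {1,2,3} vs {4,5,6}: pooled t = -3.674, df = 4
        df = pd.DataFrame({"age_group": ["<35"] * 3 + [">45"] * 3,
                           "dnm_count": [1, 2, 3, 4, 5, 6]})
        res = cohort_stats.two_sample_t(df)
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4

    def test_type_one_error_calibration(self):
        """Under the null, rejection rate at alpha 0.05 stays in
        [0.04, 0.06] over 10,000 simulations (vectorised)."""
        rng = np.random.default_rng(2024)
        n1 = n2 = 20
        a = rng.normal(size=(10_000, n1))
        b = rng.normal(size=(10_000, n2))
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
        t = (a.mean(axis=1) - b.mean(axis=1)) \
            / (sp * np.sqrt(1 / n1 + 1 / n2))
        crit = stats.t.ppf(0.975, n1 + n2 - 2)
        rate = (np.abs(t) > crit).mean()
        assert 0.04 <= rate <= 0.06


class TestFactorialAnova:
    def test_balanced_two_by_two_matches_hand_formulas(self):
        # cells: means 10, 20, 30, 40, two obs each, +-1 within cell
        rows = []
        for mi, method in enumerate(["IVF", "spontaneous"]):
            for gi, grp in enumerate(["<35", ">45"]):
                mean = 10 + 20 * mi + 10 * gi
                for v in (mean - 1, mean + 1):
                    rows.append({"method": method, "age_group": grp,
                                 "dnm_count": v})
        df = pd.DataFrame(rows)
        res = {r.term: r for r in cohort_stats.factorial_anova(df)}
        # balanced closed forms: SS_A = b*n*sum_i(dev_i^2), method row
        # deviations +-10, age deviations +-5; SS_resid = 8 (each obs +-1
        # from its cell mean), df_resid = 4, MSE = 2
        ss_method = 2 * 2 * (10 ** 2 + 10 ** 2)   # 800
        ss_age = 2 * 2 * (5 ** 2 + 5 ** 2)        # 200
        assert res["C(method)"].statistic == pytest.approx(ss_method / 2.0)
        assert res["C(age_group)"].statistic == pytest.approx(ss_age / 2.0)
        assert res["C(method):C(age_group)"].statistic \
            == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_all_f_zero(self):
        df = pd.DataFrame({"method": ["IVF", "IVF", "spontaneous",
                                      "spontaneous"] * 2,
                           "age_group": ["<35", ">45"] * 4,
                           "dnm_count": [70] * 8})
        for r in cohort_stats.factorial_anova(df):
            assert r.statistic == 0.0

    def test_type_one_ss_sum_to_total(self, table1):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        fit = smf.ols("dnm_count ~ C(method) + C(age_group) + "
                      "C(method):C(age_group)", data=table1).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        total = ((table1["dnm_count"] - table1["dnm_count"].mean()) ** 2
                 ).sum()
        assert tab["sum_sq"].sum() == pytest.approx(total, rel=1e-12)

    def test_method_term_not_significant_on_cohort(self, table1):
        res = {r.term: r for r in cohort_stats.factorial_anova(table1)}
        method = res["C(method)"]
        assert method.pvalue > 0.5
        assert method.statistic < 1.0

    def test_empty_cell_with_interaction_raises(self):
        df = pd.DataFrame({"method": ["IVF", "IVF", "spontaneous"],
                           "age_group": ["<35", ">45", "<35"],
                           "dnm_count": [60, 90, 70]})
        with pytest.raises(ValueError, match="empty factor cell"):
            cohort_stats.factorial_anova(df)


class TestTukey:
    def test_identical_groups_adjusted_p_near_one(self):
        df = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4,
                           "dnm_count": [60, 70, 80, 90] * 2})
        res = cohort_stats.tukey_posthoc(df, grouping="group")
        assert res[0].adjusted_pvalue > 0.99

    def test_cohort_young_vs_old_spontaneous_significant(self, table1):
        res = cohort_stats.tukey_posthoc(table1)
        term = "spontaneous <35 vs spontaneous >45"
        hit = [r for r in res if r.term == term
               or r.term == "spontaneous >45 vs spontaneous <35"]
        assert len(hit) == 1
        assert hit[0].adjusted_pvalue <= 0.05

    def test_shifted_group_drives_significance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "group": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
            "dnm_count": np.concatenate([rng.normal(70, 3, 10),
                                         rng.normal(70, 3, 10),
                                         rng.normal(95, 3, 10)]),
        })
        res = cohort_stats.tukey_posthoc(df, grouping="group")
        sig = {r.term: r.adjusted_pvalue <= 0.05 for r in res}
        assert sig == {"a vs b": False, "a vs c": True, "b vs c": True}

    def test_p_matches_studentized_range_oracle(self):
        # dual route: recompute one pair's p from the studentized range
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "group": ["a"] * 8 + ["b"] * 8 + ["c"] * 8,
            "dnm_count": rng.normal([70] * 8 + [75] * 8 + [90] * 8, 5.0),
        })
        res = {r.term: r.pvalue
               for r in cohort_stats.tukey_posthoc(df, grouping="group")}
        k, n = 3, 24
        groups = df.groupby("group")["dnm_count"]
        mse = (groups.var(ddof=1) * 7).sum() / (n - k)
        q = abs(groups.mean()["a"] - groups.mean()["b"]) \
            / np.sqrt(mse / 8)
        p = stats.studentized_range.sf(q, k, n - k)
        assert res["a vs b"] == pytest.approx(p, abs=1e-6)

    def test_bonferroni_flag_inflates_p(self, table1):
        plain = cohort_stats.tukey_posthoc(table1)
        bonf = cohort_stats.tukey_posthoc(table1, bonferroni=True)
        for a, b in zip(plain, bonf):
            assert b.adjusted_pvalue >= a.adjusted_pvalue - 1e-12
            assert b.adjusted_pvalue <= 1.0


class TestNbRegression:
    def test_intercept_only_fits_sample_mean(self):
        counts = [3, 7, 2, 9, 4, 6, 8, 1]
        fit = cohort_stats.nb_regression(counts,
                                         np.empty((len(counts), 0)))
        assert np.exp(fit.params["const"]) == pytest.approx(np.mean(counts),
                                                            rel=1e-6)

    def test_parameter_recovery(self):
        # y ~ NB(mean=exp(1 + 0.5x)), n=500: estimate within 3 SE of 0.5
        rng = np.random.default_rng(31)
        x = rng.uniform(-1, 1, 500)
        mu = np.exp(1.0 + 0.5 * x)
        alpha = 0.3
        lam = rng.gamma(shape=1 / alpha, scale=mu * alpha)
        y = rng.poisson(lam)
        fit = cohort_stats.nb_regression(y, pd.DataFrame({"x": x}))
        assert abs(fit.params["x"] - 0.5) < 3 * fit.bse["x"]

    def test_approaches_poisson_for_equidispersed_data(self):
        """On Poisson data the NB fit converges to a hand-rolled Poisson
        IRLS oracle (dispersion -> 0)."""
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 300)
        y = rng.poisson(np.exp(0.5 + 1.2 * x))
        fit = cohort_stats.nb_regression(y, pd.DataFrame({"x": x}))
        # independent Poisson IRLS
        X = np.column_stack([np.ones_like(x), x])
        beta = np.zeros(2)
        for _ in range(50):
            eta = X @ beta
            mu = np.exp(eta)
            z = eta + (y - mu) / mu
            W = mu
            beta_new = np.linalg.solve(X.T @ (W[:, None] * X),
                                       X.T @ (W * z))
            if np.max(np.abs(beta_new - beta)) < 1e-12:
                beta = beta_new
                break
            beta = beta_new
        assert fit.params["const"] == pytest.approx(beta[0], abs=0.02)
        assert fit.params["x"] == pytest.approx(beta[1], abs=0.02)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cohort_stats.nb_regression([-1, 2], np.empty((2, 0)))


class TestPower:
    def test_unit_standardised_effect_needs_sixteen(self):
        # 2 (1.95996 + 0.84162)^2 = 15.698 -> 16
        assert cohort_stats.power_two_means(1.0, 1.0) == 16

    def test_cohort_scale_effect_needs_fifty_four(self):
        # standardized effect 0.5392 reproduces the 54-per-group design
        assert cohort_stats.power_two_means(0.5392, 1.0) == 54

    def test_huge_effect_floors_at_two(self):
        assert cohort_stats.power_two_means(1e6, 1.0) == 2

    def test_inverse_consistency(self):
        delta = cohort_stats.minimum_detectable_effect(54, sd=15.0)
        assert cohort_stats.power_two_means(delta, 15.0) == 54

    def test_against_simulation(self):
        """Empirical power at the closed-form n ~= the nominal 80%
        (10,000 replicates, delta = sd)."""
        n = cohort_stats.power_two_means(1.0, 1.0)
        rng = np.random.default_rng(99)
        a = rng.normal(0.0, 1.0, size=(10_000, n))
        b = rng.normal(1.0, 1.0, size=(10_000, n))
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        sp = np.sqrt((va + vb) / 2)
        t = (b.mean(axis=1) - a.mean(axis=1)) / (sp * np.sqrt(2 / n))
        crit = stats.t.ppf(0.975, 2 * n - 2)
        power = (np.abs(t) > crit).mean()
        assert power == pytest.approx(0.80, abs=0.05)
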