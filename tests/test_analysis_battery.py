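"""Descriptives, test selection, exact Poisson intervals, Cox fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

import linklevel as ll
from linklevel.analysis_battery import select_categorical_test


def cohort_from_contingency(table):
    """Long-format cohort realizing a variable x group contingency table."""
    rows = []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            rows += [{"var": f"v{i}", "grp": f"g{j}"}] * count
    return pd.DataFrame(rows)


class TestDescribe:
    def test_categorical_percentage(self):
        df = pd.DataFrame({"x": ["a"] * 172 + ["b"] * 828})
        out = ll.describe(df, ["x"])
        cell = out.loc[out["level"] == "a", "summary"].item()
        assert cell == "172 (17.2%)"

    def test_constant_continuous(self):
        df = pd.DataFrame({"x": [2.0] * 9})
        out = ll.describe(df, ["x"])
        assert "2.00 ± 0.00" in out["summary"].item()
        assert "2 (2, 2)" in out["summary"].item()

    def test_order_statistics(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 100]})
        out = ll.describe(df, ["x"])
        assert "3 (1, 100)" in out["summary"].item()

    def test_empty_stratum_flagged(self):
        df = pd.DataFrame({"x": [np.nan], "s": ["a"]})
        out = ll.describe(df, ["x"], strata="s")
        assert (out["flag"] == "empty").any()


class TestGroupComparisonSelection:
    def test_balanced_2x2_uses_chi_square_with_p_one(self):
        df = cohort_from_contingency([[5, 5], [5, 5]])
        res = ll.compare_groups(df, "var", "grp")
        assert res.test_used == "chi-square"
        assert res.p_value == pytest.approx(1.0)

    def test_sparse_2x2_uses_fisher(self):
        # expected frequencies 1.5 in two of four cells -> 50% > 20%
        df = cohort_from_contingency([[1, 9], [2, 8]])
        res = ll.compare_groups(df, "var", "grp")
        assert res.test_used == "Fisher"

    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 5], [5, 5]], "chi-square"),
            ([[1, 9], [2, 8]], "Fisher"),
            ([[50, 60], [40, 30], [10, 4]], "chi-square"),  # 1/6 cells < 5
            ([[3, 3], [3, 3], [30, 30]], "Fisher"),
        ],
    )
    def test_expected_frequency_rule(self, table, expected):
        assert select_categorical_test(np.array(table)) == expected

    def test_identical_continuous_samples_give_p_one(self):
        x = np.r_[np.arange(10.0), 100.0]  # outlier defeats normality
        df = pd.DataFrame({"y": np.r_[x, x], "grp": ["a"] * 11 + ["b"] * 11})
        res = ll.compare_groups(df, "y", "grp")
        assert res.p_value == pytest.approx(1.0)
        assert res.test_used in ("t-test", "Mann-Whitney")

    def test_normal_two_groups_selects_t_test(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.normal(size=400), "grp": ["a", "b"] * 200})
        assert ll.compare_groups(df, "y", "grp").test_used == "t-test"

    def test_skewed_two_groups_selects_mann_whitney(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.exponential(size=400) ** 2, "grp": ["a", "b"] * 200})
        assert ll.compare_groups(df, "y", "grp").test_used == "Mann-Whitney"

    def test_three_groups_normal_and_skewed(self):
        rng = np.random.default_rng(2)
        grp = ["a", "b", "c"] * 200
        normal = pd.DataFrame({"y": rng.normal(size=600), "grp": grp})
        skewed = pd.DataFrame({"y": rng.exponential(size=600) ** 2, "grp": grp})
        assert ll.compare_groups(normal, "y", "grp").test_used == "ANOVA"
        assert ll.compare_groups(skewed, "y", "grp").test_used == "Kruskal-Wallis"

    def test_monte_carlo_fisher_for_larger_tables(self):
        df = cohort_from_contingency([[3, 3, 2], [2, 3, 3], [30, 30, 30]])
        res = ll.compare_groups(df, "var", "grp", seed=5)
        assert res.test_used == "Fisher"
        assert 0.5 < res.p_value <= 1.0  # near-homogeneous table

    def test_tiny_group_raises_named_error(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "grp": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="b"):
            ll.compare_groups(df, "y", "grp")


def garwood_oracle(k, py, per=100_000.0):
    """Brute-force Poisson tail inversion, independent of chi-square quantiles."""
    if k == 0:
        low = 0.0
    else:
        low = brentq(lambda mu: stats.poisson.sf(k - 1, mu) - 0.025, 1e-12, 10 * k + 50, xtol=1e-12)
    high = brentq(lambda mu: stats.poisson.cdf(k, mu) - 0.025, 1e-12, 10 * k + 60, xtol=1e-12)
    return low / py * per, high / py * per


class TestIncidence:
    def test_zero_events_closed_form(self):
        est = ll.incidence_rate(0, 1000.0)
        assert est.rate == 0.0 and est.ci_low == 0.0
        assert est.ci_high == pytest.approx(-np.log(0.025) / 1000.0 * 100_000, rel=1e-6)

    def test_rate_arithmetic_and_bracketing(self):
        est = ll.incidence_rate(10, 100_000.0)
        assert est.rate == pytest.approx(10.0)
        assert est.ci_low < est.rate < est.ci_high

    def test_matches_tail_inversion_oracle(self):
        for k in (0, 1, 3, 17):
            est = ll.incidence_rate(k, 50_000.0)
            low, high = garwood_oracle(k, 50_000.0)
            assert est.ci_low == pytest.approx(low, rel=1e-9)
            assert est.ci_high == pytest.approx(high, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ll.incidence_rate(1, 0.0)
        with pytest.raises(ValueError):
            ll.incidence_rate(-1, 10.0)


def toy_cox_data():
    return pd.DataFrame(
        {
            "treatment_arm": ["trt", "ctrl", "trt", "ctrl"],
            "event_time_years": [1.0, 2.0, 3.0, 4.0],
            "event_indicator": ["fracture", "fracture", "censored", "censored"],
        }
    )


def toy_partial_likelihood(beta):
    # events at t=1 (risk set x = 1,0,1,0) and t=2 (risk set x = 0,1,0)
    eb = np.exp(beta)
    return np.log(eb / (2 * eb + 2)) + np.log(1.0 / (eb + 2))


class TestCox:
    def test_toy_fit_matches_partial_likelihood_grid(self):
        grid = np.arange(-5, 5, 1e-4)
        beta_star = grid[np.argmax(toy_partial_likelihood(grid))]
        fit = ll.fit_cox(toy_cox_data(), "treatment_arm", [], reference_arm="ctrl")
        est = fit.estimate_for("treatment_arm=trt")
        assert np.log(est.hr) == pytest.approx(beta_star, abs=1e-3)
        # fit-level log-likelihood agrees with the hand-written one
        assert fit.log_likelihood == pytest.approx(toy_partial_likelihood(np.log(est.hr)), abs=1e-6)
        assert fit.log_likelihood_null == pytest.approx(toy_partial_likelihood(0.0), abs=1e-6)

    def test_reference_arm_reported_as_unity(self):
        fit = ll.fit_cox(toy_cox_data(), "treatment_arm", [], reference_arm="ctrl")
        ref = [e for e in fit.estimates if e.is_reference]
        assert len(ref) == 1 and ref[0].hr == 1.0 and ref[0].term == "treatment_arm=ctrl"

    def test_null_effect_recovery(self):
        rng = np.random.default_rng(3)
        n = 10_000
        df = pd.DataFrame(
            {
                "treatment_arm": rng.choice(["a", "b"], n),
                "event_time_years": rng.exponential(5.0, n).clip(1e-6),
                "event_indicator": rng.choice(["fracture", "censored"], n, p=[0.6, 0.4]),
            }
        )
        fit = ll.fit_cox(df, "treatment_arm", [], reference_arm="a")
        est = fit.estimate_for("treatment_arm=b")
        assert 0.9 < est.hr < 1.1
        assert est.ci_low < 1.0 < est.ci_high

    def test_no_events_is_an_error(self):
        df = toy_cox_data()
        df["event_indicator"] = "censored"
        with pytest.raises(ValueError, match="no events"):
            ll.fit_cox(df, "treatment_arm", [])

    def test_adjusted_fit_reports_covariates(self):
        rng = np.random.default_rng(4)
        n = 2000
        df = pd.DataFrame(
            {
                "treatment_arm": rng.choice(["a", "b"], n),
                "age_years": rng.normal(60, 10, n),
                "event_time_years": rng.exponential(5.0, n).clip(1e-6),
                "event_indicator": rng.choice(["fracture", "censored"], n),
            }
        )
        fit = ll.fit_cox(df, "treatment_arm", ["age_years"], reference_arm="a")
        est = fit.estimate_for("treatment_arm=b")
        assert est.adjusted and est.covariates == ["age_years"]


class TestSubgroup:
    def make_cohort(self, seed=0, n=4000, hr_a=2.0, hr_b=1.0):
        rng = np.random.default_rng(seed)
        stratum = rng.choice(["A", "B"], n)
        arm = rng.choice(["ctrl", "trt"], n)
        beta = np.where(stratum == "A", np.log(hr_a), np.log(hr_b)) * (arm == "trt")
        t = rng.exponential(1.0, n) / (0.2 * np.exp(beta))
        censor = 8.0
        return pd.DataFrame(
            {
                "treatment_arm": arm,
                "stratum": stratum,
                "event_time_years": np.minimum(t, censor),
                "event_indicator": np.where(t <= censor, "fracture", "censored"),
            }
        )

    def test_single_level_stratifier_equals_plain_fit(self):
        df = self.make_cohort(seed=1)
        df["stratum"] = "only"
        fits, skipped = ll.subgroup_effects(df, "treatment_arm", [], "stratum", reference_arm="ctrl")
        assert not skipped and list(fits) == ["only"]
        direct = ll.fit_cox(df, "treatment_arm", [], reference_arm="ctrl")
        assert fits["only"].estimate_for("treatment_arm=trt").hr == pytest.approx(
            direct.estimate_for("treatment_arm=trt").hr
        )

    def test_interaction_recovered_within_ci(self):
        df = self.make_cohort(seed=2, n=10_000, hr_a=2.0, hr_b=1.0)
        fits, _ = ll.subgroup_effects(df, "treatment_arm", [], "stratum", reference_arm="ctrl")
        est_a = fits["A"].estimate_for("treatment_arm=trt")
        est_b = fits["B"].estimate_for("treatment_arm=trt")
        assert est_a.ci_low < 2.0 < est_a.ci_high
        assert est_b.ci_low < 1.0 < est_b.ci_high

    def test_eventless_stratum_skipped_with_log(self):
        df = self.make_cohort(seed=3, n=500)
        df.loc[df["stratum"] == "B", "event_indicator"] = "censored"
        fits, skipped = ll.subgroup_effects(df, "treatment_arm", [], "stratum", reference_arm="ctrl")
        assert "A" in fits and "B" not in fits
        assert any(s.startswith("B") for s in skipped)
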