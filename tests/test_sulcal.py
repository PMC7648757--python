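"""Asymmetry index, group tests, covariate-adjusted contrasts and
summary-statistic reconstructions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sulcnet.cohort_tables import GENDER_COUNTS, PANSS_P1, PANSS_P3, PANSS_P3_YEAR_AVERAGE
from sulcnet.data import ValidationError
from sulcnet.sulcal import (
    ai_group_tests,
    anova_from_summary,
    asymmetry_index,
    chisq_from_table,
    correlate_lgi_sulcal,
    icc_agreement,
    sulcal_regression,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


@pytest.mark.parametrize(
    "left,right,expected",
    [(2.0, 2.0, 0.0), (1.0, 3.0, 1.0), (3.0, 1.0, -1.0), (0.0, 5.0, 2.0), (5.0, 0.0, -2.0)],
)
def test_asymmetry_index_values(left, right, expected):
    assert asymmetry_index(left, right) == pytest.approx(expected)


def test_asymmetry_index_absent_sulcus_is_missing():
    assert math.isnan(asymmetry_index(0.0, 0.0))


@given(left=positive, right=positive, c=st.floats(min_value=1e-3, max_value=1e3))
def test_asymmetry_index_properties(left, right, c):
    """Antisymmetric under L-R swap, bounded in [-2, 2], scale-invariant."""
    ai = asymmetry_index(left, right)
    assert -2.0 <= ai <= 2.0
    assert asymmetry_index(right, left) == pytest.approx(-ai, abs=1e-12)
    assert asymmetry_index(c * left, c * right) == pytest.approx(ai, rel=1e-9)


class TestSummaryAnova:
    def test_reconstructs_printed_group_statistics(self):
        """One-way F from published per-group mean/SD/n reproduces the
        reported statistics within the rounding of the printed inputs."""
        for table, rel in ((PANSS_P3, 0.02), (PANSS_P1, 0.02), (PANSS_P3_YEAR_AVERAGE, 0.02)):
            res = anova_from_summary(table["means"], table["sds"], table["ns"])
            assert res.value == pytest.approx(table["reported_f"], rel=rel)
            assert res.df == tuple(float(d) for d in table["reported_df"])

    def test_equal_means_give_zero_f(self):
        res = anova_from_summary([1.5, 1.5, 1.5], [0.3, 0.4, 0.5], [10, 12, 9])
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_equals_pooled_t_squared(self):
        """k=2: F equals the square of the pooled two-sample t from the same summaries."""
        m, s, n = [3.1, 2.4], [1.2, 0.9], [40, 55]
        res = anova_from_summary(m, s, n)
        sp2 = ((n[0] - 1) * s[0] ** 2 + (n[1] - 1) * s[1] ** 2) / (n[0] + n[1] - 2)
        t = (m[0] - m[1]) / math.sqrt(sp2 * (1 / n[0] + 1 / n[1]))
        assert res.value == pytest.approx(t**2, rel=1e-10)

    def test_matches_raw_data_anova(self):
        """Summaries of raw data reproduce the classical ANOVA to 10 digits."""
        rng = np.random.default_rng(7)
        groups = [rng.normal(mu, 1.0, n) for mu, n in ((0.0, 20), (0.4, 35), (0.1, 15))]
        res = anova_from_summary(
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
            [g.size for g in groups],
        )
        oracle = stats.f_oneway(*groups)
        assert res.value == pytest.approx(oracle.statistic, rel=1e-10)
        assert res.p == pytest.approx(oracle.pvalue, rel=1e-8)

    def test_rejects_small_groups(self):
        with pytest.raises(ValidationError):
            anova_from_summary([1.0, 2.0], [0.1, 0.2], [1, 5])


class TestChiSquare:
    def test_reconstructs_printed_gender_table(self):
        res = chisq_from_table(GENDER_COUNTS["table"])
        assert res.value == pytest.approx(GENDER_COUNTS["reported_chi2"], rel=0.02)
        assert res.df == (float(GENDER_COUNTS["reported_df"]),)

    def test_identical_proportions_give_zero(self):
        res = chisq_from_table([[10, 20], [5, 10], [20, 40]])
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_expanded_formula(self):
        """Pearson chi2 on a 2x2 table vs brute-force expected counts."""
        table = np.array([[10.0, 20.0], [20.0, 10.0]])
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        oracle = ((table - expected) ** 2 / expected).sum()
        res = chisq_from_table(table)
        assert res.value == pytest.approx(oracle, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chisq_from_table([[0, 0], [5, 3]])


class TestICC:
    def test_perfect_agreement(self):
        x = np.linspace(10, 60, 50)
        res = icc_agreement(x, x)
        assert res.value == pytest.approx(1.0, abs=1e-9)
        assert "ICC2" in res.note or "absolute agreement" in res.note

    def test_no_agreement(self):
        rng = np.random.default_rng(11)
        res = icc_agreement(rng.normal(size=500), rng.normal(size=500))
        assert abs(res.value) < 0.1

    def test_variance_ratio_closed_form(self):
        """True-score variance 9x the rater noise -> ICC near 0.9."""
        rng = np.random.default_rng(13)
        true = rng.normal(0, 3.0, 4000)
        a = true + rng.normal(0, 1.0, 4000)
        b = true + rng.normal(0, 1.0, 4000)
        res = icc_agreement(a, b)
        assert res.value == pytest.approx(0.9, abs=0.02)
        assert res.ci[0] < res.value < res.ci[1]

    def test_constant_ratings_flagged(self):
        res = icc_agreement(np.ones(10), np.ones(10))
        assert math.isnan(res.value) and "undefined" in res.note


def _subjects(n, rng, group="H+"):
    return pd.DataFrame(
        {
            "group": group,
            "age": rng.normal(25, 5, n),
            "sex": np.where(rng.random(n) < 0.4, "F", "M"),
            "site": rng.choice(["s1", "s2", "s3"], n),
            "tiv": rng.normal(1.48e6, 2e5, n),
        },
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id"),
    )


class TestSulcalRegression:
    def test_recovers_planted_covariate_betas(self):
        """Zero group effect, planted covariate slopes recovered within 3 SE."""
        rng = np.random.default_rng(17)
        n = 500
        subjects = pd.concat(
            [_subjects(n // 2, rng, "H+"), _subjects(n // 2, rng, "H-")]
        )
        subjects.index = [f"S{i:05d}" for i in range(n)]
        beta_age, beta_tiv = -0.08, 2e-5
        y = (
            50
            + beta_age * subjects["age"]
            + beta_tiv * subjects["tiv"]
            + rng.normal(0, 3, n)
        )
        import statsmodels.api as sm

        from sulcnet.sulcal import covariate_design

        X, names = covariate_design(subjects)
        fit = sm.OLS(y.to_numpy(), X).fit()
        for target, name in ((beta_age, "age"), (beta_tiv, "tiv")):
            j = names.index(name)
            assert abs(fit.params[j] - target) < 3 * fit.bse[j]
        # and the group contrast itself is null
        res = sulcal_regression(y, subjects, ("H+", "H-"))
        assert res.p > 0.001

    def test_matches_pooled_t_without_covariate_effects(self):
        """Two groups, covariates pure noise: contrast t ~ pooled two-sample t."""
        rng = np.random.default_rng(19)
        subjects = pd.concat([_subjects(60, rng, "H+"), _subjects(60, rng, "H-")])
        subjects.index = [f"S{i:05d}" for i in range(120)]
        subjects[["age", "tiv"]] = [25.0, 1.48e6]
        subjects["sex"] = "M"
        subjects["site"] = "s1"
        y = pd.Series(rng.normal(0, 1, 120), index=subjects.index)
        y[subjects["group"] == "H+"] += 0.8
        res = sulcal_regression(y, subjects, ("H+", "H-"))
        t_oracle = stats.ttest_ind(
            y[subjects["group"] == "H+"], y[subjects["group"] == "H-"]
        )
        assert res.t == pytest.approx(t_oracle.statistic, rel=1e-6)

    def test_constant_metric_flagged_degenerate(self):
        rng = np.random.default_rng(23)
        subjects = pd.concat([_subjects(30, rng, "H+"), _subjects(30, rng, "H-")])
        subjects.index = [f"S{i:05d}" for i in range(60)]
        y = pd.Series(5.0, index=subjects.index)
        res = sulcal_regression(y, subjects, ("H+", "H-"))
        assert res.degenerate and res.estimate == 0.0


class TestAiGroupTests:
    def test_null_anova_p_is_uniform(self):
        """Three mean-zero groups: ANOVA p uniform over 200 replicates (KS at 0.01)."""
        rng = np.random.default_rng(29)
        ps = []
        for _ in range(200):
            groups = {k: rng.normal(0, 1, 200) for k in ("a", "b", "c")}
            ps.append(ai_group_tests(groups)["anova"].p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_no_between_group_signal(self):
        """Equal group means: F small, all Tukey p near 1."""
        rng = np.random.default_rng(31)
        groups = {k: 0.1 + rng.normal(0, 0.5, 400) for k in ("a", "b", "c")}
        res = ai_group_tests(groups)
        assert res["anova"].p > 0.05
        assert (res["tukey"]["p_adj"] > 0.05).all()
        # one-sample tests still see the common 0.1 offset
        assert all(sr.p < 0.01 for sr in res["per_group"].values())

    def test_tukey_power_ordering(self):
        """A 0.5 SD shift planted in one group is the pair detected most often."""
        rng = np.random.default_rng(37)
        wins = {"ab": 0, "ac": 0, "bc": 0}
        for _ in range(100):
            groups = {
                "a": rng.normal(0.5, 1.0, 100),
                "b": rng.normal(0.0, 1.0, 100),
                "c": rng.normal(0.0, 1.0, 100),
            }
            tukey = ai_group_tests(groups)["tukey"].set_index(["group1", "group2"])
            for (g1, g2), row in tukey.iterrows():
                if row["p_adj"] < 0.05:
                    wins[g1[0] + g2[0]] += 1
        assert wins["ab"] > wins["bc"] and wins["ac"] > wins["bc"]

    def test_zero_variance_group_flagged_not_raised(self):
        res = ai_group_tests({"a": np.full(5, 0.2), "b": np.random.default_rng(1).normal(0, 1, 5)})
        assert math.isinf(res["per_group"]["a"].value)


class TestLgiSulcalCorrelation:
    def test_planted_dependence_detected(self):
        rng = np.random.default_rng(41)
        idx = pd.Index([f"S{i}" for i in range(200)])
        lgi = pd.DataFrame({"pcs_region": rng.normal(2.5, 0.2, 200)}, index=idx)
        sulc = pd.DataFrame(
            {"pcs_length": 20 * lgi["pcs_region"] + rng.normal(0, 0.5, 200)}, index=idx
        )
        out = correlate_lgi_sulcal(lgi, sulc)
        assert out["r"].iloc[0] > 0.9 and out["p"].iloc[0] < 1e-6

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(43)
        idx = pd.Index([f"S{i}" for i in range(1000)])
        lgi = pd.DataFrame({"x": rng.normal(size=1000)}, index=idx)
        sulc = pd.DataFrame({"y": rng.normal(size=1000)}, index=idx)
        out = correlate_lgi_sulcal(lgi, sulc)
        assert abs(out["r"].iloc[0]) < 0.1

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(47)
        idx = pd.Index([f"S{i}" for i in range(50)])
        ps = []
        for _ in range(200):
            lgi = pd.DataFrame({"x": rng.normal(size=50)}, index=idx)
            sulc = pd.DataFrame({"y": rng.normal(size=50)}, index=idx)
            ps.append(correlate_lgi_sulcal(lgi, sulc)["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
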