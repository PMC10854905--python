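"""Statistical workflow: gates, tests, logistic models, report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fundusgeom import stats as fs
from fundusgeom import synthgen as sg


class TestGate:
    def test_normal_samples_route_parametric_equal_variance(self):
        rng = np.random.default_rng(5)
        g = fs.normality_and_variance_gate(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
        assert g.parametric and g.equal_var

    def test_lognormal_samples_route_nonparametric(self):
        rng = np.random.default_rng(5)
        g = fs.normality_and_variance_gate(rng.lognormal(0, 1, 200),
                                           rng.lognormal(0, 1, 200))
        assert not g.parametric

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(8)
        g = fs.normality_and_variance_gate(rng.normal(0, 1, 300), rng.normal(0, 4, 300))
        assert g.equal_var is False

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(fs.DegenerateDataError, match="constant"):
            fs.normality_and_variance_gate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_tiny_sample_rejected(self):
        with pytest.raises(fs.DegenerateDataError):
            fs.normality_and_variance_gate([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTwoGroup:
    def test_identical_paired_samples(self):
        r = fs.two_group_continuous([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_pooled_t_hand_computed(self):
        """x=[1,2,3], y=[2,3,4]: pooled s^2 = 1, t = -1/sqrt(2/3)."""
        r = fs.two_group_continuous([1, 2, 3], [2, 3, 4],
                                    gate=fs.GatePolicy(True, True))
        assert r.statistic == pytest.approx(-1.2247, abs=5e-5)
        assert "pooled" in r.test

    def test_welch_route_when_variances_unequal(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 200), rng.normal(0, 5, 200)
        r = fs.two_group_continuous(x, y, gate=fs.GatePolicy(True, False))
        assert "Welch" in r.test

    def test_null_rejection_rate_calibrated(self):
        """Gated two-sample test on N(0,1) vs N(0,1), n=30: type-I error
        at alpha=0.05 stays within [0.04, 0.06] over 5000 replicates."""
        rng = np.random.default_rng(2024)
        rej = 0
        reps = 5000
        for _ in range(reps):
            r = fs.two_group_continuous(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
            rej += r.p_value < 0.05
        assert 0.04 <= rej / reps <= 0.06

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            fs.two_group_continuous([1, 2, 3], [1, 2], paired=True)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mann_whitney_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 1, 30)
        gate = fs.GatePolicy(False, True)
        r1 = fs.two_group_continuous(x, y, gate=gate)
        r2 = fs.two_group_continuous(np.exp(x), np.exp(y), gate=gate)
        assert r1.statistic == r2.statistic
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


class TestChiSquare:
    def test_printed_sex_table(self):
        """The 18/16 vs 16/9 male/female table gives chi2 = 0.722,
        p = 0.396 — the uncorrected Pearson statistic (Yates would give
        0.340, which does not match)."""
        r = fs.chi_square_2x2(18, 16, 16, 9)
        assert r.statistic == pytest.approx(0.722, abs=5e-4)
        assert r.p_value == pytest.approx(0.396, abs=5e-4)

    def test_homogeneous_table_gives_zero(self):
        assert fs.chi_square_2x2(10, 10, 10, 10).statistic == 0.0

    def test_closed_form_small_table(self):
        assert fs.chi_square_2x2(3, 1, 1, 3).statistic == pytest.approx(2.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(fs.DegenerateDataError, match="degenerate"):
            fs.chi_square_2x2(0, 0, 5, 7)

    def test_matches_closed_form_on_random_tables(self):
        """1000 random tables with positive margins: statistic equals
        N(ad-bc)^2 / product-of-margins to 1e-12."""
        rng = np.random.default_rng(99)
        done = 0
        while done < 1000:
            a, b, c, d = (int(v) for v in rng.integers(0, 40, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert fs.chi_square_2x2(a, b, c, d).statistic == pytest.approx(
                expected, abs=1e-12)
            done += 1


class TestAnova:
    def test_identical_groups(self):
        r = fs.anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_hand_anova_table(self):
        """[1,2],[3,4],[5,6]: SSB=16 (df 2), SSW=1.5 (df 3) -> F=16."""
        r = fs.anova_oneway([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(16.0, abs=1e-9)

    def test_all_constant_groups_rejected(self):
        with pytest.raises(fs.DegenerateDataError):
            fs.anova_oneway([[2.0, 2.0], [2.0, 2.0]])

    def test_null_rejection_rate_calibrated(self):
        """Four equal-mean normal groups, 2000 replicates: rejection rate
        approx 0.05 +- 0.01."""
        rng = np.random.default_rng(77)
        rej = sum(
            fs.anova_oneway([rng.normal(0, 1, 15) for _ in range(4)]).p_value < 0.05
            for _ in range(2000))
        assert 0.04 <= rej / 2000 <= 0.06

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pooled_t_squared_equals_two_group_f(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 12), rng.normal(0.3, 1, 17)
        t = fs.two_group_continuous(x, y, gate=fs.GatePolicy(True, True)).statistic
        f = fs.anova_oneway([x, y]).statistic
        assert t**2 == pytest.approx(f, abs=1e-9)


class TestLogistic:
    @staticmethod
    def _simulate(beta, n, seed, base=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        p = 1.0 / (1.0 + np.exp(-(base + beta * x)))
        y = (rng.random(n) < p).astype(int)
        return pd.DataFrame({"x": x, "y": y})

    def test_null_covariate_or_near_one(self):
        df = self._simulate(0.0, 5000, seed=3)
        t = fs.logistic_regression("y", df, ["x"]).term("x")
        assert 0.9 <= t.odds_ratio <= 1.1

    def test_or_two_recovered(self):
        df = self._simulate(np.log(2.0), 5000, seed=4)
        t = fs.logistic_regression("y", df, ["x"]).term("x")
        assert 1.8 <= t.odds_ratio <= 2.2
        assert t.ci_low <= 2.0 <= t.ci_high

    def test_log_or_bias_small_across_seeds(self):
        """Parameter recovery: |mean log-OR bias| <= 0.05 at n=5000 over
        20 seeds (true OR 2)."""
        biases = [
            fs.logistic_regression("y", self._simulate(np.log(2.0), 5000, seed=s),
                                   ["x"]).term("x").coef - np.log(2.0)
            for s in range(20)
        ]
        assert abs(np.mean(biases)) <= 0.05

    def test_constant_outcome_degenerate(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [1, 1, 1, 1]})
        with pytest.raises(fs.DegenerateDataError, match="outcome"):
            fs.logistic_regression("y", df, ["x"])

    def test_perfect_separation_names_covariate(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0],
                           "y": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(fs.SeparationError, match="x"):
            fs.logistic_regression("y", df, ["x"])

    def test_listwise_deletion_counted(self):
        df = self._simulate(0.5, 200, seed=6)
        df.loc[:9, "x"] = np.nan
        res = fs.logistic_regression("y", df, ["x"])
        assert res.n_dropped == 10 and res.n_used == 190

    def test_standardized_or_is_per_sd(self):
        df = self._simulate(np.log(2.0), 4000, seed=8)
        df["x10"] = df["x"] * 10.0  # same information, tenth-size unit
        raw = fs.logistic_regression("y", df, ["x10"]).term("x10")
        std = fs.logistic_regression("y", df, ["x10"], standardize=True).term("x10")
        assert std.odds_ratio == pytest.approx(raw.odds_ratio ** df["x10"].std(ddof=1),
                                               rel=1e-6)


class TestReport:
    def test_effect_pattern_reproduced_at_n200(self):
        """Cohort simulated at reported effect sizes (n=200/group): the
        CRVO affected-vs-contralateral venular-caliber difference is
        significant, the BRVO one is not, and the venular caliber has an
        adjusted OR > 1 (CI excluding 1) for CRVO vs BRVO."""
        cohort = sg.generate_cohort(sg.CohortSpec(n_brvo=200, n_crvo=200, seed=42))
        rep = fs.build_comparison_report(cohort)
        t2 = rep.table2.set_index("variable")
        assert t2.loc["rel_venular_caliber", "paired_crvo_p"] < 0.05
        assert t2.loc["rel_venular_caliber", "paired_brvo_p"] > 0.05
        ven = rep.model_crvo_vs_brvo["rel_venular_caliber"].term("rel_venular_caliber")
        assert ven.odds_ratio > 1.0 and ven.ci_low > 1.0

    def test_null_cohort_paired_false_positive_rate(self):
        """With all affected-eye effects off, paired within-group tests
        reject at about the nominal 5% (the per-run count of significant
        tests is a Binomial(n_tests, 0.05), not zero)."""
        sig = total = 0
        for seed in range(6):
            cohort = sg.generate_cohort(sg.null_cohort_spec(60, seed=seed))
            rep = fs.build_comparison_report(cohort)
            for col in ("paired_brvo_p", "paired_crvo_p"):
                p = rep.table2[col].to_numpy()
                sig += (p < 0.05).sum()
                total += len(p)
        # 204 null tests: binomial(204, .05) 99.9% upper bound ~ 21
        assert sig <= 21
        assert total == 6 * 2 * len(fs.TABLE2_VARIABLES)

    def test_missing_column_is_named(self):
        cohort = sg.generate_cohort(sg.CohortSpec(n_brvo=5, n_crvo=5, seed=0))
        df = cohort.df.drop(columns=["avr"])
        with pytest.raises(ValueError, match="avr"):
            fs.build_comparison_report(df)

    def test_two_rows_per_subject_enforced(self):
        cohort = sg.generate_cohort(sg.CohortSpec(n_brvo=5, n_crvo=5, seed=0))
        with pytest.raises(ValueError, match="2 eyes"):
            fs.build_comparison_report(cohort.df.iloc[1:])

    def test_table1_includes_demographics_and_sex_chi2(self):
        cohort = sg.generate_cohort(sg.CohortSpec(seed=17))
        rep = fs.build_comparison_report(cohort)
        assert "Gender, male/female" in set(rep.table1["variable"])
        assert len(rep.table1) == 6
        assert rep.table1["p_value"].between(0, 1).all()
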