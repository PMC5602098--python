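import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rescover.compare import (aquastat_category, category_false_reporting,
                              classify_adoption, confusion_30, fit_lpm,
                              fit_lpm_for_method, measurement_error_outcome,
                              spearman_matrix, summarize_distributions)


def brute_force_spearman(x, y):
    """Rank-formula oracle 1 - 6*sum(d^2)/(n(n^2-1)), tie-free vectors only."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = np.sum((rx - ry) ** 2)
    n = len(x)
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        rho, _, _ = spearman_matrix(df, ["a", "b"])
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1]})
        rho, _, _ = spearman_matrix(df, ["a", "b"])
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_small_rank_formula_example(self):
        # d^2 = (1, 1, 1, 1, 0): 1 - 6*4/(5*24) = 0.8
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5]})
        rho, _, _ = spearman_matrix(df, ["a", "b"])
        assert rho.loc["a", "b"] == pytest.approx(
            brute_force_spearman(df["a"].to_numpy(), df["b"].to_numpy()))
        assert rho.loc["a", "b"] == pytest.approx(0.8)

    def test_matches_rank_formula_oracle_on_permutations(self):
        """scipy's estimator equals the explicit d^2 formula on every
        tie-free arrangement (spot-check across permutations of 1..6)."""
        x = np.arange(1, 7)
        for perm in itertools.permutations(range(1, 7)):
            y = np.array(perm)
            assert stats.spearmanr(x, y).statistic == pytest.approx(
                brute_force_spearman(x, y), abs=1e-12)

    def test_pairwise_complete_sample_sizes(self, default_survey):
        plots, _ = default_survey
        rho, n, _ = spearman_matrix(plots, ["lt", "m1", "m5", "m6"])
        assert n.loc["lt", "m1"] == 314
        assert n.loc["lt", "m5"] == 182
        assert n.loc["lt", "m6"] == 251
        assert np.allclose(np.diag(rho.to_numpy()), 1.0)

    def test_all_tied_vector_flagged_undefined(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        rho, _, _ = spearman_matrix(df, ["a", "b"])
        assert np.isnan(rho.loc["a", "b"])


class TestSummaries:
    def test_constant_column(self):
        df = pd.DataFrame({"lt": [60.0] * 5})
        s = summarize_distributions(df, ["lt"])
        assert (s.loc["lt", ["min", "q1", "median", "q3", "max"]] == 60.0).all()

    def test_simple_median(self):
        df = pd.DataFrame({"lt": [10.0, 20, 30, 40, 50]})
        assert summarize_distributions(df, ["lt"]).loc["lt", "median"] == 30.0

    def test_median_gap_to_benchmark(self):
        df = pd.DataFrame({"lt": [50.0, 60, 70], "m1": [20.0, 30, 40]})
        s = summarize_distributions(df, ["lt", "m1"])
        assert s.loc["m1", "median_minus_lt"] == -30.0


class TestAdoption:
    @pytest.mark.parametrize("cover,adopter", [(30.0, True), (29.9, False),
                                               (100.0, True), (0.0, False)])
    def test_threshold_inclusive(self, cover, adopter):
        assert classify_adoption([cover])[0] == adopter

    @pytest.mark.parametrize("cover,cat", [(0, "<30"), (29.99, "<30"),
                                           (30, "30-60"), (59.9, "30-60"),
                                           (60, "60-90"), (89.9, "60-90"),
                                           (90, ">90"), (95, ">90"), (100, ">90")])
    def test_aquastat_bins(self, cover, cat):
        assert aquastat_category([cover])[0] == cat


class TestConfusion:
    def test_identical_method_is_perfect(self):
        df = pd.DataFrame({"lt": [10.0, 40, 70], "m": [10.0, 40, 70]})
        c = confusion_30(df, "m")
        assert c.accuracy == 100.0
        assert c.false_positive == c.false_negative == 0

    def test_both_misclassified(self):
        df = pd.DataFrame({"lt": [45.0, 20.0], "m": [25.0, 35.0]})
        c = confusion_30(df, "m")
        assert c.false_negative == 1 and c.false_positive == 1
        assert c.accuracy == 0.0

    def test_half_right(self):
        df = pd.DataFrame({"lt": [60.0, 60, 10, 10], "m": [70.0, 20, 5, 40]})
        c = confusion_30(df, "m")
        assert c.accuracy == 50.0

    def test_accuracy_plus_error_rate_is_total(self, default_survey):
        plots, _ = default_survey
        for m in ("m1", "m4", "m5"):
            c = confusion_30(plots, m)
            assert c.accuracy + c.error_rate == pytest.approx(100.0)


class TestCategoryFalseReporting:
    def test_identity_method(self):
        df = pd.DataFrame({"lt": [10.0, 45, 75, 95], "m": [10.0, 45, 75, 95]})
        table, rates = category_false_reporting(df, "m")
        assert np.array_equal(np.diag(table.to_numpy()), [1, 1, 1, 1])
        assert (rates["correct"] == 1.0).all()

    def test_all_zero_method_fully_underreports(self):
        df = pd.DataFrame({"lt": [45.0, 75, 95], "m": [0.0, 0, 0]})
        _, rates = category_false_reporting(df, "m")
        assert rates.loc["30-60", "under"] == 1.0
        assert rates.loc["60-90", "under"] == 1.0
        assert rates.loc[">90", "under"] == 1.0

    def test_three_plot_toy(self):
        df = pd.DataFrame({"lt": [35.0, 65, 95], "m": [10.0, 65, 80]})
        table, rates = category_false_reporting(df, "m")
        assert rates.loc["30-60", "under"] == 1.0    # 35 -> 10
        assert rates.loc["60-90", "correct"] == 1.0  # 65 -> 65
        assert rates.loc[">90", "under"] == 1.0      # 95 -> 80

    def test_margins_conserved_under_permutation(self, rng):
        df = pd.DataFrame({"lt": rng.uniform(0, 100, 50),
                           "m": rng.uniform(0, 100, 50)})
        t1, _ = category_false_reporting(df, "m")
        t2, _ = category_false_reporting(df.sample(frac=1, random_state=0), "m")
        assert t1.sum().sum() == t2.sum().sum()
        assert (t1.sum(axis=1) == t2.sum(axis=1)).all()


class TestMeasurementErrorOutcome:
    @pytest.mark.parametrize("lt,m,err", [(45, 25, 1), (45, 50, 0), (29, 31, 1)])
    def test_disagreement_coding(self, lt, m, err):
        df = pd.DataFrame({"lt": [float(lt)], "m": [float(m)]})
        assert measurement_error_outcome(df, "m").iloc[0] == err

    def test_missing_rows_excluded(self, default_survey):
        plots, _ = default_survey
        assert len(measurement_error_outcome(plots, "m5")) == 182
        assert len(measurement_error_outcome(plots, "m6")) == 251


class TestFitLpm:
    def test_outcome_equal_to_covariate(self):
        y = pd.Series([0, 1, 0, 1, 1, 0], dtype=float)
        x = pd.DataFrame({"d": y.to_numpy(), "z": [0.1, 0.9, 0.4, 0.2, 0.8, 0.3]})
        fit = fit_lpm(y, x)
        assert fit.params["d"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["z"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_intercept_only_recovers_mean(self):
        y = pd.Series([1, 0, 0, 1, 1], dtype=float)
        x = pd.DataFrame(index=y.index)
        fit = fit_lpm(y, x)
        assert fit.params["const"] == pytest.approx(y.mean())

    def test_matches_normal_equations_oracle(self):
        """Six-row design solved explicitly via (X'X)^-1 X'y."""
        y = pd.Series([0.0, 1, 1, 0, 1, 0])
        x = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [0.0, 1, 0, 1, 0, 1]})
        fit = fit_lpm(y, x)
        xm = np.column_stack([np.ones(6), x["a"], x["b"]])
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y.to_numpy())
        assert fit.params["const"] == pytest.approx(beta[0])
        assert fit.params["a"] == pytest.approx(beta[1])
        assert fit.params["b"] == pytest.approx(beta[2])
        # adjusted R2 from its definition
        resid = y.to_numpy() - xm @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        r2_adj = 1 - (1 - r2) * (6 - 1) / (6 - 2 - 1)
        assert fit.r2_adj == pytest.approx(r2_adj)

    def test_rank_deficient_design_rejected(self):
        y = pd.Series([0.0, 1, 0, 1])
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank"):
            fit_lpm(y, x)

    def test_interviewee_models_include_household_covariates(self, large_survey_records):
        f1 = fit_lpm_for_method(large_survey_records, "m1")
        f2 = fit_lpm_for_method(large_survey_records, "m2")
        assert "head_age" in f1.params.index
        assert "head_age" not in f2.params.index
        assert "distance" in f1.params.index and "distance" not in f2.params.index

    def test_error_covariate_signs_recovered(self, large_survey_records):
        """The generator's configured error drivers are detectable: larger
        and more distant fields raise interviewee misreporting, sloped
        fields lower it."""
        fit = fit_lpm_for_method(large_survey_records, "m1")
        assert fit.params["field_size"] > 0 and fit.tvalues["field_size"] > 2
        assert fit.params["distance"] > 0 and fit.tvalues["distance"] > 2
        assert fit.params["slight_slope"] < 0 and fit.tvalues["slight_slope"] < -2
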