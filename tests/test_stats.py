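import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cryptkin.stats import (
    association_block,
    bh_adjust,
    chi_square,
    fit_linear,
    fit_logistic,
    group_difference,
    km_logrank,
    spearman,
)


class TestSpearman:
    def test_perfect_monotone_agreement(self):
        x = np.arange(20.0)
        rho, _ = spearman(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_tied_data_equals_pearson_on_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(expected)

    def test_exact_permutation_p_for_small_n(self):
        # n=5 monotone: only 2 of 120 rank orderings reach |rho| = 1,
        # so the exact two-sided p is 2/120
        x = np.arange(5.0)
        _, p = spearman(x, x)
        assert p == pytest.approx(2 / 120)

    def test_constant_vector_reports_missing(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)


class TestChiSquare:
    def test_independent_table_gives_zero_statistic(self):
        res = chi_square([[25, 25], [25, 25]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_equals_direct_formula(self):
        # [[30,10],[10,30]]: all expected counts are 20, sum (O-E)^2/E = 20
        res = chi_square([[30, 10], [10, 30]])
        assert res.statistic == pytest.approx(20.0)

    def test_row_permutation_invariance(self, rng):
        table = rng.integers(1, 50, size=(3, 4))
        a = chi_square(table).statistic
        b = chi_square(table[[2, 0, 1]]).statistic
        assert a == pytest.approx(b)

    def test_low_expected_count_flagged(self):
        res = chi_square([[1, 9], [2, 8]])
        assert res.warnings

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[5, 5]])


def brute_force_bh(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(n)
    prev = np.inf
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top, 1.0)
        out[i] = val
        prev = val
    return out


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_equals_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(50)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestGroupDifference:
    def test_planted_two_sd_shift_detected(self, rng):
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        groups = np.array(["a"] * 50 + ["b"] * 50)
        assert group_difference(values, groups, "anova").p_value < 0.05
        assert group_difference(values, groups, "median_test").p_value < 0.05

    def test_label_permutation_leaves_statistic_unchanged(self, rng):
        values = rng.normal(size=60)
        groups = np.array(["a", "b", "c"] * 20)
        perm = rng.permutation(60)
        a = group_difference(values, groups, "anova").statistic
        b = group_difference(values[perm], groups[perm], "anova").statistic
        assert a == pytest.approx(b)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference([1.0, 2.0, 3.0], ["a", "a", "a"], "anova")


class TestLinearRegression:
    def test_exact_fit_recovers_slope_and_unit_r2(self):
        x = np.arange(20.0)
        fit = fit_linear(2 * x, pd.DataFrame({"x": x}))
        assert fit.coef("x") == pytest.approx(2.0)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_parameter_recovery_with_negative_methylation_slope(self, rng):
        n = 800
        meth = rng.beta(2, 2, n)
        cna_term = rng.integers(-2, 3, n).astype(float)
        y = -0.6 * meth + 0.1 * cna_term + rng.normal(0, 0.3, n)
        fit = fit_linear(y, pd.DataFrame({"methylation": meth, "cna": cna_term}))
        # recovered within 3 SE of the planted truth, methylation sign negative
        se_meth = 0.3 / (np.std(meth) * np.sqrt(n))
        se_cna = 0.3 / (np.std(cna_term) * np.sqrt(n))
        assert abs(fit.coef("methylation") + 0.6) < 3 * se_meth
        assert abs(fit.coef("cna") - 0.1) < 3 * se_cna
        assert fit.coef("methylation") < 0

    def test_constant_column_dropped_and_reported(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.1, 50)
        fit_plain = fit_linear(y, pd.DataFrame({"x": x}))
        fit_const = fit_linear(y, pd.DataFrame({"x": x, "c": np.ones(50)}))
        assert "c" in fit_const.dropped_terms
        assert fit_const.coef("x") == pytest.approx(fit_plain.coef("x"))

    def test_collinear_column_dropped(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.1, 50)
        fit = fit_linear(y, pd.DataFrame({"x": x, "x2": 2 * x}))
        assert fit.dropped_terms == ["x2"]


class TestLogisticRegression:
    def test_null_predictors_have_small_coefficients(self, rng):
        y = rng.integers(0, 2, 400)
        X = pd.DataFrame({"x": rng.normal(size=400)})
        fit = fit_logistic(y, X)
        assert abs(fit.coef("x")) < 0.5
        assert not fit.separation_flag

    def test_planted_log_odds_recovered_within_three_se(self, rng):
        n = 800
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + 1.0 * x)))
        y = (rng.random(n) < p).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        # asymptotic SE for logistic slope at n=800 is about 0.1
        assert abs(fit.coef("x") - 1.0) < 0.35

    def test_label_flip_negates_coefficients(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        X = pd.DataFrame({"x": x})
        a = fit_logistic(y, X).coef("x")
        b = fit_logistic(1 - y, X).coef("x")
        assert a == pytest.approx(-b, abs=1e-6)

    def test_single_class_outcome_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(20), pd.DataFrame({"x": rng.normal(size=20)}))

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.full(15, -2.0), np.full(15, 2.0)]) + np.linspace(0, 0.1, 30)
        y = (x > 0).astype(int)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.separation_flag


def oracle_logrank(time, event, group_a_mask):
    """Textbook log-rank: sum over event times of observed-minus-expected in
    group A, variance from the hypergeometric at each risk set."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    a = np.asarray(group_a_mask, bool)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & a).sum()
        d = (event & (time == t)).sum()
        d_a = (event & (time == t) & a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        time = [5.0, 10, 15, 5, 10, 15]
        event = [1, 1, 0, 1, 1, 0]
        group = ["a", "a", "a", "b", "b", "b"]
        chi2, p, curves = km_logrank(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert set(curves) == {"a", "b"}

    def test_six_subject_worked_set_matches_hand_tabulated_oracle(self):
        time = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 1], dtype=bool)
        group = np.array(["a", "a", "a", "b", "b", "b"])
        chi2, p, _ = km_logrank(time, event, group)
        expected = oracle_logrank(time, event, group == "a")
        assert chi2 == pytest.approx(expected, rel=1e-9)

    def test_statistic_grows_with_planted_hazard_ratio(self):
        rng = np.random.default_rng(8)
        stats = []
        for hr in (1.0, 2.0, 4.0):
            t_a = rng.exponential(10.0, 120)
            t_b = rng.exponential(10.0 / hr, 120)
            time = np.concatenate([t_a, t_b])
            event = np.ones(240, bool)
            group = np.array(["a"] * 120 + ["b"] * 120)
            chi2, _, _ = km_logrank(time, event, group)
            stats.append(chi2)
        assert stats[0] < stats[1] < stats[2]

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [0, 0], ["a", "b"])


class TestCalibration:
    def test_type_one_error_within_band_over_null_simulations(self):
        # 500 null replicates per test at alpha = 0.05
        rng = np.random.default_rng(17)
        n_rep, alpha = 500, 0.05
        rejections = {"chi_square": 0, "anova": 0, "median_test": 0, "logrank": 0}
        for _ in range(n_rep):
            g = rng.integers(0, 2, 80)
            x = rng.normal(size=80)
            cat = rng.integers(0, 2, 80)
            table = pd.crosstab(pd.Series(cat), pd.Series(g)).to_numpy()
            if chi_square(table).p_value < alpha:
                rejections["chi_square"] += 1
            labels = np.where(g == 0, "a", "b")
            if group_difference(x, labels, "anova").p_value < alpha:
                rejections["anova"] += 1
            if group_difference(x, labels, "median_test").p_value < alpha:
                rejections["median_test"] += 1
            time = rng.exponential(10, 80)
            event = rng.random(80) < 0.7
            if event.any():
                _, p, _ = km_logrank(time, event, labels)
                if p < alpha:
                    rejections["logrank"] += 1
        for name, k in rejections.items():
            assert 0.03 <= k / n_rep <= 0.07, f"{name}: {k / n_rep}"


class TestAssociationBlock:
    def test_block_applies_bh_within_block(self):
        results = [
            chi_square([[30, 10], [10, 30]], predictor=f"v{i}", outcome="g")
            for i in range(3)
        ]
        frame = association_block(results)
        np.testing.assert_allclose(frame["fdr"], bh_adjust(frame["p_value"]))
        assert len(frame) == 3
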