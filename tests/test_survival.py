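"""Youden cutpoint scan, adjusted Cox fits, Kaplan-Meier / log-rank."""

import numpy as np
import pandas as pd
import pytest
from _oracles import manual_logrank
from scipy import stats

from layerquant import (
    ConfigurationError,
    fit_adjusted_ph,
    km_logrank,
    make_survival_table,
    scan_cutoffs,
    youden_index,
)


def null_covariates(n, rng):
    return {
        "age": rng.normal(58, 8, n),
        "sex": rng.integers(0, 2, n),
        "smoking": rng.integers(0, 2, n),
        "alcohol": rng.integers(0, 2, n),
    }


class TestYoudenIndex:
    def test_perfect_classifier(self):
        outcome = np.array([1, 1, 0, 0, 1])
        assert youden_index(outcome.astype(bool), outcome).j == pytest.approx(1.0)

    def test_constant_classifier_is_uninformative(self):
        outcome = np.array([1, 0, 1, 0])
        assert youden_index(np.ones(4, bool), outcome).j == pytest.approx(0.0)
        assert youden_index(np.zeros(4, bool), outcome).j == pytest.approx(0.0)

    def test_two_by_two_table_arithmetic(self):
        # TP=30, FN=10, FP=20, TN=40 -> J = 30/40 + 40/60 - 1
        high = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)].astype(bool)
        outcome = np.r_[np.ones(40), np.zeros(60)].astype(bool)
        res = youden_index(high, outcome)
        assert (res.tp, res.fn, res.fp, res.tn) == (30, 10, 20, 40)
        assert res.j == pytest.approx(30 / 40 + 40 / 60 - 1)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ConfigurationError):
            youden_index(np.array([True, False]), np.array([1, 1]))


class TestAdjustedPHFit:
    def test_null_simulation_coefficient_near_zero(self):
        df = make_survival_table(n=500, hazard_ratio=1.0, seed=21)
        fit = fit_adjusted_ph(df, (df["expression"] > 25).to_numpy())
        assert fit.converged and fit.ties == "efron"
        assert abs(fit.coef) <= 3 * fit.se

    def test_planted_log_hazard_ratio_recovered(self):
        df = make_survival_table(n=500, hazard_ratio=4.0, seed=22)
        fit = fit_adjusted_ph(df, (df["expression"] > 25).to_numpy())
        assert abs(fit.coef - np.log(4.0)) <= 3 * fit.se

    def test_matches_closed_form_exponential_rate_ratio(self):
        # no censoring, no covariate effects: Cox log-HR ~ log rate-ratio MLE
        rng = np.random.default_rng(23)
        n = 300
        group = np.r_[np.zeros(n), np.ones(n)].astype(int)
        times = np.r_[rng.exponential(1.0, n), rng.exponential(1.0 / 3.0, n)]
        df = pd.DataFrame({"time": times, "event": 1, **null_covariates(2 * n, rng)})
        fit = fit_adjusted_ph(df, group)
        rate_ratio = (n / times[n:].sum()) / (n / times[:n].sum())
        assert fit.coef == pytest.approx(np.log(rate_ratio), rel=0.05)

    def test_group_without_events_rejected(self):
        df = make_survival_table(n=50, seed=1)
        df.loc[df["expression"] > 25, "event"] = 0
        with pytest.raises(ConfigurationError):
            fit_adjusted_ph(df, (df["expression"] > 25).to_numpy())


class TestScanCutoffs:
    def test_planted_cutoff_recovered_in_containing_gap(self):
        for seed in range(5):
            df = make_survival_table(n=400, true_cutoff=25.0, hazard_ratio=6.0, seed=seed)
            scan = scan_cutoffs(df)
            assert 24.0 < scan.selected_cutoff < 26.0
            assert scan.fit.converged

    def test_scan_table_satisfies_youden_identity(self):
        df = make_survival_table(n=100, seed=30)
        scan = scan_cutoffs(df)
        np.testing.assert_allclose(
            scan.table["j"], scan.table["sensitivity"] + scan.table["specificity"] - 1
        )
        assert scan.j_max == scan.table["j"].max()

    def test_scaling_expression_scales_the_selected_cutoff(self):
        df = make_survival_table(n=150, seed=31)
        doubled = df.assign(expression=2 * df["expression"])
        assert scan_cutoffs(doubled).selected_cutoff == pytest.approx(
            2 * scan_cutoffs(df).selected_cutoff
        )

    def test_constant_expression_has_no_admissible_cutoff(self):
        df = make_survival_table(n=50, seed=32).assign(expression=25.0)
        with pytest.raises(ConfigurationError):
            scan_cutoffs(df)

    def test_min_group_fraction_excludes_extreme_cutoffs(self):
        df = make_survival_table(n=200, seed=33)
        scan = scan_cutoffs(df, min_group_frac=0.3)
        assert (scan.table[["n_high", "n_low"]] >= 60).all().all()

    def test_fit_all_flags_every_admissible_row(self):
        df = make_survival_table(n=100, seed=34)
        scan = scan_cutoffs(df, fit_all=True)
        assert {"coef", "se", "p", "converged"} <= set(scan.table.columns)

    def test_null_selection_is_anticonservative_and_documented(self):
        # Maximizing J over cutoffs then reading the naive p at the optimum
        # inflates the type-I error above the nominal 5%; this property of
        # max-selection is asserted, not hidden.
        hits = 0
        n_rep = 300
        for seed in range(n_rep):
            df = make_survival_table(n=200, hazard_ratio=1.0, seed=7000 + seed)
            scan = scan_cutoffs(df)
            if scan.fit.converged and scan.fit.p <= 0.05:
                hits += 1
        assert hits / n_rep > 0.05


class TestKMLogrank:
    def test_identical_groups_give_null_statistic(self):
        df = make_survival_table(n=100, seed=40)
        both = pd.concat([df, df], ignore_index=True)
        group = np.r_[np.zeros(len(df)), np.ones(len(df))]
        res = km_logrank(both, group)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_computed_logrank_on_small_set(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "event": [1, 1, 1, 1, 1, 1]}
        )
        group = np.array([1, 0, 1, 0, 1, 0])
        res = km_logrank(df, group)
        expected = manual_logrank(df["time"], df["event"], group)
        assert res.statistic == pytest.approx(expected)
        assert res.p == pytest.approx(stats.chi2.sf(expected, 1))

    def test_km_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(41)
        times = rng.exponential(1.0, 40)
        df = pd.DataFrame({"time": np.r_[times, times + 100], "event": 1})
        group = np.r_[np.zeros(40), np.ones(40)]
        curve = km_logrank(df, group).curves["low"]
        for t, s in zip(curve["time"][1:], curve["survival"][1:]):
            assert s == pytest.approx((times > t).mean())

    def test_km_curves_are_nonincreasing_from_one(self):
        df = make_survival_table(n=150, seed=42)
        res = km_logrank(df, (df["expression"] > 25).to_numpy())
        for curve in res.curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)

    def test_empty_group_rejected(self):
        df = make_survival_table(n=50, seed=43)
        with pytest.raises(ConfigurationError):
            km_logrank(df, np.zeros(len(df)))
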