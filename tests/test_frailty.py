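"""Dichotomization, Fried index, odds ratios, logistic models, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthomorph.frailty import (AnalysisConfig, compare_groups,
                                dichotomize_cohort, fit_logistic,
                                met_expenditure, odds_ratio_2x2,
                                sex_stratified_quantile_cut)


class TestMet:
    @pytest.mark.parametrize(
        "args,expected",
        [((30, 7, 0, 0, 0, 0), 693.0),
         ((0, 0, 0, 0, 0, 0), 0.0),
         ((10, 2, 20, 3, 5, 1), 346.0)],
    )
    def test_formula(self, args, expected):
        assert met_expenditure(*args) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            met_expenditure(-1, 1, 0, 0, 0, 0)

    def test_more_than_seven_days_rejected(self):
        with pytest.raises(ValueError):
            met_expenditure(10, 8, 0, 0, 0, 0)


class TestQuantileCut:
    def test_bottom_fifth_flagged(self):
        values = np.arange(1.0, 11.0)
        cutoffs, flags = sex_stratified_quantile_cut(values, ["F"] * 10, "lowest")
        assert list(flags) == [True, True] + [False] * 8
        assert cutoffs["F"] == pytest.approx(np.quantile(values, 0.2))

    def test_all_equal_degenerate_flags_everyone(self):
        _, flags = sex_stratified_quantile_cut([5.0] * 8, ["M"] * 8, "lowest")
        assert all(flags)

    def test_matches_per_stratum_oracle(self, rng):
        values = rng.normal(size=60)
        sexes = rng.choice(["F", "M"], size=60)
        cutoffs, flags = sex_stratified_quantile_cut(values, sexes, "highest", 0.2)
        for sex in ("F", "M"):
            stratum = values[sexes == sex]
            cut = np.quantile(stratum, 0.8)
            expected = stratum >= cut
            got = np.array([f for f, s in zip(flags, sexes) if s == sex])
            np.testing.assert_array_equal(got.astype(bool), expected)

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            sex_stratified_quantile_cut([1, 2, 3], ["F", "F", "F"], "lowest")


def _raw_cohort(n=40, rng=None):
    r = np.random.default_rng(rng)
    return pd.DataFrame({
        "sex": r.choice(["F", "M"], n),
        "weight_loss": r.random(n) < 0.1,
        "walk_min": r.uniform(0, 60, n),
        "walk_days": r.integers(0, 8, n).astype(float),
        "mod_min": r.uniform(0, 60, n),
        "mod_days": r.integers(0, 8, n).astype(float),
        "vig_min": r.uniform(0, 30, n),
        "vig_days": r.integers(0, 8, n).astype(float),
        "sit_hours": r.uniform(2, 12, n),
        "tug_s": r.uniform(6, 20, n),
        "hgs_kg": r.uniform(10, 40, n),
        "exhaustion": r.random(n) < 0.1,
        "adl": r.integers(3, 8, n).astype(float),
        "moca": r.integers(10, 31, n).astype(float),
        "gait_speed": r.uniform(0.3, 1.5, n),
        "fr_cm": r.uniform(8, 40, n),
        "fall": r.random(n) < 0.2,
    })


class TestDichotomize:
    def test_clinical_thresholds(self):
        df = _raw_cohort(rng=0)
        df.loc[0, ["tug_s", "moca", "gait_speed", "fr_cm", "adl"]] = \
            [14.0, 26.0, 0.6, 15.0, 5.0]
        ind = dichotomize_cohort(df)
        assert ind.loc[0, "slow_tug"] == True          # > 13.5 s
        assert ind.loc[0, "cognition_impaired"] == False  # strict < 26
        assert ind.loc[0, "slow_gait"] == True         # <= 0.6 m/s
        assert ind.loc[0, "balance_impaired"] == False  # strict < 15 cm
        assert ind.loc[0, "adl_compromised"] == True   # <= 5

    def test_fried_composition_and_bounds(self):
        df = _raw_cohort(rng=1)
        ind = dichotomize_cohort(df)
        activity = ind["low_activity"] | ind["sedentary"]
        expected = (ind["weight_loss"].astype(int) + activity.astype(int)
                    + ind["slow_tug"].astype(int) + ind["weak_grip"].astype(int)
                    + ind["exhaustion"].astype(int))
        assert (ind["fried_count"] == expected).all()
        assert ind["fried_count"].between(0, 5).all()
        assert (ind["fried_positive"] == (ind["fried_count"] >= 2)).all()

    def test_fried_monotone_in_indicators(self):
        df = _raw_cohort(rng=2)
        base = dichotomize_cohort(df)
        df2 = df.copy()
        df2["weight_loss"] = True
        bumped = dichotomize_cohort(df2)
        assert (bumped["fried_count"] >= base["fried_count"]).all()

    def test_missing_value_propagates(self):
        df = _raw_cohort(rng=3)
        df.loc[2, "tug_s"] = np.nan
        ind = dichotomize_cohort(df)
        assert pd.isna(ind.loc[2, "slow_tug"])
        assert pd.isna(ind.loc[2, "fried_count"]) or isinstance(
            ind.loc[2, "fried_count"], (int, np.integer))


class TestOddsRatio2x2:
    def test_equal_proportions_is_one(self):
        res = odds_ratio_2x2(10, 20, 10, 20)
        assert res.or_hat == pytest.approx(1.0)

    def test_reciprocal_under_group_swap(self):
        a = odds_ratio_2x2(42, 209, 70, 254)
        b = odds_ratio_2x2(70, 254, 42, 209)
        assert a.or_hat == pytest.approx(1.0 / b.or_hat)
        assert a.ci_low == pytest.approx(1.0 / b.ci_high)

    def test_invariant_to_double_label_swap(self):
        # swap case/non-case AND exposed/reference simultaneously
        a = odds_ratio_2x2(42, 209, 70, 254)
        b = odds_ratio_2x2(254 - 70, 254, 209 - 42, 209)
        assert a.or_hat == pytest.approx(b.or_hat)

    def test_zero_cell_errors_without_continuity(self):
        with pytest.raises(ValueError, match="zero cell"):
            odds_ratio_2x2(0, 20, 5, 20)
        res = odds_ratio_2x2(0, 20, 5, 20, continuity=True)
        assert res.or_hat < 1.0

    def test_ci_brackets_estimate(self):
        res = odds_ratio_2x2(49, 213, 33, 254)
        assert res.ci_low <= res.or_hat <= res.ci_high


class TestLogistic:
    def test_single_binary_predictor_equals_2x2(self):
        a, n1, c, n0 = 42, 209, 70, 254
        y = np.concatenate([np.ones(a), np.zeros(n1 - a),
                            np.ones(c), np.zeros(n0 - c)])
        x = np.concatenate([np.ones(n1), np.zeros(n0)])
        design = pd.DataFrame({"cluster": x})
        res = fit_logistic(y, design, "cluster")
        exact = odds_ratio_2x2(a, n1, c, n0)
        assert res.or_hat == pytest.approx(exact.or_hat, rel=1e-6)
        assert res.ci_low == pytest.approx(exact.ci_low, rel=1e-6)
        assert res.ci_high == pytest.approx(exact.ci_high, rel=1e-6)
        assert res.wald_p == pytest.approx(exact.wald_p, rel=1e-6)

    def test_beats_coarse_grid_search(self, rng):
        n = 30
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        design = pd.DataFrame({"x": x})
        res = fit_logistic(y, design, "x")

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        grid_best = max(loglik(b0, b1)
                        for b0 in np.linspace(-3, 3, 41)
                        for b1 in np.linspace(-3, 3, 41))
        # optimizing the intercept at the fitted slope recovers the joint MLE
        mle = loglik(_intercept(y, x, res), np.log(res.or_hat))
        assert grid_best <= mle + 1e-9

    def test_separation_raises_named_error(self):
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        with pytest.raises(RuntimeError, match="cluster"):
            fit_logistic(y, pd.DataFrame({"cluster": x}), "cluster")

    def test_ci_coverage_near_nominal(self, rng):
        # true OR = 2.0; coverage of the 95% Wald interval over replicates
        true_beta = np.log(2.0)
        n, reps, covered = 2000, 60, 0
        for _ in range(reps):
            x = rng.integers(0, 2, size=n).astype(float)
            p = 1 / (1 + np.exp(-(-0.5 + true_beta * x)))
            y = (rng.random(n) < p).astype(float)
            res = fit_logistic(y, pd.DataFrame({"x": x}), "x")
            covered += res.ci_low <= 2.0 <= res.ci_high
        assert covered / reps > 0.85


def _intercept(y, x, res):
    # recover the fitted intercept by a 1-d refit given the slope (profile);
    # cheap Newton on the intercept only
    b1 = np.log(res.or_hat)
    b0 = 0.0
    for _ in range(50):
        eta = b0 + b1 * x
        mu = 1 / (1 + np.exp(-eta))
        g = np.sum(y - mu)
        h = -np.sum(mu * (1 - mu))
        b0 -= g / h
    return b0


class TestCompareGroups:
    def test_identical_groups_p_near_one(self, rng):
        vals = rng.normal(size=60)
        df = pd.DataFrame({
            "g": np.repeat(["A", "B", "C"], 60),
            "x": np.tile(vals, 3),
            "b": np.tile(rng.random(60) < 0.5, 3),
        })
        rep = compare_groups(df, "g", categorical=["b"], continuous=["x"])
        assert (rep["p"] > 0.95).all()

    def test_chi2_matches_textbook_computation(self):
        # 2x3 count table checked against the direct sum over cells
        counts = np.array([[10, 20, 30], [20, 20, 20]], dtype=float)
        expected = counts.sum(axis=1, keepdims=True) * counts.sum(axis=0) / counts.sum()
        chi2_manual = (((counts - expected) ** 2) / expected).sum()
        stat, _, _, _ = stats.chi2_contingency(counts, correction=False)
        assert stat == pytest.approx(chi2_manual)
        rows = []
        for j, n in enumerate(counts.T):
            rows += [{"g": f"G{j}", "b": True}] * int(n[0])
            rows += [{"g": f"G{j}", "b": False}] * int(n[1])
        rep = compare_groups(pd.DataFrame(rows), "g", categorical=["b"])
        assert rep.loc[0, "test"] == "chi2"
        assert rep.loc[0, "statistic"] == pytest.approx(chi2_manual)

    def test_bonferroni_flag_implies_nominal_significance(self, rng):
        df = pd.DataFrame({
            "g": np.repeat(["A", "B"], 50),
            "x": np.concatenate([rng.normal(0, 1, 50), rng.normal(1.5, 1, 50)]),
        })
        rep = compare_groups(df, "g", continuous=["x"], alpha=0.017)
        for pw in rep.loc[0, "pairwise"]:
            if pw["significant"]:
                assert pw["p"] < 0.05

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"g": ["A", "A"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_groups(df, "g", continuous=["x"])
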