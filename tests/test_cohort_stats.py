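"""Statistical pipeline: normality screen, group tests, screen, stepwise, ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbooi.cohort_stats import (
    compare_groups,
    compare_predictors,
    normality_screen,
    roc_auc,
    stepwise_forward_logistic,
    univariate_screen,
)
from mbooi.errors import AnalysisError, SeparationError


class TestNormalityScreen:
    def test_normal_and_exponential_samples(self, rng):
        assert normality_screen(rng.normal(size=5000)).normal
        assert not normality_screen(rng.exponential(size=5000)).normal

    def test_statistic_matches_hand_rolled_ks(self, rng):
        """Oracle: D = max(D+, D-) against the fitted normal CDF."""
        x = np.sort(rng.uniform(0, 1, 10))
        res = normality_screen(x)
        cdf = stats.norm.cdf(x, loc=x.mean(), scale=x.std(ddof=1))
        n = x.size
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        assert res.statistic == pytest.approx(max(d_plus, d_minus), abs=1e-12)

    def test_constant_sample_degenerate(self):
        res = normality_screen([3.0] * 20)
        assert not res.normal and res.degenerate

    def test_small_sample_rejected(self):
        with pytest.raises(AnalysisError):
            normality_screen([1, 2, 3])

    def test_lilliefors_variant_runs(self, rng):
        res = normality_screen(rng.normal(size=200), lilliefors=True)
        assert res.method == "lilliefors"
        assert 0 <= res.p_value <= 1


def permutation_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in group_a for y in group_b
        )

    observed = u_stat(a, b)
    mean_u = na * len(b) / 2.0
    dev = abs(observed - mean_u)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mean_u) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestCompareGroups:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(a, a, normal=False)
        assert res.p_value > 0.95

    def test_extreme_separation_matches_enumeration(self):
        a, b = (1, 2, 3), (4, 5, 6)
        res = compare_groups(a, b, normal=False)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(permutation_mw_p(a, b))
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("na, nb, seed", [(4, 5, 0), (6, 7, 1), (5, 5, 2), (7, 6, 3)])
    def test_small_sample_p_matches_enumeration(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=na), rng.normal(0.8, size=nb)
        res = compare_groups(a, b, normal=False)
        assert res.p_value == pytest.approx(permutation_mw_p(a, b), abs=1e-10)

    def test_t_test_detects_shift(self, rng):
        res = compare_groups(rng.normal(0, 1, 500), rng.normal(0.5, 1, 500), normal=True)
        assert res.test_used == "t_test"
        assert res.p_value < 1e-3

    def test_tiny_group_rejected(self):
        with pytest.raises(AnalysisError):
            compare_groups([1.0], [2.0, 3.0], normal=True)


class TestUnivariateScreen:
    def test_perfect_predictor(self, rng):
        y = rng.integers(1, 5, 200).astype(float)
        df = pd.DataFrame({"x": y, "overall_grade": y})
        row = univariate_screen(df, ["x"]).iloc[0]
        assert row["slope"] == pytest.approx(1.0)
        assert row["p_value"] < 1e-10 and row["selected"]

    def test_two_point_predictor_closed_form(self, rng):
        x = np.repeat([0.0, 1.0], 50)
        y = np.concatenate([rng.normal(2, 1, 50), rng.normal(3, 1, 50)])
        df = pd.DataFrame({"x": x, "overall_grade": y})
        slope = univariate_screen(df, ["x"]).iloc[0]["slope"]
        assert slope == pytest.approx(y[50:].mean() - y[:50].mean())

    def test_zero_variance_excluded_with_reason(self):
        df = pd.DataFrame({"x": [1.0] * 30, "overall_grade": np.arange(30) % 4 + 1})
        row = univariate_screen(df, ["x"]).iloc[0]
        assert not row["selected"] and "zero-variance" in row["reason"]


def closed_form_2x2(a, b, c, d):
    """OR and Wald CI of a 2x2 exposure/outcome table."""
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)


class TestStepwiseLogistic:
    def _table_cohort(self, a=30, b=10, c=10, d=30):
        # exposure=1: a events, b non-events; exposure=0: c events, d non-events
        x = [1] * (a + b) + [0] * (c + d)
        y = [1] * a + [0] * b + [1] * c + [0] * d
        return pd.DataFrame({"x": x, "effective": y})

    def test_two_by_two_matches_closed_form(self):
        model = stepwise_forward_logistic(self._table_cohort(), ["x"])
        row = model.table.iloc[0]
        or_, lo, hi = closed_form_2x2(30, 10, 10, 30)
        assert row["odds_ratio"] == pytest.approx(or_, abs=1e-6)
        assert or_ == 9.0
        assert row["ci_low"] == pytest.approx(lo, rel=1e-4)
        assert row["ci_high"] == pytest.approx(hi, rel=1e-4)

    def test_uncorrelated_candidate_not_selected(self):
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(size=n)
        signal = rng.normal(size=n)
        y = (signal + 0.5 * rng.normal(size=n) > 0).astype(int)
        df = pd.DataFrame({"noise": x, "signal": signal, "effective": y})
        model = stepwise_forward_logistic(df, ["noise", "signal"])
        assert model.selection_order == ["signal"]

    def test_selection_invariant_to_candidate_order(self, rng):
        n = 500
        df = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.normal(size=n),
            }
        )
        logit = 1.2 * df["a"] - 0.8 * df["b"] + 0.3 * df["c"]
        df["effective"] = (logit + rng.logistic(size=n) > 0).astype(int)
        orders = [["a", "b", "c"], ["c", "b", "a"], ["b", "a", "c"]]
        selections = {tuple(stepwise_forward_logistic(df, o).selection_order) for o in orders}
        assert len(selections) == 1

    def test_collinear_candidate_skipped(self, rng):
        n = 300
        a = rng.normal(size=n)
        df = pd.DataFrame({"a": a, "twice_a": 2 * a})
        df["effective"] = (a + rng.logistic(size=n) > 0).astype(int)
        model = stepwise_forward_logistic(df, ["a", "twice_a"])
        assert model.selection_order == ["a"]
        assert "twice_a" in model.skipped

    def test_perfect_separation_detected(self):
        x = np.concatenate([np.arange(20), np.arange(30, 50)])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        df = pd.DataFrame({"x": x, "effective": y})
        with pytest.raises(SeparationError):
            stepwise_forward_logistic(df, ["x"])

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "effective": [0, 1, 2]})
        with pytest.raises(AnalysisError):
            stepwise_forward_logistic(df, ["x"])


def pair_counting_auc(scores, labels):
    """Brute-force AUC: fraction of positive/negative pairs ordered correctly."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_known_small_examples(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]).auc == 0.75
        assert roc_auc([10, 1, 1, 1], [1, 0, 0, 0]).auc == 1.0

    def test_null_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        res = roc_auc(rng.normal(size=2000), y)
        assert 0.47 <= res.auc <= 0.53

    def test_delong_ci_matches_proc_reference(self):
        # frozen values computed with R pROC ci.auc(method="delong")
        labels = [0] * 10 + [1] * 8
        scores = [2.1, 3.4, 1.2, 5.6, 2.8, 4.4, 3.3, 2.2, 6.1,
                  3.9, 5.9, 4.8, 6.3, 3.1, 7.2, 5.5, 4.9, 6.8]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(0.8375)
        assert res.ci_low == pytest.approx(0.6429184, abs=1e-6)
        assert res.ci_high == 1.0

    def test_delong_ci_with_ties_matches_proc_reference(self):
        res = roc_auc([1, 2, 2, 3, 4, 5, 2, 4, 4, 5, 6, 6],
                      [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        assert res.auc == pytest.approx(0.7916667, abs=1e-6)
        assert res.ci_low == pytest.approx(0.5266216, abs=1e-6)

    def test_ci_brackets_auc(self, rng):
        res = roc_auc(rng.normal(size=100) + np.repeat([0, 1], 50), np.repeat([0, 1], 50))
        assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1

    def test_one_class_rejected(self):
        with pytest.raises(AnalysisError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_bootstrap_ci_close_to_delong(self, rng):
        s = np.concatenate([rng.normal(0, 1, 150), rng.normal(1, 1, 150)])
        y = np.repeat([0, 1], 150)
        d = roc_auc(s, y, ci_method="delong")
        b = roc_auc(s, y, ci_method="bootstrap", n_boot=500, seed=7)
        assert b.ci_low == pytest.approx(d.ci_low, abs=0.05)
        assert b.ci_high == pytest.approx(d.ci_high, abs=0.05)


class TestComparePredictors:
    def test_identical_predictors_identical_auc(self, rng):
        grades = rng.integers(1, 5, 300)
        df = pd.DataFrame(
            {"p1": rng.normal(size=300), "overall_grade": grades}
        )
        df["p2"] = df["p1"]
        out = compare_predictors(df, predictors=("p1", "p2"), axes={"overall": "overall_grade"})
        assert out["auc"].nunique() == 1

    def test_driving_predictor_ranks_first(self, rng):
        n = 2000
        tzv = rng.normal(25, 19, n)
        other = rng.normal(87, 40, n)
        grade = np.where(tzv + 8 * rng.normal(size=n) > 25, 3, 2)
        df = pd.DataFrame({"tzv": tzv, "mbooi": other, "overall_grade": grade})
        out = compare_predictors(df, predictors=("mbooi", "tzv"), axes={"overall": "overall_grade"})
        assert out.iloc[0]["predictor"] == "tzv"
        assert out.iloc[0]["rank"] == 1
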