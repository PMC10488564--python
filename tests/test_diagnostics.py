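"""Cutoffs, odds ratios, logistic models, ROC and rank tests vs oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iodect import (
    TwoByTwoTable,
    ValidationError,
    binarize_feature,
    binary_performance,
    crosstab,
    odds_ratio_wald,
    rank_tests,
    roc_auc_continuous,
    stepwise_logistic,
    univariate_logistic,
    youden_cutoff,
)
from iodect.diagnostics import Direction

from conftest import table_to_arrays


def youden_oracle(values, outcome):
    """Exhaustive search over all cutoffs and both directions; returns max J."""
    values = list(map(float, values))
    best_j = -2.0
    best_dir = None
    for c in sorted(set(values)):
        for gt in (True, False):
            scores = [(v > c) if gt else (v <= c) for v in values]
            sens = sum(s for s, y in zip(scores, outcome) if y == 1) / sum(outcome)
            spec = sum(not s for s, y in zip(scores, outcome) if y == 0) / (
                len(outcome) - sum(outcome)
            )
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_dir = j, gt
    return best_j, best_dir


class TestYoudenCutoff:
    def test_perfect_separation(self):
        values = [10, 11, 1, 2]
        outcome = [1, 1, 0, 0]
        res = youden_cutoff(values, outcome)
        assert res.direction is Direction.GREATER_THAN
        assert res.youden_j == pytest.approx(1.0)
        assert res.cutoff == 2.0  # tie-rule: the smallest-|c| perfect rule
        assert res.youden_j == pytest.approx(
            res.sens_at_cutoff + res.spec_at_cutoff - 1.0
        )

    def test_constant_values_give_zero_j(self):
        res = youden_cutoff([3.0] * 6, [1, 1, 1, 0, 0, 0])
        assert res.youden_j == pytest.approx(0.0)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValidationError):
            youden_cutoff([1, 2, 3], [1, 1, 1])

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(314)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            values = np.round(rng.normal(size=n), 2)
            outcome = rng.integers(0, 2, size=n)
            if outcome.min() == outcome.max():
                outcome[0] = 1 - outcome[0]
            res = youden_cutoff(values, outcome)
            j_star, _ = youden_oracle(values, outcome)
            assert res.youden_j == pytest.approx(j_star, abs=1e-12)


class TestBinarization:
    def test_greater_than_rule(self):
        from iodect.diagnostics import CutoffResult

        rule = CutoffResult("ecv", 21.47, Direction.GREATER_THAN, 1, 1, 1)
        assert binarize_feature([27.0, 15.0], rule).tolist() == [1, 0]

    def test_less_or_equal_rule_is_boundary_inclusive(self):
        from iodect.diagnostics import CutoffResult

        rule = CutoffResult("iodine_effect", 1.31, Direction.LESS_OR_EQUAL, 1, 1, 1)
        assert binarize_feature([1.31, 1.32], rule).tolist() == [1, 0]

    def test_all_below_greater_than_cutoff_scores_zero(self):
        from iodect.diagnostics import CutoffResult

        rule = CutoffResult("x", 5.0, Direction.GREATER_THAN, 0, 0, 0)
        assert binarize_feature([1.0, 2.0, 4.9], rule).sum() == 0


class TestCrosstab:
    def test_reconstructed_ecv_counts(self):
        scores, outcome = table_to_arrays(TwoByTwoTable(5, 11, 1, 25))
        tab = crosstab(scores, outcome)
        assert (tab.a, tab.b, tab.c, tab.d) == (5, 11, 1, 25)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        scores, outcome = table_to_arrays(TwoByTwoTable(3, 4, 5, 6))
        perm = rng.permutation(len(scores))
        assert crosstab(scores[perm], outcome[perm]) == crosstab(scores, outcome)

    def test_empty_score1_stratum(self):
        tab = crosstab([0, 0, 0], [1, 0, 1])
        assert tab.a == tab.b == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            crosstab([1, 0], [1, 0, 1])


class TestOddsRatioWald:
    def test_null_table_has_unit_or(self):
        for k in (1, 3, 10):
            res = odds_ratio_wald(TwoByTwoTable(k, k, k, k))
            assert res.or_value == pytest.approx(1.0)
            assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_flagged_not_estimated(self):
        res = odds_ratio_wald(TwoByTwoTable(6, 28, 0, 8))
        assert res.separation_flag and res.or_value is None

    def test_haldane_correction_is_opt_in(self):
        res = odds_ratio_wald(TwoByTwoTable(6, 28, 0, 8), zero_cell_correction=True)
        assert res.separation_flag and res.corrected
        assert res.or_value == pytest.approx((6.5 * 8.5) / (28.5 * 0.5))

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_label_swap_inverts_or(self, a, b, c, d):
        res = odds_ratio_wald(TwoByTwoTable(a, b, c, d))
        # swapping the outcome labels swaps (a<->b, c<->d)
        swapped = odds_ratio_wald(TwoByTwoTable(b, a, d, c))
        assert swapped.or_value == pytest.approx(1.0 / res.or_value, rel=1e-12)
        assert swapped.p_value == pytest.approx(res.p_value, rel=1e-9)


class TestUnivariateLogistic:
    @pytest.mark.parametrize(
        "table",
        [TwoByTwoTable(5, 11, 1, 25), TwoByTwoTable(14, 10, 2, 10),
         TwoByTwoTable(4, 14, 2, 22)],
    )
    def test_mle_or_equals_cross_product(self, table):
        scores, outcome = table_to_arrays(table)
        fit = univariate_logistic(scores, outcome)
        wald = odds_ratio_wald(table)
        est = fit.estimates["score"]
        assert est.or_value == pytest.approx(table.cross_product_or, rel=1e-6)
        assert est.ci_low == pytest.approx(wald.ci_low, rel=1e-5)
        assert est.ci_high == pytest.approx(wald.ci_high, rel=1e-5)
        assert est.p_value == pytest.approx(wald.p_value, rel=1e-5)

    def test_zero_cell_raises_separation_flag(self):
        scores, outcome = table_to_arrays(TwoByTwoTable(6, 28, 0, 8))
        fit = univariate_logistic(scores, outcome)
        assert fit.separation_flags["score"] and not fit.converged

    def test_perfect_predictor_is_separated(self):
        y = np.array([0, 0, 1, 1, 1, 0])
        fit = univariate_logistic(y, y)
        assert fit.separation_flags["score"]

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            univariate_logistic([1, 1, 1, 1], [0, 1, 0, 1])


class TestStepwise:
    def test_single_candidate_reduces_to_univariate(self):
        scores, outcome = table_to_arrays(TwoByTwoTable(5, 11, 1, 25))
        uni = univariate_logistic(scores, outcome)
        step = stepwise_logistic({"ecv": scores}, outcome)
        assert step.included_predictors == ["ecv"]
        assert step.estimates["ecv"].or_value == pytest.approx(
            uni.estimates["score"].or_value, rel=1e-9
        )
        assert step.selection_trace[0]["action"] == "enter"

    def test_duplicate_candidate_enters_once(self):
        scores, outcome = table_to_arrays(TwoByTwoTable(12, 4, 3, 13))
        step = stepwise_logistic({"a": scores, "b": scores.copy()}, outcome)
        assert step.included_predictors == ["a"]  # lexicographic tie-break

    def test_nonsignificant_candidate_yields_empty_model(self):
        scores, outcome = table_to_arrays(TwoByTwoTable(5, 5, 5, 5))
        step = stepwise_logistic({"noise": scores}, outcome)
        assert step.included_predictors == []
        assert step.estimates == {}


class TestParameterRecovery:
    def test_ecv_selected_on_phantom_cohorts(self):
        """With the built-in class effect on ECV, the stepwise pipeline keeps
        ECV in at least 9 of 10 seeded 200-case-per-class replicates."""
        import dataclasses

        from iodect import Contrast, PhantomConfig, TumorGroup, analyze_cohort
        from iodect import generate_cohort

        hits = 0
        for rep in range(10):
            cfg = dataclasses.replace(
                PhantomConfig(seed=1000 + rep),
                cases_per_class={g: 200 for g in TumorGroup},
            )
            _, table = generate_cohort(cfg)
            report = analyze_cohort(table, Contrast.CARCINOMA_VS_THYMOMA)
            if "ecv" in report["stepwise"]["included"]:
                hits += 1
        assert hits >= 9


class TestPerformance:
    @pytest.mark.parametrize(
        "table, sens, spec, auc",
        [
            (TwoByTwoTable(5, 11, 1, 25), 5 / 6, 25 / 36, 0.7639),
            (TwoByTwoTable(14, 10, 2, 10), 14 / 16, 0.5, 0.6875),
        ],
    )
    def test_published_operating_points(self, table, sens, spec, auc):
        perf = binary_performance(table)
        assert perf.sensitivity == pytest.approx(sens, abs=1e-12)
        assert perf.specificity == pytest.approx(spec, abs=1e-12)
        assert perf.auc == pytest.approx(auc, abs=1e-4)
        assert perf.auc == pytest.approx((perf.sensitivity + perf.specificity) / 2)

    def test_perfect_table(self):
        perf = binary_performance(TwoByTwoTable(6, 0, 0, 36))
        assert perf.sensitivity == perf.specificity == perf.auc == 1.0

    def test_empty_outcome_arm_rejected(self):
        with pytest.raises(ValidationError):
            binary_performance(TwoByTwoTable(2, 0, 3, 0))


class TestContinuousAuc:
    def test_perfect_separation_and_all_ties(self):
        assert roc_auc_continuous([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0
        assert roc_auc_continuous([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = 30
            x = np.round(rng.normal(size=n), 1)  # rounding forces ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            pos = x[y == 1]
            neg = x[y == 0]
            pairs = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos for q in neg
            )
            oracle = pairs / (pos.size * neg.size)
            assert roc_auc_continuous(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_label_swap_reflects_auc(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = rng.integers(0, 2, size=25)
        y[0], y[1] = 0, 1
        assert roc_auc_continuous(x, 1 - y) == pytest.approx(
            1.0 - roc_auc_continuous(x, y), abs=1e-12
        )

    def test_binarized_auc_equals_two_point_performance(self):
        scores, outcome = table_to_arrays(TwoByTwoTable(5, 11, 1, 25))
        perf = binary_performance(crosstab(scores, outcome))
        assert roc_auc_continuous(scores, outcome) == pytest.approx(perf.auc, abs=1e-12)


class TestRankTests:
    def test_kruskal_wallis_hand_computed_h(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: H = 12/(N(N+1)) sum n_i(Rbar_i - Rbar)^2 = 7.2."""
        res = rank_tests([[1, 2, 3], [4, 5, 6], [7, 8, 9]], "kruskal_wallis")
        assert res.statistic == pytest.approx(7.2, abs=1e-9)

    def test_identical_groups_have_exact_p_one(self):
        res = rank_tests([[1, 2, 3], [1, 2, 3]], "mann_whitney_u")
        assert res.p_value == pytest.approx(1.0)

    def test_small_sample_exact_p_matches_enumeration(self):
        x = [1.0, 4.0, 6.0]
        y = [2.0, 3.0, 5.0]
        res = rank_tests([x, y], "mann_whitney_u")
        # oracle: enumerate all C(6,3) = 20 rank assignments directly
        from scipy.stats import rankdata

        pooled = np.array(x + y)
        ranks = rankdata(pooled)
        mu = 9 / 2.0
        u_obs = ranks[:3].sum() - 6.0
        count = sum(
            1
            for idx in itertools.combinations(range(6), 3)
            if abs(ranks[list(idx)].sum() - 6.0 - mu) >= abs(u_obs - mu) - 1e-9
        )
        assert res.p_value == pytest.approx(count / 20.0)

    def test_wrong_group_count_rejected(self):
        with pytest.raises(ValidationError):
            rank_tests([[1], [2], [3]], "mann_whitney_u")
        with pytest.raises(ValidationError):
            rank_tests([[1], [2]], "kruskal_wallis")
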