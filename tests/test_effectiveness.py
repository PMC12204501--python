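import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from price import (
    UtilityParams,
    becc_expected_cost,
    cost_effectiveness_report,
    effective_cost,
    enumerate_paths,
    expected_effectiveness,
    expected_gain_utility,
    negative_predictive_value,
    outcome_utility,
    positive_predictive_value,
    posterior_prevalence_after_negative,
    PredictiveValues,
)
from price.effectiveness import path_utility
from price.exceptions import (
    NonPositiveEffectivenessError,
    UndefinedPredictiveValueError,
    UnsupportedResultError,
)


def contingency_pv(se, sp, p, n=10**6):
    """Independent oracle: expected 2x2 contingency table at cohort size n."""
    tp = n * p * se
    fn = n * p * (1 - se)
    tn = n * (1 - p) * sp
    fp = n * (1 - p) * (1 - sp)
    return tp / (tp + fp), tn / (tn + fn)


class TestPredictiveValues:
    def test_all_diseased_gives_ppv_one(self):
        assert positive_predictive_value(0.9, 0.9, 1.0) == pytest.approx(1.0)

    def test_perfect_specificity_gives_ppv_one(self):
        assert positive_predictive_value(0.42, 1.0, 0.3) == pytest.approx(1.0)

    def test_cma_ppv_matches_contingency_table(self):
        ppv, _ = contingency_pv(0.9068, 0.9440, 0.1665)
        assert positive_predictive_value(0.9068, 0.9440, 0.1665) == pytest.approx(ppv, abs=1e-12)
        assert ppv == pytest.approx(0.7639, abs=5e-5)

    def test_nobody_diseased_gives_npv_one(self):
        assert negative_predictive_value(0.5, 0.9, 0.0) == pytest.approx(1.0)

    def test_perfect_sensitivity_gives_npv_one(self):
        assert negative_predictive_value(1.0, 0.7, 0.4) == pytest.approx(1.0)

    def test_cma_npv_matches_contingency_table(self):
        _, npv = contingency_pv(0.9068, 0.9440, 0.1665)
        assert negative_predictive_value(0.9068, 0.9440, 0.1665) == pytest.approx(npv, abs=1e-12)
        assert npv == pytest.approx(0.9807, abs=5e-5)

    def test_undefined_denominators_raise(self):
        with pytest.raises(UndefinedPredictiveValueError):
            positive_predictive_value(0.0, 1.0, 0.5)
        with pytest.raises(UndefinedPredictiveValueError):
            negative_predictive_value(1.0, 0.0, 1.0)

    def test_posterior_rules_out_with_perfect_sensitivity(self):
        assert posterior_prevalence_after_negative(0.3, 1.0, 0.8) == 0.0

    def test_posterior_cma_value(self):
        post = posterior_prevalence_after_negative(0.1665, 0.9068, 0.9440)
        assert post == pytest.approx(0.0193, abs=5e-5)

    @settings(derandomize=True, max_examples=200)
    @given(se=st.floats(0.05, 1.0), sp=st.floats(0.05, 1.0), p=st.floats(0.0, 0.99))
    def test_posterior_is_one_minus_npv(self, se, sp, p):
        post = posterior_prevalence_after_negative(p, se, sp)
        npv = negative_predictive_value(se, sp, p)
        assert post == pytest.approx(1.0 - npv, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(se=st.floats(0.01, 1.0), sp=st.floats(0.0, 0.99), p=st.floats(0.01, 1.0))
    def test_pv_match_contingency_oracle(self, se, sp, p):
        ppv, _ = contingency_pv(se, sp, p)
        assert positive_predictive_value(se, sp, p) == pytest.approx(ppv, abs=1e-9)


class TestEGUAndUtility:
    def test_perfect_test_egu(self):
        params = UtilityParams(alpha=1.0, lambda_=0.03)
        pv = PredictiveValues(ppv=1.0, npv=1.0)
        assert expected_gain_utility("positive", pv, params) == 1.0

    def test_coin_flip_ppv_cancels(self):
        params = UtilityParams(alpha=1.0, lambda_=0.03)
        pv = PredictiveValues(ppv=0.5, npv=0.5)
        assert expected_gain_utility("positive", pv, params) == pytest.approx(0.0)

    def test_negative_closed_form(self):
        params = UtilityParams(alpha=1.0, lambda_=0.03)
        pv = PredictiveValues(ppv=0.0, npv=0.9807)
        # 2*NPV - 1 when U_TN = 1, U_FN = -1
        assert expected_gain_utility("negative", pv, params) == pytest.approx(0.9614)

    def test_no_result_outcome_uses_configured_egu(self):
        params = UtilityParams(alpha=1.0, lambda_=0.03, no_result_egu=0.25)
        assert expected_gain_utility("none", None, params) == 0.25

    def test_accuracy_only_limit(self):
        params = UtilityParams(alpha=1.0, lambda_=0.03)
        assert outcome_utility(0.5278, tat=40.0, params=params) == pytest.approx(0.5278)

    def test_timeliness_only_at_zero_delay(self):
        params = UtilityParams(alpha=0.0, lambda_=0.03)
        assert outcome_utility(-0.9, tat=0.0, params=params) == pytest.approx(1.0)

    def test_closed_form_evaluation(self):
        params = UtilityParams(alpha=0.5, lambda_=0.03)
        expected = 0.5 * 0.5278 + 0.5 * math.exp(-0.03 * 6)
        assert outcome_utility(0.5278, tat=6.0, params=params) == pytest.approx(expected)
        assert expected == pytest.approx(0.6815, abs=5e-5)

    @settings(derandomize=True, max_examples=100)
    @given(egu=st.floats(-1, 1), t1=st.floats(0, 100), t2=st.floats(0, 100),
           alpha=st.floats(0, 1), lam=st.floats(0.0, 0.2))
    def test_utility_non_increasing_in_tat(self, egu, t1, t2, alpha, lam):
        params = UtilityParams(alpha=alpha, lambda_=lam)
        lo, hi = sorted((t1, t2))
        assert outcome_utility(egu, hi, params) <= outcome_utility(egu, lo, params) + 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(e1=st.floats(-1, 1), e2=st.floats(-1, 1), w=st.floats(0, 1),
           tat=st.floats(0, 50), alpha=st.floats(0, 1))
    def test_utility_linear_in_egu_at_fixed_tat(self, e1, e2, w, tat, alpha):
        params = UtilityParams(alpha=alpha, lambda_=0.05)
        mix = outcome_utility(w * e1 + (1 - w) * e2, tat, params)
        parts = w * outcome_utility(e1, tat, params) + (1 - w) * outcome_utility(e2, tat, params)
        assert mix == pytest.approx(parts, abs=1e-9)


class TestExpectedEffectiveness:
    def test_scenario1_matches_hand_path_enumeration(self, scenario_trees, utility):
        """Probability-weighted utilities recomputed path-by-path from first principles."""
        tree = scenario_trees[1]
        total = 0.0
        for path in enumerate_paths(tree):
            final = path.final_result
            test = tree.tests[final.test_ref]
            if final.value == "positive":
                pv = positive_predictive_value(test.sensitivity, test.specificity, utility.prevalence)
                egu = pv * utility.u_tp + (1 - pv) * utility.u_fp
            else:
                pv = negative_predictive_value(test.sensitivity, test.specificity, utility.prevalence)
                egu = pv * utility.u_tn + (1 - pv) * utility.u_fn
            total += path.probability * (
                utility.alpha * egu + (1 - utility.alpha) * math.exp(-utility.lambda_ * path.tat))
        report = expected_effectiveness(tree, utility)
        assert report.expected_effectiveness == pytest.approx(total, rel=1e-12)
        # internal consistency of the per-path table
        assert report.expected_effectiveness == pytest.approx(
            sum(pu.path.probability * pu.utility for pu in report.per_path), abs=1e-9)

    def test_alpha_one_perfect_positive_tree_equals_utp(self, case_params):
        from conftest import make_tree
        from price import EdgeSpec, NodeSpec, TestPerformance

        nodes = [
            NodeSpec("a", "action"),
            NodeSpec("r", "result", result_value="positive", test_ref="t"),
            NodeSpec("x", "exit"),
        ]
        edges = [EdgeSpec("a", "r", 1.0), EdgeSpec("r", "x", 1.0)]
        tree = make_tree(nodes, edges, "a", tests={"t": TestPerformance("t", 1.0, 1.0)})
        params = UtilityParams(alpha=1.0, lambda_=0.03, u_tp=0.8, prevalence=0.4)
        assert expected_effectiveness(tree, params).expected_effectiveness == pytest.approx(0.8)

    def test_missing_test_ref_raises(self, oracle_tree, utility):
        with pytest.raises(UnsupportedResultError, match="test_ref"):
            expected_effectiveness(oracle_tree, utility)

    def test_numeric_result_value_rejected(self, utility):
        from conftest import make_tree
        from price import EdgeSpec, NodeSpec

        nodes = [
            NodeSpec("a", "action"),
            NodeSpec("r", "result", result_value="3.2"),
            NodeSpec("x", "exit"),
        ]
        tree = make_tree(nodes, [EdgeSpec("a", "r", 1.0), EdgeSpec("r", "x", 1.0)], "a")
        with pytest.raises(UnsupportedResultError, match="numeric"):
            expected_effectiveness(tree, utility)

    def test_serial_bayes_chains_posterior_manually(self, scenario_trees, case_params):
        """Serial mode must reproduce an explicit Bayes chain on scenario 2's ES paths."""
        from price import default_utility_params

        utility = default_utility_params(params=case_params, pv_mode="serial_bayes")
        tree = scenario_trees[2]
        es_pos = next(p for p in enumerate_paths(tree)
                      if p.final_result.value == "positive" and p.final_result.test_ref == "es")
        p1 = posterior_prevalence_after_negative(case_params.prevalence,
                                                 case_params.se_cma, case_params.sp_cma)
        p2 = posterior_prevalence_after_negative(p1, case_params.se_gp, case_params.sp_gp)
        ppv = positive_predictive_value(case_params.se_es, case_params.sp_es, p2)
        expected_egu = 2 * ppv - 1
        assert path_utility(tree, es_pos, utility).egu == pytest.approx(expected_egu, rel=1e-12)


class TestEffectiveCost:
    def test_definition(self, scenario_trees, utility):
        tree = scenario_trees[3]
        ec = becc_expected_cost(tree).expected_cost
        ee = expected_effectiveness(tree, utility).expected_effectiveness
        assert effective_cost(tree, utility) == pytest.approx(ec / ee)

    def test_doubling_costs_doubles_effective_cost(self, case_params, utility):
        from dataclasses import replace as drep

        from price import build_scenario

        doubled = drep(case_params, expert_fee=330.0, cost_cma=1650.0,
                       cost_gp=3000.0, cost_es=9178.8)
        base = build_scenario(2, case_params)
        twice = build_scenario(2, doubled)
        assert effective_cost(twice, utility) == pytest.approx(2 * effective_cost(base, utility))
        assert expected_effectiveness(twice, utility).expected_effectiveness == pytest.approx(
            expected_effectiveness(base, utility).expected_effectiveness)

    def test_non_positive_effectiveness_is_signalled(self):
        from conftest import make_tree
        from price import EdgeSpec, NodeSpec

        nodes = [NodeSpec("a", "action", cost=100.0), NodeSpec("x", "exit")]
        tree = make_tree(nodes, [EdgeSpec("a", "x", 1.0)], "a")
        params = UtilityParams(alpha=1.0, lambda_=0.03, no_result_egu=0.0)
        with pytest.raises(NonPositiveEffectivenessError):
            effective_cost(tree, params)

    def test_scenario1_dominates_scenario4_across_alpha(self, case_params):
        from price import build_scenario, default_utility_params

        s1, s4 = build_scenario(1, case_params), build_scenario(4, case_params)
        for alpha in [i / 10 for i in range(11)]:
            u = default_utility_params(alpha=alpha, params=case_params)
            assert effective_cost(s1, u) < effective_cost(s4, u)

    def test_report_is_internally_consistent(self, scenario_trees, utility):
        rep = cost_effectiveness_report(scenario_trees[2], utility)
        assert rep.effective_cost == pytest.approx(rep.expected_cost / rep.expected_effectiveness)
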