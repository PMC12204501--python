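"""Effectiveness and cost-effectiveness of diagnostic pathways.

The outcome of a pathway is summarised by an outcome state: the final test
result at the exit and the turnaround time (TAT) accumulated on the way
there.  The utility of an outcome state blends diagnostic accuracy and
timeliness:

    U(S) = alpha * EGU + (1 - alpha) * exp(-lambda * TAT)

where EGU is the expected gain in utility of the final result — positive
results weight the utility of a true positive against the disutility of a
false positive through the positive predictive value (PPV), and negative
results do the same with the NPV:

    EGU(positive) = PPV * U_TP + (1 - PPV) * U_FP
    EGU(negative) = NPV * U_TN + (1 - NPV) * U_FN

PPV/NPV follow from disease prevalence p and the sensitivity Se and
specificity Sp of the test that produced the final result.  The expected
effectiveness of a strategy is the probability-weighted sum of outcome-state
utilities over all root-to-exit paths, and the effective cost is the ratio
of the expected diagnostic cost to the expected effectiveness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .cost_engine import becc_expected_cost
from .exceptions import (
    NonPositiveEffectivenessError,
    UndefinedPredictiveValueError,
    UnsupportedResultError,
)
from .tree_model import DiagnosticTree, PathRecord, enumerate_paths

PV_MODES = ("final_test", "serial_bayes")


@dataclass(frozen=True)
class UtilityParams:
    """Utility-model parameters.

    alpha
        Weight in [0, 1] on diagnostic accuracy versus timeliness.
    lambda_
        Exponential decay rate of the timeliness term, per week of TAT
        (clinically sensible values for a slowly evolving indication lie in
        [0.01, 0.1]).
    u_tp, u_tn
        Utilities of true positive / true negative final results, in [0, 1].
    u_fp, u_fn
        Disutilities of false positive / false negative results, in [-1, 0].
    prevalence
        Pre-test disease probability p.
    pv_mode
        ``final_test``: predictive values use the final test's Se/Sp at the
        baseline prevalence.  ``serial_bayes``: the prevalence is updated by
        Bayes' rule after every preceding negative result on the path.
    no_result_egu
        EGU assigned to paths that exit without any test result (the
        timeliness term still applies).
    """

    alpha: float
    lambda_: float
    u_tp: float = 1.0
    u_fp: float = -1.0
    u_tn: float = 1.0
    u_fn: float = -1.0
    prevalence: float = 0.5
    pv_mode: str = "final_test"
    no_result_egu: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if self.lambda_ < 0:
            raise ValueError(f"lambda_={self.lambda_} must be >= 0")
        if not 0.0 <= self.u_tp <= 1.0 or not 0.0 <= self.u_tn <= 1.0:
            raise ValueError("u_tp and u_tn must lie in [0, 1]")
        if not -1.0 <= self.u_fp <= 0.0 or not -1.0 <= self.u_fn <= 0.0:
            raise ValueError("u_fp and u_fn must lie in [-1, 0]")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence={self.prevalence} outside [0, 1]")
        if self.pv_mode not in PV_MODES:
            raise ValueError(f"pv_mode must be one of {PV_MODES}, got {self.pv_mode!r}")


class PredictiveValues(NamedTuple):
    ppv: float
    npv: float


@dataclass(frozen=True)
class PathUtility:
    """Per-path effectiveness bookkeeping."""

    path: PathRecord
    egu: float
    utility: float


@dataclass
class EffectivenessReport:
    expected_effectiveness: float
    per_path: list = field(default_factory=list)


@dataclass
class CEAReport:
    """Joint cost/effectiveness summary of one diagnostic strategy."""

    expected_cost: float
    expected_tat: float
    expected_effectiveness: float
    effective_cost: float
    per_path: list = field(default_factory=list)


def _check_unit(name, value):
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")


def positive_predictive_value(se: float, sp: float, p: float) -> float:
    """PPV = Se p / (Se p + (1 - Sp)(1 - p))."""
    _check_unit("se", se), _check_unit("sp", sp), _check_unit("p", p)
    denom = se * p + (1.0 - sp) * (1.0 - p)
    if denom <= 0.0:
        raise UndefinedPredictiveValueError(
            f"PPV undefined: no predicted positives for se={se}, sp={sp}, p={p}")
    return se * p / denom


def negative_predictive_value(se: float, sp: float, p: float) -> float:
    """NPV = Sp (1 - p) / (Sp (1 - p) + (1 - Se) p)."""
    _check_unit("se", se), _check_unit("sp", sp), _check_unit("p", p)
    denom = sp * (1.0 - p) + (1.0 - se) * p
    if denom <= 0.0:
        raise UndefinedPredictiveValueError(
            f"NPV undefined: no predicted negatives for se={se}, sp={sp}, p={p}")
    return sp * (1.0 - p) / denom


def posterior_prevalence_after_negative(p: float, se: float, sp: float) -> float:
    """Post-test disease probability after a negative result; equals 1 - NPV."""
    _check_unit("se", se), _check_unit("sp", sp), _check_unit("p", p)
    denom = (1.0 - se) * p + sp * (1.0 - p)
    if denom <= 0.0:
        raise UndefinedPredictiveValueError(
            f"posterior undefined: P(negative)=0 for se={se}, sp={sp}, p={p}")
    return (1.0 - se) * p / denom


def expected_gain_utility(outcome: str, pv: Optional[PredictiveValues], params: UtilityParams) -> float:
    """EGU of a final outcome, weighting true/false results by PPV or NPV."""
    if outcome == "positive":
        return pv.ppv * params.u_tp + (1.0 - pv.ppv) * params.u_fp
    if outcome == "negative":
        return pv.npv * params.u_tn + (1.0 - pv.npv) * params.u_fn
    if outcome == "none":
        return params.no_result_egu
    raise UnsupportedResultError(f"unsupported outcome {outcome!r}; expected positive/negative/none")


def outcome_utility(egu: float, tat: float, params: UtilityParams) -> float:
    """U(S) = alpha * EGU + (1 - alpha) * exp(-lambda * TAT)."""
    if tat < 0:
        raise ValueError(f"tat={tat} must be >= 0")
    return params.alpha * egu + (1.0 - params.alpha) * math.exp(-params.lambda_ * tat)


def _path_prevalence(tree: DiagnosticTree, path: PathRecord, params: UtilityParams) -> float:
    """Prevalence entering the final test, optionally Bayes-updated serially."""
    if params.pv_mode == "final_test":
        return params.prevalence
    p = params.prevalence
    result_ids = [nid for nid in path.nodes if tree.nodes[nid].kind == "result"]
    for nid in result_ids[:-1]:  # every result before the final one
        node = tree.nodes[nid]
        if node.result_value == "negative" and node.test_ref is not None:
            t = tree.tests[node.test_ref]
            p = posterior_prevalence_after_negative(p, t.sensitivity, t.specificity)
    return p


def path_utility(tree: DiagnosticTree, path: PathRecord, params: UtilityParams) -> PathUtility:
    """EGU and outcome-state utility of one root-to-exit path."""
    final = path.final_result
    if final is None or final.value not in ("positive", "negative"):
        if final is not None and final.value is not None and _looks_numeric(final.value):
            raise UnsupportedResultError(
                f"numeric result value {final.value!r} is not supported by the utility model")
        egu = params.no_result_egu  # no diagnostic information at exit (incl. AI gate labels)
    else:
        if final.test_ref is None:
            raise UnsupportedResultError(
                f"final result on path {'-'.join(path.nodes)} lacks a test_ref; "
                "predictive values cannot be computed")
        test = tree.tests[final.test_ref]
        p = _path_prevalence(tree, path, params)
        pv = PredictiveValues(
            ppv=positive_predictive_value(test.sensitivity, test.specificity, p),
            npv=negative_predictive_value(test.sensitivity, test.specificity, p),
        )
        egu = expected_gain_utility(final.value, pv, params)
    return PathUtility(path=path, egu=egu, utility=outcome_utility(egu, path.tat, params))


def _looks_numeric(value: str) -> bool:
    try:
        float(value)
    except (TypeError, ValueError):
        return False
    return True


def expected_effectiveness(tree: DiagnosticTree, params: UtilityParams) -> EffectivenessReport:
    """Probability-weighted sum of outcome-state utilities over all paths."""
    per_path = [path_utility(tree, path, params) for path in enumerate_paths(tree)]
    total = sum(pu.path.probability * pu.utility for pu in per_path)
    return EffectivenessReport(expected_effectiveness=total, per_path=per_path)


def effective_cost(tree: DiagnosticTree, params: UtilityParams) -> float:
    """Expected diagnostic cost per unit of expected effectiveness."""
    eff = expected_effectiveness(tree, params).expected_effectiveness
    if eff <= 0.0:
        raise NonPositiveEffectivenessError(
            f"expected effectiveness is {eff}; the cost/effectiveness ratio is undefined")
    return becc_expected_cost(tree).expected_cost / eff


def cost_effectiveness_report(tree: DiagnosticTree, params: UtilityParams) -> CEAReport:
    """Expected cost, TAT, effectiveness and effective cost in one report."""
    cost = becc_expected_cost(tree)
    eff = expected_effectiveness(tree, params)
    if eff.expected_effectiveness <= 0.0:
        raise NonPositiveEffectivenessError(
            f"expected effectiveness is {eff.expected_effectiveness}; "
            "the cost/effectiveness ratio is undefined")
    return CEAReport(
        expected_cost=cost.expected_cost,
        expected_tat=cost.expected_tat,
        expected_effectiveness=eff.expected_effectiveness,
        effective_cost=cost.expected_cost / eff.expected_effectiveness,
        per_path=eff.per_path,
    )
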