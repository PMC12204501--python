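"""Tiered genetic-testing case study: developmental delay & multiple congenital anomalies.

Four expert-alone strategies for DD & MCA are modelled, built from three
tests — chromosomal microarray analysis (CMA), a targeted gene panel (GP)
and exome sequencing (ES):

1. CMA, then GP on a negative CMA;
2. CMA, then GP, then ES;
3. CMA, then ES;
4. ES only (first tier).

plus an AI-delegated variant of strategy 2/3: after a negative CMA, an AI
action node predicts whether GP will yield a positive result.  If the
predicted probability clears the threshold r*, GP is ordered automatically
(and ES follows a negative GP) with no expert involvement on that branch;
otherwise an expert decides and the patient proceeds directly to ES.

Node ids mirror the reference workflow numbering ("1", "2", ..., with
primes for AI-introduced nodes); exit nodes take an ``e`` prefix where the
numbering does not name them.  Decision nodes carry the expert fee C_E and
consultation turnaround T_E — including decisions whose only option is to
exit, since the terminal expert review is still billed (disable with
``free_exit_decisions``).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import pandas as pd

from .ai_delegation import AIConfig, delegate
from .effectiveness import UtilityParams, cost_effectiveness_report
from .tree_model import DiagnosticTree, EdgeSpec, NodeSpec, TestPerformance

SCENARIOS = (1, 2, 3, 4)


@dataclass(frozen=True)
class CaseStudyParameters:
    """Point parameter registry for the DD & MCA case study.

    Costs are US dollars; turnaround times are weeks.  Diagnostic yields are
    the fraction of *all* tested individuals with a positive result (not
    sensitivity): ``yield_es_tier1/2/3`` are the marginal ES yields when ES
    is used as a first-, second- or third-tier test.  Point values follow
    the deterministic reference configuration; the uncertainty module holds
    the corresponding prior distributions.
    """

    expert_fee: float = 165.0            # C_E
    cost_cma: float = 825.0              # C_0
    cost_gp: float = 1500.0              # C_1
    cost_es: float = 4589.4              # C_2
    tat_cma: float = 2.0                 # T_0
    tat_gp: float = 4.0                  # T_1
    tat_es: float = 8.0                  # T_2
    tat_expert: float = 4.0              # T_E
    tat_ai: float = 0.0                  # T_AI
    yield_cma: float = 0.1               # YD_0
    yield_gp: float = 0.11               # YD_1
    yield_es_tier1: float = 0.37         # YD_21
    yield_es_tier2: float = 0.35         # YD_22
    yield_es_tier3: float = 0.33         # YD_23
    se_cma: float = 0.9068
    sp_cma: float = 0.9440
    se_gp: float = 0.8960
    sp_gp: float = 0.9250
    se_es: float = 0.9593
    sp_es: float = 0.9933
    prevalence: float = 0.1665
    ai_precision: float = 0.87

    def __post_init__(self):
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if v < 0:
                raise ValueError(f"{f_.name}={v} must be >= 0")
            if f_.name.startswith(("yield_", "se_", "sp_")) or f_.name in ("prevalence", "ai_precision"):
                if v > 1:
                    raise ValueError(f"{f_.name}={v} outside [0, 1]")

    def tests(self) -> dict:
        return {
            "cma": TestPerformance("cma", self.se_cma, self.sp_cma),
            "gp": TestPerformance("gp", self.se_gp, self.sp_gp),
            "es": TestPerformance("es", self.se_es, self.sp_es),
        }


def default_utility_params(
    alpha: float = 0.5,
    lambda_: float = 0.03,
    params: CaseStudyParameters | None = None,
    **kwargs,
) -> UtilityParams:
    """Reference utility configuration: U_TP = U_TN = 1, U_FP = U_FN = -1."""
    params = params or CaseStudyParameters()
    kwargs.setdefault("prevalence", params.prevalence)
    return UtilityParams(alpha=alpha, lambda_=lambda_, **kwargs)


def _entry_and_first_decision(p: CaseStudyParameters):
    nodes = [
        NodeSpec("1", "action", label="patient entry"),
        NodeSpec("2", "decision", label="Decision 1", cost=p.expert_fee, tat=p.tat_expert),
    ]
    edges = [EdgeSpec("1", "2", 1.0)]
    return nodes, edges


def _cma_tier(p: CaseStudyParameters):
    nodes = [
        NodeSpec("3", "action", label="CMA", cost=p.cost_cma, tat=p.tat_cma),
        NodeSpec("5", "result", label="CMA positive", result_value="positive", test_ref="cma"),
        NodeSpec("6", "result", label="CMA negative", result_value="negative", test_ref="cma"),
        NodeSpec("e5", "exit", label="diagnosis reached"),
    ]
    edges = [
        EdgeSpec("2", "3", 1.0),
        EdgeSpec("3", "5", p.yield_cma),
        EdgeSpec("3", "6", 1.0 - p.yield_cma),
        EdgeSpec("5", "e5", 1.0),
    ]
    return nodes, edges


def _gp_tier(p: CaseStudyParameters):
    nodes = [
        NodeSpec("10", "decision", label="Decision 2", cost=p.expert_fee, tat=p.tat_expert),
        NodeSpec("14", "action", label="gene panel", cost=p.cost_gp, tat=p.tat_gp),
        NodeSpec("17", "result", label="GP positive", result_value="positive", test_ref="gp"),
        NodeSpec("18", "result", label="GP negative", result_value="negative", test_ref="gp"),
        NodeSpec("e17", "exit", label="diagnosis reached"),
    ]
    edges = [
        EdgeSpec("6", "10", 1.0),
        EdgeSpec("10", "14", 1.0),
        EdgeSpec("14", "17", p.yield_gp),
        EdgeSpec("14", "18", 1.0 - p.yield_gp),
        EdgeSpec("17", "e17", 1.0),
    ]
    return nodes, edges


def build_scenario(
    scenario: int,
    params: CaseStudyParameters | None = None,
    free_exit_decisions: bool = False,
) -> DiagnosticTree:
    """Build the expert-alone tree for one of the four strategies.

    ``free_exit_decisions`` zeroes the fee of decision nodes whose every
    option is an exit (a sensitivity toggle for whether the terminal expert
    review is billed).
    """
    p = params or CaseStudyParameters()
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")

    nodes, edges = _entry_and_first_decision(p)

    if scenario == 4:
        nodes += [
            NodeSpec("4", "action", label="ES (first tier)", cost=p.cost_es, tat=p.tat_es),
            NodeSpec("7", "result", label="ES positive", result_value="positive", test_ref="es"),
            NodeSpec("8", "result", label="ES negative", result_value="negative", test_ref="es"),
            NodeSpec("e7", "exit"), NodeSpec("e8", "exit"),
        ]
        edges += [
            EdgeSpec("2", "4", 1.0),
            EdgeSpec("4", "7", p.yield_es_tier1),
            EdgeSpec("4", "8", 1.0 - p.yield_es_tier1),
            EdgeSpec("7", "e7", 1.0), EdgeSpec("8", "e8", 1.0),
        ]
    else:
        n, e = _cma_tier(p)
        nodes += n
        edges += e
        if scenario == 3:
            nodes += [
                NodeSpec("10", "decision", label="Decision 2", cost=p.expert_fee, tat=p.tat_expert),
                NodeSpec("13", "action", label="ES (second tier)", cost=p.cost_es, tat=p.tat_es),
                NodeSpec("15", "result", label="ES positive", result_value="positive", test_ref="es"),
                NodeSpec("16", "result", label="ES negative", result_value="negative", test_ref="es"),
                NodeSpec("e15", "exit"), NodeSpec("e16", "exit"),
            ]
            edges += [
                EdgeSpec("6", "10", 1.0),
                EdgeSpec("10", "13", 1.0),
                EdgeSpec("13", "15", p.yield_es_tier2),
                EdgeSpec("13", "16", 1.0 - p.yield_es_tier2),
                EdgeSpec("15", "e15", 1.0), EdgeSpec("16", "e16", 1.0),
            ]
        else:
            n, e = _gp_tier(p)
            nodes += n
            edges += e
            if scenario == 1:
                exit_fee = 0.0 if free_exit_decisions else p.expert_fee
                nodes += [
                    NodeSpec("22", "decision", label="Decision 3 (exit review)",
                             cost=exit_fee, tat=p.tat_expert),
                    NodeSpec("23", "exit", label="process exhausted"),
                ]
                edges += [EdgeSpec("18", "22", 1.0), EdgeSpec("22", "23", 1.0)]
            else:  # scenario 2: third-tier ES
                nodes += [
                    NodeSpec("22", "decision", label="Decision 3", cost=p.expert_fee, tat=p.tat_expert),
                    NodeSpec("24", "action", label="ES (third tier)", cost=p.cost_es, tat=p.tat_es),
                    NodeSpec("25", "result", label="ES positive", result_value="positive", test_ref="es"),
                    NodeSpec("26", "result", label="ES negative", result_value="negative", test_ref="es"),
                    NodeSpec("e25", "exit"), NodeSpec("e26", "exit"),
                ]
                edges += [
                    EdgeSpec("18", "22", 1.0),
                    EdgeSpec("22", "24", 1.0),
                    EdgeSpec("24", "25", p.yield_es_tier3),
                    EdgeSpec("24", "26", 1.0 - p.yield_es_tier3),
                    EdgeSpec("25", "e25", 1.0), EdgeSpec("26", "e26", 1.0),
                ]

    tree = DiagnosticTree(
        nodes={n.id: n for n in nodes},
        edges=edges,
        root="1",
        tests=p.tests(),
        meta={"scenario": scenario, "prevalence": p.prevalence},
    )
    tree.require_valid()
    return tree


def build_ai_tree(params: CaseStudyParameters | None = None, ai: AIConfig | None = None) -> DiagnosticTree:
    """AI-delegated tree: strategy 2's GP tier automated, strategy 3 as fallback.

    Built by applying :func:`~price.ai_delegation.delegate` to the
    scenario-2 tree at Decision 2: the ``r >= r*`` branch orders GP
    automatically (positive probability = AI precision) and continues to
    third-tier ES with no expert nodes; the ``r < r*`` branch reinstates the
    human Decision 2 followed by second-tier ES only.
    """
    p = params or CaseStudyParameters()
    ai = ai or AIConfig(precision=p.ai_precision, gate_prob=1.0, ai_tat=p.tat_ai)

    base = build_scenario(2, p)
    fallback = _fallback_es_subtree(p)
    return delegate(
        base,
        decision_id="10",
        ai=ai,
        automated_action_id="14",
        fallback_subtree=fallback,
        ai_ids=("1'", "2'", "3'"),
    )


def _fallback_es_subtree(p: CaseStudyParameters) -> DiagnosticTree:
    """Human Decision 2 -> second-tier ES, as in strategy 3."""
    nodes = [
        NodeSpec("10", "decision", label="Decision 2", cost=p.expert_fee, tat=p.tat_expert),
        NodeSpec("13", "action", label="ES (second tier)", cost=p.cost_es, tat=p.tat_es),
        NodeSpec("15", "result", label="ES positive", result_value="positive", test_ref="es"),
        NodeSpec("16", "result", label="ES negative", result_value="negative", test_ref="es"),
        NodeSpec("e15", "exit"), NodeSpec("e16", "exit"),
    ]
    edges = [
        EdgeSpec("10", "13", 1.0),
        EdgeSpec("13", "15", p.yield_es_tier2),
        EdgeSpec("13", "16", 1.0 - p.yield_es_tier2),
        EdgeSpec("15", "e15", 1.0), EdgeSpec("16", "e16", 1.0),
    ]
    return DiagnosticTree(
        nodes={n.id: n for n in nodes}, edges=edges, root="10", tests=p.tests())


# ---------------------------------------------------------------------------
# Sweep engine
# ---------------------------------------------------------------------------

METRICS = ("expected_cost", "expected_effectiveness", "effective_cost")

_UTILITY_PARAMS = {"alpha": (0.0, 1.0), "lambda": (0.01, 0.1), "lambda_": (0.01, 0.1)}
_AI_PARAMS = {"precision": (0.0, 1.0), "gate_prob": (0.0, 1.0), "threshold": (0.0, 1.0),
              "ai_cost": (0.0, None), "ai_tat": (0.0, None)}


def _case_param_bounds(name: str):
    if name.startswith(("yield_", "se_", "sp_")) or name in ("prevalence", "ai_precision"):
        return (0.0, 1.0)
    return (0.0, None)


def sweep(
    metric: str,
    param: str,
    grid,
    scenarios,
    params: CaseStudyParameters | None = None,
    utility: UtilityParams | None = None,
    ai: AIConfig | None = None,
    free_exit_decisions: bool = False,
) -> pd.DataFrame:
    """Recompute cost-effectiveness metrics over a parameter grid.

    ``scenarios`` mixes the integers 1-4 with the string ``"ai"``.  The
    returned table has one row per (scenario, grid point) with all three
    metrics; ``metric`` names the primary one and is validated.  Grid values
    outside the parameter's legal range raise a ``ValueError`` naming the
    bound.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("grid must be non-empty")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")

    params = params or CaseStudyParameters()
    utility = utility or default_utility_params(params=params)
    ai = ai or AIConfig(precision=params.ai_precision, gate_prob=1.0)

    if param in _UTILITY_PARAMS:
        lo, hi = _UTILITY_PARAMS[param]
    elif param in _AI_PARAMS:
        lo, hi = _AI_PARAMS[param]
    elif param in {f_.name for f_ in fields(CaseStudyParameters)}:
        lo, hi = _case_param_bounds(param)
    else:
        raise ValueError(f"unknown sweep parameter {param!r}")
    for g in grid:
        if g < lo or (hi is not None and g > hi):
            bound = f"[{lo}, {hi if hi is not None else 'inf'}]"
            raise ValueError(f"grid value {g} outside the legal range {bound} of {param!r}")

    rows = []
    for g in grid:
        p_g, u_g, ai_g = params, utility, ai
        if param in ("alpha",):
            u_g = replace(utility, alpha=g)
        elif param in ("lambda", "lambda_"):
            u_g = replace(utility, lambda_=g)
        elif param in _AI_PARAMS:
            ai_g = replace(ai, **{param: g})
        else:
            p_g = replace(params, **{param: g})
            if param == "prevalence":
                u_g = replace(utility, prevalence=g)
        for s in scenarios:
            if s == "ai":
                tree = build_ai_tree(p_g, ai_g)
            else:
                tree = build_scenario(int(s), p_g, free_exit_decisions=free_exit_decisions)
            report = cost_effectiveness_report(tree, u_g)
            rows.append({
                "scenario": str(s),
                "param_value": g,
                "expected_cost": report.expected_cost,
                "expected_effectiveness": report.expected_effectiveness,
                "effective_cost": report.effective_cost,
            })
    return pd.DataFrame(rows, columns=["scenario", "param_value"] + list(METRICS))


# ---------------------------------------------------------------------------
# Uncertainty registry (reference prior distributions for the PSA)
# ---------------------------------------------------------------------------

def default_distribution_specs() -> dict:
    """Reference prior distributions of the uncertain case-study parameters.

    The CMA cost gamma is read in shape/rate form (mean ~= 823.8, matching
    the 825 point value); the ES cost normal is mean/sd truncated at zero;
    the GP cost range is modelled as uniform.  Note the GP-yield beta prior
    has mean ~= 0.21 while the deterministic point value is 0.11 — the point
    value is used for all deterministic runs and the prior only here.
    """
    from . import uncertainty as u

    return {
        "cost_cma": u.gamma(2010.0, 2.44),
        "cost_gp": u.uniform(1450.0, 1750.0),
        "cost_es": u.normal(4589.4, 45.0, truncation=(0.0, float("inf"))),
        "yield_cma": u.beta(154.0, 1382.0),
        "yield_gp": u.beta(24.0, 89.0),
        "yield_es_tier1": u.beta(27.0, 46.0),
        "yield_es_tier2": u.point(0.35),
        "yield_es_tier3": u.beta(228.0, 464.0),
    }


def case_study_psa(scenario, n: int, seed, utility: UtilityParams | None = None,
                   specs: dict | None = None, params: CaseStudyParameters | None = None,
                   ai: AIConfig | None = None):
    """PSA over the case-study priors for one scenario (1-4 or ``"ai"``)."""
    from .uncertainty import probabilistic_sensitivity

    base = params or CaseStudyParameters()
    utility = utility or default_utility_params(params=base)
    specs = specs if specs is not None else default_distribution_specs()

    def builder(draw: dict) -> DiagnosticTree:
        p = replace(base, **draw)
        if scenario == "ai":
            return build_ai_tree(p, ai)
        return build_scenario(int(scenario), p)

    return probabilistic_sensitivity(builder, specs, utility, n, seed)
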