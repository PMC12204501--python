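"""AI-delegation restructuring of expert decision points.

In the expert-alone mode a decision node is a human judgment point that
carries an expert fee and a consultation turnaround time.  Under AI
delegation the "decision node + N action nodes" block is replaced by an AI
action node that predicts whether the cheaper candidate test will succeed,
followed by two AI result nodes split by a confidence threshold r*:

* ``r >= r*`` — the predicted test is ordered automatically.  This branch
  is fully automated: no expert decision nodes remain on it, so neither the
  expert fee nor the consultation TAT is incurred anywhere downstream until
  the process exits.  The positive-result probability (diagnostic yield) of
  the automated test becomes the AI's precision P(test positive | predicted
  positive); the test's intrinsic Se/Sp — and hence its PPV/NPV — are
  unchanged, because the AI alters which patients take the test, not the
  test itself.
* ``r < r*`` — the workflow falls back to a human decision subtree,
  unaffected by AI performance.

At the population level the gate probability q = P(r >= r*) lies in (0, 1);
for a single patient the prediction is a fixed score, so q is exactly 0
or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .effectiveness import UtilityParams, effective_cost
from .exceptions import DelegationError, NonMonotoneObjectiveError
from .tree_model import DiagnosticTree, EdgeSpec, NodeSpec


@dataclass(frozen=True)
class AIConfig:
    """Configuration of one AI delegation step.

    threshold
        Confidence threshold r* in [0, 1] above which the AI's predicted
        test is ordered without expert review.
    precision
        P_AI = P(test positive | AI predicted positive); becomes the
        diagnostic yield of the automated branch's test.
    gate_prob
        q = P(r >= r*).  Population mode: any value in [0, 1]; patient
        mode: exactly 0 or 1 (the score of a given patient is fixed).
    ai_cost, ai_tat
        Cost and turnaround time of the AI action node itself (both default
        to zero: AI decision-making is immediate and carries no fee in the
        reference parameterization).
    patient_mode
        If true, ``gate_prob`` must be exactly 0 or 1.
    """

    precision: float
    threshold: float = 0.8
    gate_prob: float = 1.0
    ai_cost: float = 0.0
    ai_tat: float = 0.0
    patient_mode: bool = False

    def __post_init__(self):
        for name in ("precision", "threshold", "gate_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ai_cost < 0 or self.ai_tat < 0:
            raise ValueError("ai_cost and ai_tat must be >= 0")
        if self.patient_mode and self.gate_prob not in (0.0, 1.0):
            raise ValueError("patient mode requires gate_prob in {0, 1}")


def ai_transition_probabilities(ai: AIConfig) -> dict:
    """Edge probabilities introduced by the AI structure."""
    return {
        "gate": ai.gate_prob,
        "no_gate": 1.0 - ai.gate_prob,
        "automated_positive": ai.precision,
        "automated_negative": 1.0 - ai.precision,
    }


def delegate(
    tree: DiagnosticTree,
    decision_id: str,
    ai: AIConfig,
    automated_action_id: str,
    fallback_subtree: DiagnosticTree,
    ai_ids=None,
    automated_suffix: str = "'",
) -> DiagnosticTree:
    """Replace an expert decision node by the AI action/result structure.

    The decision node and its entire subtree are removed.  In their place:

    * an AI action node (actor ``ai``, cost ``ai.ai_cost``, TAT
      ``ai.ai_tat``) is attached to the decision's former parent edge;
    * an AI result node ``r_ge_threshold`` (probability ``gate_prob``)
      leads to a copy of the subtree formerly rooted at
      ``automated_action_id``, with node ids suffixed by
      ``automated_suffix``, every decision node inside it automated
      (actor ``ai``, cost 0, TAT 0), and the automated test's
      positive-result probability set to ``ai.precision``;
    * an AI result node ``r_lt_threshold`` (probability ``1 - gate_prob``)
      leads to ``fallback_subtree``, whose root must be a human decision
      node.

    ``ai_ids`` optionally names the three new nodes (AI action, gate
    result, no-gate result); the default appends primes to ``decision_id``.
    A degenerate gate probability (exactly 0 or 1) leaves the dead branch
    in place with zero mass and records a note in the tree's ``meta``.
    """
    tree.require_valid()
    if decision_id not in tree.nodes:
        raise DelegationError(f"node {decision_id!r} does not exist")
    decision = tree.nodes[decision_id]
    if decision.kind != "decision":
        raise DelegationError(f"node {decision_id!r} is a {decision.kind} node, not a decision")
    child_ids = [e.dst for e in tree.children(decision_id)]
    if automated_action_id not in child_ids:
        raise DelegationError(
            f"{automated_action_id!r} is not a candidate action of decision {decision_id!r}")
    if tree.nodes[automated_action_id].kind != "action":
        raise DelegationError(f"automated node {automated_action_id!r} must be an action node")
    fb_root = fallback_subtree.nodes[fallback_subtree.root]
    if fb_root.kind != "decision" or fb_root.actor != "human":
        raise DelegationError("the fallback subtree must be headed by a human decision node")

    ai_action_id, gate_id, nogate_id = ai_ids or (
        f"{decision_id}{automated_suffix}",
        f"{decision_id}{automated_suffix}{automated_suffix}",
        f"{decision_id}{automated_suffix}{automated_suffix}{automated_suffix}",
    )

    removed = tree.subtree_ids(decision_id)
    nodes = {nid: n for nid, n in tree.nodes.items() if nid not in removed}
    edges = [e for e in tree.edges if e.src not in removed and e.dst not in removed]

    # Re-target the decision's former incoming edge at the AI action node.
    incoming = [e for e in tree.edges if e.dst == decision_id]
    if incoming:
        edges.extend(EdgeSpec(e.src, ai_action_id, e.prob) for e in incoming)
    else:
        raise DelegationError("delegating the root decision is not supported; wrap it in an entry node")

    nodes[ai_action_id] = NodeSpec(
        id=ai_action_id, kind="action", actor="ai",
        label="AI test selection", cost=ai.ai_cost, tat=ai.ai_tat)
    nodes[gate_id] = NodeSpec(id=gate_id, kind="result", actor="ai",
                              label="r >= r*", result_value="r_ge_threshold")
    nodes[nogate_id] = NodeSpec(id=nogate_id, kind="result", actor="ai",
                                label="r < r*", result_value="r_lt_threshold")
    edges.append(EdgeSpec(ai_action_id, gate_id, ai.gate_prob))
    edges.append(EdgeSpec(ai_action_id, nogate_id, 1.0 - ai.gate_prob))

    # Automated branch: suffixed copy of the subtree under the chosen action,
    # with all expert involvement stripped and the test yield set to P_AI.
    auto_ids = tree.subtree_ids(automated_action_id)
    rename = {nid: f"{nid}{automated_suffix}" for nid in auto_ids}
    for nid in auto_ids:
        node = tree.nodes[nid]
        if rename[nid] in nodes:
            raise DelegationError(f"automated-branch id {rename[nid]!r} collides with an existing node")
        if node.kind == "decision":
            node = replace(node, actor="ai", cost=0.0, tat=0.0)
        nodes[rename[nid]] = replace(node, id=rename[nid])
    pos_edges = 0
    for e in tree.edges:
        if e.src in auto_ids and e.dst in auto_ids:
            prob = e.prob
            if e.src == automated_action_id:
                value = tree.nodes[e.dst].result_value
                if value == "positive":
                    prob, pos_edges = ai.precision, pos_edges + 1
                elif value == "negative":
                    prob = 1.0 - ai.precision
                else:
                    raise DelegationError(
                        f"automated action {automated_action_id!r} must lead to "
                        "positive/negative result nodes")
            edges.append(EdgeSpec(rename[e.src], rename[e.dst], prob))
    if pos_edges != 1:
        raise DelegationError(
            f"automated action {automated_action_id!r} must have exactly one positive result child")
    edges.append(EdgeSpec(gate_id, rename[automated_action_id], 1.0))

    # Fallback branch: splice the human-decision subtree.
    overlap = set(fallback_subtree.nodes) & set(nodes)
    if overlap:
        raise DelegationError(f"fallback subtree ids collide with the tree: {sorted(overlap)}")
    nodes.update(fallback_subtree.nodes)
    edges.extend(fallback_subtree.edges)
    edges.append(EdgeSpec(nogate_id, fallback_subtree.root, 1.0))

    tests = dict(tree.tests)
    tests.update(fallback_subtree.tests)
    meta = dict(tree.meta)
    meta["delegated_decision"] = decision_id
    if ai.gate_prob in (0.0, 1.0):
        dead = "fallback" if ai.gate_prob == 1.0 else "automated"
        meta["delegation_note"] = f"gate_prob={ai.gate_prob}: the {dead} branch carries zero mass"

    out = DiagnosticTree(nodes=nodes, edges=edges, root=tree.root, tests=tests, meta=meta)
    out.require_valid()
    return out


def crossover_precision(
    ai_tree_builder,
    baselines,
    params: UtilityParams,
    tol: float = 1e-4,
    grid_points: int = 101,
):
    """Smallest AI precision at which the delegated pathway wins on effective cost.

    ``ai_tree_builder`` maps a precision in [0, 1] to a delegated tree.  The
    effective cost of the delegated tree must be monotone non-increasing in
    precision; this is checked on a ``grid_points``-point pre-scan and a
    :class:`NonMonotoneObjectiveError` is raised otherwise (re-run with a
    dense grid scan in that case).  Returns the smallest precision p* (to
    within ``tol``, by bisection, ties toward the smaller precision) such
    that the delegated effective cost is <= the minimum baseline effective
    cost, or ``None`` if no crossover exists in [0, 1].
    """
    if not baselines:
        raise ValueError("at least one baseline tree is required")
    target = min(effective_cost(b, params) for b in baselines)

    def f(p):
        return effective_cost(ai_tree_builder(p), params)

    grid = np.linspace(0.0, 1.0, grid_points)
    values = [f(p) for p in grid]
    for a, b in zip(values, values[1:]):
        if b > a + 1e-9 * (1.0 + abs(a)):
            raise NonMonotoneObjectiveError(
                "effective cost is not monotone non-increasing in precision on the scan grid; "
                "fall back to a dense grid scan")

    if values[0] <= target:
        return 0.0
    if values[-1] > target:
        return None

    # Bracket from the scan, then bisect.
    hi_idx = next(i for i, v in enumerate(values) if v <= target)
    lo, hi = grid[hi_idx - 1], grid[hi_idx]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) <= target:
            hi = mid
        else:
            lo = mid
    return float(hi)
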