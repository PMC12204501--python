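"""Expected-cost computation on diagnostic trees.

The core recursion (BECC, back-propagation expected-cost calculation) starts
from the leaves and propagates towards the root:

    EC+_i = C_i                                   if children(n_i) is empty
    EC+_i = C_i + sum_j P_ij * EC+_j              otherwise

The root value is the expected total cost of the whole diagnostic process.
The same recursion applied to per-node turnaround times gives the expected
TAT, since expectation is linear along paths.  A stochastic cohort simulator
is provided as an independent Monte-Carlo check of the recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree_model import (
    DiagnosticTree,
    EdgeSpec,
    NodeSpec,
    PathRecord,  # noqa: F401  (re-export: path records originate here conceptually)
    enumerate_paths,
)

_ATTRIBUTES = {"cost": "cost", "tat": "tat"}


@dataclass
class CostReport:
    """Root expected cost/TAT plus the accumulated expectation at every node."""

    expected_cost: float
    expected_tat: float
    per_node_expected: dict


@dataclass
class CohortSummary:
    """Empirical summary of a simulated patient cohort."""

    n: int
    mean_cost: float
    se_cost: float
    mean_tat: float
    se_tat: float
    outcome_frequencies: dict
    leaf_counts: dict = field(repr=False, default_factory=dict)


def _postorder(tree: DiagnosticTree) -> list:
    """Node ids in leaf-to-root order (explicit stack; no recursion limit)."""
    order, stack = [], [tree.root]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(e.dst for e in tree.children(nid))
    order.reverse()
    return order


def expected_attribute(tree: DiagnosticTree, attribute: str = "cost") -> float:
    """Root expectation of one per-node attribute under the BECC recursion."""
    if attribute not in _ATTRIBUTES:
        raise ValueError(f"unknown attribute {attribute!r}; expected one of {sorted(_ATTRIBUTES)}")
    return _becc(tree, attribute)[tree.root]


def _becc(tree: DiagnosticTree, attribute: str) -> dict:
    tree.require_valid()
    acc: dict = {}
    for nid in _postorder(tree):
        node = tree.nodes[nid]
        value = getattr(node, _ATTRIBUTES[attribute])
        for e in tree.children(nid):
            value += e.prob * acc[e.dst]
        acc[nid] = value
    return acc


def becc_expected_cost(tree: DiagnosticTree) -> CostReport:
    """Expected cost (and TAT) of the process by leaf-to-root propagation."""
    per_node = _becc(tree, "cost")
    per_node_tat = _becc(tree, "tat")
    return CostReport(
        expected_cost=per_node[tree.root],
        expected_tat=per_node_tat[tree.root],
        per_node_expected=per_node,
    )


def simulate_cohort(tree: DiagnosticTree, n: int, seed) -> CohortSummary:
    """Simulate ``n`` independent root-to-leaf walks through the tree.

    Patients are propagated top-down: at each internal node the cohort
    arriving there is split among the children by a multinomial draw with the
    edge probabilities, which is distribution-identical to walking each
    patient independently edge by edge.  Reproducible for a fixed ``seed``.
    Reports cohort means of cost and TAT with Monte-Carlo standard errors and
    the frequencies of the final outcomes.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    tree.require_valid()
    rng = np.random.default_rng(seed)

    counts = {tree.root: int(n)}
    stack = [tree.root]
    while stack:
        nid = stack.pop()
        kids = tree.children(nid)
        if not kids:
            continue
        probs = np.array([e.prob for e in kids], dtype=float)
        draw = rng.multinomial(counts[nid], probs / probs.sum())
        for e, c in zip(kids, draw):
            counts[e.dst] = int(c)
            stack.append(e.dst)

    leaf_counts, costs, tats, outcomes = {}, [], [], {}
    for path in enumerate_paths(tree):
        c = counts.get(path.leaf, 0)
        leaf_counts[path.leaf] = c
        costs.append(path.cost)
        tats.append(path.tat)
        key = path.final_result.value if path.final_result else "none"
        outcomes[key] = outcomes.get(key, 0) + c

    w = np.array([leaf_counts[p.leaf] for p in enumerate_paths(tree)], dtype=float)
    costs, tats = np.array(costs), np.array(tats)

    def mean_se(x):
        mean = float(np.sum(w * x) / n)
        if n == 1:
            return mean, 0.0
        var = float(np.sum(w * (x - mean) ** 2) / (n - 1))
        return mean, float(np.sqrt(var / n))

    mean_cost, se_cost = mean_se(costs)
    mean_tat, se_tat = mean_se(tats)
    return CohortSummary(
        n=n,
        mean_cost=mean_cost,
        se_cost=se_cost,
        mean_tat=mean_tat,
        se_tat=se_tat,
        outcome_frequencies={k: v / n for k, v in sorted(outcomes.items())},
        leaf_counts=leaf_counts,
    )


def random_tree(seed=None, rng=None, max_depth: int = 6, max_children: int = 3) -> DiagnosticTree:
    """Generate a random valid diagnostic tree for property testing.

    Construction: node kinds alternate decision -> action -> result; result
    nodes continue to a decision or stop at an exit; edge probabilities are
    Dirichlet(1, ..., 1) distributed; costs and TATs are uniform.  The
    construction is fully determined by the seed, so failing cases are
    reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes, edges = {}, []
    counter = [0]

    def new_node(kind, **kw):
        counter[0] += 1
        nid = f"n{counter[0]}"
        nodes[nid] = NodeSpec(
            id=nid,
            kind=kind,
            cost=float(np.round(rng.uniform(0, 1000), 2)),
            tat=float(np.round(rng.uniform(0, 10), 1)),
            **kw,
        )
        return nid

    def grow(kind, depth):
        if kind == "exit" or depth >= max_depth:
            return new_node("exit")
        if kind == "result":
            value = "positive" if rng.random() < 0.5 else "negative"
            nid = new_node("result", result_value=value)
            child = grow("decision" if rng.random() < 0.5 else "exit", depth + 1)
            edges.append(EdgeSpec(nid, child, 1.0))
            return nid
        nid = new_node(kind)
        k = int(rng.integers(1, max_children + 1))
        probs = rng.dirichlet(np.ones(k))
        next_kind = "action" if kind == "decision" else "result"
        for j in range(k):
            child = grow(next_kind, depth + 1)
            edges.append(EdgeSpec(nid, child, float(probs[j])))
        return nid

    root = grow("decision", 0)
    tree = DiagnosticTree(nodes=nodes, edges=edges, root=root)
    tree.require_valid()
    return tree
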