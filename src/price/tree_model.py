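"""Diagnostic-tree data model: schema, validation, path enumeration, serialization.

A diagnostic process is a rooted tree ``T = (N, E)``.  Nodes are of four
kinds:

``decision``
    A clinical judgment point where the next action is chosen (an expert
    office visit; carries the expert fee and consultation turnaround time).
``action``
    Execution of a diagnostic step — taking a test, a consultation, or an
    AI prediction step in delegated workflows.
``result``
    The dichotomous outcome of a test (``positive``/``negative``) or a gate
    label produced by an AI threshold split.  Result-to-decision transitions
    are always trivial: a result node has exactly one child.
``exit``
    Termination of the diagnostic process.

Each node carries a monetary cost ``C_i`` and a turnaround time ``T_i`` in
weeks.  Each edge carries a transition probability ``P_ij``; the outgoing
probabilities of every non-leaf node sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import networkx as nx

from .exceptions import InvalidTreeError, TreeFormatError

NODE_KINDS = ("decision", "action", "result", "exit")
ACTORS = ("human", "ai")

#: Absolute tolerance for outgoing-probability sums (inputs are hand-written decimals).
PROB_SUM_TOL = 1e-9


@dataclass(frozen=True)
class NodeSpec:
    """One node of a diagnostic tree."""

    id: str
    kind: str
    actor: str = "human"
    label: str = ""
    cost: float = 0.0
    tat: float = 0.0
    result_value: Optional[str] = None
    test_ref: Optional[str] = None
    terminal: bool = False

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise TreeFormatError(f"node {self.id!r}: unknown kind {self.kind!r}")
        if self.actor not in ACTORS:
            raise TreeFormatError(f"node {self.id!r}: unknown actor {self.actor!r}")


@dataclass(frozen=True)
class EdgeSpec:
    """A directed edge with transition probability ``P_ij``."""

    src: str
    dst: str
    prob: float


@dataclass(frozen=True)
class TestPerformance:
    """Sensitivity/specificity of one diagnostic test."""

    name: str
    sensitivity: float
    specificity: float

    def __post_init__(self):
        for attr in ("sensitivity", "specificity"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise TreeFormatError(f"test {self.name!r}: {attr}={v} outside [0, 1]")


class Violation(NamedTuple):
    """One validation finding; violations are data, not exceptions."""

    node_id: str
    code: str
    message: str


class FinalResult(NamedTuple):
    """The last result observed on a root-to-leaf path."""

    value: str
    test_ref: Optional[str]


@dataclass(frozen=True)
class PathRecord:
    """One root-to-leaf trajectory with accumulated attributes.

    ``probability`` is the product of edge probabilities along the path,
    ``cost`` and ``tat`` the sums of node costs / turnaround times, and
    ``final_result`` the value and test of the last result node on the path
    (``None`` if the path reaches an exit without any result).
    """

    nodes: tuple
    probability: float
    cost: float
    tat: float
    final_result: Optional[FinalResult] = None

    @property
    def leaf(self) -> str:
        return self.nodes[-1]


@dataclass
class DiagnosticTree:
    """A validated rooted diagnostic tree plus its test-performance registry."""

    nodes: dict
    edges: list
    root: str
    tests: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._rebuild_index()

    def _rebuild_index(self):
        self._children: dict = {nid: [] for nid in self.nodes}
        for e in self.edges:
            if e.src in self._children:
                self._children[e.src].append(e)

    # -- structural helpers -------------------------------------------------

    def node(self, node_id: str) -> NodeSpec:
        return self.nodes[node_id]

    def children(self, node_id: str) -> list:
        """Outgoing edges of ``node_id`` in document order."""
        return list(self._children.get(node_id, ()))

    def is_leaf(self, node_id: str) -> bool:
        return not self._children.get(node_id)

    def subtree_ids(self, node_id: str) -> set:
        """All node ids reachable from ``node_id`` (inclusive)."""
        seen, stack = set(), [node_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                continue
            seen.add(nid)
            stack.extend(e.dst for e in self._children.get(nid, ()))
        return seen

    def validate(self) -> list:
        return validate_tree(self)

    def require_valid(self):
        violations = self.validate()
        if violations:
            raise InvalidTreeError(violations)

    def __eq__(self, other):
        if not isinstance(other, DiagnosticTree):
            return NotImplemented
        return (
            self.root == other.root
            and self.nodes == other.nodes
            and sorted(self.edges, key=lambda e: (e.src, e.dst))
            == sorted(other.edges, key=lambda e: (e.src, e.dst))
            and self.tests == other.tests
            and self.meta == other.meta
        )


# ---------------------------------------------------------------------------
# Parsing / serialization (JSON tree format)
# ---------------------------------------------------------------------------

_NODE_KEYS = {"id", "kind", "actor", "label", "cost", "tat", "result_value", "test_ref", "terminal"}


def _parse_node(raw: dict) -> NodeSpec:
    if not isinstance(raw, dict) or "id" not in raw or "kind" not in raw:
        raise TreeFormatError(f"node entry {raw!r} must be an object with 'id' and 'kind'")
    unknown = set(raw) - _NODE_KEYS
    if unknown:
        raise TreeFormatError(f"node {raw.get('id')!r}: unknown keys {sorted(unknown)}")
    return NodeSpec(
        id=str(raw["id"]),
        kind=raw["kind"],
        actor=raw.get("actor", "human"),
        label=raw.get("label", ""),
        cost=float(raw.get("cost", 0.0)),
        tat=float(raw.get("tat", 0.0)),
        result_value=raw.get("result_value"),
        test_ref=raw.get("test_ref"),
        terminal=bool(raw.get("terminal", False)),
    )


def parse_tree(document) -> DiagnosticTree:
    """Parse a JSON tree document (text, mapping, or file-like) into a tree.

    Applies all field defaults, checks schema-level constraints (duplicate
    ids, dangling edge endpoints, out-of-range probabilities), and runs full
    structural validation, raising :class:`InvalidTreeError` on violations.
    """
    if hasattr(document, "read"):
        document = document.read()
    if isinstance(document, (str, bytes)):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise TreeFormatError(f"document is not valid JSON: {exc}") from exc
    if not isinstance(document, dict):
        raise TreeFormatError("tree document must be a JSON object")
    for key in ("root", "nodes", "edges"):
        if key not in document:
            raise TreeFormatError(f"tree document missing required key {key!r}")

    nodes: dict = {}
    for raw in document["nodes"]:
        node = _parse_node(raw)
        if node.id in nodes:
            raise TreeFormatError(f"duplicate node id {node.id!r}")
        nodes[node.id] = node

    edges = []
    for raw in document["edges"]:
        if not isinstance(raw, dict) or not {"from", "to"} <= set(raw):
            raise TreeFormatError(f"edge entry {raw!r} must be an object with 'from' and 'to'")
        edges.append(EdgeSpec(src=str(raw["from"]), dst=str(raw["to"]), prob=float(raw.get("prob", 1.0))))

    tests = {}
    for name, perf in (document.get("tests") or {}).items():
        tests[name] = TestPerformance(name=name, sensitivity=float(perf["se"]), specificity=float(perf["sp"]))

    tree = DiagnosticTree(
        nodes=nodes,
        edges=edges,
        root=str(document["root"]),
        tests=tests,
        meta=dict(document.get("meta") or {}),
    )
    tree.require_valid()
    return tree


def serialize_tree(tree: DiagnosticTree) -> str:
    """Serialize a tree to its canonical JSON text.

    Output is byte-stable: UTF-8, two-space indent, sorted keys, nodes sorted
    by id and edges by (from, to).  Default-valued optional fields are
    omitted; ``parse_tree`` re-applies them, so round-trips are identities.
    """
    def node_obj(n: NodeSpec) -> dict:
        obj = {"id": n.id, "kind": n.kind, "cost": n.cost, "tat": n.tat}
        if n.actor != "human":
            obj["actor"] = n.actor
        if n.label:
            obj["label"] = n.label
        if n.result_value is not None:
            obj["result_value"] = n.result_value
        if n.test_ref is not None:
            obj["test_ref"] = n.test_ref
        if n.terminal:
            obj["terminal"] = True
        return obj

    doc = {
        "root": tree.root,
        "nodes": [node_obj(tree.nodes[nid]) for nid in sorted(tree.nodes)],
        "edges": [
            {"from": e.src, "to": e.dst, "prob": e.prob}
            for e in sorted(tree.edges, key=lambda e: (e.src, e.dst))
        ],
        "tests": {
            name: {"se": t.sensitivity, "sp": t.specificity}
            for name, t in sorted(tree.tests.items())
        },
        "meta": tree.meta,
    }
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_tree(tree: DiagnosticTree) -> list:
    """Check every structural invariant; return violations sorted by node id.

    Checked invariants: edge endpoints exist, probabilities lie in [0, 1],
    outgoing probabilities of non-leaf nodes sum to one (within 1e-9), the
    structure is a tree rooted at ``root`` (single parent, acyclic, no
    unreachable nodes), ``result_value`` present iff the node is a result,
    exits have no outgoing edges, results have exactly one child (or are
    flagged terminal leaves), every leaf is an exit or terminal result, and
    costs/TATs are non-negative.
    """
    out: list = []

    def add(node_id, code, message):
        out.append(Violation(str(node_id), code, message))

    if tree.root not in tree.nodes:
        add(tree.root, "missing-root", "root id does not name a node")
        return sorted(out)

    for e in tree.edges:
        if e.src not in tree.nodes:
            add(e.src, "dangling-edge", f"edge source {e.src!r} is not a node")
        if e.dst not in tree.nodes:
            add(e.dst, "dangling-edge", f"edge target {e.dst!r} is not a node")
        if not 0.0 <= e.prob <= 1.0:
            add(e.src, "prob-range", f"edge {e.src!r}->{e.dst!r} has prob {e.prob} outside [0, 1]")

    g = nx.DiGraph()
    g.add_nodes_from(tree.nodes)
    g.add_edges_from((e.src, e.dst) for e in tree.edges if e.src in tree.nodes and e.dst in tree.nodes)

    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        add(cyc[0][0], "cycle", "cycle detected: " + " -> ".join(a for a, _ in cyc))
    else:
        reachable = {tree.root} | nx.descendants(g, tree.root)
        for nid in tree.nodes:
            if nid not in reachable:
                add(nid, "unreachable", "node is not reachable from the root")

    for nid, deg in g.in_degree():
        if nid == tree.root:
            if deg > 0:
                add(nid, "root-parent", "root node has an incoming edge")
        elif deg == 0:
            add(nid, "orphan", "non-root node has no parent")
        elif deg > 1:
            add(nid, "multi-parent", f"node has {deg} parents; the structure must be a tree")

    seen_pairs = set()
    for e in tree.edges:
        if (e.src, e.dst) in seen_pairs:
            add(e.src, "duplicate-edge", f"duplicate edge {e.src!r}->{e.dst!r}")
        seen_pairs.add((e.src, e.dst))

    for nid, node in tree.nodes.items():
        if node.cost < 0:
            add(nid, "negative-cost", f"cost {node.cost} < 0")
        if node.tat < 0:
            add(nid, "negative-tat", f"tat {node.tat} < 0")
        if (node.result_value is not None) != (node.kind == "result"):
            add(nid, "result-value", "result_value must be present iff kind is 'result'")
        if node.test_ref is not None and node.test_ref not in tree.tests:
            add(nid, "unknown-test", f"test_ref {node.test_ref!r} not in the test registry")

        kids = tree.children(nid)
        if node.kind == "exit" and kids:
            add(nid, "exit-outgoing", "exit nodes must have no outgoing edges")
        if kids:
            total = sum(e.prob for e in kids)
            if abs(total - 1.0) > PROB_SUM_TOL:
                add(nid, "prob-sum", f"outgoing probabilities sum to {total!r}, expected 1")
            if node.kind == "result" and len(kids) > 1:
                add(nid, "non-trivial-result",
                    "result-to-decision transitions are trivial: a result node must have exactly one child")
        else:
            ok_leaf = node.kind == "exit" or (node.kind == "result" and node.terminal)
            if not ok_leaf:
                add(nid, "bad-leaf", "every leaf must be an exit node or a terminal result node")

    return sorted(out, key=lambda v: (v.node_id, v.code))


# ---------------------------------------------------------------------------
# Path enumeration
# ---------------------------------------------------------------------------

def enumerate_paths(tree: DiagnosticTree) -> list:
    """All root-to-leaf paths with probability, accumulated cost and TAT.

    The probability of a path is the product of its edge probabilities; cost
    and TAT are sums of node attributes along the path (the TAT of an exit
    state is the turnaround accumulated across every ancestor node).  Path
    probabilities sum to one for a valid tree.  Paths of probability zero
    (dead branches) are retained.
    """
    tree.require_valid()
    records: list = []

    root = tree.nodes[tree.root]
    stack = [((tree.root,), 1.0, root.cost, root.tat,
              FinalResult(root.result_value, root.test_ref) if root.kind == "result" else None)]
    while stack:
        path, prob, cost, tat, final = stack.pop()
        kids = tree.children(path[-1])
        if not kids:
            records.append(PathRecord(nodes=path, probability=prob, cost=cost, tat=tat, final_result=final))
            continue
        for e in reversed(kids):
            child = tree.nodes[e.dst]
            child_final = (FinalResult(child.result_value, child.test_ref)
                           if child.kind == "result" else final)
            stack.append((path + (e.dst,), prob * e.prob, cost + child.cost, tat + child.tat, child_final))
    return records
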