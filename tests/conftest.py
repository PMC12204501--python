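import pytest

from price import (
    CaseStudyParameters,
    DiagnosticTree,
    EdgeSpec,
    NodeSpec,
    build_scenario,
    default_utility_params,
)


def make_tree(nodes, edges, root, tests=None, meta=None):
    return DiagnosticTree(
        nodes={n.id: n for n in nodes},
        edges=list(edges),
        root=root,
        tests=tests or {},
        meta=meta or {},
    )


@pytest.fixture
def oracle_tree():
    """decision(165) -> action(825) -> {pos 0.1 -> exit, neg 0.9 -> decision(165) -> exit}.

    Hand-enumerable: two paths, (p=0.1, cost=990) and (p=0.9, cost=1155),
    so the expected cost is 0.1*990 + 0.9*1155 = 1138.5.
    """
    nodes = [
        NodeSpec("d1", "decision", cost=165.0),
        NodeSpec("a1", "action", cost=825.0),
        NodeSpec("rp", "result", result_value="positive"),
        NodeSpec("rn", "result", result_value="negative"),
        NodeSpec("d2", "decision", cost=165.0),
        NodeSpec("x1", "exit"),
        NodeSpec("x2", "exit"),
    ]
    edges = [
        EdgeSpec("d1", "a1", 1.0),
        EdgeSpec("a1", "rp", 0.1),
        EdgeSpec("a1", "rn", 0.9),
        EdgeSpec("rp", "x1", 1.0),
        EdgeSpec("rn", "d2", 1.0),
        EdgeSpec("d2", "x2", 1.0),
    ]
    return make_tree(nodes, edges, "d1")


@pytest.fixture(scope="session")
def case_params():
    return CaseStudyParameters()


@pytest.fixture(scope="session")
def utility(case_params):
    return default_utility_params(params=case_params)


@pytest.fixture(scope="session")
def scenario_trees(case_params):
    return {s: build_scenario(s, case_params) for s in (1, 2, 3, 4)}
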