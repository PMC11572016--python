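"""DAG construction, d-separation, and empirical association checks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from collidersim import (
    Dag,
    SeparationVerdict,
    build_study_dag,
    d_separated,
    diagnose_selection,
    empirical_association,
)
from collidersim.dag import read_edgelist, to_dot, write_edgelist
from collidersim.scm import Scenario, default_params, generate_batch, survival_mask


# ---------------------------------------------------------------- construction

def test_study_dag_edge_sets():
    null = build_study_dag(include_treatment_effect=False)
    assert null.nodes == {"A", "W", "S", "L", "Y"}
    assert null.edges == {("A", "W"), ("L", "W"), ("L", "Y"), ("W", "S")}
    full = build_study_dag(include_treatment_effect=True)
    assert full.edges == null.edges | {("A", "Y")}


def test_dag_rejects_cycles_self_loops_duplicates():
    dag = Dag(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")])
    with pytest.raises(ValueError, match="cycle"):
        dag.add_edge("Z", "X")
    assert dag.edges == {("X", "Y"), ("Y", "Z")}  # rollback on failure
    with pytest.raises(ValueError, match="self-loop"):
        dag.add_edge("X", "X")
    with pytest.raises(ValueError, match="duplicate"):
        dag.add_edge("X", "Y")
    with pytest.raises(KeyError):
        dag.add_edge("X", "Q")


def test_verdict_consistency_enforced():
    with pytest.raises(ValueError):
        SeparationVerdict(separated=True, witness_paths=(("A", "W", "Y"),))


# -------------------------------------------------------------- study verdicts

def test_collider_path_closed_unconditionally():
    """Null model: randomization leaves A and Y d-separated."""
    verdict = d_separated(build_study_dag(), "A", "Y", set())
    assert verdict.separated and verdict


def test_conditioning_on_survival_opens_collider_path():
    verdict = d_separated(build_study_dag(), "A", "Y", {"S"})
    assert not verdict.separated
    assert ("A", "W", "L", "Y") in verdict.witness_paths


def test_adjusting_for_initial_volume_recloses_path():
    assert d_separated(build_study_dag(), "A", "Y", {"S", "L"}).separated


def test_d_separated_query_validation():
    dag = build_study_dag()
    with pytest.raises(KeyError):
        d_separated(dag, "A", "Q", set())
    with pytest.raises(ValueError):
        d_separated(dag, "A", "Y", {"A"})
    with pytest.raises(ValueError):
        d_separated(dag, "A", "A", set())


def test_diagnose_selection_on_study_dag():
    dag = build_study_dag(include_treatment_effect=True)
    assert not diagnose_selection(dag, "A", "Y", "S").separated  # biased
    assert diagnose_selection(dag, "A", "Y", "S", adjustment={"L"}).separated
    chain = Dag(["X", "M", "Y", "S"], [("X", "M"), ("M", "Y"), ("X", "S")])
    assert diagnose_selection(chain, "X", "Y", "S").separated  # no collider anywhere


# ------------------------------------------------- equivalence on random DAGs

def _moralized_separation(g: nx.DiGraph, x: str, y: str, given: frozenset) -> bool:
    """Independent oracle: ancestral subgraph, moralize, drop Z, check reachability."""
    keep = set(given) | {x, y}
    ancestral = set(keep)
    for node in keep:
        ancestral |= nx.ancestors(g, node)
    sub = g.subgraph(ancestral)
    moral = nx.Graph(sub.to_undirected())
    for node in sub.nodes:
        for u, v in itertools.combinations(sorted(sub.predecessors(node)), 2):
            moral.add_edge(u, v)
    moral.remove_nodes_from(given)
    return not (x in moral and y in moral and nx.has_path(moral, x, y))


def _random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float) -> nx.DiGraph:
    nodes = [f"v{i}" for i in range(n_nodes)]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i, j in itertools.combinations(range(n_nodes), 2):  # i<j: acyclic by order
        if rng.random() < p_edge:
            g.add_edge(nodes[i], nodes[j])
    return g


def test_d_separation_agrees_with_independent_oracles(rng):
    """Path enumeration vs moralization vs networkx on 200 random small DAGs."""
    checked = 0
    for _ in range(200):
        n_nodes = int(rng.integers(3, 8))
        g = _random_dag(rng, n_nodes, p_edge=float(rng.uniform(0.15, 0.6)))
        dag = Dag(g.nodes, g.edges)
        nodes = sorted(g.nodes)
        for x, y in itertools.combinations(nodes, 2):
            rest = [v for v in nodes if v not in (x, y)]
            subsets = [frozenset()] + [
                frozenset(c) for r in range(1, len(rest) + 1) for c in itertools.combinations(rest, r)
            ]
            for given in subsets[:: max(1, len(subsets) // 8)]:  # thinned but seeded
                ours = d_separated(dag, x, y, given).separated
                assert ours == _moralized_separation(g, x, y, given)
                assert ours == nx.is_d_separator(g, {x}, {y}, set(given))
                checked += 1
    assert checked > 1000


# ----------------------------------------------------------------- file formats

def test_edgelist_round_trip(tmp_path):
    dag = build_study_dag(include_treatment_effect=True)
    path = tmp_path / "study.dag"
    write_edgelist(dag, path)
    again = read_edgelist(path)
    assert again.nodes == dag.nodes and again.edges == dag.edges


def test_edgelist_parses_comments_and_isolated_nodes(tmp_path):
    path = tmp_path / "g.dag"
    path.write_text("# a comment\nA W  # trailing\nZ\nL W\n")
    dag = read_edgelist(path)
    assert dag.nodes == {"A", "W", "L", "Z"}
    assert dag.edges == {("A", "W"), ("L", "W")}
    path.write_text("A W extra\n")
    with pytest.raises(ValueError, match="expected"):
        read_edgelist(path)


def test_dot_output_marks_conditioned_nodes():
    dot = to_dot(build_study_dag(), highlight={"S"})
    assert '"S" [shape=box];' in dot
    assert '"A" -> "W";' in dot


# --------------------------------------------------------- empirical agreement

@pytest.fixture(scope="module")
def pooled_data():
    """10^5 animals under major side effects with median-welfare censoring."""
    rng = np.random.default_rng(19)
    scenario = Scenario(n_total=100, gamma1=-6.0, attrition_q=0.5)
    A, L, W, Y = generate_batch(scenario, default_params(-6.0), rng, reps=1000)
    survive = survival_mask(W, 0.5)
    return pd.DataFrame(
        {
            "arm": np.tile(A, 1000),
            "initial_volume_mm3": L.ravel(),
            "welfare": W.ravel(),
            "final_volume_mm3": Y.ravel(),
            "survived": survive.ravel().astype(int),
        }
    )


def test_randomization_gives_null_arm_volume_association(pooled_data):
    r, se = empirical_association(pooled_data, "arm", "initial_volume_mm3")
    assert abs(r) < 3 * se


def test_survivor_restriction_induces_negative_association(pooled_data):
    r, se = empirical_association(
        pooled_data, "arm", "initial_volume_mm3", restrict_to_survivors=True
    )
    assert r < -3 * se


def test_adjustment_closes_the_open_path(pooled_data):
    r_open, se_open = empirical_association(
        pooled_data, "arm", "final_volume_mm3", restrict_to_survivors=True
    )
    assert r_open < -3 * se_open  # collider bias visible in survivors
    r_adj, se_adj = empirical_association(
        pooled_data, "arm", "final_volume_mm3",
        given=["initial_volume_mm3"], restrict_to_survivors=True,
    )
    assert abs(r_adj) < 3 * se_adj


def test_faithfulness_of_graph_verdicts(pooled_data):
    """d-separation verdicts match zero/non-zero partial correlations in the data."""
    dag = build_study_dag()
    column = {
        "A": "arm", "L": "initial_volume_mm3", "W": "welfare", "Y": "final_volume_mm3",
    }
    queries = [
        ("A", "L", (), False),
        ("A", "W", (), False),
        ("L", "Y", (), False),
        ("W", "Y", (), False),
        ("A", "Y", (), False),
        ("W", "Y", ("L",), False),
        ("A", "Y", ("W",), False),
        ("A", "L", (), True),   # restriction = conditioning on S
        ("A", "Y", (), True),
        ("A", "Y", ("L",), True),
    ]
    for x, y, given, restrict in queries:
        cond = set(given) | ({"S"} if restrict else set())
        separated = d_separated(dag, x, y, cond).separated
        r, se = empirical_association(
            pooled_data, column[x], column[y],
            given=[column[g] for g in given], restrict_to_survivors=restrict,
        )
        assert (abs(r) < 3 * se) == separated, (x, y, cond, r, se)


def test_empirical_association_input_validation(pooled_data):
    with pytest.raises(ValueError, match="constant"):
        empirical_association(
            pooled_data.assign(const=1.0), "arm", "welfare", given=["const"]
        )
    with pytest.raises(ValueError, match="too small"):
        empirical_association(pooled_data.head(100), "arm", "welfare")
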