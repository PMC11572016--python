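"""Causal diagrams and d-separation for selection-bias diagnosis.

The study DAG has five nodes: treatment ``A``, welfare ``W``, survival
``S``, initial infarct volume ``L`` and final infarct volume ``Y``, with
edges ``A→W``, ``L→W``, ``L→Y``, ``W→S`` (and optionally ``A→Y``).
``W`` is a collider on ``A→W←L→Y``: unconditionally the path is blocked
and randomization makes ``A ⊥ Y`` under the null; conditioning on the
collider's child ``S`` (analyzing survivors only) opens it, inducing a
spurious treatment–outcome association; additionally conditioning on
``L`` closes it again, which is why covariate adjustment for the initial
volume removes the selection bias.

``d_separated`` enumerates every undirected path between the query nodes
and applies the standard blocking rules, returning the open paths as
witnesses when separation fails. Exhaustive enumeration is exponential in
principle but the graphs of interest have a handful of nodes; tests check
it against an independent moralization-based oracle on random DAGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Dag",
    "SeparationVerdict",
    "build_study_dag",
    "d_separated",
    "diagnose_selection",
    "empirical_association",
    "read_edgelist",
    "write_edgelist",
    "to_dot",
]


class Dag:
    """Labelled directed acyclic graph supporting separation queries.

    Validates acyclicity, declared endpoints, and the absence of
    self-loops and duplicate edges on construction and on every edge
    insertion.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self._g = nx.DiGraph()
        self._g.add_nodes_from(nodes)
        for parent, child in edges:
            self.add_edge(parent, child)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._g.edges)

    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    def add_edge(self, parent: str, child: str) -> None:
        if parent not in self._g or child not in self._g:
            raise KeyError(f"edge endpoints must be declared nodes: {parent!r} -> {child!r}")
        if parent == child:
            raise ValueError(f"self-loop {parent!r} -> {child!r} not allowed")
        if self._g.has_edge(parent, child):
            raise ValueError(f"duplicate edge {parent!r} -> {child!r}")
        self._g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(self._g):
            self._g.remove_edge(parent, child)
            raise ValueError(f"edge {parent!r} -> {child!r} would create a directed cycle")

    def remove_edge(self, parent: str, child: str) -> None:
        self._g.remove_edge(parent, child)

    def parents(self, node: str) -> set[str]:
        return set(self._g.predecessors(node))

    def children(self, node: str) -> set[str]:
        return set(self._g.successors(node))

    def descendants(self, node: str) -> set[str]:
        return nx.descendants(self._g, node)

    def copy(self) -> "Dag":
        return Dag(self.nodes, self.edges)

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __repr__(self) -> str:
        return f"Dag(nodes={sorted(self._g.nodes)}, edges={sorted(self._g.edges)})"


@dataclass(frozen=True)
class SeparationVerdict:
    """Outcome of a d-separation query; open paths listed when not separated."""

    separated: bool
    witness_paths: tuple[tuple[str, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.separated != (len(self.witness_paths) == 0):
            raise ValueError("separated must hold exactly when no witness path exists")

    def __bool__(self) -> bool:
        return self.separated


def build_study_dag(include_treatment_effect: bool = False) -> Dag:
    """The five-node attrition DAG.

    Always contains ``A→W``, ``L→W``, ``L→Y``, ``W→S``. The direct
    treatment effect ``A→Y`` is included only on request: the simulated
    null model omits it (``beta1 = 0``), while the diagram a researcher
    interrogates for identifiability includes it.
    """
    edges = [("A", "W"), ("L", "W"), ("L", "Y"), ("W", "S")]
    if include_treatment_effect:
        edges.append(("A", "Y"))
    return Dag(nodes=["A", "W", "S", "L", "Y"], edges=edges)


def _path_blocked(dag: Dag, path: Sequence[str], given: frozenset[str]) -> bool:
    """Blocking rules along one undirected path.

    A chain or fork is blocked iff its middle node is conditioned on; a
    collider is blocked iff neither it nor any of its descendants is.
    """
    for i in range(1, len(path) - 1):
        prev, mid, nxt = path[i - 1], path[i], path[i + 1]
        into_mid_left = (prev, mid) in dag.edges
        into_mid_right = (nxt, mid) in dag.edges
        if into_mid_left and into_mid_right:  # collider
            if mid not in given and not (dag.descendants(mid) & given):
                return True
        else:  # chain or fork
            if mid in given:
                return True
    return False


def d_separated(dag: Dag, x: str, y: str, given: Iterable[str] = ()) -> SeparationVerdict:
    """Decide d-separation of ``x`` and ``y`` given a conditioning set.

    Enumerates all simple undirected paths between ``x`` and ``y`` and
    applies the blocking rules; any unblocked path is returned as a
    witness, so a non-separated verdict carries the concrete open paths
    (e.g. the collider path ``A→W←L→Y`` once ``S`` is conditioned on).
    """
    given = frozenset(given)
    for node in (x, y, *given):
        if node not in dag:
            raise KeyError(f"unknown node {node!r}")
    if x == y:
        raise ValueError("query nodes must be distinct")
    if x in given or y in given:
        raise ValueError("query nodes must not be in the conditioning set")
    skeleton = dag.to_networkx().to_undirected()
    open_paths = tuple(
        tuple(path)
        for path in nx.all_simple_paths(skeleton, x, y)
        if not _path_blocked(dag, path, given)
    )
    return SeparationVerdict(separated=not open_paths, witness_paths=open_paths)


def diagnose_selection(
    dag: Dag,
    exposure: str,
    outcome: str,
    selection: str,
    adjustment: Iterable[str] = (),
) -> SeparationVerdict:
    """Is an analysis restricted to one selection stratum biased?

    Asks whether any *non-causal* path between exposure and outcome is
    open once the selection node joins the conditioning set. Open paths
    that are directed causal routes from exposure to outcome (the direct
    edge or mediated chains) are the effect being estimated, not bias,
    and are excluded from the verdict. A non-separated verdict means the
    selected-sample analysis with that adjustment is biased; the witness
    paths name the open non-causal routes.
    """
    if selection not in dag:
        raise KeyError(f"unknown selection node {selection!r}")
    verdict = d_separated(dag, exposure, outcome, set(adjustment) | {selection})
    non_causal = tuple(
        path
        for path in verdict.witness_paths
        if not all((path[i], path[i + 1]) in dag.edges for i in range(len(path) - 1))
    )
    return SeparationVerdict(separated=not non_causal, witness_paths=non_causal)


def empirical_association(
    data,
    x: str,
    y: str,
    given: Iterable[str] = (),
    restrict_to_survivors: bool = False,
    survival_column: str = "survived",
) -> tuple[float, float]:
    """Sample partial correlation of two variables in pooled cohort data.

    ``data`` is a tidy per-animal table (anything accepted by
    ``pandas.DataFrame``). Conditioning is by linear residualization on
    the ``given`` columns; survival restriction (``S = 1``) is applied by
    subsetting, matching how a complete-case analysis conditions on
    survival. Returns ``(r, se)`` with the large-sample standard error
    ``1/sqrt(n - k - 3)`` for ``k`` conditioning variables.
    """
    import pandas as pd

    frame = pd.DataFrame(data)
    if restrict_to_survivors:
        frame = frame[frame[survival_column] == 1]
    given = list(given)
    n = len(frame)
    k = len(given)
    if n < 10 ** 3:
        raise ValueError(f"pooled sample too small for a stable partial correlation: n={n}")
    xv = frame[x].to_numpy(dtype=float)
    yv = frame[y].to_numpy(dtype=float)
    if given:
        Z = frame[given].to_numpy(dtype=float)
        if np.any(Z.std(axis=0) == 0):
            constant = [g for g, s in zip(given, Z.std(axis=0)) if s == 0]
            raise ValueError(f"conditioning variable(s) constant in sample: {constant}")
        Z = np.column_stack([np.ones(n), Z])
        xv = xv - Z @ np.linalg.lstsq(Z, xv, rcond=None)[0]
        yv = yv - Z @ np.linalg.lstsq(Z, yv, rcond=None)[0]
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("degenerate input: a query variable is constant (after residualization)")
    r = float(np.corrcoef(xv, yv)[0, 1])
    se = 1.0 / math.sqrt(n - k - 3)
    return r, se


def read_edgelist(path) -> Dag:
    """Read a DAG from a whitespace-separated edge list (``#`` comments)."""
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) == 1:  # isolated node
                nodes.append(parts[0])
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'parent child', got {line!r}")
            nodes.extend(parts)
            edges.append((parts[0], parts[1]))
    return Dag(dict.fromkeys(nodes), edges)


def write_edgelist(dag: Dag, path) -> None:
    """Write a DAG as a whitespace-separated edge list."""
    with open(path, "w") as handle:
        for node in sorted(dag.nodes - {n for e in dag.edges for n in e}):
            handle.write(f"{node}\n")
        for parent, child in sorted(dag.edges):
            handle.write(f"{parent} {child}\n")


def to_dot(dag: Dag, highlight: Iterable[str] = ()) -> str:
    """DOT-format rendering; nodes in ``highlight`` are drawn boxed."""
    highlight = set(highlight)
    lines = ["digraph dag {"]
    for node in sorted(dag.nodes):
        shape = "box" if node in highlight else "ellipse"
        lines.append(f'  "{node}" [shape={shape}];')
    for parent, child in sorted(dag.edges):
        lines.append(f'  "{parent}" -> "{child}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
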