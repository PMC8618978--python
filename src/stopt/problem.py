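"""Optimization problem definition and partitioning into independent groups.

A problem consists of *parameters* (each with a closed input domain
``[c, d]`` to search), *metrics* (each with a closed target range
``[a, b]`` its replicate-averaged value must reach), and a bipartite
dependency graph recording which metrics are functions of which
parameters.  Connected components of that graph are *groups*: a group's
metrics depend only on the group's parameters, so groups can be
optimized independently and simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from ._rng import name_key

__all__ = [
    "Parameter",
    "Metric",
    "DependencyGraph",
    "Group",
    "Problem",
    "validate_problem",
    "partition_groups",
]


@dataclass(frozen=True)
class Parameter:
    """A tunable parameter with its input domain ``[c, d]`` (``c < d``).

    Units are problem-specific: for MCMC move sizes typically Angstroms
    (translations) or radians (rotations).
    """

    name: str
    domain: tuple[float, float]

    @property
    def lower(self) -> float:
        return self.domain[0]

    @property
    def upper(self) -> float:
        return self.domain[1]

    @property
    def width(self) -> float:
        return self.domain[1] - self.domain[0]


@dataclass(frozen=True)
class Metric:
    """A noisy objective with its closed target range ``[a, b]`` (``a <= b``).

    A solution requires the replicate-averaged metric value to lie inside
    the target range; both boundaries count as inside.
    """

    name: str
    target: tuple[float, float]

    def contains(self, value: float) -> bool:
        a, b = self.target
        return a <= value <= b


@dataclass(frozen=True)
class DependencyGraph:
    """Bipartite parameter->metric edges: ``(p, m)`` means metric ``m`` is a
    function of parameter ``p``."""

    edges: frozenset[tuple[str, str]]

    def __init__(self, edges: Iterable[tuple[str, str]]):
        object.__setattr__(self, "edges", frozenset((str(p), str(m)) for p, m in edges))

    def parameters_of(self, metric: str) -> set[str]:
        return {p for p, m in self.edges if m == metric}

    def metrics_of(self, parameter: str) -> set[str]:
        return {m for p, m in self.edges if p == parameter}


@dataclass(frozen=True)
class Group:
    """A maximally connected component of the dependency graph.

    ``parameters`` and ``metrics`` are sorted by name; ``index`` is the
    group's position in the deterministic group ordering (by smallest
    parameter name).
    """

    index: int
    parameters: tuple[Parameter, ...]
    metrics: tuple[Metric, ...]

    @property
    def n(self) -> int:
        """Number of parameters (the dimensionality of the group's root search)."""
        return len(self.parameters)

    @property
    def k(self) -> int:
        """Number of metrics."""
        return len(self.metrics)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.metrics)

    def stream_key(self) -> int:
        """Stable random-stream key: depends only on the group's own parameter
        names, so the group's noise streams do not change when other groups
        are added to or removed from the problem."""
        return name_key(*sorted(self.parameter_names))


@dataclass
class Problem:
    """A full optimization problem: parameters, metrics and their dependency graph."""

    parameters: list[Parameter]
    metrics: list[Metric]
    graph: DependencyGraph
    name: str = "problem"

    def parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def metric(self, name: str) -> Metric:
        for m in self.metrics:
            if m.name == name:
                return m
        raise KeyError(name)

    def groups(self) -> list[Group]:
        return partition_groups(self.graph, self.parameters, self.metrics)


def validate_problem(problem: Problem) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the problem is well formed.  Violations are
    returned (not raised) so a config loader can report all of them at
    once.
    """
    violations: list[str] = []
    pnames = [p.name for p in problem.parameters]
    mnames = [m.name for m in problem.metrics]

    if not problem.parameters:
        violations.append("problem declares no parameters")
    if not problem.metrics:
        violations.append("problem declares no metrics")

    seen: set[str] = set()
    for n in pnames:
        if n in seen:
            violations.append(f"duplicate parameter name {n!r}")
        seen.add(n)
    seen = set()
    for n in mnames:
        if n in seen:
            violations.append(f"duplicate metric name {n!r}")
        seen.add(n)
    if set(pnames) & set(mnames):
        for n in sorted(set(pnames) & set(mnames)):
            violations.append(f"name {n!r} used for both a parameter and a metric")

    for p in problem.parameters:
        c, d = p.domain
        if not (c < d):
            violations.append(
                f"parameter {p.name!r} has degenerate or reversed domain [{c}, {d}] (need c < d)"
            )
    for m in problem.metrics:
        a, b = m.target
        if not (a <= b):
            violations.append(
                f"metric {m.name!r} has reversed target range [{a}, {b}] (need a <= b)"
            )

    pset, mset = set(pnames), set(mnames)
    for p, m in sorted(problem.graph.edges):
        if p not in pset:
            violations.append(f"edge references undeclared parameter {p!r}")
        if m not in mset:
            violations.append(f"edge references undeclared metric {m!r}")

    linked_p = {p for p, _ in problem.graph.edges}
    linked_m = {m for _, m in problem.graph.edges}
    for n in pnames:
        if n not in linked_p:
            violations.append(f"parameter {n!r} influences no metric (orphan parameter)")
    for n in mnames:
        if n not in linked_m:
            violations.append(f"metric {n!r} depends on no parameter (orphan metric)")

    return violations


def partition_groups(
    graph: DependencyGraph,
    parameters: Sequence[Parameter],
    metrics: Sequence[Metric],
) -> list[Group]:
    """Partition parameters and metrics into maximally connected groups.

    Groups are the connected components of the bipartite dependency
    graph.  The returned list is ordered by each group's smallest
    parameter name; within a group, parameters and metrics are sorted by
    name.  Raises ``ValueError`` on orphan parameters or metrics (every
    declared element must carry at least one edge).
    """
    pmap = {p.name: p for p in parameters}
    mmap = {m.name: m for m in metrics}

    linked_p = {p for p, _ in graph.edges}
    linked_m = {m for _, m in graph.edges}
    orphan_p = sorted(set(pmap) - linked_p)
    orphan_m = sorted(set(mmap) - linked_m)
    if orphan_p or orphan_m:
        raise ValueError(
            f"cannot partition: orphan parameters {orphan_p}, orphan metrics {orphan_m}"
        )
    unknown = [(p, m) for p, m in graph.edges if p not in pmap or m not in mmap]
    if unknown:
        raise ValueError(f"edges reference undeclared names: {sorted(unknown)}")

    g = nx.Graph()
    g.add_nodes_from(("p", n) for n in pmap)
    g.add_nodes_from(("m", n) for n in mmap)
    g.add_edges_from((("p", p), ("m", m)) for p, m in graph.edges)

    comps = []
    for comp in nx.connected_components(g):
        ps = sorted(n for kind, n in comp if kind == "p")
        ms = sorted(n for kind, n in comp if kind == "m")
        comps.append((ps, ms))
    comps.sort(key=lambda c: c[0][0])

    return [
        Group(
            index=i,
            parameters=tuple(pmap[n] for n in ps),
            metrics=tuple(mmap[n] for n in ms),
        )
        for i, (ps, ms) in enumerate(comps)
    ]
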