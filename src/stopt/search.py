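"""m-ary grid search with depth-first refinement of feasible ranges.

The search for one group proceeds as a depth-first branch-and-bound over
sub-intervals of the parameter domains:

* The **root** node samples a full ``m(n)^n`` grid over the group's
  parameter box, with ``m`` equally spaced values per axis *including*
  both domain endpoints.
* A **feasible range** is an interval between two axis-adjacent grid
  points whose metric values, for every metric of the group, span an
  interval that intersects the metric's target range.  By the
  intermediate value theorem a continuous noiseless metric must cross
  the target band inside such an interval.
* Each feasible range becomes a child node.  A child samples ``m`` new
  *strictly interior* points (the interval endpoints were evaluated at
  the parent and are inherited), splitting the range into ``m + 1``
  sub-intervals.  Selecting one of them therefore rejects ``m/(m+1)`` of
  the range per level, while the root level rejects ``(m-2)/(m-1)`` of
  the domain.
* Children are visited in descending order of a spline-interpolation
  score: each metric is interpolated along the range's grid line and the
  score is the fraction of 100 equally spaced query points at which all
  interpolated metrics lie in their target bands.  Ties preserve
  discovery (lexicographic grid) order.
* A node whose candidate points include a point with every
  replicate-averaged metric inside its target band ends the group search
  in **success**.  A node fails when it yields no feasible ranges or sits
  at the maximum depth; the search then backtracks (depth-first) and
  fails overall once every node is resolved.

The depth cap bounds the runtime and stops noise-induced misclassified
ranges from being refined forever.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline

from ._rng import derive_rng, name_key
from .problem import Group

__all__ = [
    "NodeStatus",
    "CandidatePoint",
    "FeasibleRange",
    "SearchNode",
    "DFSTree",
    "SearchSettings",
    "GroupSearch",
    "generate_root_grid",
    "generate_child_points",
    "is_solution",
    "find_feasible_ranges",
    "prioritize_ranges",
    "expand_node",
    "run_group_search",
]


class NodeStatus(str, Enum):
    PENDING = "pending"
    EXPLORING = "exploring"
    SUCCESS = "success"
    FAILED_NO_RANGES = "failed-no-ranges"
    FAILED_MAX_DEPTH = "failed-max-depth"
    FAILED_CHILDREN = "failed-children"  # expanded, but every child subtree failed


@dataclass
class SearchSettings:
    """Branching factors, depth cap and prioritization resolution.

    ``m_table`` maps a group dimensionality ``n`` to the per-axis number
    of candidate points ``m(n) >= 2``.  ``max_depth`` caps the DFS depth
    (root = 0).  ``interp_points`` is the number of spline query points
    used to score feasible ranges.
    """

    m_table: Mapping[int, int]
    max_depth: int = 5
    interp_points: int = 100

    def __post_init__(self):
        for n, m in self.m_table.items():
            if m < 2:
                raise ValueError(f"m({n}) = {m}, but m must be >= 2")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")

    def m(self, n: int) -> int:
        try:
            return int(self.m_table[n])
        except KeyError:
            raise KeyError(
                f"m(n) is undefined for n = {n}; configured table: {dict(self.m_table)}"
            ) from None


@dataclass
class CandidatePoint:
    """A parameter vector being explored, with its replicate bookkeeping.

    ``grid_index`` locates the point on its node's grid (root: one index
    per axis; deeper nodes: a single index along the varied axis).
    ``averaged`` holds the replicate-averaged metric values once the
    point is explored.
    """

    coordinates: dict[str, float]
    grid_index: tuple[int, ...]
    index: int  # flat position within the node's candidate list
    replicates: dict[str, list[float]] = field(default_factory=dict)
    averaged: dict[str, float] | None = None

    @property
    def explored(self) -> bool:
        return self.averaged is not None

    def add_replicate(self, values: Mapping[str, float]) -> None:
        for name, v in values.items():
            self.replicates.setdefault(name, []).append(float(v))

    def replicate_count(self) -> int:
        if not self.replicates:
            return 0
        return min(len(v) for v in self.replicates.values())

    def finalize(self) -> None:
        self.averaged = {name: float(np.mean(v)) for name, v in self.replicates.items()}


@dataclass
class FeasibleRange:
    """A sub-interval along one axis that may contain a solution.

    ``axis`` is the varied parameter; ``anchor`` fixes the group's other
    parameters at previously evaluated candidate values.  ``support``
    holds the evaluated (coordinate, metric-values) points along the
    range's grid line, used for spline prioritization and for inheriting
    the endpoint values into the child node.  ``score`` is the
    prioritization score in [0, 1].
    """

    axis: str
    bounds: tuple[float, float]
    anchor: dict[str, float]
    support: list[tuple[float, dict[str, float]]] = field(default_factory=list)
    score: float = float("nan")

    def endpoint_values(self) -> dict[float, dict[str, float]]:
        sup = dict(self.support)
        return {self.bounds[0]: sup[self.bounds[0]], self.bounds[1]: sup[self.bounds[1]]}


@dataclass
class SearchNode:
    """One DFS node: the root box or a feasible range plus its candidates."""

    node_id: int
    depth: int
    feasible_range: FeasibleRange | None  # None for the root
    candidates: list[CandidatePoint] = field(default_factory=list)
    children: list["SearchNode"] = field(default_factory=list)
    status: NodeStatus = NodeStatus.PENDING
    parent: "SearchNode | None" = field(default=None, repr=False)

    @property
    def is_root(self) -> bool:
        return self.feasible_range is None

    def unexplored(self) -> list[CandidatePoint]:
        return [c for c in self.candidates if not c.explored]

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "depth": self.depth,
            "status": self.status.value,
            "candidates": [
                {
                    "coordinates": c.coordinates,
                    "grid_index": list(c.grid_index),
                    "averaged": c.averaged,
                }
                for c in self.candidates
            ],
            "children": [ch.to_dict() for ch in self.children],
        }
        if self.feasible_range is not None:
            fr = self.feasible_range
            d["range"] = {
                "axis": fr.axis,
                "bounds": list(fr.bounds),
                "anchor": fr.anchor,
                "score": None if np.isnan(fr.score) else fr.score,
            }
        return d


@dataclass
class DFSTree:
    """The complete search tree of one group, with its visiting-order log."""

    root: SearchNode
    visit_log: list[int] = field(default_factory=list)
    solution: CandidatePoint | None = None
    solution_depth: int | None = None

    def nodes(self) -> list[SearchNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def to_dict(self) -> dict:
        return {
            "visit_log": list(self.visit_log),
            "solution": None if self.solution is None else self.solution.coordinates,
            "solution_depth": self.solution_depth,
            "root": self.root.to_dict(),
        }


# ---------------------------------------------------------------------------
# candidate generation


def generate_root_grid(group: Group, settings: SearchSettings) -> list[CandidatePoint]:
    """Full ``m(n)^n`` grid over the group's parameter box.

    Along each axis the ``m`` values are equally spaced and include both
    domain endpoints; grid indices run in lexicographic order.
    """
    m = settings.m(group.n)
    axes = [np.linspace(p.lower, p.upper, m) for p in group.parameters]
    names = group.parameter_names
    points = []
    for flat, idx in enumerate(itertools.product(range(m), repeat=group.n)):
        coords = {names[a]: float(axes[a][i]) for a, i in enumerate(idx)}
        points.append(CandidatePoint(coordinates=coords, grid_index=tuple(idx), index=flat))
    return points


def generate_child_points(range_: FeasibleRange, m: int) -> list[CandidatePoint]:
    """``m`` strictly interior, equally spaced points of a feasible range.

    Points sit at ``u + j (v - u)/(m + 1)`` for ``j = 1..m``; together
    with the endpoint values inherited from the parent this partitions
    the range into ``m + 1`` sub-intervals, so selecting one sub-interval
    rejects ``m/(m+1)`` of the range.
    """
    u, v = range_.bounds
    if not (u < v):
        raise ValueError(f"degenerate feasible range [{u}, {v}] on axis {range_.axis!r}")
    step = (v - u) / (m + 1)
    points = []
    for j in range(1, m + 1):
        coords = dict(range_.anchor)
        coords[range_.axis] = u + j * step
        points.append(CandidatePoint(coordinates=coords, grid_index=(j,), index=j - 1))
    return points


# ---------------------------------------------------------------------------
# feasibility and solutions


def is_solution(point: CandidatePoint, group: Group) -> bool:
    """True iff every group metric's replicate-averaged value lies inside its
    closed target range."""
    if point.averaged is None:
        raise ValueError(f"candidate {point.coordinates} has not been explored")
    return all(m.contains(point.averaged[m.name]) for m in group.metrics)


def _interval_feasible(vp: Mapping[str, float], vq: Mapping[str, float], group: Group) -> bool:
    for m in group.metrics:
        lo = min(vp[m.name], vq[m.name])
        hi = max(vp[m.name], vq[m.name])
        a, b = m.target
        if hi < a or lo > b:  # value span does not intersect the target band
            return False
    return True


def _node_line_points(node: SearchNode) -> list[tuple[float, dict[str, float]]]:
    """Evaluated points along a 1-D node's grid line (inherited endpoints
    plus own candidates), sorted by coordinate."""
    fr = node.feasible_range
    axis = fr.axis
    pts = [(c.coordinates[axis], c.averaged) for c in node.candidates]
    for coord, vals in fr.endpoint_values().items():
        pts.append((coord, vals))
    pts.sort(key=lambda t: t[0])
    return pts


def find_feasible_ranges(node: SearchNode, group: Group) -> list[FeasibleRange]:
    """Feasible ranges between axis-adjacent evaluated points of a node.

    An interval is feasible iff, for every metric of the group, the
    closed interval spanned by the metric values at its two endpoints
    intersects the target range.  For the root of an ``n``-D group the
    intervals run along grid lines, with the remaining coordinates
    recorded as the anchor.  Returned in lexicographic grid order
    (pairs sorted by lower grid index, then axis), before prioritization.
    """
    if any(not c.explored for c in node.candidates):
        raise ValueError("all candidate points must be explored before range detection")

    ranges: list[FeasibleRange] = []
    if node.is_root and group.n > 1:
        m = round(len(node.candidates) ** (1.0 / group.n))
        by_idx = {c.grid_index: c for c in node.candidates}
        names = group.parameter_names
        pairs = []
        for idx in sorted(by_idx):
            for a in range(group.n):
                nb = tuple(i + 1 if ax == a else i for ax, i in enumerate(idx))
                if nb in by_idx:
                    pairs.append((idx, a, nb))
        pairs.sort(key=lambda t: (t[0], t[1]))
        for idx, a, nb in pairs:
            p, q = by_idx[idx], by_idx[nb]
            if not _interval_feasible(p.averaged, q.averaged, group):
                continue
            axis = names[a]
            anchor = {k: v for k, v in p.coordinates.items() if k != axis}
            # support: all m evaluated points along this grid line
            line = []
            for i in range(m):
                key = tuple(i if ax == a else j for ax, j in enumerate(idx))
                c = by_idx[key]
                line.append((c.coordinates[axis], c.averaged))
            ranges.append(
                FeasibleRange(
                    axis=axis,
                    bounds=(p.coordinates[axis], q.coordinates[axis]),
                    anchor=anchor,
                    support=line,
                )
            )
        return ranges

    # 1-D: root of a singleton group, or any deeper node
    if node.is_root:
        axis = group.parameter_names[0]
        pts = sorted(
            ((c.coordinates[axis], c.averaged) for c in node.candidates), key=lambda t: t[0]
        )
        anchor: dict[str, float] = {}
    else:
        axis = node.feasible_range.axis
        anchor = dict(node.feasible_range.anchor)
        pts = _node_line_points(node)

    for (x0, v0), (x1, v1) in zip(pts, pts[1:]):
        if _interval_feasible(v0, v1, group):
            ranges.append(
                FeasibleRange(axis=axis, bounds=(x0, x1), anchor=anchor, support=list(pts))
            )
    return ranges


def prioritize_ranges(
    node: SearchNode,
    ranges: Sequence[FeasibleRange],
    group: Group,
    settings: SearchSettings,
) -> list[FeasibleRange]:
    """Order feasible ranges by an interpolation-based promise score.

    For each range, every metric is interpolated with a 1-D spline
    (degree ``min(3, support points - 1)``) through the evaluated points
    along the range's grid line; the splines are queried at
    ``interp_points`` equally spaced values inside the range, and the
    score is the fraction of query values at which *all* metrics lie in
    their target bands.  Ranges are returned in descending score order;
    ties preserve the incoming (lexicographic discovery) order.
    """
    scored = []
    for fr in ranges:
        if len(fr.support) < 2:
            raise ValueError(f"range on {fr.axis!r} has {len(fr.support)} support points; need >= 2")
        xs = np.array([x for x, _ in fr.support])
        order = np.argsort(xs)
        xs = xs[order]
        q = np.linspace(fr.bounds[0], fr.bounds[1], settings.interp_points)
        ok = np.ones(len(q), dtype=bool)
        k = min(3, len(xs) - 1)
        for metric in group.metrics:
            ys = np.array([vals[metric.name] for _, vals in fr.support])[order]
            spline = make_interp_spline(xs, ys, k=k)
            vals_q = spline(q)
            a, b = metric.target
            ok &= (vals_q >= a) & (vals_q <= b)
        fr.score = float(ok.mean())
        scored.append(fr)
    return sorted(scored, key=lambda fr: -fr.score)  # stable: ties keep discovery order


# ---------------------------------------------------------------------------
# DFS driver


def expand_node(
    node: SearchNode,
    group: Group,
    settings: SearchSettings,
    id_start: int | None = None,
) -> NodeStatus:
    """Resolve a fully explored node: success, failure, or children.

    If any candidate is a solution the node ends in ``SUCCESS`` (the
    group search stops there).  Otherwise, at ``max_depth`` the node
    fails with ``FAILED_MAX_DEPTH``; below it, children are created from
    the prioritized feasible ranges (``FAILED_NO_RANGES`` when none).
    Children get sequential ids starting at ``id_start`` (default:
    ``node_id + 1``, suitable only for isolated single-node use; the
    DFS driver passes its own allocator).
    """
    if any(not c.explored for c in node.candidates):
        raise ValueError("cannot expand a node with unexplored candidate points")

    if any(is_solution(c, group) for c in node.candidates):
        node.status = NodeStatus.SUCCESS
        return node.status

    if node.depth >= settings.max_depth:
        node.status = NodeStatus.FAILED_MAX_DEPTH
        return node.status

    ranges = find_feasible_ranges(node, group)
    ranges = prioritize_ranges(node, ranges, group, settings)
    if not ranges:
        node.status = NodeStatus.FAILED_NO_RANGES
        return node.status

    start = node.node_id + 1 if id_start is None else id_start
    m_child = settings.m(1)
    for i, fr in enumerate(ranges):
        child = SearchNode(
            node_id=start + i,
            depth=node.depth + 1,
            feasible_range=fr,
            candidates=generate_child_points(fr, m_child),
            parent=node,
        )
        node.children.append(child)
    return node.status  # still EXPLORING; resolution comes from the subtree


class GroupSearch:
    """Incremental DFS state machine for one group.

    Drives the tree one node at a time: the scheduler (or the standalone
    :func:`run_group_search` driver) repeatedly reads
    :meth:`unexplored`, records replicate results with :meth:`record`,
    and calls :meth:`advance` once the current node has no unexplored
    candidates left.  ``status`` is ``"active"`` until the search
    completes with ``"success"`` or ``"failure"``.
    """

    def __init__(self, group: Group, settings: SearchSettings, replicates: int = 1):
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.group = group
        self.settings = settings
        self.replicates = replicates
        root = SearchNode(
            node_id=0,
            depth=0,
            feasible_range=None,
            candidates=generate_root_grid(group, settings),
        )
        self._next_id = 1
        self.tree = DFSTree(root=root)
        self.current: SearchNode | None = root
        self.status = "active"
        self.last_explored: CandidatePoint | None = None
        self._visit(root)

    # -- bookkeeping

    def _visit(self, node: SearchNode) -> None:
        node.status = NodeStatus.EXPLORING
        self.tree.visit_log.append(node.node_id)
        self.current = node

    @property
    def t(self) -> int:
        """Unexplored candidate count of the current node (t_j in the block formula)."""
        if self.status != "active" or self.current is None:
            return 0
        return len(self.current.unexplored())

    def unexplored(self) -> list[CandidatePoint]:
        if self.status != "active" or self.current is None:
            return []
        return self.current.unexplored()

    def record(self, candidate: CandidatePoint, values: Mapping[str, float]) -> None:
        """Attach one replicate's metric values (group metrics only) to a candidate.

        The candidate becomes explored (averaged value stored) when all
        configured replicates have arrived.
        """
        wanted = {name: values[name] for name in self.group.metric_names}
        candidate.add_replicate(wanted)
        if candidate.replicate_count() >= self.replicates and not candidate.explored:
            candidate.finalize()
            self.last_explored = candidate

    def fixed_values(self) -> dict[str, float]:
        """Parameter values a completed group contributes to later runs:
        the solution point on success, else the last explored candidate."""
        if self.status == "success":
            assert self.tree.solution is not None
            return dict(self.tree.solution.coordinates)
        if self.last_explored is not None:
            return dict(self.last_explored.coordinates)
        # never explored anything (cannot happen after a completed search)
        return {p.name: (p.lower + p.upper) / 2.0 for p in self.group.parameters}

    # -- DFS movement

    def advance(self) -> None:
        """Resolve the current node if fully explored, then move depth-first.

        Expands the node (success check, range detection, child
        creation), descends into the first pending child, or backtracks
        to the nearest ancestor with a pending child.  Completes the
        search when a solution is found or every node is resolved.
        """
        if self.status != "active":
            return
        node = self.current
        if node is None or node.unexplored():
            return

        expand_node(node, self.group, self.settings, id_start=self._next_id)
        self._next_id += len(node.children)

        if node.status is NodeStatus.SUCCESS:
            sol = next(c for c in node.candidates if is_solution(c, self.group))
            self.tree.solution = sol
            self.tree.solution_depth = node.depth
            self.status = "success"
            self.current = None
            return

        # descend or backtrack
        probe: SearchNode | None = node
        while probe is not None:
            pending = next(
                (ch for ch in probe.children if ch.status is NodeStatus.PENDING), None
            )
            if pending is not None:
                self._visit(pending)
                return
            if probe.children and all(
                ch.status
                in (
                    NodeStatus.FAILED_NO_RANGES,
                    NodeStatus.FAILED_MAX_DEPTH,
                    NodeStatus.FAILED_CHILDREN,
                )
                for ch in probe.children
            ):
                probe.status = NodeStatus.FAILED_CHILDREN
            probe = probe.parent

        self.status = "failure"
        self.current = None


def run_group_search(
    group: Group,
    evaluator: Callable[[Mapping[str, float], Callable[[str], np.random.Generator]], Mapping[str, float]],
    settings: SearchSettings,
    replicates: int = 1,
    seed: int = 0,
) -> DFSTree:
    """Run one group's search to completion with a serial driver.

    Every replicate of every candidate draws from a stream derived from
    ``(seed, group stream key, node id, candidate index, replicate,
    metric)``, the same derivation the block scheduler uses — so the
    resulting tree is bit-identical to a co-scheduled run of the same
    group.
    """
    gs = GroupSearch(group, settings, replicates)
    gkey = group.stream_key()
    while gs.status == "active":
        node = gs.current
        for cand in list(gs.unexplored()):
            for rep in range(replicates):
                def factory(metric_name: str, _n=node, _c=cand, _r=rep):
                    return derive_rng(seed, gkey, _n.node_id, _c.index, _r, name_key(metric_name))

                values = evaluator(cand.coordinates, factory)
                gs.record(cand, values)
        gs.advance()
    return gs.tree
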