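"""Parallel block scheduling of full-parameter-vector evaluations.

Each underlying run (e.g. one sampling run) requires a value for *every*
parameter of the problem, while each group's search only cares about its
own parameters.  The scheduler therefore advances all group searches
simultaneously: at each step it assembles a *block* whose slot count is
the minimum, over active groups, of the number of unexplored candidate
points in the group's current node (``min_j t_j``; completed groups are
excluded and contribute their fixed values to every run).  Slot ``i``
pairs the ``i``-th unexplored candidate of each active group into one
full vector, expanded into one request per replicate.  After a block is
dispatched the group states are updated, nodes are expanded, and the
loop repeats until every group completes.

Because every request's noise streams are derived from per-group keys,
results do not depend on execution order and a group's DFS tree is
bit-identical whether it is optimized alone or co-scheduled.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._rng import derive_rng, name_key
from .problem import Group, Problem, validate_problem
from .search import CandidatePoint, DFSTree, GroupSearch, SearchSettings
from .evaluators import EvaluationError

__all__ = [
    "OptimizerSettings",
    "GroupState",
    "RunRequest",
    "Block",
    "OptimizationReport",
    "default_m_table",
    "recommendation_warnings",
    "assemble_block",
    "dispatch_block",
    "update_group_state",
    "run_optimization",
]

Evaluator = Callable[
    [Mapping[str, float], Callable[[str], np.random.Generator]], Mapping[str, float]
]


def default_m_table(group_sizes: Sequence[int], m1: int = 8) -> dict[int, int]:
    """Default branching table when the user does not supply ``m(n)``.

    ``m(1)`` defaults to ``m1``.  For each higher dimensionality ``n``,
    the table picks the largest integer ``q >= 2`` with
    ``q**n <= max(m(1)**2, 64)`` such that ``q**n`` is a multiple of
    ``m(1)`` (so block sizes stay aligned with the parallel capacity),
    falling back to 2 when no such ``q`` exists.
    """
    table = {1: int(m1)}
    cap = max(m1 * m1, 64)
    for n in sorted(set(group_sizes)):
        if n == 1:
            continue
        q = 2
        candidate = int(cap ** (1.0 / n))
        for c in range(candidate, 1, -1):
            if c**n <= cap and (c**n) % m1 == 0:
                q = c
                break
        table[n] = max(q, 2)
    return table


def recommendation_warnings(
    m_table: Mapping[int, int],
    group_sizes: Sequence[int],
    max_processes: int,
    replicates: int,
) -> list[str]:
    """CPU-economy recommendation checks (advisory, not errors).

    For full utilization of ``max_processes`` parallel workers it is
    recommended that (a) ``m(n)**n`` be a multiple of ``m(1)`` for every
    group dimensionality ``n`` in the problem, so blocks contain at
    least ``m(1)`` slots at all steps, and (b) ``max_processes`` be a
    multiple of ``m(1)`` with the replicate count a multiple of the
    quotient ``max_processes / m(1)``.
    """
    warns = []
    m1 = m_table.get(1)
    if m1 is None:
        return ["m(1) is not defined; cannot check CPU-economy recommendations"]
    for n in sorted(set(group_sizes)):
        m = m_table.get(n)
        if m is None:
            warns.append(f"m({n}) is not defined but a group of {n} parameters exists")
        elif (m**n) % m1 != 0:
            warns.append(
                f"m({n})^{n} = {m**n} is not a multiple of m(1) = {m1}; "
                "some blocks will contain fewer than m(1) runs"
            )
    if max_processes == 1:
        return warns  # serial execution: no parallel capacity to underuse
    if max_processes % m1 != 0:
        warns.append(
            f"max_processes = {max_processes} is not a multiple of m(1) = {m1}; "
            "parallel capacity may be underused"
        )
    else:
        quotient = max_processes // m1
        if quotient > 1 and replicates % quotient != 0:
            warns.append(
                f"replicates = {replicates} is not a multiple of "
                f"max_processes/m(1) = {quotient}; parallel capacity may be underused"
            )
    return warns


@dataclass
class OptimizerSettings:
    """Global optimizer settings shared by all groups.

    ``m_table`` may be ``None`` to use :func:`default_m_table`.
    ``replicates`` is the number of repeated evaluations averaged per
    candidate point; ``max_processes`` bounds evaluation concurrency;
    ``seed`` fixes every random stream.
    """

    m_table: dict[int, int] | None = None
    max_depth: int = 5
    replicates: int = 1
    max_processes: int = 1
    seed: int = 0
    interp_points: int = 100

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_processes < 1:
            raise ValueError("max_processes must be >= 1")

    def search_settings(self, group_sizes: Sequence[int]) -> SearchSettings:
        table = self.m_table
        if table is None:
            table = default_m_table(group_sizes)
        else:
            table = {int(k): int(v) for k, v in table.items()}
            missing = [n for n in set(group_sizes) | {1} if n not in table]
            if missing:
                defaults = default_m_table(group_sizes, m1=table.get(1, 8))
                for n in missing:
                    table[n] = defaults.get(n, 2)
        return SearchSettings(
            m_table=table, max_depth=self.max_depth, interp_points=self.interp_points
        )


@dataclass
class GroupState:
    """One group's live search plus its completion bookkeeping."""

    group: Group
    search: GroupSearch

    @property
    def status(self) -> str:
        return {
            "active": "active",
            "success": "completed-success",
            "failure": "completed-failure",
        }[self.search.status]

    @property
    def active(self) -> bool:
        return self.search.status == "active"

    @property
    def t(self) -> int:
        return self.search.t

    @property
    def fixed(self) -> dict[str, float] | None:
        if self.active:
            return None
        return self.search.fixed_values()


@dataclass
class RunRequest:
    """One full-parameter-vector evaluation request (one replicate).

    ``provenance`` maps a group index to ``(node_id, candidate_index)``
    for the active groups whose candidates this run serves; completed
    groups contribute fixed values and do not appear.  ``stream_keys``
    carries the per-group random-stream key tuples.
    """

    vector: dict[str, float]
    replicate: int
    provenance: dict[int, tuple[int, int]]
    stream_keys: dict[int, tuple[int, ...]]
    slot: int


@dataclass
class Block:
    """The set of co-scheduled requests at one scheduler step."""

    requests: list[RunRequest]
    size: int  # number of slots, min_j t_j


def assemble_block(states: Sequence[GroupState], replicates: int) -> Block:
    """Build the next block from the current group states.

    Block size ``b`` is the minimum over active groups of the unexplored
    candidate count ``t_j``.  Slot ``i`` combines the ``i``-th
    unexplored candidate of each active group with the fixed values of
    every completed group; each slot expands into ``replicates``
    requests with distinct replicate indices.
    """
    active = [s for s in states if s.active]
    if not active:
        raise ValueError("no active group: nothing to schedule")
    b = min(s.t for s in active)
    if b == 0:
        raise ValueError("an active group has no unexplored candidates; advance it first")

    fixed_part: dict[str, float] = {}
    for s in states:
        if not s.active:
            fixed_part.update(s.fixed or {})

    pending = {s.group.index: s.search.unexplored() for s in active}
    requests = []
    for i in range(b):
        vector = dict(fixed_part)
        provenance: dict[int, tuple[int, int]] = {}
        base_keys: dict[int, tuple[int, ...]] = {}
        for s in active:
            cand = pending[s.group.index][i]
            vector.update(cand.coordinates)
            node = s.search.current
            provenance[s.group.index] = (node.node_id, cand.index)
            base_keys[s.group.index] = (s.group.stream_key(), node.node_id, cand.index)
        for rep in range(replicates):
            requests.append(
                RunRequest(
                    vector=dict(vector),
                    replicate=rep,
                    provenance=dict(provenance),
                    stream_keys={g: (*k, rep) for g, k in base_keys.items()},
                    slot=i,
                )
            )
    return Block(requests=requests, size=b)


def _metric_group_map(groups: Sequence[Group]) -> dict[str, int]:
    return {name: g.index for g in groups for name in g.metric_names}


def dispatch_block(
    block: Block,
    evaluator: Evaluator,
    max_processes: int,
    seed: int,
    groups: Sequence[Group],
) -> list[tuple[RunRequest, dict[str, float]]]:
    """Evaluate every request of a block with bounded concurrency.

    Each request's noise stream for a metric is derived from the stream
    key of the metric's own group, so results are independent of
    execution order and of which other groups are being co-scheduled.  A
    failed evaluation is retried once; a second failure aborts the
    optimization with a diagnostic naming the request.
    """
    metric_group = _metric_group_map(groups)

    def one(request: RunRequest) -> dict[str, float]:
        def factory(metric_name: str) -> np.random.Generator:
            gidx = metric_group.get(metric_name)
            keys = request.stream_keys.get(gidx) if gidx is not None else None
            if keys is None:
                # metric of a completed/foreign group: any deterministic stream
                keys = (name_key(metric_name), 0, 0, request.replicate)
            return derive_rng(seed, *keys, name_key(metric_name))

        last_error: Exception | None = None
        for _attempt in range(2):
            try:
                return dict(evaluator(request.vector, factory))
            except Exception as e:  # retried once, then aborted
                last_error = e
        raise EvaluationError(
            f"evaluation failed twice for slot {request.slot}, replicate "
            f"{request.replicate}, vector {request.vector}: {last_error}"
        ) from last_error

    if max_processes == 1 or len(block.requests) == 1:
        results = [one(r) for r in block.requests]
    else:
        with ThreadPoolExecutor(max_workers=max_processes) as pool:
            results = list(pool.map(one, block.requests))
    return list(zip(block.requests, results))


def update_group_state(
    state: GroupState, results: Sequence[tuple[RunRequest, Mapping[str, float]]]
) -> GroupState:
    """Feed a block's results into one group's search state.

    Replicate values accumulate on the group's candidate points; a
    candidate becomes explored once all replicates arrived.  When the
    current node has no unexplored candidates left, the node is expanded
    and the DFS advances (possibly completing the group).
    """
    if not state.active:
        return state
    search = state.search
    node = search.current
    candidates = {c.index: c for c in node.candidates}
    for request, values in results:
        key = request.provenance.get(state.group.index)
        if key is None:
            continue
        node_id, cand_index = key
        if node_id != node.node_id or cand_index not in candidates:
            raise ValueError(
                f"result for unknown candidate (node {node_id}, index {cand_index}) "
                f"in group {state.group.index}"
            )
        search.record(candidates[cand_index], values)
    if search.t == 0:
        search.advance()
    return state


@dataclass
class OptimizationReport:
    """Outcome of a full optimization: per-group results plus accounting."""

    problem_name: str
    group_results: list[dict]
    trees: dict[int, DFSTree]
    total_evaluations: int
    total_blocks: int
    block_log: list[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def solutions(self) -> dict[int, dict[str, float] | None]:
        return {
            g["index"]: g["solution"] for g in self.group_results
        }

    def to_dict(self) -> dict:
        return {
            "problem": self.problem_name,
            "seed": self.seed,
            "total_evaluations": self.total_evaluations,
            "total_blocks": self.total_blocks,
            "groups": self.group_results,
            "trees": {str(i): t.to_dict() for i, t in self.trees.items()},
            "block_log": self.block_log,
        }


def run_optimization(
    problem: Problem,
    evaluator: Evaluator,
    settings: OptimizerSettings,
) -> OptimizationReport:
    """Optimize every group of a problem with block scheduling.

    Validates the problem, partitions it into groups, then loops
    assemble -> dispatch -> update until every group completes.  Fully
    reproducible for a fixed ``settings.seed``.
    """
    violations = validate_problem(problem)
    if violations:
        raise ValueError("invalid problem: " + "; ".join(violations))

    groups = problem.groups()
    search_settings = settings.search_settings([g.n for g in groups])
    states = [
        GroupState(group=g, search=GroupSearch(g, search_settings, settings.replicates))
        for g in groups
    ]

    total_evaluations = 0
    block_log: list[dict] = []
    while any(s.active for s in states):
        block = assemble_block(states, settings.replicates)
        results = dispatch_block(
            block, evaluator, settings.max_processes, settings.seed, groups
        )
        total_evaluations += len(block.requests)
        block_log.append(
            {
                "block": len(block_log),
                "size": block.size,
                "requests": len(block.requests),
                "groups": sorted(
                    {g for r in block.requests for g in r.provenance}
                ),
                "nodes": sorted(
                    {r.provenance[g][0] for r in block.requests for g in r.provenance}
                ),
            }
        )
        for s in states:
            update_group_state(s, results)

    group_results = []
    for s in states:
        entry = {
            "index": s.group.index,
            "parameters": list(s.group.parameter_names),
            "metrics": list(s.group.metric_names),
            "status": s.status,
            "solution": dict(s.search.tree.solution.coordinates)
            if s.search.tree.solution is not None
            else None,
            "solution_depth": s.search.tree.solution_depth,
            "fixed_values": s.fixed,
        }
        group_results.append(entry)

    return OptimizationReport(
        problem_name=problem.name,
        group_results=group_results,
        trees={s.group.index: s.search.tree for s in states},
        total_evaluations=total_evaluations,
        total_blocks=len(block_log),
        block_log=block_log,
        seed=settings.seed,
    )
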