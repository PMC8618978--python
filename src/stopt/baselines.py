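"""Comparison methods: 1-D binary search, the worst-case m-ary iteration
formula, and a genetic-algorithm search over continuous landscapes.

These serve as baselines for benchmarking the grid/DFS optimizer, not as
production search strategies.  The binary search assumes a monotonic
single-parameter, single-metric landscape with a user-supplied gradient
sign; the GA follows elitism (25% retained), uniform bounded mutation
(75% mutants) and single-coordinate crossover over half the population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .evaluators import NoiseModel, SyntheticEvaluator
from .landscapes import Landscape
from .scheduler import OptimizerSettings, run_optimization

__all__ = [
    "GAConfig",
    "BenchmarkResult",
    "binary_search_1d",
    "worst_case_iterations",
    "fitness",
    "ga_search",
    "stop_search",
    "run_benchmark",
]


@dataclass(frozen=True)
class BenchmarkResult:
    """Outcome of one search run on one landscape."""

    algorithm: str
    landscape: str
    seed: int
    success: bool
    evaluations: int
    solution: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.evaluations < 0:
            raise ValueError("evaluation count must be >= 0")


@dataclass
class BinarySearchResult:
    success: bool
    x: float | None
    iterations: int


def binary_search_1d(
    f: Callable[[float], float],
    target: tuple[float, float],
    domain: tuple[float, float],
    increasing: bool,
    max_iterations: int = 60,
) -> BinarySearchResult:
    """Bisect a monotonic 1-D landscape until the metric enters the target range.

    At each iteration the midpoint of the current interval is evaluated;
    if its value lies in ``[a, b]`` the search succeeds, otherwise half
    the interval is rejected using the supplied gradient sign and
    whether the value over- or undershot the band.  A wrong gradient
    sign (or a non-monotonic landscape) makes the search walk away from
    the desired range and fail after ``max_iterations``.
    """
    a, b = target
    lo, hi = domain
    for it in range(1, max_iterations + 1):
        mid = (lo + hi) / 2.0
        v = f(mid)
        if a <= v <= b:
            return BinarySearchResult(success=True, x=mid, iterations=it)
        undershoot = v < a
        # monotone increasing: undershoot -> move right; decreasing: mirrored
        if undershoot == increasing:
            lo = mid
        else:
            hi = mid
    return BinarySearchResult(success=False, x=None, iterations=max_iterations)


def worst_case_iterations(r: float, m: int) -> float:
    """Worst-case m-ary iteration count for a monotonic 1-D landscape.

    ``r`` is the ratio of the input-domain width to the desired-range
    width.  The first iteration rejects ``(m-2)/(m-1)`` of the domain
    and every later one rejects ``m/(m+1)`` of the remaining range,
    giving ``log(r/(m-1)) / log(m+1) + 1`` iterations.  Requires
    ``r > m - 1`` (otherwise a single iteration suffices and the
    logarithm's argument is not positive).
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if r <= m - 1:
        raise ValueError(f"formula requires r > m - 1 (got r = {r}, m = {m})")
    return math.log(r / (m - 1)) / math.log(m + 1) + 1.0


def fitness(value: float, target: tuple[float, float]) -> float:
    """GA fitness: 0 inside the target range, else minus the distance to the
    closest range edge."""
    a, b = target
    if a <= value <= b:
        return 0.0
    return -min(abs(value - a), abs(value - b))


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    Per generation: the top ``elite_fraction`` of the population by
    fitness is retained, the rest are mutants of the retained set (each
    coordinate perturbed by a uniform draw in ±``max_mutation``, clipped
    to the domain), and crossover swaps one random coordinate between
    random pairs of a subset of ``crossover_fraction`` of the
    population.  ``budget`` caps total metric evaluations;
    ``generations = budget // population``.
    """

    population: int = 5
    elite_fraction: float = 0.25
    mutant_fraction: float = 0.75
    max_mutation: float = 0.1
    crossover_fraction: float = 0.5
    budget: int = 10_000

    def __post_init__(self):
        if not (0 < self.elite_fraction < 1) or not (0 < self.mutant_fraction < 1):
            raise ValueError("elite and mutant fractions must lie in (0, 1)")
        if self.budget < self.population:
            raise ValueError("budget must allow at least one generation")

    @property
    def generations(self) -> int:
        return self.budget // self.population

    @property
    def n_elite(self) -> int:
        return max(1, int(self.elite_fraction * self.population))


def ga_search(
    landscape: Landscape,
    config: GAConfig,
    seed: int = 0,
    noise_sd: float | None = None,
    metric: str | None = None,
) -> BenchmarkResult:
    """Genetic-algorithm search for a point whose metric enters its target range.

    The population is initialized uniformly in the parameter box.  The
    search stops at the first evaluated point whose (noisy) metric value
    lies inside the target range, or when the evaluation budget is
    exhausted.  For multi-metric landscapes the fitness is the sum of
    per-metric fitnesses and success requires all metrics in band.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x6A5, int(seed)]))
    sd = landscape.noise_sd if noise_sd is None else noise_sd
    if metric is None:
        metrics = landscape.metrics
    else:
        metrics = tuple(m for m in landscape.metrics if m.name == metric)
        if not metrics:
            raise KeyError(metric)
    lows = np.array([p.lower for p in landscape.parameters])
    highs = np.array([p.upper for p in landscape.parameters])
    d = len(lows)
    pop = rng.uniform(lows, highs, size=(config.population, d))

    evaluations = 0
    for _gen in range(config.generations):
        values = {
            m.name: np.asarray(landscape.functions[m.name](pop), dtype=float)
            for m in metrics
        }
        if sd > 0:
            for name in values:
                values[name] = values[name] + rng.normal(0.0, sd, size=config.population)
        evaluations += config.population

        in_band = np.ones(config.population, dtype=bool)
        fit = np.zeros(config.population)
        for m in metrics:
            v = values[m.name]
            a, b = m.target
            in_band &= (v >= a) & (v <= b)
            fit += np.where(
                (v >= a) & (v <= b), 0.0, -np.minimum(np.abs(v - a), np.abs(v - b))
            )
        if in_band.any():
            i = int(np.argmax(in_band))
            return BenchmarkResult(
                algorithm="ga",
                landscape=landscape.name,
                seed=seed,
                success=True,
                evaluations=evaluations,
                solution=tuple(pop[i]),
            )

        # elitism + mutation
        order = np.argsort(-fit, kind="stable")
        elite = pop[order[: config.n_elite]]
        n_mut = config.population - config.n_elite
        parents = elite[rng.integers(0, len(elite), size=n_mut)]
        mutants = parents + rng.uniform(-config.max_mutation, config.max_mutation, size=(n_mut, d))
        mutants = np.clip(mutants, lows, highs)
        pop = np.vstack([elite, mutants])

        # crossover on a random subset half the population size
        n_cross = int(config.crossover_fraction * config.population)
        n_cross -= n_cross % 2
        if n_cross >= 2:
            idx = rng.choice(config.population, size=n_cross, replace=False)
            for i1, i2 in zip(idx[0::2], idx[1::2]):
                c = int(rng.integers(0, d))
                pop[i1, c], pop[i2, c] = pop[i2, c], pop[i1, c]

    return BenchmarkResult(
        algorithm="ga",
        landscape=landscape.name,
        seed=seed,
        success=False,
        evaluations=evaluations,
        solution=None,
    )


def stop_search(
    landscape: Landscape,
    seed: int = 0,
    m: int | None = None,
    replicates: int = 10,
    max_depth: int = 5,
    noise_sd: float | None = None,
) -> BenchmarkResult:
    """Run the grid/DFS optimizer on a landscape and report its evaluation count.

    Evaluations are counted as underlying (single-replicate) metric
    evaluations, i.e. candidate points explored times replicates, to be
    comparable with the GA's per-point evaluations.
    """
    sd = landscape.noise_sd if noise_sd is None else noise_sd
    m_val = landscape.m if m is None else m
    problem = landscape.problem()
    settings = OptimizerSettings(
        m_table={n: m_val for n in (1, landscape.dimension)},
        max_depth=max_depth,
        replicates=replicates,
        max_processes=1,
        seed=seed,
    )
    evaluator = SyntheticEvaluator(landscape, NoiseModel(sd))
    report = run_optimization(problem, evaluator, settings)
    g = report.group_results[0]
    return BenchmarkResult(
        algorithm="stop",
        landscape=landscape.name,
        seed=seed,
        success=g["status"] == "completed-success",
        evaluations=report.total_evaluations,
        solution=tuple(g["solution"].values()) if g["solution"] else None,
    )


def run_benchmark(
    landscapes: Sequence[Landscape],
    algorithms: dict[str, Callable[[Landscape, int], BenchmarkResult]],
    seeds: Sequence[int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every algorithm on every landscape for every seed.

    Returns ``(results, summary)``: one row per run, and per-algorithm
    success rates with the 10th/50th/90th percentiles of the evaluation
    counts (failed runs contribute their at-termination counts).
    """
    if not landscapes or not algorithms:
        raise ValueError("need at least one landscape and one algorithm")
    rows = []
    for land in landscapes:
        for name, algo in algorithms.items():
            for seed in seeds:
                res = algo(land, seed)
                rows.append(
                    {
                        "landscape": land.name,
                        "algorithm": name,
                        "seed": seed,
                        "success": res.success,
                        "evaluations": res.evaluations,
                    }
                )
    results = pd.DataFrame(rows)
    summary = (
        results.groupby("algorithm")
        .agg(
            success_rate=("success", "mean"),
            p10=("evaluations", lambda s: float(np.percentile(s, 10))),
            p50=("evaluations", lambda s: float(np.percentile(s, 50))),
            p90=("evaluations", lambda s: float(np.percentile(s, 90))),
            runs=("evaluations", "size"),
        )
        .reset_index()
    )
    return results, summary
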