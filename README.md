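# stopt

Stochastic optimization of sampling parameters: a derivative-free,
global, parallel, multiobjective heuristic that finds parameter values
whose **noisy** metrics fall inside user-given **target ranges**.

## The problem

Integrative structure modeling (and MCMC sampling generally) exposes
tuning parameters — move sizes: the maximum translation or rotation
proposed for a rigid body or flexible bead per Monte Carlo step — whose
values strongly affect sampling efficiency. The quality criterion is not
a quantity to minimize but a *range* to hit: for example, each Monte
Carlo acceptance rate should land in [0.3, 0.6]. The metrics are
computed from stochastic sampling runs, are expensive to evaluate, have
no usable gradients, and several metrics may depend on several
parameters at once.

`stopt` solves this as a search problem. Given parameters `x_i` with
input domains `[c_i, d_i]`, metrics `f_j` with target ranges
`[a_j, b_j]`, and a bipartite dependency graph recording which metric is
a function of which parameter, it finds `x*` with
`f_j(x*) ∈ [a_j, b_j]` for all `j`, where each `f_j(x)` is the
expectation of a noisy evaluation, approximated by averaging `R`
replicate runs.

## The method

1. **Grouping.** Connected components of the dependency graph are
   independent subproblems ("groups") optimized simultaneously.
2. **m-ary grid search.** A group of `n` parameters starts with an
   `m(n)^n` grid over its parameter box (endpoints included). If the
   averaged metric values at two axis-adjacent grid points bracket a
   target range, the intermediate value theorem guarantees (for a
   continuous noiseless metric) that the range is crossed in between:
   that interval is a *feasible range*. With several metrics in a group,
   an interval counts only if it is feasible for all of them.
3. **Depth-first refinement.** Each feasible range becomes a node of a
   DFS tree. A node places `m` new interior points in its range
   (endpoints are inherited), rejecting `m/(m+1)` of the range per
   level — and `(m-2)/(m-1)` of the domain at the root. Sibling order
   follows a spline-interpolation score: the fraction of 100 query
   points inside the range at which all interpolated metrics are in
   band. A capped depth bounds runtime and resists noise-induced
   misclassification. The first candidate point whose averaged metrics
   are all in band ends the group's search.
4. **Block scheduling.** Every underlying run needs *all* parameters,
   so at each step the scheduler co-schedules `min_j t_j` runs (the
   minimum over active groups of unexplored candidate counts), each
   expanded into `R` replicates, on up to `max_processes` workers.
   Completed groups pin their parameters to the solution (or the last
   explored point).

Baselines for comparison are included: 1-D binary search with a known
gradient sign, the worst-case m-ary iteration formula
`log(r/(m-1))/log(m+1) + 1` (with `r` the domain/desired-range width
ratio), and an elitist genetic algorithm with bounded uniform mutation.

## Worked example

The bundled `fig6a` landscape is `f(x) = 1 - x^2` on `[-1, 1]` with
target `[0.6, 0.68]`, Gaussian noise sd 0.05 averaged over 100
replicates, and `m(1) = 3`:

```sh
$ stopt example fig6a --seed 1 --replicates 100
group 0 (x): SOLVED at depth 2: {'x': -0.625}
total: 900 evaluations in 3 blocks
```

The root grid `{-1, 0, 1}` brackets the band on `[-1, 0]` and `[0, 1]`;
refining `[-1, 0]` keeps `[-0.75, -0.5]`, and its midpoint `x = -0.625`
has `f = 0.609375`, inside the band — a solution two levels below the
root after 9 candidate points × 100 replicates. The two-metric variant
shows backtracking out of a branch where the per-metric feasible ranges
do not overlap:

```sh
$ stopt example fig6b --seed 1 --replicates 100
group 0 (x): SOLVED at depth 3: {'x': 0.59375}
total: 1500 evaluations in 5 blocks
```

The same engine drives external simulations through a JSON file
protocol (`stopt example mock-sampler` tunes a bundled random-walk
Metropolis script's move size until its acceptance rate lands in
[0.3, 0.6]), and `stopt run --config problem.yaml` optimizes any
user-declared problem; see `src/stopt/data/fig6a.yaml` for the config
schema. Library use mirrors the CLI:

```python
from stopt import (NoiseModel, OptimizerSettings, SyntheticEvaluator,
                   run_optimization, worked_example)

land = worked_example("fig6a")
report = run_optimization(
    land.problem(),
    SyntheticEvaluator(land, NoiseModel(0.05)),
    OptimizerSettings(m_table={1: 3}, replicates=100, seed=1),
)
print(report.group_results[0]["solution"])   # {'x': -0.625}
```

`stopt benchmark` compares the optimizer with the GA baseline on seeded
random smooth 2-D landscapes and prints success rates with
10th/50th/90th-percentile evaluation counts.

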