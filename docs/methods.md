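# Methods

This note records the model behind `stopt`, the parameter choices that
matter, the numerical conventions, and what the synthetic test
conditions do and do not demonstrate.

## Problem model

A problem is a triple (parameters, metrics, dependency graph). Each
parameter has a closed input domain `[c, d]` with `c < d` (units are
whatever the underlying simulation uses — Å for translations, radians
for rotations). Each metric has a closed target range `[a, b]`; a value
equal to `a` or `b` counts as inside (closed-interval convention). The
bipartite graph's edge `x -> f` asserts that `f` is a function of `x`;
the user supplies it, and the package treats it as ground truth — it
never infers dependencies. Orphan parameters or metrics are hard
validation errors rather than being dropped silently: an unlinked metric
can never be driven into its band, which is almost always a config
mistake.

Metrics are expectations of noisy per-run observables, estimated by the
arithmetic mean of `R` replicate evaluations at the same parameter
vector. With Gaussian observation noise of sd `σ`, the averaged noise
has sd `σ/√R`; all in-band decisions are made on averaged values.

## Search

**Grouping.** Connected components of the dependency graph are
independent subproblems. Groups are ordered by their smallest parameter
name purely for reproducibility; the ordering has no algorithmic effect.

**Root grid.** A group with `n` parameters starts with `m(n)` equally
spaced values per axis *including both domain endpoints*, i.e.
`m(n)^n` candidate points and `m-1` intervals per axis. An interval
between two axis-adjacent (never diagonal) points is *feasible* for a
metric iff the closed interval spanned by the two averaged values
intersects the target range. This generalizes strict flanking (one value
below `a`, the other above `b`) to cover endpoint values that already
lie inside the band; in the single-metric case the two rules coincide,
because an in-band value ends the search as a solution before ranges are
examined. An interval is kept only if feasible for *every* metric of the
group.

**Children.** Each kept interval becomes a DFS node. It evaluates `m(1)`
new strictly interior points `u + j(v-u)/(m+1)`, inheriting the endpoint
values from the parent, which yields `m+1` sub-intervals per level.
Consequences, exact by construction: a root-level selection retains
`1/(m-1)` of the domain (rejects `(m-2)/(m-1)`), every deeper selection
retains `1/(m+1)`. This placement is the only one consistent with those
two rejection fractions, and it reproduces the worked parabola trace
exactly (depth-1 range `[-0.75, -0.5]`, solution `x = -0.625` with
`f = 0.609375`).

**Visiting order.** When a node yields several feasible ranges, each
range is scored by interpolation: every metric is fit with a 1-D spline
through the evaluated points along the range's grid line — cubic with
≥ 4 support points, quadratic with 3, linear with 2 — and evaluated at
100 equally spaced query points inside the range. The score is the
fraction of query points at which all metrics are simultaneously in
band; ranges are visited in descending score order, ties preserving
lexicographic grid order. The deliberate consequence for symmetric
landscapes: the left-most range is explored first.

**Termination.** Root depth is 0. A node succeeds if any candidate's
averaged metrics are all in band; it fails at `max_depth` (default 5,
configurable) or when no feasible range exists; on failure the DFS
backtracks. The search ends at the first solution or when every node is
resolved. Total candidate evaluations are bounded by
`m^n + (nodes - 1)·m`, and the node count is finite because each level
multiplies by at most the number of feasible ranges while depth is
capped.

On noiseless monotone 1-D landscapes whose desired range is `1/r` of the
domain, success comes within `ceil(log(r/(m-1))/log(m+1) + 1)` levels;
binary search needs up to `ceil(log2 r)` iterations but requires the
gradient sign, which the m-ary search does not.

## Scheduling

Each underlying run requires the full parameter vector, so group
searches advance in lock-step *blocks*: a block has `min_j t_j` slots
(`t_j` = unexplored candidates in group `j`'s current node, completed
groups excluded), and slot `i` combines the `i`-th unexplored candidate
of every active group with the fixed values of completed groups
(solution point, else the last explored candidate). Each slot expands
into `R` replicate requests dispatched to a thread pool of at most
`max_processes` workers. The description of a "run count" per block is
ambiguous about replicates; here slots and replicates are kept separate
(block = slots × R requests), which preserves the `min_j t_j` slot
formula while honoring replicate averaging.

**Random streams.** Every replicate's noise stream is derived from
`(seed, group key, node id, candidate index, replicate index, metric
name)`, where the group key depends only on the group's own parameter
names. Results are therefore reproducible, independent of dispatch
order, and — verified by test — a group's DFS tree is bit-identical
whether the group is optimized alone or co-scheduled with others.

**CPU-economy checks.** The recommended configuration — `m(n)^n` a
multiple of `m(1)`; `max_processes` a multiple of `m(1)` with `R` a
multiple of the quotient — is checked at config load and reported as
warnings, not errors (it is advice about utilization, not correctness).
Serial runs (`max_processes = 1`) skip the utilization warnings since
there is no parallel capacity to waste. When `m(n)` is unspecified, the
default sets `m(1) = 8` and, for higher `n`, the largest `q ≥ 2` with
`q^n ≤ max(m(1)², 64)` and `q^n` a multiple of `m(1)`, falling back
to 2.

## Evaluators

The synthetic backend adds independent zero-mean Gaussian noise per
metric and replicate to a landscape function; cross-metric noise
correlation is deliberately zero (nothing in the model constrains it,
and independence is the simplest defensible choice). The external
backend writes the parameter vector to a JSON file (one key per
parameter plus a reserved `_seed` integer so external runs are
reproducible), invokes `<command> <input> <output>`, and reads one
numeric value per metric back; one invocation is one replicate. A failed
evaluation is retried once, then the optimization aborts naming the
offending request. The bundled mock sampler is a random-walk Metropolis
chain on a standard normal (3000 steps) whose acceptance rate decreases
with move size — a stand-in workload for exercising the external
protocol end to end, not a model of any particular system.

## Landscapes and the benchmark generator

The four worked examples are fixed polynomials with known traces; they
double as exact test oracles. Two of their properties are worth noting.
The two-metric example fails inside `[-1, 0]` at depth 1 because the
per-metric feasible sub-ranges do not overlap — backtracking then finds
the depth-3 solution `x = 0.59375` in the `[0, 1]` branch; under noise
the depth can differ by one level since near-boundary values (`f2` at
`x = 0.625` is 0.5996, 0.0004 below the band) flip in and out. The
off-center parabola fails *despite its peak exceeding the band*, because
both root intervals have endpoint values entirely below the band —
bracketing detection sees nothing, which is exactly the documented
failure mode addressed by raising `m` or shrinking the domain.

The random generator for benchmarking sums `h` Gaussian radial bumps
(random centers in `[-1, 1]^n`, widths uniform in [0.3, 0.9], signed
amplitudes with magnitude in [0.5, 1]) and affinely rescales the sum to
span `[0, 1]` over a dense probe grid (201 per axis for `n ≤ 2`, 4096
random probes above). The rescale guarantees any target band inside
(0, 1) is crossed, so generated instances are solvable by construction;
`h = 1` gives a unimodal surface, `h = 5` a plausibly multimodal one.
This generator is this package's own design: its instances are smooth,
bounded and multimodal like acceptance-rate response surfaces, but
benchmark results on them are properties of this generator, not
reproductions of any published curve. Default benchmark conditions,
chosen once: target band `[0.3, 0.6]` (the conventional acceptance-rate
target), noise sd 0.05, optimizer `m = 5` with 10 replicates, GA
population 5 with a 10,000-evaluation budget.

## Genetic-algorithm baseline

Fitness is 0 inside the band and minus the distance to the nearest band
edge outside (summed over metrics when there are several). Each
generation retains the top 25% (at least one member; 1 of 5, 12 of 50),
fills the rest with mutants of retained members (each coordinate
perturbed by a uniform draw in ±max-mutation-size, clipped to the
domain), then crosses over random pairs from a random half-population
subset, drawn without replacement, by swapping one uniformly chosen
coordinate — the literature leaves the crossover operator open, so the
simplest coordinate swap is used. The search stops at the first
evaluated point in band or after `budget // population` generations
(2000 at population 5, 200 at 50, for a 10,000-evaluation budget).

## Known limitations

* Feasibility detection needs the metric to *cross* the band between
  two adjacent candidates; bands hiding inside one sub-interval with
  both endpoints on the same side are invisible at that `m` (the
  off-center parabola case above).
* Multi-parameter groups refine only along grid lines through evaluated
  anchors; solutions off every grid line require the root grid (or a
  deeper line) to pass near them. Interior sampling of hyper-rectangles
  is out of scope.
* The depth cap trades completeness for noise robustness; with very
  noisy metrics and few replicates, misclassified ranges still waste
  one subtree each.
* Thread-based dispatch assumes evaluations release the GIL (subprocess
  or I/O bound) or are cheap; multi-host execution is out of scope.
* Problem sizes in the test suite and acceptance script are desk-scale
  (50-seed repetitions, 100 replicates, 20 benchmark landscapes) —
  chosen so the whole suite runs in seconds while keeping noiseless
  margins ≥ 6 averaged-noise standard deviations where exact range
  identification is asserted.

Synthetic landscapes emulate the *shape* of acceptance-rate responses
(bounded, smooth, monotone-ish in move size) but none of the systematic
effects of real sampling runs — score-landscape ruggedness, replica
coupling, drifting acceptance over a run, or run-to-run variance that
depends on the parameter value. Passing tests demonstrate the search
logic, bookkeeping and reproducibility contracts, not performance on
any particular molecular system.
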