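"""Grid generation, feasibility detection, prioritization and the DFS driver.

Expected values for the worked examples were computed analytically from
the landscape polynomials (noiseless evaluation of 1 - x^2 etc. at the
grid points the search visits) and are frozen here.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from stopt.evaluators import NoiseModel, SyntheticEvaluator
from stopt.landscapes import worked_example
from stopt.problem import DependencyGraph, Metric, Parameter, Problem
from stopt.search import (
    CandidatePoint,
    FeasibleRange,
    GroupSearch,
    NodeStatus,
    SearchNode,
    SearchSettings,
    expand_node,
    find_feasible_ranges,
    generate_child_points,
    generate_root_grid,
    is_solution,
    prioritize_ranges,
    run_group_search,
)

from conftest import linear_landscape


def settings(m=3, max_depth=5):
    return SearchSettings(m_table={1: m, 2: m}, max_depth=max_depth)


def group_of(landscape):
    return landscape.problem().groups()[0]


def explored_root(landscape, m=3):
    """Root node of a landscape's group with noiselessly explored candidates."""
    group = group_of(landscape)
    node = SearchNode(
        node_id=0, depth=0, feasible_range=None,
        candidates=generate_root_grid(group, settings(m)),
    )
    for c in node.candidates:
        c.add_replicate(landscape.evaluate(c.coordinates))
        c.finalize()
    return node, group


class TestGridGeneration:
    def test_2d_m3_grid_is_nine_corner_points(self):
        land = worked_example("fig6c")
        group = group_of(land)
        pts = generate_root_grid(group, settings(3))
        assert len(pts) == 9
        got = {(p.coordinates["x1"], p.coordinates["x2"]) for p in pts}
        assert got == set(itertools.product([-1.0, 0.0, 1.0], repeat=2))
        # lexicographic grid indices
        assert [p.grid_index for p in pts] == list(itertools.product(range(3), repeat=2))

    @pytest.mark.parametrize(
        "m, domain, expected",
        [
            (2, (0.0, 1.0), [0.0, 1.0]),
            (5, (0.0, 10.0), [0.0, 2.5, 5.0, 7.5, 10.0]),
        ],
    )
    def test_1d_grid_includes_endpoints(self, m, domain, expected):
        group = Problem(
            parameters=[Parameter("x", domain)],
            metrics=[Metric("f", (0, 1))],
            graph=DependencyGraph([("x", "f")]),
        ).groups()[0]
        pts = generate_root_grid(group, SearchSettings(m_table={1: m}))
        assert [p.coordinates["x"] for p in pts] == pytest.approx(expected)

    def test_undefined_m_raises(self):
        land = worked_example("fig6c")
        with pytest.raises(KeyError, match="m\\(n\\) is undefined"):
            generate_root_grid(group_of(land), SearchSettings(m_table={1: 3}))

    @pytest.mark.parametrize(
        "bounds, m, expected",
        [
            ((-1.0, 0.0), 3, [-0.75, -0.5, -0.25]),
            ((0.0, 1.0), 2, [1 / 3, 2 / 3]),
            ((-0.75, -0.5), 3, [-0.6875, -0.625, -0.5625]),
        ],
    )
    def test_child_points_strictly_interior_equally_spaced(self, bounds, m, expected):
        fr = FeasibleRange(axis="x", bounds=bounds, anchor={})
        pts = generate_child_points(fr, m)
        assert [p.coordinates["x"] for p in pts] == pytest.approx(expected)

    def test_child_points_depth2_value_in_band(self):
        # the midpoint of the depth-2 range carries f(-0.625) = 0.609375,
        # inside the [0.6, 0.68] band
        assert 1 - 0.625**2 == pytest.approx(0.609375)
        assert 0.6 <= 1 - 0.625**2 <= 0.68

    def test_degenerate_range_raises(self):
        fr = FeasibleRange(axis="x", bounds=(0.5, 0.5), anchor={})
        with pytest.raises(ValueError, match="degenerate"):
            generate_child_points(fr, 3)

    @given(
        u=st.floats(-100, 100),
        width=st.floats(1e-6, 100),
        m=st.integers(2, 10),
    )
    @hyp_settings(deadline=None, derandomize=True)
    def test_child_points_interior_and_equally_spaced_property(self, u, width, m):
        """For any range and m, the m child points are strictly interior and
        split the range into m + 1 equal sub-intervals."""
        v = u + width
        fr = FeasibleRange(axis="x", bounds=(u, v), anchor={})
        xs = [p.coordinates["x"] for p in generate_child_points(fr, m)]
        assert len(xs) == m
        assert all(u < x < v for x in xs)
        gaps = np.diff([u] + xs + [v])
        assert gaps == pytest.approx([width / (m + 1)] * (m + 1), rel=1e-9)


class TestSolutionTest:
    def make_point(self, values):
        p = CandidatePoint(coordinates={"x": 0.0}, grid_index=(0,), index=0)
        for name, v in values.items():
            p.add_replicate({name: v})
        p.finalize()
        return p

    def test_single_metric_inside_band(self):
        land = worked_example("fig6a")
        assert is_solution(self.make_point({"f": 0.609375}), group_of(land))

    def test_boundary_counts_as_inside(self):
        land = worked_example("fig6a")
        assert is_solution(self.make_point({"f": 0.6}), group_of(land))
        assert is_solution(self.make_point({"f": 0.68}), group_of(land))

    def test_two_metrics_one_below_band_fails(self):
        land = worked_example("fig6b")
        # analytic values at x = 0.625: f1 = 0.609375, f2 = 0.599609375 < 0.6
        pt = self.make_point({"f1": 1 - 0.625**2, "f2": 1 - 0.625**3 - 1.2 * 0.625**2 + 0.5 * 0.625})
        assert pt.averaged["f2"] == pytest.approx(0.599609375)
        assert not is_solution(pt, group_of(land))

    def test_unexplored_point_raises(self):
        land = worked_example("fig6a")
        p = CandidatePoint(coordinates={"x": 0.0}, grid_index=(0,), index=0)
        with pytest.raises(ValueError, match="not been explored"):
            is_solution(p, group_of(land))


class TestFeasibleRanges:
    def test_fig6a_root_two_ranges(self):
        node, group = explored_root(worked_example("fig6a"))
        ranges = find_feasible_ranges(node, group)
        assert [r.bounds for r in ranges] == [(-1.0, 0.0), (0.0, 1.0)]

    def test_fig6c_root_four_edge_ranges(self):
        node, group = explored_root(worked_example("fig6c"))
        ranges = find_feasible_ranges(node, group)
        got = [(r.axis, r.bounds, tuple(sorted(r.anchor.items()))) for r in ranges]
        assert got == [
            ("x1", (-1.0, 0.0), (("x2", -1.0),)),
            ("x2", (-1.0, 0.0), (("x1", -1.0),)),
            ("x1", (0.0, 1.0), (("x2", 1.0),)),
            ("x2", (0.0, 1.0), (("x1", 1.0),)),
        ]

    def test_fig6d_root_no_ranges(self):
        node, group = explored_root(worked_example("fig6d"))
        vals = [c.averaged["f"] for c in node.candidates]
        assert vals == pytest.approx([-1.25, 0.75, 0.75])
        assert find_feasible_ranges(node, group) == []

    def test_unexplored_candidates_raise(self):
        land = worked_example("fig6a")
        group = group_of(land)
        node = SearchNode(
            node_id=0, depth=0, feasible_range=None,
            candidates=generate_root_grid(group, settings()),
        )
        with pytest.raises(ValueError, match="explored"):
            find_feasible_ranges(node, group)

    @pytest.mark.parametrize("trial", range(15))
    def test_random_grids_match_brute_force_oracle(self, trial):
        """Every axis-adjacent pair whose value span intersects every target
        band, and only those, must be returned."""
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(1, 3))
        m = int(rng.integers(2, 5))
        k = int(rng.integers(1, 3))
        params = tuple(Parameter(f"x{i}", (-1.0, 1.0)) for i in range(n))
        metrics = tuple(
            Metric(f"f{j}", tuple(sorted(rng.uniform(-1, 1, 2)))) for j in range(k)
        )
        from stopt.problem import Group

        group = Group(index=0, parameters=params, metrics=metrics)
        node = SearchNode(
            node_id=0, depth=0, feasible_range=None,
            candidates=generate_root_grid(group, SearchSettings(m_table={n: m, 1: m})),
        )
        values = {}
        for c in node.candidates:
            vals = {f.name: float(rng.normal()) for f in metrics}
            values[c.grid_index] = vals
            c.add_replicate(vals)
            c.finalize()

        got = {(r.axis, r.bounds) for r in find_feasible_ranges(node, group)}

        expected = set()
        for idx, vals in values.items():
            for a in range(n):
                nb = tuple(i + 1 if ax == a else i for ax, i in enumerate(idx))
                if nb not in values:
                    continue
                feas = all(
                    min(vals[f.name], values[nb][f.name]) <= f.target[1]
                    and max(vals[f.name], values[nb][f.name]) >= f.target[0]
                    for f in metrics
                )
                if feas:
                    step = 2.0 / (m - 1)
                    lo = -1.0 + idx[a] * step
                    expected.add((f"x{a}", (lo, lo + step)))
        norm = lambda s: {(ax, (round(b[0], 12), round(b[1], 12))) for ax, b in s}
        assert norm(got) == norm(expected)


class TestPrioritization:
    def test_single_range_unchanged(self):
        node, group = explored_root(worked_example("fig6d"))
        fr = FeasibleRange(
            axis="x", bounds=(-1.0, 0.0), anchor={},
            support=[(c.coordinates["x"], c.averaged) for c in node.candidates],
        )
        out = prioritize_ranges(node, [fr], group, settings())
        assert out == [fr]

    def test_symmetric_tie_preserves_discovery_order(self):
        node, group = explored_root(worked_example("fig6a"))
        ranges = find_feasible_ranges(node, group)
        out = prioritize_ranges(node, ranges, group, settings())
        assert out[0].bounds == (-1.0, 0.0)
        assert out[0].score == out[1].score > 0

    def test_wider_in_band_spline_fraction_ranked_first(self):
        """Constructed case: range B's interpolant spends ~40% of the query
        points in band, range A's ~10%; B must come first."""
        group = Problem(
            parameters=[Parameter("x", (0.0, 2.0))],
            metrics=[Metric("f", (0.0, 1.0))],
            graph=DependencyGraph([("x", "f")]),
        ).groups()[0]
        # piecewise-linear supports: on [0,1] f rises 10 -> -0.1 (in band only
        # near the end); on [1,2] f stays shallowly in band ~40% of queries
        support_a = [(0.0, {"f": 10.0}), (1.0, {"f": -0.1})]
        support_b = [(1.0, {"f": -1.5}), (2.0, {"f": 1.1})]
        fr_a = FeasibleRange(axis="x", bounds=(0.0, 1.0), anchor={}, support=support_a)
        fr_b = FeasibleRange(axis="x", bounds=(1.0, 2.0), anchor={}, support=support_b)
        node = SearchNode(node_id=0, depth=0, feasible_range=None)
        out = prioritize_ranges(node, [fr_a, fr_b], group, settings())
        # linear-interpolation oracle
        frac_a = np.mean([(0 <= 10 + (-10.1) * t <= 1) for t in np.linspace(0, 1, 100)])
        frac_b = np.mean([(0 <= -1.5 + 2.6 * t <= 1) for t in np.linspace(0, 1, 100)])
        assert frac_b > frac_a
        assert out[0] is fr_b
        assert out[0].score == pytest.approx(frac_b)
        assert out[1].score == pytest.approx(frac_a)

    def test_too_few_support_points_raise(self):
        node, group = explored_root(worked_example("fig6a"))
        fr = FeasibleRange(axis="x", bounds=(-1.0, 0.0), anchor={}, support=[(0.0, {"f": 1.0})])
        with pytest.raises(ValueError, match="support"):
            prioritize_ranges(node, [fr], group, settings())


class TestExpandAndSearch:
    def run_noiseless(self, name, m=3, max_depth=5, seed=0):
        land = worked_example(name)
        evaluator = SyntheticEvaluator(land, NoiseModel(0.0))
        return run_group_search(
            group_of(land), evaluator, settings(m, max_depth), replicates=1, seed=seed
        )

    def test_fig6a_noiseless_full_trace(self):
        tree = self.run_noiseless("fig6a")
        assert tree.solution_depth == 2
        assert tree.solution.coordinates["x"] == pytest.approx(-0.625)
        assert tree.solution.averaged["f"] == pytest.approx(0.609375)
        # depth-1 node explored is the [-0.75, -0.5] sub-range of [-1, 0]
        depth1 = tree.root.children[0]
        assert depth1.feasible_range.bounds == (-1.0, 0.0)
        depth2 = depth1.children[0]
        assert depth2.feasible_range.bounds == pytest.approx((-0.75, -0.5))

    def test_fig6d_noiseless_fails_with_single_visited_node(self):
        tree = self.run_noiseless("fig6d")
        assert tree.solution is None
        assert tree.visit_log == [0]
        assert tree.root.status is NodeStatus.FAILED_NO_RANGES

    def test_fig6b_noiseless_backtracks_then_succeeds(self):
        tree = self.run_noiseless("fig6b")
        assert tree.solution is not None
        assert tree.solution_depth <= 3
        # both depth-1 siblings visited: the [-1,0] branch fails first
        depth1 = tree.root.children
        assert [c.feasible_range.bounds for c in depth1] == [(-1.0, 0.0), (0.0, 1.0)]
        assert depth1[0].status is NodeStatus.FAILED_NO_RANGES
        assert tree.solution.coordinates["x"] == pytest.approx(0.59375)

    def test_expand_at_max_depth_fails(self):
        land = worked_example("fig6a")
        group = group_of(land)
        node, _ = explored_root(land)
        # pretend the root sits at the depth cap: non-solution points fail it
        node.depth = 2
        status = expand_node(node, group, SearchSettings(m_table={1: 3}, max_depth=2))
        assert status is NodeStatus.FAILED_MAX_DEPTH
        assert node.children == []

    def test_expand_success_records_solution(self):
        land = worked_example("fig6a")
        group = group_of(land)
        fr = FeasibleRange(
            axis="x", bounds=(-0.75, -0.5), anchor={},
            support=[(-0.75, {"f": 0.4375}), (-0.5, {"f": 0.75})],
        )
        node = SearchNode(
            node_id=3, depth=2, feasible_range=fr,
            candidates=generate_child_points(fr, 3),
        )
        for c in node.candidates:
            c.add_replicate(land.evaluate(c.coordinates))
            c.finalize()
        assert expand_node(node, group, settings()) is NodeStatus.SUCCESS

    def test_dfs_discipline_and_depth_cap(self):
        """The visit log never opens a sibling before the current subtree is
        resolved, and no node exceeds max_depth."""
        land = worked_example("fig6b")
        evaluator = SyntheticEvaluator(land, NoiseModel(0.05))
        for seed in range(5):
            tree = run_group_search(
                group_of(land), evaluator, settings(3, max_depth=3), replicates=25, seed=seed
            )
            nodes = {n.node_id: n for n in tree.nodes()}
            assert all(n.depth <= 3 for n in nodes.values())
            # DFS: when a node is visited, its parent must be the most recent
            # ancestor on the log whose subtree is still open
            open_path = []
            for nid in tree.visit_log:
                node = nodes[nid]
                if node.parent is None:
                    open_path = [node]
                    continue
                while open_path and open_path[-1] is not node.parent:
                    open_path.pop()
                assert open_path and open_path[-1] is node.parent
                open_path.append(node)

    def test_termination_evaluation_budget(self):
        """Total candidates <= m^n + (nodes - 1) * m."""
        land = worked_example("fig6b")
        evaluator = SyntheticEvaluator(land, NoiseModel(0.05))
        tree = run_group_search(
            group_of(land), evaluator, settings(3, max_depth=4), replicates=10, seed=3
        )
        n_nodes = len(tree.nodes())
        total_candidates = sum(len(n.candidates) for n in tree.nodes())
        assert total_candidates <= 3**1 + (n_nodes - 1) * 3


class TestSearchSpaceReduction:
    @pytest.mark.parametrize("m", range(2, 11))
    def test_root_and_child_retained_fractions_exact(self, m):
        """Root: a selected feasible range keeps 1/(m-1) of the domain (so
        (m-2)/(m-1) is rejected); every deeper level keeps 1/(m+1)."""
        group = Problem(
            parameters=[Parameter("x", (0.0, 1.0))],
            metrics=[Metric("f", (0, 1))],
            graph=DependencyGraph([("x", "f")]),
        ).groups()[0]
        pts = generate_root_grid(group, SearchSettings(m_table={1: m}))
        coords = [p.coordinates["x"] for p in pts]
        root_widths = [b - a for a, b in zip(coords, coords[1:])]
        assert root_widths == pytest.approx([1.0 / (m - 1)] * (m - 1))

        fr = FeasibleRange(axis="x", bounds=(0.0, 1.0 / (m - 1)), anchor={})
        child = generate_child_points(fr, m)
        xs = [0.0] + [p.coordinates["x"] for p in child] + [1.0 / (m - 1)]
        child_widths = [b - a for a, b in zip(xs, xs[1:])]
        assert child_widths == pytest.approx([1.0 / ((m - 1) * (m + 1))] * (m + 1))


class TestIntermediateValueSoundness:
    @pytest.mark.parametrize("trial", range(10))
    def test_returned_ranges_bracket_or_touch_target(self, trial):
        """For noiseless single-metric polynomial landscapes every returned
        range's endpoint value span intersects the target band."""
        rng = np.random.default_rng(900 + trial)
        coeffs = rng.normal(size=4)
        poly = np.polynomial.Polynomial(coeffs)
        target = tuple(sorted(rng.uniform(-2, 2, 2)))
        from stopt.landscapes import Landscape

        land = Landscape(
            name="poly",
            parameters=(Parameter("x", (-1.0, 1.0)),),
            metrics=(Metric("f", target),),
            functions={"f": lambda x: poly(x[..., 0])},
        )
        node, group = explored_root(land, m=5)
        for r in find_feasible_ranges(node, group):
            v0, v1 = poly(r.bounds[0]), poly(r.bounds[1])
            assert min(v0, v1) <= target[1] and max(v0, v1) >= target[0]


class TestWorstCaseDepth:
    @pytest.mark.parametrize("r", [10, 100, 1000])
    @pytest.mark.parametrize("m", [3, 4, 5])
    def test_monotone_search_within_formula_levels(self, r, m):
        """On f(x) = x with a desired range 1/r of the domain, success comes
        within ceil(log(r/(m-1))/log(m+1) + 1) levels (level = depth + 1)."""
        import math

        bound = math.ceil(math.log(r / (m - 1)) / math.log(m + 1) + 1)
        for offset in [0.0, 0.37, 0.81]:
            a = offset * (1 - 1 / r)
            land = linear_landscape(target=(a, a + 1 / r))
            evaluator = SyntheticEvaluator(land, NoiseModel(0.0))
            tree = run_group_search(
                land.problem().groups()[0],
                evaluator,
                SearchSettings(m_table={1: m}, max_depth=bound + 2),
                replicates=1,
                seed=0,
            )
            assert tree.solution is not None
            assert tree.solution_depth + 1 <= bound
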