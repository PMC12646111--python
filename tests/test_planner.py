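"""Tree transform, firm power, epsilon-Pareto portfolio selection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from resghg.planner import (
    AssetMetrics,
    DEFAULT_OBJECTIVES,
    ObjectiveSpec,
    TreeNetwork,
    epsilon_pareto,
    firm_power,
    frontier_report,
    to_tree,
)
from resghg.errors import (
    CyclicInput,
    EmptyTree,
    MultipleOutlets,
    SeriesTooShort,
)

OBJ3 = (
    ObjectiveSpec("hp", "max", "energy", "sum"),
    ObjectiveSpec("ghg", "min", "emissions", "sum"),
    ObjectiveSpec("forest", "min", "forest_loss", "sum"),
)


def make_asset(i, rng=None, existing=False, ror=False):
    if rng is None:
        vals = (100.0 * (i + 1), 40.0 * (i + 1), 1000.0 * (i + 1), 1.0, 2.0)
    else:
        vals = (float(rng.uniform(10, 500)), float(rng.uniform(5, 200)),
                float(rng.uniform(100, 9000)), float(rng.uniform(0, 5)),
                float(rng.uniform(0, 5)))
    e, f, g, cl, fl = vals
    if ror:
        cl = fl = 0.0
    return AssetMetrics(
        id=f"a{i}", asset_type="ror" if ror else "reservoir", energy=e,
        firm_power=f, emissions={"model": g, "ef": g * 1.3},
        cropland_loss=cl, forest_loss=fl, existing=existing,
    )


def random_tree(n, rng, existing_fraction=0.0):
    children = {"n0": []}
    assets = {}
    for i in range(n):
        parent = f"n{rng.integers(0, i + 1)}"
        node = f"n{i + 1}"
        children.setdefault(parent, []).append(node)
        children.setdefault(node, [])
        assets[(parent, node)] = make_asset(
            i, rng, existing=bool(rng.random() < existing_fraction))
    return TreeNetwork(root="n0", children=children, assets=assets)


def brute_force_frontier(assets, objectives):
    """Enumerate all portfolios; return the unique non-dominated vectors
    (minimisation sense) as a lexicographically sorted array."""
    vecs = []
    for mask in itertools.product([0, 1], repeat=len(assets)):
        sel = [a for m, a in zip(mask, assets) if m]
        v = []
        for ob in objectives:
            xs = [a.metric(ob.source, ob.method) for a in sel]
            agg = sum(xs) if ob.aggregation == "sum" else \
                (np.mean(xs) if xs else 0.0)
            v.append(-agg if ob.sense == "max" else agg)
        vecs.append(v)
    arr = np.array(vecs)
    keep = []
    for i, v in enumerate(arr):
        dom = np.all(arr <= v, axis=1) & np.any(arr < v, axis=1)
        if not dom.any():
            keep.append(v)
    return _unique_sorted(np.array(keep))


def frontier_vectors(frontier, objectives):
    out = [
        [-p.objectives[ob.name] if ob.sense == "max" else p.objectives[ob.name]
         for ob in objectives]
        for p in frontier
    ]
    return _unique_sorted(np.array(out))


def _unique_sorted(arr, decimals=6):
    rounded = np.round(arr, decimals)
    uniq = np.unique(rounded, axis=0)
    return uniq[np.lexsort(uniq.T[::-1])]


def assert_same_vectors(a, b, tol=1e-6):
    assert a.shape == b.shape, f"{a.shape} != {b.shape}"
    assert np.allclose(a, b, rtol=1e-9, atol=tol)


class TestToTree:
    def test_single_dam(self):
        g = nx.DiGraph()
        g.add_node("out")
        g.add_node("d", kind="dam", asset=make_asset(0))
        g.add_node("src")
        g.add_edges_from([("out", "d"), ("d", "src")])
        tree = to_tree(g)
        assert tree.n_assets == 1
        assert len(tree.children) == 2

    def test_y_network(self):
        g = nx.DiGraph()
        g.add_node("out")
        g.add_node("junction")
        for i in range(3):
            g.add_node(f"d{i}", kind="dam", asset=make_asset(i))
        g.add_node("s1")
        g.add_node("s2")
        g.add_edge("out", "d0")
        g.add_edge("d0", "junction")
        g.add_edge("junction", "d1")
        g.add_edge("junction", "d2")
        g.add_edge("d1", "s1")
        g.add_edge("d2", "s2")
        tree = to_tree(g)
        assert tree.n_assets == 3
        assert len(tree.children) == 4  # out-region, junction-region, 2 sources

    def test_edge_count_equals_dam_count(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(1, 20))
            g = nx.DiGraph()
            g.add_node("river0")
            rivers = ["river0"]
            for i in range(n):
                down = rivers[rng.integers(0, len(rivers))]
                g.add_node(f"d{i}", kind="dam", asset=make_asset(i, rng))
                g.add_node(f"river{i + 1}")
                g.add_edge(down, f"d{i}")
                g.add_edge(f"d{i}", f"river{i + 1}")
                rivers.append(f"river{i + 1}")
            tree = to_tree(g)
            assert tree.n_assets == n
            # connectivity: every region reachable from the root
            seen, stack = set(), [tree.root]
            while stack:
                v = stack.pop()
                seen.add(v)
                stack.extend(tree.children.get(v, []))
            assert seen == set(tree.children)

    def test_cycle_rejected(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(CyclicInput):
            to_tree(g)

    def test_multiple_outlets_rejected(self):
        g = nx.DiGraph()
        g.add_edge("a", "b")
        g.add_node("c")
        with pytest.raises(MultipleOutlets):
            to_tree(g)


class TestFirmPower:
    def test_constant_series(self):
        assert firm_power([5.0] * 30) == 5.0

    def test_linear_series_matches_sort_oracle(self):
        series = np.arange(1.0, 101.0)
        assert firm_power(series) == pytest.approx(np.percentile(series, 5))
        assert firm_power(series) == pytest.approx(1 + 0.05 * 99)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 10, 60)
        assert firm_power(s) == firm_power(rng.permutation(s))

    def test_annualization(self):
        assert firm_power([7.0] * 52, periods_per_year=52.0) == pytest.approx(364.0)

    def test_too_short(self):
        with pytest.raises(SeriesTooShort):
            firm_power([1.0] * 5)


class TestEpsilonPareto:
    def test_single_dam_two_points(self):
        tree = TreeNetwork(
            root="r", children={"r": ["u"], "u": []},
            assets={("r", "u"): make_asset(0)},
        )
        front = epsilon_pareto(tree, OBJ3, epsilon=0.0)
        assert len(front) == 2
        assert {len(p.portfolio) for p in front} == {0, 1}

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = int(rng.integers(3, 11))
            tree = random_tree(n, rng)
            front = epsilon_pareto(tree, OBJ3, epsilon=0.0)
            assert_same_vectors(frontier_vectors(front, OBJ3),
                                brute_force_frontier(tree.all_assets(), OBJ3))

    def test_exact_with_mean_objectives(self):
        objs = (
            ObjectiveSpec("hp", "max", "energy", "sum"),
            ObjectiveSpec("ghg", "min", "emissions", "mean"),
        )
        rng = np.random.default_rng(2)
        for _ in range(20):
            tree = random_tree(int(rng.integers(3, 9)), rng)
            front = epsilon_pareto(tree, objs, epsilon=0.0)
            assert_same_vectors(frontier_vectors(front, objs),
                                brute_force_frontier(tree.all_assets(), objs))

    @pytest.mark.parametrize("epsilon", [0.01, 0.05])
    def test_epsilon_coverage_guarantee(self, epsilon):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            tree = random_tree(n, rng)
            assets = tree.all_assets()
            front = epsilon_pareto(tree, OBJ3, epsilon=epsilon)
            got = frontier_vectors(front, OBJ3)
            # normalisation ranges as the planner defines them
            mat = np.array([
                [-a.energy, a.emissions["model"], a.forest_loss] for a in assets
            ])
            scale = (np.where(mat > 0, mat, 0).sum(axis=0)
                     - np.where(mat < 0, mat, 0).sum(axis=0))
            feasible = brute_force_frontier(assets, OBJ3)
            for v in feasible:
                diffs = (got - v) / scale
                assert (diffs.max(axis=1) <= epsilon + 1e-9).any(), \
                    f"vector {v} not epsilon-covered"

    def test_frontier_shrinks_with_epsilon(self):
        rng = np.random.default_rng(4)
        tree = random_tree(10, rng)
        sizes = [len(epsilon_pareto(tree, OBJ3, epsilon=e))
                 for e in (0.0, 0.01, 0.05, 0.2)]
        assert sizes == sorted(sizes, reverse=True)

    def test_built_scenario_forces_existing(self):
        rng = np.random.default_rng(5)
        tree = random_tree(8, rng, existing_fraction=0.4)
        forced = {a.id for a in tree.all_assets() if a.existing}
        assert forced
        for p in epsilon_pareto(tree, OBJ3, epsilon=0.0, scenario="built"):
            assert forced <= p.portfolio

    def test_all_existing_single_point(self):
        tree = TreeNetwork(
            root="r", children={"r": ["u"], "u": ["v"], "v": []},
            assets={("r", "u"): make_asset(0, existing=True),
                    ("u", "v"): make_asset(1, existing=True)},
        )
        front = epsilon_pareto(tree, OBJ3, epsilon=0.0, scenario="built")
        assert len(front) == 1
        assert front[0].portfolio == {"a0", "a1"}

    def test_scenario_nesting(self):
        # any HP level reached by a built portfolio is matched or beaten by
        # a not-built portfolio on every other objective
        rng = np.random.default_rng(6)
        tree = random_tree(9, rng, existing_fraction=0.5)
        built = epsilon_pareto(tree, OBJ3, epsilon=0.0, scenario="built")
        free = epsilon_pareto(tree, OBJ3, epsilon=0.0, scenario="not-built")
        for pb in built:
            ok = any(
                pf.objectives["hp"] >= pb.objectives["hp"]
                and pf.objectives["ghg"] <= pb.objectives["ghg"] + 1e-9
                and pf.objectives["forest"] <= pb.objectives["forest"] + 1e-9
                for pf in free
            )
            assert ok

    def test_empty_tree(self):
        with pytest.raises(EmptyTree):
            epsilon_pareto(TreeNetwork(root="r", children={"r": []}, assets={}),
                           OBJ3)


class TestFrontierReport:
    def test_single_point(self):
        tree = TreeNetwork(root="r", children={"r": ["u"], "u": []},
                           assets={("r", "u"): make_asset(0)})
        front = epsilon_pareto(tree, OBJ3, 0.0)
        rep = frontier_report(front, tree)
        assert len(rep) == 2

    def test_all_ror_ei_is_constant(self):
        assets = {("r", f"u{i}"): make_asset(i, ror=True) for i in range(3)}
        children = {"r": [f"u{i}" for i in range(3)]}
        children.update({f"u{i}": [] for i in range(3)})
        tree = TreeNetwork(root="r", children=children, assets=assets)
        front = epsilon_pareto(tree, OBJ3, 0.0)
        rep = frontier_report(front, tree)
        nonempty = rep[rep["hp_production_gwh"] > 0]
        assert np.allclose(nonempty["emission_intensity_g_per_kwh"], 3.0)

    def test_ei_matches_per_asset_sums(self):
        rng = np.random.default_rng(7)
        tree = random_tree(6, rng)
        front = epsilon_pareto(tree, OBJ3, 0.0)
        rep = frontier_report(front, tree, method="model")
        by_id = {a.id: a for a in tree.all_assets()}
        for _, row in rep.iterrows():
            ids = [s for s in row["portfolio"].split(";") if s]
            e = sum(by_id[i].energy for i in ids)
            g = sum(by_id[i].emissions["model"] for i in ids)
            expected = g / e if e > 0 else 0.0
            assert row["emission_intensity_g_per_kwh"] == pytest.approx(expected)
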