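"""The 12-metric suite against exhaustive brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from dentinet import metrics as mx
from dentinet import phantom as ph
from dentinet.spatialgraph import SpatialGraph

from conftest import build_graph, random_spatial_graph, straight_pts


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_components(g):
    """Union-find connected components."""
    parent = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in g.edges():
        parent[find(u)] = find(v)
    comps = {}
    for n in g.nodes:
        comps.setdefault(find(n), set()).add(n)
    return list(comps.values())


def oracle_fs(g):
    """Exhaustive bridge fraction: delete each largest-component edge in
    turn and recount components of that subgraph."""
    comps = oracle_components(g)
    largest = max(comps, key=len)
    sub = g.subgraph(largest).copy()
    e_star = sub.number_of_edges()
    if e_star == 0:
        return None
    n_before = len(oracle_components(sub))
    n_bridges = 0
    for u, v, k in list(sub.edges(keys=True)):
        trial = sub.copy()
        trial.remove_edge(u, v, key=k)
        if len(oracle_components(trial)) > n_before:
            n_bridges += 1
    return n_bridges / e_star


def oracle_paths(g):
    """Floyd-Warshall all-pairs shortest paths on the largest component."""
    comps = oracle_components(g)
    largest = sorted(max(comps, key=len))
    n = len(largest)
    if n < 2:
        return None, None, None
    index = {node: i for i, node in enumerate(largest)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, d in g.edges(data=True):
        if u in index and v in index and u != v:
            i, j = index[u], index[v]
            w = d["weight"]
            dist[i, j] = min(dist[i, j], w)
            dist[j, i] = min(dist[j, i], w)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    off = ~np.eye(n, dtype=bool)
    mean_l = dist[off].mean()
    diam = dist[off].max()
    di_vals = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d_euc = np.linalg.norm(g.nodes[largest[i]]["pos"]
                                   - g.nodes[largest[j]]["pos"])
            if d_euc >= mx.MIN_PAIR_DISTANCE_UM:
                di_vals.append(dist[i, j] / d_euc)
    return mean_l, diam, (np.mean(di_vals) if di_vals else None)


# ---------------------------------------------------------------------------

class TestDescriptors:
    def test_complete_graph_gamma_is_one(self):
        pos = {i: (i, i**2 % 3, 0) for i in range(5)}
        g = build_graph(pos, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        n, e, k, gamma = mx.descriptors(g)
        assert (n, e) == (5, 10)
        assert k == pytest.approx(4.0)
        assert gamma == pytest.approx(1.0)

    def test_gamma_undefined_below_two_nodes(self):
        g = build_graph({0: (0, 0, 0)}, [])
        assert mx.descriptors(g)[3] is None

    def test_linear_edge_density(self):
        # 1 m of vessel in 1 mm^3 is 1e3 mm/mm^3
        assert mx.linear_edge_density(1e6, 1.0) == pytest.approx(1e3)


class TestConnectivity:
    def test_tree_fault_sensitivity_is_one(self):
        rng = np.random.default_rng(0)
        pos = {i: tuple(rng.uniform(0, 10, 3)) for i in range(12)}
        edges = [(i, int(rng.integers(0, i))) for i in range(1, 12)]
        g = build_graph(pos, edges)
        s, k, fs = mx.connectivity(g)
        assert (s, k) == (1.0, 1)
        assert fs == 1.0

    def test_cycle_fault_sensitivity_is_zero(self):
        pos = {i: (np.cos(2 * np.pi * i / 6) * 5, np.sin(2 * np.pi * i / 6) * 5, 0)
               for i in range(6)}
        g = build_graph(pos, [(i, (i + 1) % 6) for i in range(6)])
        s, k, fs = mx.connectivity(g)
        assert fs == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_fs_matches_exhaustive_edge_removal(self, seed):
        rng = np.random.default_rng(seed)
        g = random_spatial_graph(rng, n_nodes=int(rng.integers(4, 16)),
                                 n_edges=int(rng.integers(3, 30)),
                                 allow_multi=True)
        s, k, fs = mx.connectivity(g)
        comps = oracle_components(g)
        assert k == len(comps)
        assert s == pytest.approx(max(map(len, comps)) / g.number_of_nodes())
        assert fs == pytest.approx(oracle_fs(g))


class TestDistances:
    def test_single_edge(self):
        g = build_graph({0: (0, 0, 0), 1: (0, 0, 7)}, [(0, 1)])
        w, mean_w, mean_l, diam, di = mx.distances(g, mode="exact")
        assert w == pytest.approx(7.0)
        assert diam == pytest.approx(7.0)
        assert mean_l == pytest.approx(7.0)
        assert di == pytest.approx(1.0)

    def test_path_diameter_is_route_sum(self):
        g = build_graph({0: (0, 0, 0), 1: (3, 0, 0), 2: (3, 4, 0),
                         3: (3, 4, 5)}, [(0, 1), (1, 2), (2, 3)])
        _, _, _, diam, _ = mx.distances(g, mode="exact")
        assert diam == pytest.approx(12.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_paths_match_floyd_warshall(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_spatial_graph(rng)
        w, mean_w, mean_l, diam, di = mx.distances(g, mode="exact")
        o_l, o_d, o_di = oracle_paths(g)
        if o_l is None:
            assert mean_l is None
        else:
            assert mean_l == pytest.approx(o_l, abs=1e-9)
            assert diam == pytest.approx(o_d, abs=1e-9)
            assert di == pytest.approx(o_di, abs=1e-9)

    def test_sampled_mode_approximates_exact(self):
        rng = np.random.default_rng(0)
        g = random_spatial_graph(rng, n_nodes=40, n_edges=80)
        _, _, l_ex, d_ex, di_ex = mx.distances(g, mode="exact")
        _, _, l_s, d_s, di_s = mx.distances(g, mode="sampled",
                                            sample_pairs=20_000, seed=1)
        assert l_s == pytest.approx(l_ex, rel=0.1)
        assert di_s == pytest.approx(di_ex, rel=0.1)
        assert d_s <= d_ex + 1e-9  # sampled eccentricity is a lower bound


class TestReport:
    def test_empty_graph_reports_all_missing(self):
        rep = mx.report(SpatialGraph())
        assert all(v is None for v in rep.as_dict().values())

    def test_k4_with_unit_edges(self):
        pos = {0: (0, 0, 0), 1: (1, 0, 0), 2: (0.5, 0.8, 0), 3: (0.5, 0.3, 0.7)}
        g = SpatialGraph()
        for n, p in pos.items():
            g.add_spatial_node(n, p)
        for i in range(4):
            for j in range(i + 1, 4):
                pts = straight_pts(pos[i], pos[j], n=5)
                k = g.add_polyline_edge(i, j, pts)
                g.edges[i, j, k]["weight"] = 1.0  # unit-length K4 by fiat
        rep = mx.report(g, mode="exact")
        assert (rep.n, rep.e) == (4, 6)
        assert rep.mean_degree == pytest.approx(3.0)
        assert rep.gamma == pytest.approx(1.0)
        assert (rep.s, rep.k) == (1.0, 1)
        assert rep.fs == 0.0
        assert rep.w == pytest.approx(6.0)
        assert rep.mean_edge_length == pytest.approx(1.0)
        assert rep.mean_shortest_path == pytest.approx(1.0)
        assert rep.diameter == pytest.approx(1.0)
        # DI vs direct arithmetic oracle: mean over ordered pairs of
        # 1 / euclidean distance
        di_oracle = np.mean([1.0 / np.linalg.norm(np.subtract(pos[i], pos[j]))
                             for i in range(4) for j in range(4) if i != j])
        assert rep.detour_index == pytest.approx(di_oracle, rel=1e-9)

    def test_identities_hold_on_random_reports(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = random_spatial_graph(rng)
            rep = mx.report(g, mode="exact")
            if rep.e:
                assert rep.mean_edge_length * rep.e == pytest.approx(rep.w,
                                                                     rel=1e-9)
            if rep.gamma is not None:
                assert rep.gamma * rep.n * (rep.n - 1) == pytest.approx(
                    2 * rep.e, rel=1e-9)
            if rep.detour_index is not None:
                assert rep.detour_index >= 1.0 - 1e-9
            assert rep.s * rep.n == pytest.approx(rep.n_star)
            if rep.diameter is not None:
                assert rep.diameter >= rep.mean_shortest_path - 1e-9

    def test_component_monotonicity_under_edge_addition(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = random_spatial_graph(rng, n_nodes=12, n_edges=8)
            s0, k0, _ = mx.connectivity(g)
            nodes = list(g.nodes)
            u, v = rng.choice(len(nodes), size=2, replace=False)
            g.add_polyline_edge(nodes[u], nodes[v],
                                straight_pts(g.nodes[nodes[u]]["pos"],
                                             g.nodes[nodes[v]]["pos"], n=4))
            s1, k1, _ = mx.connectivity(g)
            assert k1 <= k0
            assert s1 >= s0 - 1e-12


class TestMetricMaps:
    def test_patch_positions_follow_overlap_rule(self):
        # 25 µm patches at 50% overlap on a 100 µm axis: 7 positions
        assert len(mx.patch_positions(100.0, 25.0, 0.5)) == 7

    def test_single_patch_equals_global_report(self):
        rng = np.random.default_rng(2)
        g = random_spatial_graph(rng, n_nodes=15, n_edges=25, box=8.0)
        maps = mx.metric_maps(g, (10.0, 10.0), patch_xy_um=10.0, overlap=0.0)
        rep = mx.report(g)
        for name, mm in maps.items():
            val = mm.values[0, 0]
            expect = getattr(rep, name)
            if expect is None:
                assert np.isnan(val)
            else:
                assert val == pytest.approx(expect, rel=1e-9)

    def test_empty_patches_flagged_not_zero_filled(self):
        g = build_graph({0: (1, 1, 0), 1: (2, 1, 0)}, [(0, 1)])
        maps = mx.metric_maps(g, (20.0, 20.0), patch_xy_um=5.0, overlap=0.5)
        mm = maps["n"]
        assert mm.empty.any()
        assert np.isnan(mm.values[mm.empty]).all()

    def test_gradient_phantom_has_higher_map_variation(self):
        """Maps across a branching-density gradient fluctuate more than
        maps of a uniform phantom (coefficient of variation of N)."""
        cvs = {"uniform": [], "gradient": []}
        for seed in range(5):
            for label, factors in (("uniform", (1.0, 1.0)),
                                   ("gradient", (1.6, 0.1))):
                spec = ph.PhantomSpec(
                    domain_size=(25.6, 51.2, 25.9), tubule_count=36,
                    branch_density=0.18,
                    gradient=ph.GradientProfile(
                        transition_depth_um=25.6,
                        branch_density_factors=factors))
                gt = ph.generate_network(spec, seed=seed)
                maps = mx.metric_maps(gt, (25.6, 51.2), patch_xy_um=12.8,
                                      overlap=0.5)
                vals = maps["n"].values[~maps["n"].empty]
                cvs[label].append(vals.std() / vals.mean())
        assert np.mean(cvs["gradient"]) > np.mean(cvs["uniform"])
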