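"""Error-attack models: semantics, sweeps, monotonicity, reliability."""

import numpy as np
import pytest

from dentinet import attacks as at
from dentinet import metrics as mx
from dentinet import phantom as ph
from dentinet.metrics import MetricReport
from dentinet.spatialgraph import SpatialGraph

from conftest import build_graph, straight_pts


_SMALL_DENSE = ph.PhantomSpec(domain_size=(16.0, 16.0, 16.1),
                              tubule_count=16, branch_density=0.22,
                              branch_connect_prob=0.8)


def _dense_gt(seed=1):
    """Well-connected phantom network at unit-test scale."""
    gt = ph.generate_network(_SMALL_DENSE, seed=seed)
    return ph.attach_intensity_model(gt, ph.ImagingSpec())


class TestNodeDisconnections:
    def test_zero_target_is_identity(self):
        g = _dense_gt()
        out = at.attack_node_disconnections(g, "physical", 0.0, seed=0)
        assert out.number_of_nodes() == g.number_of_nodes()
        assert out.number_of_edges() == g.number_of_edges()

    def test_random_model_removes_stated_edge_count(self):
        # star graph: removal leaves no degree-2 nodes, so the cleanup
        # does not change E further and E' = E - round(f * E) is exact
        pos = {0: (0, 0, 0)}
        pos.update({i: (np.cos(i), np.sin(i), 2.0) for i in range(1, 11)})
        g = build_graph(pos, [(0, i) for i in range(1, 11)])
        out = at.attack_node_disconnections(g, "random", 0.3, seed=0)
        assert out.number_of_edges() == 10 - round(0.3 * 10)

    def test_physical_detaches_thinnest_arm_of_y_junction(self):
        g = build_graph(
            {0: (0, 0, 0), 1: (5, 0, 0), 2: (10, 3, 0), 3: (10, -3, 0)},
            [(0, 1, {"radius": 1.0}), (1, 2, {"radius": 1.0}),
             (1, 3, {"radius": 0.3})])
        out = at.attack_node_disconnections(g, "physical", 1.0, seed=0)
        # thin arm detached; the two thick arms merged into one edge;
        # the detached thin arm survives as a separate component
        comps = list(__import__("networkx").connected_components(out))
        assert len(comps) == 2
        weights = sorted(d["weight"] for _, _, d in out.edges(data=True))
        assert len(weights) == 2
        # merged thick path: 5 µm stem + hypot(5, 3) µm arm
        assert max(weights) == pytest.approx(5.0 + np.hypot(5, 3), rel=0.01)

    def test_clamps_when_target_exceeds_junction_fraction(self):
        g = _dense_gt()
        n_junc = sum(1 for n in g.nodes if g.degree(n) >= 3)
        assert n_junc < g.number_of_nodes()
        with pytest.warns(UserWarning, match="clamped"):
            at.attack_node_disconnections(g, "physical", 1.0, seed=0)

    def test_determinism(self):
        g = _dense_gt()
        a = at.attack_node_disconnections(g, "physical", 0.2, seed=9)
        b = at.attack_node_disconnections(g, "physical", 0.2, seed=9)
        assert set(a.nodes) == set(b.nodes)
        assert sorted(d["weight"] for _, _, d in a.edges(data=True)) == \
            sorted(d["weight"] for _, _, d in b.edges(data=True))


def _two_parallel_vessels(offset_axis="z", offset=0.5):
    """Two 10 µm Y-oriented vessels separated along a perpendicular axis."""
    shift = {"z": (0, 0, offset), "x": (offset, 0, 0)}[offset_axis]
    g = SpatialGraph()
    nid = 0
    for base in ((0.0, 0.0, 0.0), shift):
        a = np.array([0.0, 0.0, 0.0]) + base
        b = np.array([0.0, 10.0, 0.0]) + base
        pts = straight_pts(a, b)
        g.add_spatial_node(nid, a)
        g.add_spatial_node(nid + 1, b)
        g.add_polyline_edge(nid, nid + 1, pts, radius=np.full(len(pts), 0.3))
        nid += 2
    return g


class TestEdgeBridges:
    def test_z_offset_bridges_at_unweighted_distance(self):
        g = _two_parallel_vessels("z", 0.5)
        # first candidate appears at weighted distance 0.5 (Z unscaled)
        out = at.attack_edge_bridges(g, "physical", target=0.6, seed=0)
        assert out.number_of_edges() > g.number_of_edges()
        below = at.attack_edge_bridges(g, "physical", target=0.4, seed=0)
        assert below.number_of_edges() == g.number_of_edges()

    def test_x_offset_weighted_by_psf_anisotropy(self):
        g = _two_parallel_vessels("x", 0.5)
        # X distances are multiplied by 3.5: first bridge at 1.75
        none_yet = at.attack_edge_bridges(g, "physical", target=1.5, seed=0)
        assert none_yet.number_of_edges() == g.number_of_edges()
        bridged = at.attack_edge_bridges(g, "physical", target=1.8, seed=0)
        assert bridged.number_of_edges() > g.number_of_edges()

    def test_random_model_adds_requested_bridge_count(self):
        g = _dense_gt()
        out = at.attack_edge_bridges(g, "random", target=15, seed=3)
        # each bridge adds 1 new edge plus up to 2 splits (each +1 edge)
        added = out.number_of_edges() - g.number_of_edges()
        assert added >= 15

    def test_sweep_monotonicity(self):
        g = _dense_gt()
        curve = at.sweep(g, "edge_bridges", "physical",
                         [0.0, 1.0, 2.0, 3.5, 5.0], seed=2)
        n = curve.values("n")
        e = curve.values("e")
        k = curve.values("k")
        assert np.all(np.diff(n) >= 0)
        assert np.all(np.diff(e) >= 0)
        assert np.all(np.diff(k) <= 0)


class TestMissingEdges:
    def test_zero_threshold_is_identity(self):
        g = _dense_gt()
        out = at.attack_missing_edges(g, "physical", 0.0)
        assert out.number_of_edges() == g.number_of_edges()

    def test_threshold_above_maximum_erases_everything(self):
        g = _dense_gt()
        out = at.attack_missing_edges(g, "physical", 256.0)
        assert out.number_of_edges() == 0
        assert out.number_of_nodes() == 0

    def test_mid_edge_dip_splits_into_two_fragments(self):
        pts = straight_pts((0, 0, 0), (10, 0, 0), n=21)
        inten = np.full(21, 100.0)
        inten[9:12] = 10.0  # dip in the middle
        g = build_graph({0: (0, 0, 0), 1: (10, 0, 0)}, [])
        g.add_polyline_edge(0, 1, pts, intensity=inten)
        out = at.attack_missing_edges(g, "physical", 50.0)
        assert out.number_of_edges() == 2
        new_tips = [n for n in out.nodes if n not in (0, 1)]
        assert len(new_tips) == 2
        assert all(out.degree(n) == 1 for n in new_tips)

    def test_random_full_fraction_empties_graph(self):
        g = _dense_gt()
        curve = at.sweep(g, "missing_edges", "random", [0.0, 0.5, 1.0], seed=1)
        assert curve.reports[-1].e in (0, None)

    def test_physical_sweep_total_length_non_increasing(self):
        g = _dense_gt()
        curve = at.sweep(g, "missing_edges", "physical",
                         [0.0, 30.0, 80.0, 150.0, 220.0], seed=1)
        w = curve.values("w")
        w = w[np.isfinite(w)]
        assert np.all(np.diff(w) <= 1e-9)


class TestSweepContract:
    def test_first_report_is_pristine_graph(self):
        g = _dense_gt()
        curve = at.sweep(g, "missing_edges", "random", [0.0, 0.3], seed=0)
        base = mx.report(g, seed=0)
        assert curve.reports[0].n == base.n
        assert curve.reports[0].e == base.e

    def test_rejects_sweep_not_starting_at_zero(self):
        g = _dense_gt()
        with pytest.raises(ValueError, match="first sweep value"):
            at.sweep(g, "missing_edges", "random", [0.1, 0.5], seed=0)

    def test_disconnection_sweep_shrinks_largest_component(self):
        g = _dense_gt()
        curve = at.sweep(g, "node_disconnections", "physical",
                         [0.0, 0.1, 0.2, 0.3], seed=4)
        s = curve.values("s")
        assert np.all(np.diff(s) <= 1e-9)
        k = curve.values("k")
        assert np.all(np.diff(k) >= 0)

    def test_sweep_determinism(self):
        g = _dense_gt()
        a = at.sweep(g, "node_disconnections", "random", [0.0, 0.2], seed=8)
        b = at.sweep(g, "node_disconnections", "random", [0.0, 0.2], seed=8)
        for ra, rb in zip(a.reports, b.reports):
            assert ra.as_dict() == rb.as_dict()

    @pytest.mark.parametrize("seed", range(5))
    def test_random_physical_end_change_signs_agree(self, seed):
        """Both models move N, E, S, K, FS in the same direction at the
        end of a moderate missing-edge sweep (mean edge length excepted)."""
        gt = _dense_gt(seed=seed)
        rnd = at.sweep(gt, "missing_edges", "random", [0.0, 0.4], seed=seed)
        # pick the physical threshold that erases a comparable edge share
        phys = at.sweep(gt, "missing_edges", "physical", [0.0, 150.0],
                        seed=seed)
        for name in ("n", "e", "s", "k", "fs"):
            d_r = rnd.values(name)[-1] - rnd.values(name)[0]
            d_p = phys.values(name)[-1] - phys.values(name)[0]
            if abs(d_r) > 1e-9 and abs(d_p) > 1e-9:
                assert np.sign(d_r) == np.sign(d_p), name


class TestConfusionPoint:
    def _curve(self, values, sweep=None):
        sweep = sweep if sweep is not None else np.arange(len(values), dtype=float)
        reports = []
        for v in values:
            r = MetricReport()
            r.mean_shortest_path = v
            reports.append(r)
        return at.AttackCurve(error_class="missing_edges", model="physical",
                              sweep=sweep, reports=reports, seed=0)

    def test_identical_curves_have_no_confusion(self):
        a = self._curve([1.0, 1.0, 1.0])
        b = self._curve([1.0, 1.0, 1.0])
        assert at.confusion_point(a, b, "mean_shortest_path") is None

    def test_linear_crossing_interpolated_at_midpoint(self):
        a = self._curve([1.0, 1.0, 1.0])
        b = self._curve([0.0, 1.0, 2.0])
        cp = at.confusion_point(a, b, "mean_shortest_path")
        assert cp == pytest.approx(1.0)

    def test_mismatched_sweeps_rejected(self):
        a = self._curve([1.0, 2.0])
        b = self._curve([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            at.confusion_point(a, b, "mean_shortest_path")


class TestReliabilityTable:
    def _reports(self, **overrides):
        base = dict(n=100, e=110, mean_degree=2.2, gamma=1e-3, s=0.8, k=5,
                    fs=0.5, w=500.0, mean_edge_length=4.5,
                    mean_shortest_path=50.0, diameter=120.0, detour_index=2.0,
                    n_star=80, e_star=95)
        base.update(overrides)
        return MetricReport(**base)

    def test_perfect_pipeline_is_fully_reliable(self):
        gt = {"roi1": self._reports(), "roi2": self._reports(n=50, s=0.4)}
        table = at.reliability_table(gt, gt, gt)
        table = table.set_index("metric")
        assert (table.loc[["n", "s"], "delta_cle"] == 0).all()
        assert table.loc["n", "reliable"]

    def test_ratio_exactly_one_is_unreliable(self):
        gt = {"roi1": self._reports(n=100), "roi2": self._reports(n=90)}
        cle = {"roi1": self._reports(n=110), "roi2": self._reports(n=90)}
        table = at.reliability_table(cle, cle, gt).set_index("metric")
        assert table.loc["n", "ratio_cle"] == pytest.approx(1.0)
        assert not table.loc["n", "reliable"]

    def test_hand_computed_ratios(self):
        gt = {"r1": self._reports(fs=0.4), "r2": self._reports(fs=0.9)}
        gen = {"r1": self._reports(fs=0.3), "r2": self._reports(fs=0.95)}
        cle = {"r1": self._reports(fs=0.45), "r2": self._reports(fs=0.88)}
        table = at.reliability_table(gen, cle, gt).set_index("metric")
        assert table.loc["fs", "delta_gen"] == pytest.approx(0.1)
        assert table.loc["fs", "delta_cle"] == pytest.approx(0.05)
        assert table.loc["fs", "delta_gt12"] == pytest.approx(0.5)
        assert table.loc["fs", "ratio_cle"] == pytest.approx(0.1)
        assert table.loc["fs", "reliable"]
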