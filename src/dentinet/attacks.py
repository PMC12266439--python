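"""Error-attack simulations: quantify metric reliability under graph defects.

Three residual error classes of the graph-extraction pipeline are simulated
on a ground-truth graph, each with a *random* model (classic topological
graph attack) and a *physical* model driven by the spatial attributes that
the corresponding instrumental defect acts on:

node disconnections
    branches detached from their tubule junction (vesselness filters
    under-perform at intersections). Physical: at affected junctions the
    thinnest incident edge is trimmed free over one local diameter.
    Random: whole edges deleted uniformly.
edge bridges
    artificial connections where the anisotropic PSF fuses nearby vessels.
    Physical: closest voxel pairs of distinct edges under a metric whose X
    and Y distances are inflated (default x3.5, the axial/lateral PSF
    ratio) become bridges, shortest first up to a distance threshold.
    Random: bridges between uniformly chosen voxels of distinct edges.
missing edges
    branches invisible or fragmented due to weak staining. Physical: every
    polyline point whose intensity (or diameter) falls below a threshold
    is erased, fragmenting or deleting edges. Random: whole edges deleted
    uniformly until none remain.

Sweeps are per-level: each sweep value is applied afresh to the pristine
ground truth with the same seed, and a full metric report is computed, so
curves are reproducible and the first point is always the unmodified graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .clean import _merge_all_degree2
from .metrics import MetricReport, report
from .spatialgraph import SpatialGraph

__all__ = [
    "AttackCurve",
    "attack_node_disconnections",
    "attack_edge_bridges",
    "attack_missing_edges",
    "apply_attack",
    "sweep",
    "confusion_point",
    "reliability_table",
]

ERROR_CLASSES = ("node_disconnections", "edge_bridges", "missing_edges")
MODELS = ("random", "physical")

#: X/Y distance inflation of the bridge metric (axial/lateral PSF ratio)
DEFAULT_BRIDGE_ANISOTROPY = 3.5


@dataclass
class AttackCurve:
    """Metric values along a sweep of one error model."""

    error_class: str
    model: str
    sweep: np.ndarray
    reports: list[MetricReport]
    seed: int

    def __post_init__(self):
        self.sweep = np.asarray(self.sweep, dtype=float)
        if np.any(np.diff(self.sweep) <= 0):
            raise ValueError("sweep values must be strictly increasing")
        if len(self.reports) != len(self.sweep):
            raise ValueError("one report per sweep value required")

    def values(self, metric: str) -> np.ndarray:
        return np.array([np.nan if getattr(r, metric) is None
                         else float(getattr(r, metric)) for r in self.reports])

    def to_frame(self):
        import pandas as pd

        rows = []
        for s, rep in zip(self.sweep, self.reports):
            for name in MetricReport.COLUMNS:
                rows.append({"error_class": self.error_class, "model": self.model,
                             "sweep_value": s, "metric": name,
                             "value": getattr(rep, name), "seed": self.seed})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _next_node_id(g: SpatialGraph) -> int:
    ids = [n for n in g.nodes if isinstance(n, (int, np.integer))]
    return (max(ids) + 1) if ids else 0


def _cleanup(g: SpatialGraph) -> None:
    """Post-attack normalization: drop degree-0 nodes, merge degree-2 nodes."""
    _merge_all_degree2(g)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])


def _edge_profiles(d: dict, sl) -> dict:
    out = {}
    for name in ("radius", "intensity"):
        if d.get(name) is not None:
            out[name] = d[name][sl]
    return out


def _remove_random_edges(g: SpatialGraph, fraction: float, rng) -> None:
    edges = sorted(g.edges(keys=True))
    n_remove = int(round(fraction * len(edges)))
    if n_remove == 0:
        return
    idx = rng.choice(len(edges), size=n_remove, replace=False)
    for i in idx:
        g.remove_edge(*edges[i])


# ---------------------------------------------------------------------------
# node disconnections
# ---------------------------------------------------------------------------

def attack_node_disconnections(g: SpatialGraph, model: str, target: float,
                               seed: int) -> SpatialGraph:
    """Detach branches from junctions (or delete edges at random).

    ``target`` is the fraction of nodes to affect. The physical model
    processes junction (degree >= 3) nodes in ascending order of their
    smallest incident-edge radius and trims that edge free over one local
    diameter, creating a new degree-1 node; the random model deletes
    ``round(target * E)`` edges uniformly. Both end with degree-0 removal
    and degree-2 merging.
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError("target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = g.copy()
    if model == "random":
        _remove_random_edges(g, target, rng)
        _cleanup(g)
        return g
    if model != "physical":
        raise ValueError(f"unknown model {model!r}")

    def _end_radius(u, v, k):
        d = g.edges[u, v, k]
        rad = d.get("radius")
        if rad is None:
            return d["weight"]
        pts = g.oriented_pts(u, v, k)
        return float(rad[0] if np.allclose(pts[0], g.nodes[u]["pos"])
                     or len(rad) == 1 else rad[-1])

    junctions = [n for n in g.nodes if g.degree(n) >= 3]
    n_affect = int(round(target * g.number_of_nodes()))
    if n_affect > len(junctions):
        warnings.warn(
            f"target fraction {target:.2f} exceeds the available junction "
            f"fraction {len(junctions) / max(g.number_of_nodes(), 1):.2f}; clamped",
            stacklevel=2)
        n_affect = len(junctions)
    ranked = sorted(junctions,
                    key=lambda n: min(_end_radius(n, v, k)
                                      for _, v, k in g.edges(n, keys=True)))
    next_id = _next_node_id(g)
    for n in ranked[:n_affect]:
        inc = sorted(g.edges(n, keys=True),
                     key=lambda e: _end_radius(n, e[1], e[2]))
        _, v, k = inc[0]
        d = dict(g.edges[n, v, k])
        pts = g.oriented_pts(n, v, k)
        flipped = not np.array_equal(pts, d["pts"])
        rad = d.get("radius")
        inten = d.get("intensity")
        if flipped:
            rad = rad[::-1] if rad is not None else None
            inten = inten[::-1] if inten is not None else None
        r_local = float(rad[0]) if rad is not None else 0.1
        trim_len = max(2.0 * r_local, 0.2)  # one local diameter, >= 2 voxels
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        cut = int(np.searchsorted(arc, trim_len))
        cut = min(max(cut, 1), len(pts) - 2)
        g.remove_edge(n, v, key=k)
        new_pts = pts[cut:]
        g.add_spatial_node(next_id, new_pts[0], kind="detached")
        g.add_polyline_edge(next_id, v, new_pts,
                            radius=rad[cut:] if rad is not None else None,
                            intensity=inten[cut:] if inten is not None else None)
        next_id += 1
    _cleanup(g)
    return g


# ---------------------------------------------------------------------------
# edge bridges
# ---------------------------------------------------------------------------

def _point_table(g: SpatialGraph):
    """All polyline points with (edge triple, index); interior sampling."""
    pts, owner = [], []
    for u, v, k, d in g.edges(keys=True, data=True):
        p = d["pts"]
        for i in range(len(p)):
            pts.append(p[i])
            owner.append((u, v, k, i))
    return np.asarray(pts), owner


def _split_edge_at(g: SpatialGraph, u, v, k, index: int, next_id: int):
    """Split edge (u, v, k) at polyline index, returning the split node id.

    When the index falls on (or next to) an endpoint the existing node is
    returned and the graph is unchanged.
    """
    d = g.edges[u, v, k]
    pts = g.oriented_pts(u, v, k)
    if not np.array_equal(pts, d["pts"]):
        index = len(pts) - 1 - index
        d = dict(d)
        for name in ("radius", "intensity"):
            if d.get(name) is not None:
                d[name] = d[name][::-1]
    if index <= 0:
        return u, next_id
    if index >= len(pts) - 1:
        return v, next_id
    g.remove_edge(u, v, key=k)
    g.add_spatial_node(next_id, pts[index], kind="bridge-anchor")
    g.add_polyline_edge(u, next_id, pts[:index + 1],
                        **_edge_profiles(d, slice(None, index + 1)))
    g.add_polyline_edge(next_id, v, pts[index:],
                        **_edge_profiles(d, slice(index, None)))
    return next_id, next_id + 1


def attack_edge_bridges(g: SpatialGraph, model: str, target: float,
                        anisotropy: float = DEFAULT_BRIDGE_ANISOTROPY,
                        seed: int = 0, neighbor_k: int = 32) -> SpatialGraph:
    """Add artificial bridges between close (or random) pairs of edges.

    Physical: candidate bridges are the closest voxel pairs between
    distinct, non-adjacent edges under the anisotropic metric (x and y
    scaled by ``anisotropy``, z unscaled); every candidate with weighted
    distance <= ``target`` (µm) is added, shortest first. Random: ``target``
    is the number of bridges, drawn between uniformly chosen voxels of
    distinct non-adjacent edges (duplicates excluded). Bridge edges are
    straight polylines whose radius is the smaller of the two local radii.
    """
    if g.number_of_edges() < 2:
        raise ValueError("need at least two edges to bridge")
    rng = np.random.default_rng(seed)
    g = g.copy()
    pts, owner = _point_table(g)

    candidates: list[tuple[float, tuple, tuple]] = []
    if model == "physical":
        scaled = pts * np.array([anisotropy, anisotropy, 1.0])
        tree = cKDTree(scaled)
        k_query = min(neighbor_k, len(pts))
        dists, idxs = tree.query(scaled, k=k_query,
                                 distance_upper_bound=max(target, 1e-9))
        best: dict[tuple, tuple] = {}
        adjacency = {}  # edge triple -> endpoint set
        for (u, v, k, _i) in owner:
            adjacency[(u, v, k)] = {u, v}
        for i in range(len(pts)):
            ei = owner[i][:3]
            for dist, j in zip(np.atleast_1d(dists[i]), np.atleast_1d(idxs[i])):
                if not np.isfinite(dist) or j >= len(pts) or j == i:
                    continue
                ej = owner[j][:3]
                if ej == ei or (adjacency[ei] & adjacency[ej]):
                    continue  # same or node-sharing edges never bridge
                key = tuple(sorted((ei, ej)))
                if key not in best or dist < best[key][0]:
                    best[key] = (float(dist), pts[i], pts[j])
        candidates = sorted(best.values(), key=lambda t: t[0])
        candidates = [c for c in candidates if c[0] <= target]
    elif model == "random":
        n_bridges = int(round(target))
        seen = set()
        guard = 0
        while len(candidates) < n_bridges and guard < 100 * max(n_bridges, 1):
            guard += 1
            i, j = rng.integers(0, len(pts), size=2)
            ei, ej = owner[i][:3], owner[j][:3]
            if ei == ej or ({ei[0], ei[1]} & {ej[0], ej[1]}):
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            candidates.append((0.0, pts[i], pts[j]))
    else:
        raise ValueError(f"unknown model {model!r}")

    next_id = _next_node_id(g)
    locator = {}  # point bytes -> (u, v, k)
    for (u, v, k, i), p in zip(owner, pts):
        locator[p.tobytes()] = (u, v, k)

    def _current_edge(point: np.ndarray):
        triple = locator[point.tobytes()]
        u, v, k = triple
        if g.has_edge(u, v, k):
            d = g.edges[u, v, k]
            idx = np.where(np.all(np.isclose(d["pts"], point), axis=1))[0]
            if len(idx):
                return u, v, k, int(idx[0])
        # edge was split by an earlier bridge: find the fragment
        for u2, v2, k2, d in g.edges(keys=True, data=True):
            idx = np.where(np.all(np.isclose(d["pts"], point), axis=1))[0]
            if len(idx):
                locator[point.tobytes()] = (u2, v2, k2)
                return u2, v2, k2, int(idx[0])
        return None

    for _dist, point_a, point_b in candidates:
        loc_a = _current_edge(point_a)
        loc_b = _current_edge(point_b)
        if loc_a is None or loc_b is None:
            continue
        na, next_id = _split_edge_at(g, *loc_a[:3], loc_a[3], next_id)
        loc_b = _current_edge(point_b)  # splitting a may have touched b's edge
        if loc_b is None:
            continue
        nb, next_id = _split_edge_at(g, *loc_b[:3], loc_b[3], next_id)
        if na == nb or g.has_edge(na, nb):
            continue
        pa = g.nodes[na]["pos"]
        pb = g.nodes[nb]["pos"]
        n_pts = max(2, int(np.ceil(np.linalg.norm(pb - pa) / 0.1)) + 1)
        line = np.linspace(pa, pb, n_pts)
        r_a = _local_radius(g, na)
        r_b = _local_radius(g, nb)
        radius = None
        if r_a is not None and r_b is not None:
            radius = np.full(n_pts, min(r_a, r_b))
        g.add_polyline_edge(na, nb, line, radius=radius, synthetic=True)
    return g


def _local_radius(g: SpatialGraph, n):
    vals = []
    for _, v, k in g.edges(n, keys=True):
        d = g.edges[n, v, k]
        rad = d.get("radius")
        if rad is None:
            continue
        pts = g.oriented_pts(n, v, k)
        vals.append(float(rad[0] if np.array_equal(pts, d["pts"]) else rad[-1]))
    return min(vals) if vals else None


# ---------------------------------------------------------------------------
# missing edges
# ---------------------------------------------------------------------------

def attack_missing_edges(g: SpatialGraph, model: str, target: float,
                         attribute: str = "intensity",
                         seed: int = 0) -> SpatialGraph:
    """Erase weakly stained (or random) edges, fragmenting the graph.

    Physical: every polyline point whose attribute value (intensity counts,
    or diameter in µm for ``attribute='radius'``) falls below ``target`` is
    erased; surviving fragments of at least two points become separate
    edges with new degree-1 endpoint nodes, and wholly erased edges
    disappear. Random: ``target`` is the fraction of whole edges deleted
    uniformly. Nodes left with degree 0 are removed.
    """
    rng = np.random.default_rng(seed)
    g = g.copy()
    if model == "random":
        if not 0.0 <= target <= 1.0:
            raise ValueError("random-model target is a fraction in [0, 1]")
        _remove_random_edges(g, target, rng)
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
        return g
    if model != "physical":
        raise ValueError(f"unknown model {model!r}")

    next_id = _next_node_id(g)
    for u, v, k, d in list(g.edges(keys=True, data=True)):
        profile = d.get(attribute)
        if profile is None:
            raise ValueError(f"edge ({u}, {v}, {k}) lacks a {attribute!r} profile")
        values = 2.0 * profile if attribute == "radius" else profile
        keep = values >= target
        if keep.all():
            continue
        pts = g.oriented_pts(u, v, k)
        flipped = not np.array_equal(pts, d["pts"])
        prof = {name: (d[name][::-1] if flipped else d[name])
                for name in ("radius", "intensity") if d.get(name) is not None}
        keep_o = keep[::-1] if flipped else keep
        g.remove_edge(u, v, key=k)
        # contiguous runs of surviving points become fragment edges
        padded = np.concatenate([[False], keep_o, [False]])
        starts = np.where(~padded[:-1] & padded[1:])[0]
        ends = np.where(padded[:-1] & ~padded[1:])[0]
        for s, e in zip(starts, ends):
            if e - s < 2:
                continue
            frag_pts = pts[s:e]
            frag_prof = {name: arr[s:e] for name, arr in prof.items()}
            if s == 0:
                a = u
            else:
                a = next_id
                g.add_spatial_node(a, frag_pts[0], kind="fragment-end")
                next_id += 1
            if e == len(pts):
                b = v
            else:
                b = next_id
                g.add_spatial_node(b, frag_pts[-1], kind="fragment-end")
                next_id += 1
            g.add_polyline_edge(a, b, frag_pts, **frag_prof)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return g


# ---------------------------------------------------------------------------
# sweeps and reliability
# ---------------------------------------------------------------------------

def apply_attack(g: SpatialGraph, error_class: str, model: str, target: float,
                 seed: int, **kwargs) -> SpatialGraph:
    if error_class == "node_disconnections":
        return attack_node_disconnections(g, model, target, seed)
    if error_class == "edge_bridges":
        return attack_edge_bridges(g, model, target, seed=seed, **kwargs)
    if error_class == "missing_edges":
        return attack_missing_edges(g, model, target, seed=seed, **kwargs)
    raise ValueError(f"unknown error class {error_class!r}")


def sweep(gt: SpatialGraph, error_class: str, model: str, sweep_values,
          seed: int = 0, **kwargs) -> AttackCurve:
    """Apply one error model at each sweep level (afresh on the pristine GT).

    The first sweep value must be the no-error level (0); its report is
    computed on the unmodified input graph.
    """
    sweep_values = np.asarray(sweep_values, dtype=float)
    if sweep_values[0] != 0:
        raise ValueError("the first sweep value must be 0 (no error)")
    reports = [report(gt, seed=seed)]
    for val in sweep_values[1:]:
        attacked = apply_attack(gt, error_class, model, float(val), seed, **kwargs)
        reports.append(report(attacked, seed=seed))
    return AttackCurve(error_class=error_class, model=model, sweep=sweep_values,
                       reports=reports, seed=seed)


def confusion_point(curve_a: AttackCurve, curve_b: AttackCurve,
                    metric: str) -> float | None:
    """Sweep value where the two regions' metric curves cross, or None.

    The smallest sweep value at which the sign of (A - B) changes, located
    by linear interpolation; identical curves (or curves that never cross)
    have no confusion point.
    """
    if len(curve_a.sweep) != len(curve_b.sweep) or \
            not np.allclose(curve_a.sweep, curve_b.sweep):
        raise ValueError("curves must share the same sweep grid")
    diff = curve_a.values(metric) - curve_b.values(metric)
    ok = np.isfinite(diff)
    s = curve_a.sweep[ok]
    diff = diff[ok]
    if len(diff) < 2 or np.all(diff == 0):
        return None
    for i in range(1, len(diff)):
        d0, d1 = diff[i - 1], diff[i]
        if d0 == 0 and d1 == 0:
            continue
        if d0 == 0:
            return float(s[i - 1])
        if d0 * d1 < 0:
            return float(s[i - 1] + (s[i] - s[i - 1]) * d0 / (d0 - d1))
    return None


def reliability_table(gen_reports: dict, cle_reports: dict, gt_reports: dict):
    """Per-metric uncertainty ratios of pipeline errors vs region contrast.

    Inputs are mappings region -> MetricReport (two regions) for the
    generated, cleaned and ground-truth graphs. For each metric:
    ``delta_gen`` / ``delta_cle`` are the maxima over regions of the
    absolute generated/cleaned deviation from the GT, ``delta_gt12`` is the
    absolute GT difference between the regions, and a metric is flagged
    reliable when ``delta_cle / delta_gt12 < 1`` (remaining errors smaller
    than the topological contrast to be detected).
    """
    import pandas as pd

    regions = sorted(gt_reports)
    if len(regions) != 2 or sorted(gen_reports) != regions \
            or sorted(cle_reports) != regions:
        raise ValueError("need generated/cleaned/GT reports for the same 2 regions")
    rows = []
    for name in MetricReport.COLUMNS:
        vals = {}
        skip = False
        for label, reps in (("gen", gen_reports), ("cle", cle_reports),
                            ("gt", gt_reports)):
            for r in regions:
                v = getattr(reps[r], name)
                if v is None:
                    skip = True
                vals[(label, r)] = v
        if skip:
            rows.append({"metric": name, "note": "missing value; skipped"})
            continue
        d_gen = max(abs(vals[("gen", r)] - vals[("gt", r)]) for r in regions)
        d_cle = max(abs(vals[("cle", r)] - vals[("gt", r)]) for r in regions)
        d_gt = abs(vals[("gt", regions[0])] - vals[("gt", regions[1])])
        ratio_gen = d_gen / d_gt if d_gt > 0 else np.inf
        ratio_cle = d_cle / d_gt if d_gt > 0 else np.inf
        rows.append({"metric": name, "delta_gen": d_gen, "delta_cle": d_cle,
                     "delta_gt12": d_gt, "ratio_gen": ratio_gen,
                     "ratio_cle": ratio_cle, "reliable": bool(ratio_cle < 1)})
    return pd.DataFrame(rows)


def plot_curves(curves: list[AttackCurve], metrics_to_plot=None, path=None):
    """Render attack curves, one panel per metric (matplotlib figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics_to_plot = metrics_to_plot or ("n", "e", "s", "k", "fs",
                                          "mean_shortest_path")
    ncol = 3
    nrow = int(np.ceil(len(metrics_to_plot) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False)
    for ax, name in zip(axes.ravel(), metrics_to_plot):
        for curve in curves:
            ax.plot(curve.sweep, curve.values(name), marker="o", markersize=3,
                    label=f"{curve.error_class}/{curve.model}")
        ax.set_title(name)
        ax.set_xlabel("sweep value")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
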