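"""Complex-network metrics of the porosity graph.

Twelve metrics summarize one spatial graph:

========  ==========================================================
N, E      node / edge counts
<k>       mean degree, 2E/N
gamma     gamma index, 2E/(N(N-1)) — fraction of realized node pairs
S         node fraction of the largest connected component, N*/N
K         number of connected components
FS        fault sensitivity — fraction of largest-component edges
          whose removal splits that component (bridge-edge fraction)
W         total edge length (µm)
<w>       mean edge length, W/E (µm)
<l>       mean weighted shortest-path length over largest-component
          node pairs (µm)
D         diameter: longest shortest path (µm)
DI        mean detour index: shortest-path length over Euclidean
          node distance, averaged over the same pairs (>= 1)
========  ==========================================================

Path metrics (<l>, D, DI) are restricted to the largest component; above a
size cutoff they are estimated from a seeded uniform sample of node pairs.
Sliding-window maps recompute the full suite on XY patches with overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

from .spatialgraph import SpatialGraph

__all__ = [
    "MetricReport",
    "MetricMap",
    "gamma_index",
    "mean_degree",
    "linear_edge_density",
    "descriptors",
    "connectivity",
    "distances",
    "report",
    "metric_maps",
]

logger = logging.getLogger(__name__)

#: pairs closer than one voxel are excluded from the detour index
MIN_PAIR_DISTANCE_UM = 0.1

#: largest-component size above which path metrics switch to sampling
SAMPLED_MODE_THRESHOLD = 2000


@dataclass
class MetricReport:
    """The 12-metric summary of one graph (missing values are None)."""

    n: int | None = None
    e: int | None = None
    mean_degree: float | None = None
    gamma: float | None = None
    s: float | None = None
    k: int | None = None
    fs: float | None = None
    w: float | None = None
    mean_edge_length: float | None = None
    mean_shortest_path: float | None = None
    diameter: float | None = None
    detour_index: float | None = None
    n_star: int | None = None
    e_star: int | None = None

    #: CSV column order (mirrors the global-analysis table layout)
    COLUMNS = ("n", "e", "mean_degree", "gamma", "mean_edge_length", "w",
               "mean_shortest_path", "diameter", "detour_index", "s", "k", "fs")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_row(self) -> dict:
        return {name: getattr(self, name) for name in self.COLUMNS}


def gamma_index(n: int, e: int) -> float | None:
    """2E / (N (N-1)): the fraction of node pairs realized as edges."""
    if n < 2:
        return None
    return 2.0 * e / (n * (n - 1))


def mean_degree(n: int, e: int) -> float | None:
    return 2.0 * e / n if n else None


def linear_edge_density(total_length_um: float, volume_mm3: float) -> float:
    """Edge length per unit tissue volume, in mm/mm^3."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be > 0")
    return (total_length_um * 1e-3) / volume_mm3


# ---------------------------------------------------------------------------

def descriptors(g: SpatialGraph):
    """(N, E, <k>, gamma); <k> and gamma are None for degenerate graphs."""
    n = g.number_of_nodes()
    e = g.number_of_edges()
    return n, e, mean_degree(n, e), gamma_index(n, e)


def _largest_component(g: SpatialGraph) -> set:
    return max(nx.connected_components(g), key=len)


def connectivity(g: SpatialGraph):
    """(S, K, FS). FS counts bridge edges of the largest component.

    On a multigraph an edge is a bridge only if it is the sole edge
    between its endpoints and its removal disconnects them; self-loops and
    parallel duplicates are never bridges.
    """
    if g.number_of_nodes() == 0:
        return None, None, None
    comps = list(nx.connected_components(g))
    k = len(comps)
    largest = max(comps, key=len)
    s = len(largest) / g.number_of_nodes()
    sub = g.subgraph(largest)
    e_star = sub.number_of_edges()
    if e_star == 0:
        return s, k, None
    simple = nx.Graph(sub)
    simple.remove_edges_from(nx.selfloop_edges(simple))
    n_bridges = sum(1 for u, v in nx.bridges(simple)
                    if sub.number_of_edges(u, v) == 1)
    return s, k, n_bridges / e_star


def _euclid(g: SpatialGraph, i, j) -> float:
    return float(np.linalg.norm(g.nodes[i]["pos"] - g.nodes[j]["pos"]))


def distances(g: SpatialGraph, mode: str = "auto", sample_pairs: int = 10_000,
              seed: int = 0):
    """(W, <w>, <l>, D, DI).

    W and <w> cover all edges of the graph; <l>, D and DI are computed on
    the largest component with arc-length (``weight``) shortest paths. In
    ``sampled`` mode a seeded uniform sample of ordered node pairs
    estimates <l> and DI, and D is the maximum eccentricity over the
    sampled sources. ``auto`` selects exact below 2000 largest-component
    nodes.
    """
    e = g.number_of_edges()
    if e == 0 or g.number_of_nodes() == 0:
        return (0.0 if g.number_of_nodes() else None, None, None, None, None)
    w = g.total_length()
    mean_w = w / e
    largest = sorted(_largest_component(g))
    n_star = len(largest)
    if n_star < 2:
        return w, mean_w, None, None, None
    if mode == "auto":
        mode = "exact" if n_star <= SAMPLED_MODE_THRESHOLD else "sampled"
    sub = g.subgraph(largest)

    path_sum = 0.0
    pair_count = 0
    diam = 0.0
    di_sum = 0.0
    di_count = 0
    skipped = 0

    if mode == "exact":
        for src, dists in nx.all_pairs_dijkstra_path_length(sub, weight="weight"):
            for dst, l in dists.items():
                if dst == src:
                    continue
                path_sum += l
                pair_count += 1
                diam = max(diam, l)
                d = _euclid(g, src, dst)
                if d < MIN_PAIR_DISTANCE_UM:
                    skipped += 1
                else:
                    di_sum += l / d
                    di_count += 1
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        idx = np.array(largest, dtype=object)
        src_idx = rng.integers(0, n_star, size=sample_pairs)
        dst_idx = rng.integers(0, n_star, size=sample_pairs)
        by_src: dict = {}
        for a, b in zip(src_idx, dst_idx):
            if a != b:
                by_src.setdefault(idx[a], []).append(idx[b])
        for src, targets in by_src.items():
            dists = nx.single_source_dijkstra_path_length(sub, src, weight="weight")
            diam = max(diam, max(dists.values()))
            for dst in targets:
                l = dists[dst]
                path_sum += l
                pair_count += 1
                d = _euclid(g, src, dst)
                if d < MIN_PAIR_DISTANCE_UM:
                    skipped += 1
                else:
                    di_sum += l / d
                    di_count += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if skipped:
        logger.info("detour index: excluded %d near-coincident node pairs", skipped)
    mean_l = path_sum / pair_count if pair_count else None
    di = di_sum / di_count if di_count else None
    return w, mean_w, mean_l, diam, di


def report(g: SpatialGraph, mode: str = "auto", sample_pairs: int = 10_000,
           seed: int = 0) -> MetricReport:
    """Bundle descriptors, connectivity and distance metrics into one report."""
    rep = MetricReport()
    if g.number_of_nodes() == 0:
        return rep
    rep.n, rep.e, rep.mean_degree, rep.gamma = descriptors(g)
    rep.s, rep.k, rep.fs = connectivity(g)
    rep.w, rep.mean_edge_length, rep.mean_shortest_path, rep.diameter, \
        rep.detour_index = distances(g, mode=mode, sample_pairs=sample_pairs,
                                     seed=seed)
    largest = _largest_component(g)
    rep.n_star = len(largest)
    rep.e_star = g.subgraph(largest).number_of_edges()
    return rep


# ---------------------------------------------------------------------------
# spatial metric maps
# ---------------------------------------------------------------------------

@dataclass
class MetricMap:
    """2D sliding-window map of one metric over the XY plane."""

    metric: str
    values: np.ndarray  # (ny, nx) float, NaN where empty
    empty: np.ndarray  # (ny, nx) bool — patches with no nodes
    patch_size_um: float
    overlap: float
    origin_xy: tuple[float, float] = (0.0, 0.0)


def patch_positions(extent: float, patch: float, overlap: float) -> np.ndarray:
    """Left edges of sliding-window patches along one axis."""
    step = patch * (1.0 - overlap)
    n = int(np.floor((extent - patch) / step)) + 1
    return np.arange(max(n, 1)) * step


def metric_maps(g: SpatialGraph, volume_extent_um, patch_xy_um: float = 25.0,
                overlap: float = 0.5, seed: int = 0) -> dict[str, MetricMap]:
    """Compute the full metric suite on overlapping XY patches.

    A node belongs to a patch iff its centroid falls inside the patch
    footprint (the full Z range is included); an edge belongs iff both its
    endpoints do, and counts with its full length. Patches without nodes
    are flagged empty, not zero-filled.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    lx, ly = float(volume_extent_um[0]), float(volume_extent_um[1])
    if patch_xy_um > lx or patch_xy_um > ly:
        raise ValueError("patch must be smaller than the volume extent")
    xs = patch_positions(lx, patch_xy_um, overlap)
    ys = patch_positions(ly, patch_xy_um, overlap)
    pos = g.node_positions()
    node_ids = list(g.nodes)
    grids = {name: np.full((len(ys), len(xs)), np.nan)
             for name in MetricReport.COLUMNS}
    empty = np.zeros((len(ys), len(xs)), dtype=bool)
    for iy, y0 in enumerate(ys):
        for ix, x0 in enumerate(xs):
            if len(node_ids) == 0:
                empty[iy, ix] = True
                continue
            inside = ((pos[:, 0] >= x0) & (pos[:, 0] < x0 + patch_xy_um)
                      & (pos[:, 1] >= y0) & (pos[:, 1] < y0 + patch_xy_um))
            members = [n for n, ok in zip(node_ids, inside) if ok]
            if not members:
                empty[iy, ix] = True
                continue
            sub = SpatialGraph(g.subgraph(members))
            rep = report(sub, seed=seed)
            for name in MetricReport.COLUMNS:
                val = getattr(rep, name)
                grids[name][iy, ix] = np.nan if val is None else val
    return {name: MetricMap(metric=name, values=grids[name], empty=empty,
                            patch_size_um=patch_xy_um, overlap=overlap)
            for name in MetricReport.COLUMNS}
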