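"""Shared fixtures and graph-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from dentinet.spatialgraph import SpatialGraph


def straight_pts(a, b, n=None):
    """Straight polyline from a to b sampled every ~0.1 µm."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n is None:
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / 0.1)) + 1)
    return np.linspace(a, b, n)


def build_graph(nodes: dict, edges: list) -> SpatialGraph:
    """Build a SpatialGraph from {id: pos} and [(u, v), ...] or
    [(u, v, dict(pts=..., radius=..., intensity=...)), ...]; straight
    polylines are generated when pts is omitted."""
    g = SpatialGraph()
    for n, pos in nodes.items():
        g.add_spatial_node(n, pos)
    for edge in edges:
        u, v = edge[0], edge[1]
        opts = dict(edge[2]) if len(edge) > 2 else {}
        pts = opts.pop("pts", None)
        if pts is None:
            pts = straight_pts(nodes[u], nodes[v])
        radius = opts.pop("radius", None)
        if np.isscalar(radius):
            radius = np.full(len(pts), float(radius))
        intensity = opts.pop("intensity", None)
        if np.isscalar(intensity):
            intensity = np.full(len(pts), float(intensity))
        g.add_polyline_edge(u, v, pts, radius=radius, intensity=intensity, **opts)
    return g


def random_spatial_graph(rng, n_nodes=None, n_edges=None, box=20.0,
                         allow_multi=False, allow_self=False) -> SpatialGraph:
    """Random spatial graph with straight edges, for oracle comparisons."""
    if n_nodes is None:
        n_nodes = int(rng.integers(2, 51))
    if n_edges is None:
        n_edges = int(rng.integers(1, min(2 * n_nodes, 60)))
    pos = rng.uniform(0, box, size=(n_nodes, 3))
    g = SpatialGraph()
    for i in range(n_nodes):
        g.add_spatial_node(i, pos[i])
    for _ in range(n_edges):
        u, v = rng.integers(0, n_nodes, size=2)
        if u == v and not allow_self:
            continue
        if not allow_multi and g.has_edge(u, v):
            continue
        if np.linalg.norm(pos[u] - pos[v]) < 1e-6:
            continue
        g.add_polyline_edge(int(u), int(v), straight_pts(pos[u], pos[v], n=5))
    return g


@pytest.fixture(scope="session")
def mini_pipeline():
    """One small end-to-end run (phantom -> cleaned graph), shared."""
    from dentinet import clean as cl
    from dentinet import graphbuild as gb
    from dentinet import phantom as ph
    from dentinet import segment as seg

    spec = ph.PhantomSpec(domain_size=(12.8, 12.8, 12.95), tubule_count=9,
                          branch_density=0.2)
    gt = ph.generate_network(spec, seed=7)
    vol = ph.render_volume(gt, ph.ImagingSpec().noiseless, seed=7)
    iso = seg.equalize_and_reslice(vol, 100.0)
    resp = seg.vesselness(iso, seg.VesselnessParams(sigmas=(1.0, 2.0, 3.0, 4.0, 5.0)))
    mask = seg.denoise_mask(seg.segment(resp))
    skel = gb.skeletonize(mask, pad=10)
    g = gb.extract_graph(skel, raw=iso, mask=mask)
    gc = cl.clean(g)
    return {"spec": spec, "gt": gt, "vol": vol, "iso": iso, "resp": resp,
            "mask": mask, "skel": skel, "generated": g, "cleaned": gc}
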