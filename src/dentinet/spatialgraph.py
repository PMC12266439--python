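"""Spatially embedded multigraphs of the porosity network.

A :class:`SpatialGraph` is a :class:`networkx.MultiGraph` whose nodes carry a
world position and whose edges carry the centerline geometry of the vessel
they represent:

node attributes
    ``pos``       (3,) float array, µm, ``(x, y, z)``
    ``voxels``    optional (k, 3) int array of skeleton voxel indices (z, y, x)
    ``kind``      optional string label (``tubule-end``, ``branch-point``, ...)

edge attributes
    ``pts``       (n, 3) float array, µm — ordered centerline polyline
    ``weight``    float, µm — arc length (sum of consecutive point distances)
    ``radius``    optional (n,) float array, µm — local vessel radius per point
    ``intensity`` optional (n,) float array — raw image intensity per point
    ``synthetic`` optional bool — True for elements created by annotation
"""

from __future__ import annotations

import json

import networkx as nx
import numpy as np

__all__ = [
    "SpatialGraph",
    "polyline_length",
    "write_graphml",
    "read_graphml",
    "write_jsonl",
]


def polyline_length(pts: np.ndarray) -> float:
    """Arc length of a polyline: sum of pairwise consecutive distances."""
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"polyline must be (n, 3), got {pts.shape}")
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


class SpatialGraph(nx.MultiGraph):
    """Multigraph with spatially embedded nodes and polyline edges."""

    def add_spatial_node(self, n, pos, **attrs):
        self.add_node(n, pos=np.asarray(pos, dtype=float), **attrs)

    def add_polyline_edge(self, u, v, pts, radius=None, intensity=None, **attrs):
        """Add an edge with geometry; ``weight`` is derived from ``pts``.

        Returns the edge key.
        """
        pts = np.asarray(pts, dtype=float)
        attrs["pts"] = pts
        attrs["weight"] = polyline_length(pts)
        if radius is not None:
            radius = np.asarray(radius, dtype=float)
            if len(radius) != len(pts):
                raise ValueError("radius profile length must match pts")
            attrs["radius"] = radius
        if intensity is not None:
            intensity = np.asarray(intensity, dtype=float)
            if len(intensity) != len(pts):
                raise ValueError("intensity profile length must match pts")
            attrs["intensity"] = intensity
        return self.add_edge(u, v, **attrs)

    def node_positions(self) -> np.ndarray:
        """(N, 3) array of node positions in insertion order."""
        if self.number_of_nodes() == 0:
            return np.zeros((0, 3))
        return np.array([self.nodes[n]["pos"] for n in self.nodes])

    def oriented_pts(self, u, v, key) -> np.ndarray:
        """Edge polyline ordered so that it starts at node ``u``.

        Orientation is resolved by which polyline end lies closer to the
        node positions; for self-loops the stored order is returned.
        """
        pts = self.edges[u, v, key]["pts"]
        if u == v or len(pts) < 2:
            return pts
        pu = self.nodes[u]["pos"]
        pv = self.nodes[v]["pos"]
        d_fwd = np.linalg.norm(pts[0] - pu) + np.linalg.norm(pts[-1] - pv)
        d_rev = np.linalg.norm(pts[-1] - pu) + np.linalg.norm(pts[0] - pv)
        return pts if d_fwd <= d_rev else pts[::-1]

    def total_length(self) -> float:
        """Total edge length W in µm."""
        return float(sum(d.get("weight", 0.0) for _, _, d in self.edges(data=True)))

    def copy(self, as_view=False) -> "SpatialGraph":
        g = super().copy(as_view=as_view)
        return g


_ARRAY_EDGE_ATTRS = ("pts", "radius", "intensity")


def write_graphml(g: SpatialGraph, path) -> None:
    """Serialize to GraphML; array attributes are JSON-encoded strings."""
    out = nx.MultiGraph()
    for n, d in g.nodes(data=True):
        attrs = {}
        if "pos" in d:
            x, y, z = (float(c) for c in d["pos"])
            attrs.update(x=x, y=y, z=z)
        if "voxels" in d:
            attrs["voxels"] = json.dumps(np.asarray(d["voxels"]).tolist())
        if "kind" in d:
            attrs["kind"] = str(d["kind"])
        out.add_node(n, **attrs)
    for u, v, k, d in g.edges(keys=True, data=True):
        attrs = {"weight": float(d.get("weight", 0.0))}
        for name in _ARRAY_EDGE_ATTRS:
            if name in d:
                attrs[name] = json.dumps(np.asarray(d[name]).tolist())
        if d.get("synthetic"):
            attrs["synthetic"] = True
        out.add_edge(u, v, key=k, **attrs)
    nx.write_graphml(out, path)


def read_graphml(path) -> SpatialGraph:
    raw = nx.read_graphml(path, force_multigraph=True)
    g = SpatialGraph()
    for n, d in raw.nodes(data=True):
        attrs = {}
        if all(c in d for c in "xyz"):
            attrs["pos"] = np.array([d["x"], d["y"], d["z"]], dtype=float)
        if "voxels" in d:
            attrs["voxels"] = np.array(json.loads(d["voxels"]), dtype=int)
        if "kind" in d:
            attrs["kind"] = d["kind"]
        g.add_node(_coerce_id(n), **attrs)
    for u, v, k, d in raw.edges(keys=True, data=True):
        attrs = {"weight": float(d.get("weight", 0.0))}
        if "pts" in d:
            attrs["pts"] = np.array(json.loads(d["pts"]), dtype=float)
        if "radius" in d:
            attrs["radius"] = np.array(json.loads(d["radius"]), dtype=float)
        if "intensity" in d:
            attrs["intensity"] = np.array(json.loads(d["intensity"]), dtype=float)
        if d.get("synthetic"):
            attrs["synthetic"] = True
        g.add_edge(_coerce_id(u), _coerce_id(v), key=_coerce_id(k), **attrs)
    return g


def _coerce_id(n):
    """GraphML stores ids as strings; restore integer ids where possible."""
    try:
        return int(n)
    except (TypeError, ValueError):
        return n


def write_jsonl(g: SpatialGraph, path) -> None:
    """Dump nodes then edges as JSON lines (one record per element)."""
    with open(path, "w") as fh:
        for n, d in g.nodes(data=True):
            rec = {"type": "node", "id": n}
            if "pos" in d:
                rec["pos"] = np.asarray(d["pos"]).tolist()
            if "kind" in d:
                rec["kind"] = d["kind"]
            fh.write(json.dumps(rec) + "\n")
        for u, v, k, d in g.edges(keys=True, data=True):
            rec = {"type": "edge", "u": u, "v": v, "key": k,
                   "weight": float(d.get("weight", 0.0))}
            for name in _ARRAY_EDGE_ATTRS:
                if name in d:
                    rec[name] = np.asarray(d[name]).tolist()
            fh.write(json.dumps(rec) + "\n")
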