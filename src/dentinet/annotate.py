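"""Marker-based manual correction of extracted graphs.

Ground-truth graphs are produced by applying point-marker annotations
(exported from an image viewer such as FIJI) to a cleaned graph. Markers
carry a world position in µm and one of five actions: delete the nearest
node, delete the nearest edge, add a node, add a straight edge between two
positions, or add an edge following a broken-line path. Elements created by
annotation carry ``synthetic=True`` and geometry-derived attributes only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import MetricReport
from .spatialgraph import SpatialGraph

__all__ = ["Marker", "AnnotationSet", "apply_annotations", "graph_delta"]

ACTIONS = ("delete_node", "delete_edge", "add_node", "add_straight_edge",
           "add_polyline_edge")

#: markers snap to the nearest element within this radius (µm; 5 voxels)
CAPTURE_RADIUS_UM = 0.5


@dataclass
class Marker:
    position: tuple[float, float, float]  # µm, (x, y, z)
    action: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        self.position = tuple(float(c) for c in self.position)


@dataclass
class AnnotationSet:
    markers: list[Marker]

    def __post_init__(self):
        for m in self.markers:
            if m.action == "add_polyline_edge":
                verts = m.payload.get("vertices", [])
                if len(verts) < 2:
                    raise ValueError("polyline edges need >= 2 vertices")

    @classmethod
    def from_csv(cls, path) -> "AnnotationSet":
        """Read markers from CSV (x_um, y_um, z_um, action, payload_json)."""
        df = pd.read_csv(path)
        markers = []
        for _, row in df.iterrows():
            payload = {}
            raw = row.get("payload_json")
            if isinstance(raw, str) and raw.strip():
                payload = json.loads(raw)
            markers.append(Marker(position=(row["x_um"], row["y_um"], row["z_um"]),
                                  action=row["action"], payload=payload))
        return cls(markers)

    def to_csv(self, path) -> None:
        rows = [{"x_um": m.position[0], "y_um": m.position[1],
                 "z_um": m.position[2], "action": m.action,
                 "payload_json": json.dumps(m.payload) if m.payload else ""}
                for m in self.markers]
        pd.DataFrame(rows).to_csv(path, index=False)


class UnresolvableMarkerError(ValueError):
    pass


def _nearest_node(g: SpatialGraph, pos: np.ndarray):
    best, best_d = None, np.inf
    for n, d in g.nodes(data=True):
        if "pos" not in d:
            continue
        dist = float(np.linalg.norm(d["pos"] - pos))
        if dist < best_d:
            best, best_d = n, dist
    return best, best_d


def _nearest_edge(g: SpatialGraph, pos: np.ndarray):
    best, best_d = None, np.inf
    for u, v, k, d in g.edges(keys=True, data=True):
        pts = d.get("pts")
        if pts is None or len(pts) == 0:
            continue
        dist = float(np.min(np.linalg.norm(pts - pos, axis=1)))
        if dist < best_d:
            best, best_d = (u, v, k), dist
    return best, best_d


def apply_annotations(g: SpatialGraph, ann: AnnotationSet,
                      capture_radius: float = CAPTURE_RADIUS_UM) -> SpatialGraph:
    """Apply markers in file order, returning the corrected graph.

    Delete markers must fall within ``capture_radius`` of an existing
    node/edge voxel, otherwise an :class:`UnresolvableMarkerError` names
    the marker index and the nearest element distance. ``add_*_edge``
    markers snap their endpoints to the nearest node (within the capture
    radius) or create a new node at the stated position.
    """
    g = g.copy()
    next_id = _fresh_id(g)
    for i, m in enumerate(ann.markers):
        pos = np.asarray(m.position, dtype=float)
        if m.action == "delete_node":
            node, dist = _nearest_node(g, pos)
            if node is None or dist > capture_radius:
                raise UnresolvableMarkerError(
                    f"marker {i} (delete_node): nearest node at {dist:.2f} µm, "
                    f"beyond the {capture_radius} µm capture radius")
            g.remove_node(node)
        elif m.action == "delete_edge":
            edge, dist = _nearest_edge(g, pos)
            if edge is None or dist > capture_radius:
                raise UnresolvableMarkerError(
                    f"marker {i} (delete_edge): nearest edge at {dist:.2f} µm, "
                    f"beyond the {capture_radius} µm capture radius")
            g.remove_edge(*edge)
        elif m.action == "add_node":
            g.add_spatial_node(next_id, pos, kind="annotated", synthetic=True)
            next_id += 1
        elif m.action == "add_straight_edge":
            end = np.asarray(m.payload["end"], dtype=float)
            a, next_id = _snap_or_create(g, pos, capture_radius, next_id)
            b, next_id = _snap_or_create(g, end, capture_radius, next_id)
            pts = np.linspace(g.nodes[a]["pos"], g.nodes[b]["pos"],
                              max(2, int(np.ceil(np.linalg.norm(
                                  g.nodes[b]["pos"] - g.nodes[a]["pos"]) / 0.1)) + 1))
            g.add_polyline_edge(a, b, pts, synthetic=True)
        elif m.action == "add_polyline_edge":
            verts = np.asarray(m.payload["vertices"], dtype=float)
            a, next_id = _snap_or_create(g, verts[0], capture_radius, next_id)
            b, next_id = _snap_or_create(g, verts[-1], capture_radius, next_id)
            pts = np.vstack([g.nodes[a]["pos"], verts[1:-1].reshape(-1, 3),
                             g.nodes[b]["pos"]])
            g.add_polyline_edge(a, b, pts, synthetic=True)
    return g


def _fresh_id(g: SpatialGraph) -> int:
    ids = [n for n in g.nodes if isinstance(n, (int, np.integer))]
    return (max(ids) + 1) if ids else 0


def _snap_or_create(g: SpatialGraph, pos: np.ndarray, capture_radius: float,
                    next_id: int):
    node, dist = _nearest_node(g, pos)
    if node is not None and dist <= capture_radius:
        return node, next_id
    g.add_spatial_node(next_id, pos, kind="annotated", synthetic=True)
    return next_id, next_id + 1


def graph_delta(a: MetricReport, b: MetricReport) -> pd.DataFrame:
    """Per-metric absolute and signed relative differences of two reports.

    Relative differences are (a - b) / b as a percent (rounded to integer
    for display); a zero or missing reference value flags the relative
    difference as undefined (NaN).
    """
    rows = []
    for name in MetricReport.COLUMNS:
        va, vb = getattr(a, name), getattr(b, name)
        if va is None or vb is None:
            rows.append({"metric": name, "abs_diff": np.nan,
                         "rel_diff_pct": np.nan})
            continue
        abs_diff = abs(va - vb)
        rel = np.nan if vb == 0 else 100.0 * (va - vb) / vb
        rows.append({"metric": name, "abs_diff": abs_diff,
                     "rel_diff_pct": rel,
                     "rel_diff_pct_rounded": (np.nan if np.isnan(rel)
                                              else int(round(rel)))})
    return pd.DataFrame(rows)
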