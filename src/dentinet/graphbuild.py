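"""Skeletonization and spatial multigraph extraction.

The porosity mask is thinned to a one-voxel-wide, topology-preserving
centerline (Lee's method), and a multigraph is traced from it: skeleton
voxels with a number of 26-neighbours different from 2 become nodes —
maximal 26-connected clusters of such voxels collapse into a single node at
their centre of gravity — and the degree-2 chains between them become edges
carrying the ordered voxel polyline, its arc length in µm, and per-point
radius (Euclidean distance transform of the mask) and raw-intensity
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

from .segment import PorosityMask
from .spatialgraph import SpatialGraph
from .volume import ImageVolume

__all__ = ["Skeleton", "skeletonize", "extract_graph", "extend_terminal_edges"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_OFFSETS = [(dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)]


@dataclass
class Skeleton:
    """One-voxel-thick medial representation of a porosity mask."""

    data: np.ndarray
    spacing: float  # nm, isotropic

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("skeleton must be 3D")

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) integer (z, y, x) coordinates of skeleton voxels."""
        return np.argwhere(self.data)

    def to_tiff(self, path) -> None:
        ImageVolume(self.data.astype(np.uint8) * 255,
                    spacing=(self.spacing,) * 3).to_tiff(path)


def skeletonize(mask: PorosityMask, pad: int = 0) -> Skeleton:
    """Topology-preserving thinning of the mask to its centerlines.

    With ``pad > 0`` the mask is extended by edge replication before
    thinning and cropped back afterwards: vessels cut by the volume border
    then keep their centerline all the way to the border instead of being
    retracted by roughly one vessel radius when the thinning rounds off
    the cut end.
    """
    data = mask.data
    if pad > 0:
        data = np.pad(data, pad, mode="edge")
    skel = _sk_skeletonize(data, method="lee") > 0
    if pad > 0:
        skel = skel[pad:-pad, pad:-pad, pad:-pad]
    # thinning can erase small compact components outright; restore one
    # medial voxel per vanished component so the component count of the
    # mask is preserved exactly
    labels, n_comp = ndi.label(mask.data, structure=_CONN26)
    if n_comp:
        has_skel = np.zeros(n_comp + 1, dtype=bool)
        has_skel[labels[skel]] = True
        missing = np.flatnonzero(~has_skel[1:]) + 1
        if len(missing):
            edt = ndi.distance_transform_edt(mask.data)
            for lab in missing:
                inside = np.argwhere(labels == lab)
                best = inside[np.argmax(edt[tuple(inside.T)])]
                skel[tuple(best)] = True
    return Skeleton(skel, spacing=mask.spacing)


def _neighbors(vox, skel_set):
    z, y, x = vox
    for dz, dy, dx in _OFFSETS:
        n = (z + dz, y + dy, x + dx)
        if n in skel_set:
            yield n


def extract_graph(skel: Skeleton,
                  raw: ImageVolume | None = None,
                  mask: PorosityMask | None = None) -> SpatialGraph:
    """Trace the attributed spatial multigraph of a skeleton.

    Nodes sit at skeleton voxels with ≠2 neighbours (branch and end
    points); junction voxel clusters collapse to one node at their centre
    of gravity. Edges follow degree-2 chains; pure voxel cycles with no
    junction get a single node carrying a self-loop. Radius profiles are
    sampled from the distance transform of ``mask``, intensity profiles
    from ``raw``, when provided (both must share the skeleton's grid).
    """
    if mask is not None and mask.data.shape != skel.data.shape:
        raise ValueError("skeleton and mask shapes differ")
    if raw is not None and raw.data.shape != skel.data.shape:
        raise ValueError("skeleton and raw volume shapes differ")

    spacing_um = skel.spacing / 1000.0
    coords = skel.coords
    skel_set = set(map(tuple, coords))

    # neighbor counts decide voxel roles
    ncount = ndi.convolve(skel.data.astype(np.uint8), _CONN26.astype(np.uint8),
                          mode="constant") - skel.data.astype(np.uint8)
    is_node_voxel = skel.data & (ncount != 2)

    labels, n_nodes = ndi.label(is_node_voxel, structure=_CONN26)
    node_of_voxel: dict[tuple, int] = {}
    node_voxels: dict[int, list[tuple]] = {i: [] for i in range(n_nodes)}
    for vox in map(tuple, np.argwhere(is_node_voxel)):
        nid = int(labels[vox]) - 1
        node_of_voxel[vox] = nid
        node_voxels[nid].append(vox)

    edt = None
    if mask is not None:
        edt = ndi.distance_transform_edt(mask.data, sampling=spacing_um)

    g = SpatialGraph()

    def _voxels_to_world(voxs: np.ndarray) -> np.ndarray:
        voxs = np.asarray(voxs, dtype=float)
        return np.column_stack([voxs[:, 2], voxs[:, 1], voxs[:, 0]]) * spacing_um

    def _add_node(nid: int, voxs) -> None:
        voxs = np.asarray(voxs)
        pos = _voxels_to_world(voxs).mean(axis=0)
        g.add_spatial_node(nid, pos, voxels=voxs)

    for nid, voxs in node_voxels.items():
        _add_node(nid, voxs)

    def _add_edge(nid_a: int, nid_b: int, chain: list[tuple]) -> None:
        voxs = np.asarray(chain)
        pts = _voxels_to_world(voxs)
        radius = edt[tuple(voxs.T)] if edt is not None else None
        inten = (raw.data[tuple(voxs.T)].astype(float)
                 if raw is not None else None)
        g.add_polyline_edge(nid_a, nid_b, pts, radius=radius, intensity=inten,
                            voxels=voxs)

    visited_path: set[tuple] = set()
    direct_links: set[tuple] = set()

    for nid, voxs in node_voxels.items():
        for vox in voxs:
            for nb in _neighbors(vox, skel_set):
                other = node_of_voxel.get(nb)
                if other is not None:
                    if other == nid:
                        continue  # intra-cluster adjacency
                    pair = (min(vox, nb), max(vox, nb))
                    if pair in direct_links:
                        continue
                    direct_links.add(pair)
                    _add_edge(nid, other, [vox, nb])
                    continue
                if nb in visited_path:
                    continue
                # walk the degree-2 chain starting at nb
                chain = [vox, nb]
                visited_path.add(nb)
                prev, cur = vox, nb
                end_node = None
                while True:
                    nxt = None
                    for cand in _neighbors(cur, skel_set):
                        if cand == prev:
                            continue
                        cand_node = node_of_voxel.get(cand)
                        if cand_node is not None:
                            end_node = cand_node
                            chain.append(cand)
                            break
                        if cand not in visited_path:
                            nxt = cand
                    if end_node is not None:
                        break
                    if nxt is None:
                        break  # dead end inside a chain (shouldn't occur)
                    chain.append(nxt)
                    visited_path.add(nxt)
                    prev, cur = cur, nxt
                if end_node is None:
                    # chain returned into its own start cluster via 'prev'
                    end_node = nid
                    chain.append(vox)
                _add_edge(nid, end_node, chain)

    # leftover degree-2 voxels form pure cycles: promote one voxel per cycle
    remaining = [v for v in map(tuple, coords)
                 if v not in visited_path and v not in node_of_voxel
                 and ncount[v] == 2]
    remaining_set = set(remaining)
    next_id = n_nodes
    while remaining_set:
        start = min(remaining_set)
        _add_node(next_id, [start])
        node_of_voxel[start] = next_id
        remaining_set.discard(start)
        chain = [start]
        prev, cur = None, start
        while True:
            nxt = None
            for cand in _neighbors(cur, skel_set):
                if cand == prev or cand == start and len(chain) < 3:
                    continue
                if cand == start:
                    nxt = None
                    break
                if cand in remaining_set:
                    nxt = cand
                    break
            if nxt is None:
                break
            chain.append(nxt)
            remaining_set.discard(nxt)
            visited_path.add(nxt)
            prev, cur = cur, nxt
        chain.append(start)
        _add_edge(next_id, next_id, chain)
        next_id += 1

    return g


def extend_terminal_edges(g: SpatialGraph, mask: PorosityMask,
                          raw: ImageVolume | None = None,
                          max_extension_um: float = 2.0) -> SpatialGraph:
    """Push retracted terminal edges forward to the mask boundary.

    Thinning rounds off the free end of a vessel, so skeleton endpoints
    stop roughly one vessel radius short of the true tip. Each degree-1
    node is advanced along the mean direction of its last polyline
    segments, voxel by voxel, while the mask stays foreground (at most
    ``max_extension_um``); radius and intensity profiles are extended from
    the distance transform and the raw volume.
    """
    from scipy import ndimage as _ndi

    g = g.copy()
    spacing_um = mask.spacing / 1000.0
    edt = _ndi.distance_transform_edt(mask.data, sampling=spacing_um)
    shape = np.array(mask.data.shape)

    def _to_voxel(p):
        return np.array([p[2], p[1], p[0]]) / spacing_um

    for n in [n for n in g.nodes if g.degree(n) == 1]:
        (_, other, key), = g.edges(n, keys=True)
        d = g.edges[n, other, key]
        pts = g.oriented_pts(other, n, key)  # ends at the tip
        if len(pts) < 3:
            continue
        flipped = not np.array_equal(pts, d["pts"])
        tail = pts[-min(5, len(pts)):]
        direction = tail[-1] - tail[0]
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        direction = direction / norm
        new_pts = []
        p = pts[-1].copy()
        for _ in range(int(max_extension_um / spacing_um)):
            p = p + direction * spacing_um
            vox = np.round(_to_voxel(p)).astype(int)
            if np.any(vox < 0) or np.any(vox >= shape) or not mask.data[tuple(vox)]:
                break
            new_pts.append(p.copy())
        if not new_pts:
            continue
        new_pts = np.asarray(new_pts)
        ext_rad = edt[tuple(np.round(new_pts[:, ::-1] / spacing_um).astype(int)
                            .clip(0, shape - 1).T)]
        radius = d.get("radius")
        inten = d.get("intensity")
        if flipped:
            radius = radius[::-1] if radius is not None else None
            inten = inten[::-1] if inten is not None else None
        full_pts = np.vstack([pts, new_pts])
        if radius is not None:
            radius = np.concatenate([radius, ext_rad])
        if inten is not None and raw is not None:
            vox = (np.round(new_pts[:, ::-1] / spacing_um).astype(int)
                   .clip(0, shape - 1))
            inten = np.concatenate([inten, raw.data[tuple(vox.T)].astype(float)])
        elif inten is not None:
            inten = np.concatenate([inten, np.full(len(new_pts), inten[-1])])
        g.remove_edge(n, other, key=key)
        g.nodes[n]["pos"] = full_pts[-1].copy()
        g.add_polyline_edge(other, n, full_pts, radius=radius, intensity=inten)
    return g
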