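"""Synthetic dentin porosity phantoms with known ground truth.

The generator emulates the architecture of cellular porosity in crown
dentin: quasi-parallel, gently wavy tubules (micron-scale diameter) running
from the dentin-enamel junction (DEJ, the plane ``y = 0``) toward the pulp,
decorated with thin lateral branches (0.1–0.5 µm) that either dead-end in
the tissue or land on a neighbouring tubule and thereby connect the two.
Branch density and tubule waviness can follow a piecewise profile of the
distance to the DEJ with a transition depth, mimicking the denser, wavier
region observed near the junction.

The rendered volumes reproduce the main degradations of confocal
fluorescence imaging: anisotropic voxel sampling, an anisotropic Gaussian
PSF (wider axially than laterally), partial-volume dimming of sub-resolution
branches, in-depth attenuation, photon + read noise, and 8-bit quantization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .spatialgraph import SpatialGraph, polyline_length
from .volume import ImageVolume

__all__ = [
    "GradientProfile",
    "PhantomSpec",
    "ImagingSpec",
    "GroundTruthGraph",
    "generate_network",
    "render_volume",
    "region_presets",
    "attach_intensity_model",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class GradientProfile:
    """Piecewise (near/far of a transition depth) modulation of tubule traits.

    ``transition_depth_um`` splits the domain along the DEJ→pulp axis;
    the ``*_factors`` pairs multiply the spec's base values on the near
    (DEJ) and far (bulk) side respectively.
    """

    transition_depth_um: float
    branch_density_factors: tuple[float, float] = (1.0, 1.0)
    waviness_factors: tuple[float, float] = (1.0, 1.0)

    def branch_density_at(self, base: float, y: float) -> float:
        near, far = self.branch_density_factors
        return base * (near if y < self.transition_depth_um else far)

    def waviness_at(self, base: float, y: float) -> float:
        near, far = self.waviness_factors
        return base * (near if y < self.transition_depth_um else far)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic porosity network.

    All lengths in µm. ``domain_size`` is (x, y, z) extent; tubules run
    along y. ``branch_density`` is branches per µm of tubule arc length.
    """

    domain_size: tuple[float, float, float] = (25.6, 25.6, 25.9)
    tubule_count: int = 36
    tubule_diameter_range: tuple[float, float] = (0.8, 1.4)
    tubule_waviness_amplitude: float = 0.8
    tubule_waviness_wavelength: float = 12.0
    branch_density: float = 0.22
    branch_diameter_range: tuple[float, float] = (0.1, 0.5)
    branch_connect_prob: float = 0.8
    dead_end_length_range: tuple[float, float] = (2.0, 10.0)
    capture_radius_um: float | None = None
    gradient: GradientProfile | None = None

    def __post_init__(self):
        if any(d <= 0 for d in self.tubule_diameter_range + self.branch_diameter_range):
            raise ValueError("all diameters must be > 0")
        if not 0.0 <= self.branch_connect_prob <= 1.0:
            raise ValueError("branch_connect_prob must lie in [0, 1]")
        if self.tubule_count < 1:
            raise ValueError("need at least one tubule")
        if any(L <= 0 for L in self.domain_size):
            raise ValueError("domain_size must be positive")
        if self.branch_density < 0:
            raise ValueError("branch_density must be >= 0")
        if self.gradient is None:
            object.__setattr__(
                self, "gradient", GradientProfile(transition_depth_um=self.domain_size[1])
            )
        if not 0.0 < self.gradient.transition_depth_um <= self.domain_size[1]:
            raise ValueError("gradient transition depth must lie within the domain")

    def grid_shape(self) -> tuple[int, int]:
        """Tubule layout grid (nx, nz) in the x–z plane."""
        lx, _, lz = self.domain_size
        nx = max(1, int(round(np.sqrt(self.tubule_count * lx / lz))))
        nz = max(1, int(np.ceil(self.tubule_count / nx)))
        return nx, nz

    def nominal_spacing(self) -> float:
        nx, nz = self.grid_shape()
        return min(self.domain_size[0] / nx, self.domain_size[2] / nz)


@dataclass(frozen=True)
class ImagingSpec:
    """Confocal-like image formation parameters.

    ``voxel_size_nm`` and ``psf_fwhm_nm`` are (lateral, lateral, axial)
    given as (x/y, z); attenuation is the exponential intensity loss rate
    per µm of imaging depth (z).
    """

    voxel_size_nm: tuple[float, float, float] = (100.0, 100.0, 350.0)  # (x, y, z)
    psf_fwhm_nm: tuple[float, float] = (300.0, 700.0)  # (lateral, axial)
    stain_level: float = 230.0
    background: float = 8.0
    attenuation_per_um: float = 0.01
    photon_gain: float = 0.4  # photons per intensity count; 0 disables shot noise
    read_noise_sd: float = 2.0
    bit_depth: int = 8

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel sizes must be > 0")
        lateral, axial = self.psf_fwhm_nm
        if axial < lateral:
            raise ValueError("confocal anisotropy requires axial PSF >= lateral PSF")

    @property
    def noiseless(self) -> "ImagingSpec":
        """Benign variant: no noise, no attenuation (PSF retained)."""
        return replace(self, attenuation_per_um=0.0, photon_gain=0.0, read_noise_sd=0.0)


class GroundTruthGraph(SpatialGraph):
    """Phantom network geometry: the reference graph for recovery tests.

    Nodes carry ``pos`` (µm) and ``kind`` in {``tubule-end``,
    ``branch-point``, ``branch-tip``}; edges carry centerline ``pts`` and a
    per-point ``radius`` profile.
    """

    domain_size: tuple[float, float, float] = (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

_TUBULE_STEP = 0.25  # µm, centerline sampling step
_EVENT_MIN_SEP = 0.4  # µm, junctions closer than this along a tubule merge


def _tubule_centerline(spec: PhantomSpec, x0: float, z0: float, rng) -> np.ndarray:
    """Wavy tubule path from the DEJ plane (y=0) to y=Ly."""
    ly = spec.domain_size[1]
    n = max(2, int(np.ceil(ly / _TUBULE_STEP)) + 1)
    y = np.linspace(0.0, ly, n)
    amp = np.array([spec.gradient.waviness_at(spec.tubule_waviness_amplitude, yi) for yi in y])
    lam = spec.tubule_waviness_wavelength
    phx, phz = rng.uniform(0, 2 * np.pi, size=2)
    x = x0 + amp * np.sin(2 * np.pi * y / lam + phx)
    z = z0 + 0.5 * amp * np.sin(2 * np.pi * y / lam + phz)
    lx, _, lz = spec.domain_size
    x = np.clip(x, 0.2, lx - 0.2)
    z = np.clip(z, 0.2, lz - 0.2)
    return np.column_stack([x, y, z])


def _poisson_events(arc: np.ndarray, y: np.ndarray, base_rate: float,
                    grad: GradientProfile, rng) -> list[float]:
    """Arc positions of a (possibly inhomogeneous) Poisson process by thinning."""
    if base_rate <= 0:
        return []
    near, far = grad.branch_density_factors
    rate_max = base_rate * max(near, far)
    if rate_max <= 0:
        return []
    total = arc[-1]
    out = []
    s = rng.exponential(1.0 / rate_max)
    while s < total:
        yi = float(np.interp(s, arc, y))
        if rng.random() < grad.branch_density_at(base_rate, yi) / rate_max:
            out.append(s)
        s += rng.exponential(1.0 / rate_max)
    return out


def _point_at_arc(pts: np.ndarray, arc: np.ndarray, s: float) -> np.ndarray:
    return np.array([np.interp(s, arc, pts[:, i]) for i in range(3)])


def _wiggly_path(p: np.ndarray, q: np.ndarray, rng, n_min: int = 6) -> np.ndarray:
    """Mildly tortuous polyline from p to q (lateral half-sine deflection)."""
    length = float(np.linalg.norm(q - p))
    n = max(n_min, int(np.ceil(length / 0.2)) + 1)
    t = np.linspace(0.0, 1.0, n)
    base = p[None, :] + t[:, None] * (q - p)[None, :]
    direction = (q - p) / max(length, 1e-9)
    perp = np.cross(direction, [0.0, 1.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, [1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    amp = 0.08 * length * rng.uniform(0.3, 1.0)
    return base + np.outer(np.sin(np.pi * t) * amp, perp)


def generate_network(spec: PhantomSpec, seed: int) -> GroundTruthGraph:
    """Generate the ground-truth porosity network for a phantom spec.

    Tubules are polyline chains split at branch junctions; each branch
    starts at a degree-3 junction on its tubule and either dead-ends
    (degree-1 tip) or lands on a neighbouring tubule (second junction).
    Deterministic for a fixed ``(spec, seed)``.
    """
    max_diam = max(spec.tubule_diameter_range)
    spacing = spec.nominal_spacing()
    if spacing < 2.0 * max_diam:
        raise ValueError(
            f"tubule spacing {spacing:.2f} µm < 2×max diameter {2 * max_diam:.2f} µm: "
            "tubules would overlap unresolvably"
        )
    rng = np.random.default_rng(seed)
    lx, ly, lz = spec.domain_size
    nx, nz = spec.grid_shape()

    # jittered grid of tubule anchors in the x–z plane
    centers = []
    for i in range(nx):
        for j in range(nz):
            if len(centers) >= spec.tubule_count:
                break
            cx = (i + 0.5) * lx / nx + rng.uniform(-0.12, 0.12) * lx / nx
            cz = (j + 0.5) * lz / nz + rng.uniform(-0.12, 0.12) * lz / nz
            centers.append((cx, cz))
    tub_pts, tub_arc, tub_radius = [], [], []
    for cx, cz in centers:
        pts = _tubule_centerline(spec, cx, cz, rng)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        tub_pts.append(pts)
        tub_arc.append(arc)
        tub_radius.append(0.5 * rng.uniform(*spec.tubule_diameter_range))

    capture = spec.capture_radius_um or 1.6 * spacing

    # events[t] = list of (arc_position, event_id); branches reference event ids
    events: list[list[tuple[float, int]]] = [[] for _ in tub_pts]
    branches = []  # (src_event, dst_event_or_None, p, q_or_tip, radius)
    next_event = 0

    def _add_event(t: int, s: float) -> int:
        nonlocal next_event
        for s0, eid in events[t]:
            if abs(s0 - s) < _EVENT_MIN_SEP:
                return eid
        eid = next_event
        next_event += 1
        events[t].append((s, eid))
        return eid

    anchors = np.array(centers)
    for t, (pts, arc) in enumerate(zip(tub_pts, tub_arc)):
        for s in _poisson_events(arc, pts[:, 1], spec.branch_density, spec.gradient, rng):
            s = float(np.clip(s, _EVENT_MIN_SEP, arc[-1] - _EVENT_MIN_SEP))
            p = _point_at_arc(pts, arc, s)
            r_b = 0.5 * rng.uniform(*spec.branch_diameter_range)
            connected = False
            if rng.random() < spec.branch_connect_prob:
                d2 = np.sum((anchors - np.array([p[0], p[2]])) ** 2, axis=1)
                d2[t] = np.inf
                # any tubule within reach can receive the branch (real
                # lateral branches orient quasi-randomly in azimuth);
                # always taking the single nearest one would degenerate
                # straight-tubule regions into isolated pairs
                reachable = np.flatnonzero(d2 <= capture**2)
                u = int(rng.choice(reachable)) if len(reachable) else -1
                if u >= 0:
                    # attach to the target's interior point nearest to p
                    q_idx = int(np.argmin(np.linalg.norm(tub_pts[u] - p, axis=1)))
                    q_idx = int(np.clip(q_idx, 2, len(tub_pts[u]) - 3))
                    s_u = float(tub_arc[u][q_idx])
                    s_u = float(np.clip(s_u, _EVENT_MIN_SEP, tub_arc[u][-1] - _EVENT_MIN_SEP))
                    q = _point_at_arc(tub_pts[u], tub_arc[u], s_u)
                    src = _add_event(t, s)
                    dst = _add_event(u, s_u)
                    branches.append((src, dst, p, q, r_b))
                    connected = True
            if not connected:
                length = rng.uniform(*spec.dead_end_length_range)
                theta = rng.uniform(0, 2 * np.pi)
                tilt = rng.uniform(-0.4, 0.4)
                direction = np.array(
                    [np.cos(theta), tilt, np.sin(theta)]
                )
                direction /= np.linalg.norm(direction)
                tip = p + direction * length
                tip = np.clip(tip, [0.2, 0.0, 0.2], [lx - 0.2, ly, lz - 0.2])
                src = _add_event(t, s)
                branches.append((src, None, p, tip, r_b))

    # assemble graph: tubule chains split at events
    g = GroundTruthGraph()
    g.domain_size = spec.domain_size
    nid = 0
    event_node: dict[int, int] = {}
    for t, (pts, arc) in enumerate(zip(tub_pts, tub_arc)):
        stops = [(0.0, None), (float(arc[-1]), None)]
        stops += [(s, eid) for s, eid in events[t]]
        stops.sort(key=lambda se: se[0])
        chain_nodes = []
        for s, eid in stops:
            pos = _point_at_arc(pts, arc, s)
            kind = "tubule-end" if eid is None else "branch-point"
            g.add_spatial_node(nid, pos, kind=kind)
            if eid is not None:
                event_node[eid] = nid
            chain_nodes.append((s, nid))
            nid += 1
        r = tub_radius[t]
        for (s0, n0), (s1, n1) in zip(chain_nodes[:-1], chain_nodes[1:]):
            mask = (arc > s0) & (arc < s1)
            seg_pts = np.vstack(
                [g.nodes[n0]["pos"], pts[mask], g.nodes[n1]["pos"]]
            )
            g.add_polyline_edge(n0, n1, seg_pts, radius=np.full(len(seg_pts), r))

    for src, dst, p, q, r_b in branches:
        u = event_node[src]
        p_node = g.nodes[u]["pos"]
        if dst is None:
            g.add_spatial_node(nid, q, kind="branch-tip")
            path = _wiggly_path(p_node, q, rng)
            g.add_polyline_edge(u, nid, path, radius=np.full(len(path), r_b))
            nid += 1
        else:
            v = event_node[dst]
            if u == v or g.has_edge(u, v):
                continue  # never create self-loops or duplicate connections
            q_node = g.nodes[v]["pos"]
            path = _wiggly_path(p_node, q_node, rng)
            g.add_polyline_edge(u, v, path, radius=np.full(len(path), r_b))
    return g


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _resample_polyline(pts: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline (and its index space) at ~``step`` µm spacing."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        return pts[:1], np.array([0.0])
    n = max(2, int(np.ceil(total / step)) + 1)
    s = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(s, arc, pts[:, i]) for i in range(3)])
    return out, s


def render_volume(gt: GroundTruthGraph, imaging: ImagingSpec, seed: int) -> ImageVolume:
    """Rasterize a ground-truth network into a degraded confocal-like stack.

    Each centerline is drawn as a solid tube of its local radius with
    partial-volume weighting (sub-voxel structures contribute proportionally
    less signal), convolved with the anisotropic Gaussian PSF, attenuated
    with imaging depth, degraded with photon and read noise, and quantized.
    """
    rng = np.random.default_rng(seed)
    sx, sy, sz = (v / 1000.0 for v in imaging.voxel_size_nm)  # µm
    lx, ly, lz = gt.domain_size
    shape = (max(1, int(round(lz / sz))), max(1, int(round(ly / sy))),
             max(1, int(round(lx / sx))))
    stain = np.zeros(shape, dtype=np.float32)

    min_r = min((float(np.min(d["radius"])) for _, _, d in gt.edges(data=True)
                 if "radius" in d), default=np.inf)
    if min_r < 0.5 * sx:
        warnings.warn(
            f"smallest vessel radius {min_r:.3f} µm is below half the lateral "
            f"voxel size ({0.5 * sx:.3f} µm): sub-resolution structure",
            stacklevel=2,
        )

    soft = 0.5 * sx  # half lateral voxel: soft-edge width for partial volume
    for _, _, d in gt.edges(data=True):
        pts = d["pts"]
        radius = d.get("radius")
        if radius is None:
            radius = np.full(len(pts), 0.25)
        fine, s = _resample_polyline(pts, step=0.6 * sx)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        r_fine = np.interp(s, arc, radius)
        for p, r in zip(fine, r_fine):
            _stamp_ball(stain, p, r, (sx, sy, sz), soft)

    img = stain * imaging.stain_level
    # anisotropic PSF (FWHM -> sigma, in voxel units per axis)
    lat, ax = imaging.psf_fwhm_nm
    sigma_vox = (ax / FWHM_PER_SIGMA / imaging.voxel_size_nm[2],
                 lat / FWHM_PER_SIGMA / imaging.voxel_size_nm[1],
                 lat / FWHM_PER_SIGMA / imaging.voxel_size_nm[0])
    img = gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    if imaging.attenuation_per_um > 0:
        depth = np.arange(shape[0]) * sz
        img *= np.exp(-imaging.attenuation_per_um * depth)[:, None, None]
    img += imaging.background
    if imaging.photon_gain > 0:
        img = rng.poisson(np.clip(img, 0, None) * imaging.photon_gain) / imaging.photon_gain
    if imaging.read_noise_sd > 0:
        img = img + rng.normal(0.0, imaging.read_noise_sd, size=img.shape)
    vmax = 2 ** imaging.bit_depth - 1
    img = np.clip(np.round(img), 0, vmax)
    dtype = np.uint8 if imaging.bit_depth <= 8 else np.uint16
    return ImageVolume(
        data=img.astype(dtype),
        spacing=(imaging.voxel_size_nm[2], imaging.voxel_size_nm[1],
                 imaging.voxel_size_nm[0]),
    )


def _stamp_ball(stain, p, r, voxel_um, soft):
    """Max-combine a soft ball of radius r (µm) centred at world point p."""
    sx, sy, sz = voxel_um
    cx, cy, cz = p[0] / sx, p[1] / sy, p[2] / sz
    ex = (r + soft) / sx
    ey = (r + soft) / sy
    ez = (r + soft) / sz
    z0, z1 = int(np.floor(cz - ez)), int(np.ceil(cz + ez))
    y0, y1 = int(np.floor(cy - ey)), int(np.ceil(cy + ey))
    x0, x1 = int(np.floor(cx - ex)), int(np.ceil(cx + ex))
    nz, ny, nx = stain.shape
    z0, z1 = max(z0, 0), min(z1, nz - 1)
    y0, y1 = max(y0, 0), min(y1, ny - 1)
    x0, x1 = max(x0, 0), min(x1, nx - 1)
    if z0 > z1 or y0 > y1 or x0 > x1:
        return
    zz = (np.arange(z0, z1 + 1) * sz - p[2]) ** 2
    yy = (np.arange(y0, y1 + 1) * sy - p[1]) ** 2
    xx = (np.arange(x0, x1 + 1) * sx - p[0]) ** 2
    d = np.sqrt(zz[:, None, None] + yy[None, :, None] + xx[None, None, :])
    val = np.clip((r - d) / soft + 0.5, 0.0, 1.0).astype(np.float32)
    np.maximum(stain[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1], val,
               out=stain[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1])


# ---------------------------------------------------------------------------
# presets and intensity model
# ---------------------------------------------------------------------------

def region_presets(name: str) -> PhantomSpec:
    """Phantom specs mimicking the two topological regions of crown dentin.

    ``dense_dej`` — the region near the DEJ: wavy tubules, high branch
    density, most branches connecting (highly interconnected network).
    ``sparse_bulk`` — bulk dentin past the transition: straighter tubules,
    few branches, mostly dead-ending (fragmented, fragile network).
    """
    if name == "dense_dej":
        return PhantomSpec(
            tubule_count=36,
            tubule_diameter_range=(0.8, 1.4),
            tubule_waviness_amplitude=0.8,
            tubule_waviness_wavelength=12.0,
            branch_density=0.22,
            branch_connect_prob=0.8,
        )
    if name == "sparse_bulk":
        # calibrated to the sparse-but-spanning regime of bulk dentin: the
        # largest component reaches across the region through a handful of
        # connecting branches, so path metrics (<l>, D, DI) start *higher*
        # than in the dense region while S stays clearly lower
        return PhantomSpec(
            tubule_count=42,
            tubule_diameter_range=(0.8, 1.2),
            tubule_waviness_amplitude=0.15,
            tubule_waviness_wavelength=18.0,
            branch_density=0.08,
            branch_connect_prob=0.5,
        )
    raise ValueError(f"unknown preset {name!r}; expected 'dense_dej' or 'sparse_bulk'")


def attach_intensity_model(gt: GroundTruthGraph, imaging: ImagingSpec) -> SpatialGraph:
    """Return a copy of ``gt`` with a per-point ``intensity`` profile.

    The model mirrors image formation photometrically: an in-focus vessel
    wider than the lateral PSF reaches the full stain level, a sub-resolution
    branch is dimmed by the squared ratio of its diameter to the lateral PSF
    FWHM (area-based partial volume), and depth attenuation applies. With the
    defaults the thinnest (0.1 µm) branches land near intensity 25 on the
    8-bit scale.
    """
    g = gt.copy()
    fwhm_lat_um = imaging.psf_fwhm_nm[0] / 1000.0
    for u, v, k, d in g.edges(keys=True, data=True):
        pts = d["pts"]
        radius = d.get("radius", np.full(len(pts), 0.25))
        frac = np.clip((2.0 * radius / fwhm_lat_um) ** 2, 0.0, 1.0)
        depth = pts[:, 2]
        inten = imaging.background + imaging.stain_level * frac * np.exp(
            -imaging.attenuation_per_um * depth
        )
        d["intensity"] = np.clip(np.round(inten), 0, 2 ** imaging.bit_depth - 1)
    return g
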