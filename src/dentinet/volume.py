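"""3D image volumes with physical voxel spacing.

Conventions used throughout the package:

* array data is indexed ``[z, y, x]`` with ``z`` the optical (in-depth) axis;
* ``spacing`` is given per axis in nanometres, in ``(z, y, x)`` order;
* world coordinates are expressed in micrometres as ``(x, y, z)`` triplets,
  with the origin at the centre of voxel ``(0, 0, 0)``.

The dentin-enamel junction (DEJ) is modelled as the plane ``y = 0``; tubules
run along increasing ``y`` (toward the pulp).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageVolume", "voxel_extent_um"]

NM_PER_UM = 1000.0


@dataclass
class ImageVolume:
    """A 3D scalar field with per-axis voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensities (integer or floating point).
    spacing : tuple of float
        Voxel size in nm, ``(z, y, x)`` order.
    origin : tuple of float
        World offset of voxel (0, 0, 0) in µm, ``(x, y, z)`` order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        return max(self.spacing) - min(self.spacing) < 1e-9

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        """Voxel size in µm, (z, y, x) order."""
        return tuple(s / NM_PER_UM for s in self.spacing)

    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent of the volume in µm, (x, y, z) order."""
        nz, ny, nx = self.data.shape
        sz, sy, sx = self.spacing_um
        return (nx * sx, ny * sy, nz * sz)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map ``(z, y, x)`` voxel indices to ``(x, y, z)`` world µm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        sz, sy, sx = self.spacing_um
        world = np.empty_like(idx)
        world[:, 0] = idx[:, 2] * sx + self.origin[0]
        world[:, 1] = idx[:, 1] * sy + self.origin[1]
        world[:, 2] = idx[:, 0] * sz + self.origin[2]
        return world if np.asarray(indices).ndim == 2 else world[0]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map ``(x, y, z)`` world µm to fractional ``(z, y, x)`` indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        sz, sy, sx = self.spacing_um
        idx = np.empty_like(pts)
        idx[:, 0] = (pts[:, 2] - self.origin[2]) / sz
        idx[:, 1] = (pts[:, 1] - self.origin[1]) / sy
        idx[:, 2] = (pts[:, 0] - self.origin[0]) / sx
        return idx if np.asarray(points).ndim == 2 else idx[0]

    # -- I/O ----------------------------------------------------------------

    def to_tiff(self, path) -> None:
        """Write as a multi-page TIFF with spacing/origin in the description."""
        meta = {"spacing_nm_zyx": list(self.spacing), "origin_um_xyz": list(self.origin)}
        tifffile.imwrite(path, self.data, description=json.dumps(meta),
                         photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, spacing=None) -> "ImageVolume":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
        origin = (0.0, 0.0, 0.0)
        if spacing is None:
            try:
                meta = json.loads(desc)
                spacing = tuple(meta["spacing_nm_zyx"])
                origin = tuple(meta.get("origin_um_xyz", origin))
            except (json.JSONDecodeError, KeyError, TypeError):
                raise ValueError(
                    "TIFF carries no dentinet spacing metadata; pass spacing explicitly"
                )
        if data.ndim == 2:
            data = data[None]
        return cls(data=data, spacing=spacing, origin=origin)


def voxel_extent_um(n_voxels: int, voxel_size_nm: float) -> float:
    """Physical extent in µm covered by ``n_voxels`` of a given size.

    E.g. a mosaic of 9344 voxels at 100 nm spans 934.4 µm laterally.
    """
    if n_voxels < 0 or voxel_size_nm <= 0:
        raise ValueError("need n_voxels >= 0 and voxel_size_nm > 0")
    return n_voxels * voxel_size_nm / NM_PER_UM
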