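"""Porosity segmentation: equalization, reslicing, vesselness, thresholding.

The segmentation chain turns a raw anisotropic confocal stack into a clean
binary porosity mask:

1. global histogram equalization (compensates in-depth attenuation) and
   bicubic reslicing of the optical axis to isotropic voxels;
2. multiscale Hessian-based vesselness enhancement of bright tubular
   structures (Jerman response with regularized lambda_rho, ``tau``);
3. hysteresis thresholding with the two class boundaries of a 3-class
   multi-Otsu decomposition of the response (26-connectivity);
4. morphological cleanup: opening, removal of small foreground/background
   clusters, median filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, morphology
from skimage.filters import threshold_multiotsu
from skimage.transform import resize

from .volume import ImageVolume

__all__ = [
    "PorosityMask",
    "VesselnessParams",
    "sigma_to_fwhm",
    "equalize_and_reslice",
    "vesselness",
    "segment",
    "remove_small_clusters",
    "denoise_mask",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PorosityMask:
    """Binary porosity mask on an isotropic voxel grid (spacing in nm)."""

    data: np.ndarray
    spacing: float

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    def to_tiff(self, path) -> None:
        vol = ImageVolume(self.data.astype(np.uint8) * 255,
                          spacing=(self.spacing,) * 3)
        vol.to_tiff(path)

    @classmethod
    def from_tiff(cls, path) -> "PorosityMask":
        vol = ImageVolume.from_tiff(path)
        return cls(vol.data > 0, spacing=vol.spacing[0])


@dataclass(frozen=True)
class VesselnessParams:
    """Scale set (σ, in pixels) and sensitivity τ of the vesselness filter.

    The printed full-resolution profile is σ = 1–5 in steps of 0.05
    (FWHM 2.36–11.78 px); the default here is the coarser desk-scale
    profile with steps of 0.5, which trades a few percent of response
    accuracy for an order of magnitude in runtime.
    """

    sigmas: tuple[float, ...] = tuple(np.arange(1.0, 5.01, 0.5))
    tau: float = 0.5
    blob_suppression: float = 1.0

    def __post_init__(self):
        s = np.asarray(self.sigmas, dtype=float)
        if len(s) == 0 or np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("sigmas must be strictly increasing and > 0")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")
        if self.blob_suppression < 0:
            raise ValueError("blob_suppression must be >= 0")

    @classmethod
    def full_profile(cls, tau: float = 0.5) -> "VesselnessParams":
        return cls(sigmas=tuple(np.arange(1.0, 5.0 + 1e-9, 0.05)), tau=tau)


def sigma_to_fwhm(sigma: float) -> float:
    """FWHM (same units as σ) of a Gaussian of standard deviation σ."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return FWHM_PER_SIGMA * sigma


# ---------------------------------------------------------------------------
# equalization + reslicing
# ---------------------------------------------------------------------------

def equalize_and_reslice(vol: ImageVolume, target_spacing_nm: float) -> ImageVolume:
    """Histogram-equalize the whole stack and reslice Z to isotropic voxels.

    Equalization is global (rank transform of the full intensity histogram,
    rescaled to the input dynamic range); the Z axis is then resampled by
    bicubic interpolation so all axes share ``target_spacing_nm``. The output
    Z size is ``round(nz * sz / target)``.
    """
    sz, sy, sx = vol.spacing
    if vol.data.shape[0] < 2:
        raise ValueError("need at least 2 Z slices to reslice")
    if target_spacing_nm > sx + 1e-9 or target_spacing_nm > sy + 1e-9:
        raise ValueError(
            f"target spacing {target_spacing_nm} nm would downsample the "
            f"in-plane axes ({sy} x {sx} nm)"
        )
    if np.issubdtype(vol.data.dtype, np.integer):
        vmax = float(np.iinfo(vol.data.dtype).max)
    else:
        vmax = float(vol.data.max()) or 1.0
    eq = (exposure.equalize_hist(vol.data) * vmax).astype(np.float32)
    ratio = sz / target_spacing_nm
    nz = int(round(vol.data.shape[0] * ratio))
    out = resize(eq, (nz, *vol.data.shape[1:]), order=3, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    out = np.clip(out, 0.0, vmax)
    return ImageVolume(out.astype(np.float32), spacing=(target_spacing_nm,) * 3,
                       origin=vol.origin)


# ---------------------------------------------------------------------------
# vesselness
# ---------------------------------------------------------------------------

def _eigvalsh3(hxx, hxy, hxz, hyy, hyz, hzz):
    """Eigenvalues of symmetric 3x3 matrices, vectorized (ascending order)."""
    q = (hxx + hyy + hzz) / 3.0
    p2 = ((hxx - q) ** 2 + (hyy - q) ** 2 + (hzz - q) ** 2
          + 2.0 * (hxy**2 + hxz**2 + hyz**2))
    p = np.sqrt(np.maximum(p2 / 6.0, 1e-30))
    bxx, byy, bzz = (hxx - q) / p, (hyy - q) / p, (hzz - q) / p
    bxy, bxz, byz = hxy / p, hxz / p, hyz / p
    detb = (bxx * (byy * bzz - byz**2)
            - bxy * (bxy * bzz - byz * bxz)
            + bxz * (bxy * byz - byy * bxz))
    phi = np.arccos(np.clip(detb / 2.0, -1.0, 1.0)) / 3.0
    e1 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e3 = q + 2.0 * p * np.cos(phi)
    e2 = 3.0 * q - e1 - e3
    return e1, e2, e3


def _jerman_single_scale(data: np.ndarray, sigma: float, tau: float,
                         blob_suppression: float = 1.0) -> np.ndarray:
    """Jerman-type vesselness response at one scale, for bright tubes.

    The regularized response saturates at 1 for rounded structures as well
    as tubes; a soft penalty on the smallest-magnitude eigenvalue
    (``exp(-(lam1 / (c * lam3))^2)``, ``c = blob_suppression``) restores
    tube selectivity: on an ideal tube lam1 ~ 0 leaves the response
    untouched, while an isotropic blob (lam1 ~ lam3) is damped by e^-1 at
    the default strength. Set ``blob_suppression = 0`` for the pure
    regularized response.
    """
    h = {}
    orders = {"zz": (2, 0, 0), "zy": (1, 1, 0), "zx": (1, 0, 1),
              "yy": (0, 2, 0), "yx": (0, 1, 1), "xx": (0, 0, 2)}
    for k, order in orders.items():
        # gamma = 2 scale normalization; reflect padding avoids border
        # response; 3-sigma kernel support trades <0.3% response error for
        # a quarter of the filtering time
        h[k] = sigma**2 * ndi.gaussian_filter(data, sigma, order=order,
                                              mode="reflect",
                                              truncate=3.0).astype(np.float32)
    e1, e2, e3 = _eigvalsh3(h["xx"], h["yx"], h["zx"], h["yy"], h["zy"], h["zz"])
    del h
    # pick the 2nd/3rd largest magnitudes (e1 <= e2 <= e3, so the extreme
    # magnitude is e1 or e3), sign-flipped so they are positive inside
    # bright tubular structures
    e1_wins = np.abs(e1) > np.abs(e3)
    lam3 = -np.where(e1_wins, e1, e3)
    lam2 = -np.where(e1_wins,
                     np.where(np.abs(e2) >= np.abs(e3), e2, e3),
                     np.where(np.abs(e1) >= np.abs(e2), e1, e2))
    lam1_abs = np.abs(-(e1 + e2 + e3) - lam2 - lam3)
    del e1, e2, e3, e1_wins
    lam3_max = float(lam3.max(initial=0.0))
    if lam3_max <= 0:
        return np.zeros_like(data, dtype=np.float32)
    cut = tau * lam3_max
    lam_rho = np.where(lam3 > cut, lam3, np.where(lam3 > 0, cut, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = lam2**2 * (lam_rho - lam2) * (3.0 / (lam2 + lam_rho)) ** 3
    v = np.where((lam2 <= 0) | (lam_rho <= 0), 0.0, v)
    v = np.where((lam2 >= lam_rho / 2.0) & (lam_rho > 0), 1.0, v)
    if blob_suppression > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            penalty = np.exp(-(lam1_abs / (blob_suppression * lam3)) ** 2)
        v = np.where(lam3 > 0, v * penalty, v)
    return np.clip(np.nan_to_num(v), 0.0, 1.0).astype(np.float32)


def vesselness(vol: ImageVolume, params: VesselnessParams | None = None) -> ImageVolume:
    """Multiscale vesselness response in [0, 1] (per-voxel max over scales).

    Tubular bright structures — two strongly negative Hessian eigenvalues in
    cross-section and a weak one along the axis — score high; blobs and
    plates score lower; flat regions score zero.
    """
    params = params or VesselnessParams()
    if not vol.is_isotropic:
        raise ValueError("vesselness expects an isotropic volume; reslice first")
    support = int(np.ceil(4 * max(params.sigmas)))
    if min(vol.data.shape) <= support:
        raise ValueError(
            f"volume of shape {vol.data.shape} is thinner than the largest "
            f"filter kernel support ({support} voxels)"
        )
    data = vol.data.astype(np.float32)
    if data.max() <= data.min():
        # flat volume: zero Hessian, zero response (avoids amplifying
        # pure floating-point noise through the scale-invariant response)
        return ImageVolume(np.zeros_like(data), spacing=vol.spacing,
                           origin=vol.origin)
    data = (data - data.min()) / (data.max() - data.min())
    out = np.zeros_like(data, dtype=np.float32)
    for sigma in params.sigmas:
        np.maximum(out, _jerman_single_scale(data, float(sigma), params.tau,
                                             params.blob_suppression), out=out)
    return ImageVolume(out, spacing=vol.spacing, origin=vol.origin)


# ---------------------------------------------------------------------------
# thresholding + cleanup
# ---------------------------------------------------------------------------

def segment(response: ImageVolume,
            thresholds: tuple[float, float] | None = None) -> PorosityMask:
    """Hysteresis-threshold a vesselness response into a porosity mask.

    Unless given explicitly, the (low, high) thresholds are the two class
    boundaries of a 3-class multi-Otsu decomposition of the response. A
    voxel is foreground iff it exceeds the low threshold and belongs to a
    26-connected low-mask component that contains a voxel above the high
    threshold.
    """
    data = np.asarray(response.data)
    if not np.all(np.isfinite(data)):
        raise ValueError("response contains non-finite values")
    if thresholds is None:
        try:
            low, high = threshold_multiotsu(data, classes=3)
        except ValueError:
            warnings.warn("degenerate response (too few distinct values): "
                          "returning an empty mask", stacklevel=2)
            return PorosityMask(np.zeros(data.shape, dtype=bool),
                                spacing=response.spacing[0])
    else:
        low, high = thresholds
        if low > high:
            raise ValueError("low threshold exceeds high threshold")
    low_mask = data > low
    high_mask = data > high
    labels, _ = ndi.label(low_mask, structure=_CONN26)
    keep = np.unique(labels[high_mask])
    keep = keep[keep > 0]
    mask = np.isin(labels, keep)
    return PorosityMask(mask, spacing=response.spacing[0])


def remove_small_clusters(data: np.ndarray, min_size: int = 256) -> np.ndarray:
    """Drop isolated foreground and background clusters of size < min_size.

    Both polarities use 26-connectivity; background clusters touching the
    volume border are kept (they continue outside the field of view).
    """

    def _small(binary, keep_border):
        labels, _ = ndi.label(binary, structure=_CONN26)
        counts = np.bincount(labels.ravel())
        drop = np.zeros(len(counts), dtype=bool)
        drop[1:] = counts[1:] < min_size
        if keep_border:
            border = np.unique(np.concatenate([
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
            drop[border] = False
        return drop[labels]

    out = np.asarray(data).astype(bool).copy()
    out[_small(out, keep_border=False)] = False
    out[_small(~out, keep_border=True)] = True
    return out


def denoise_mask(mask: PorosityMask, min_cluster: int = 256) -> PorosityMask:
    """Morphological cleanup: opening, small-cluster removal, median filter.

    Order: opening with a 3-voxel-diameter ball, removal of foreground and
    background clusters below ``min_cluster`` voxels (26-connectivity), then
    a 3x3x3 median filter.
    """
    data = mask.data
    data = morphology.opening(data, morphology.ball(1))
    data = remove_small_clusters(data, min_size=min_cluster)
    data = ndi.median_filter(data.astype(np.uint8), size=3) > 0
    return PorosityMask(data, spacing=mask.spacing)
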