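"""Confocal-style image analysis: height maps and layer classification.

Mirrors the experimental pipeline used for colony morphology:

* the surface height h(x, y) is reconstructed from a 3D intensity stack by
  thresholding - per (x, y) column, the height of the topmost voxel whose
  intensity exceeds a threshold given as a fraction of the stack's maximum
  fluorescence;
* single- vs multi-layer regions of an early colony image are classified by
  a 5x5 stencil rule: for each pixel, count the neighbors above an intensity
  threshold (n); the pixel is type 1 (single layer) if 3 <= n < 16 and
  type 2 (multi-layer) if n >= 16, and the layer radii follow from the pixel
  counts, r_inner = s * sqrt(Npx2 / pi), r_outer = s * sqrt((Npx1 + Npx2) /
  pi), with s the um-per-pixel scale (0.84 um/px for the reference optics).

A synthetic-stack renderer rasterizes simulation snapshots into intensity
stacks so both operations can be round-trip tested without microscope data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .engine import Snapshot

__all__ = [
    "IntensityStack", "LayerMap",
    "height_from_stack", "classify_layers", "render_synthetic_stack",
    "read_stack", "write_stack",
]

BACKGROUND = 0
TYPE1 = 1
TYPE2 = 2

REFERENCE_UM_PER_PX = 0.84


@dataclass
class IntensityStack:
    """3D intensity array (z, y, x) with voxel-size metadata (um/px)."""

    data: np.ndarray              # non-negative intensities, axis 0 = z
    lateral_um_per_px: float
    axial_um_per_px: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3D (z, y, x)")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.lateral_um_per_px <= 0 or self.axial_um_per_px <= 0:
            raise ValueError("voxel sizes must be positive")


@dataclass
class LayerMap:
    """Single/multi-layer classification of a 2D colony image."""

    types: np.ndarray             # BACKGROUND / TYPE1 / TYPE2 per pixel
    counts: np.ndarray            # stencil counts n_ij
    Npx1: int
    Npx2: int
    r_inner: float                # um
    r_outer: float                # um
    um_per_px: float


def height_from_stack(stack: IntensityStack,
                      threshold_fraction: float = 0.5) -> np.ndarray:
    """Height map by intensity thresholding.

    The absolute threshold is ``threshold_fraction`` times the maximum
    intensity of the stack (rescaling by the colony's maximum fluorescence);
    per (x, y) column the height is the axial position of the topmost voxel
    above threshold, in um, and 0 where no voxel exceeds it.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    data = stack.data
    vmax = float(data.max())
    if vmax == 0:
        return np.zeros(data.shape[1:], dtype=float)
    thr = threshold_fraction * vmax
    above = data > thr
    nz = data.shape[0]
    # topmost True along axis 0; argmax on the reversed mask
    rev = above[::-1]
    first = np.argmax(rev, axis=0)
    any_above = above.any(axis=0)
    top_index = (nz - 1) - first
    h = np.where(any_above, (top_index + 1) * stack.axial_um_per_px, 0.0)
    return h


def classify_layers(image: np.ndarray, intensity_threshold: float,
                    um_per_px: float = REFERENCE_UM_PER_PX) -> LayerMap:
    """5x5 stencil single/multi-layer classification of a 2D image.

    For each pixel, n = number of pixels above ``intensity_threshold``
    within its 5x5 neighborhood (edge pixels use the truncated
    neighborhood).  Type 1 (single layer) iff 3 <= n < 16, type 2
    (multi-layer) iff n >= 16.  The layer radii are computed from the type
    counts as r_inner = s sqrt(Npx2/pi), r_outer = s sqrt((Npx1+Npx2)/pi).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if intensity_threshold < 0:
        raise ValueError("threshold must be non-negative")
    bright = (image > intensity_threshold).astype(np.int32)
    # zero padding == truncated neighborhoods: outside pixels never count
    counts = ndimage.uniform_filter(bright.astype(float), size=5,
                                    mode="constant", cval=0.0)
    counts = np.rint(counts * 25).astype(np.int32)
    types = np.full(image.shape, BACKGROUND, dtype=np.int8)
    types[(counts >= 3) & (counts < 16)] = TYPE1
    types[counts >= 16] = TYPE2
    Npx1 = int(np.sum(types == TYPE1))
    Npx2 = int(np.sum(types == TYPE2))
    r_inner = um_per_px * math.sqrt(Npx2 / math.pi)
    r_outer = um_per_px * math.sqrt((Npx1 + Npx2) / math.pi)
    return LayerMap(types=types, counts=counts, Npx1=Npx1, Npx2=Npx2,
                    r_inner=r_inner, r_outer=r_outer, um_per_px=um_per_px)


def render_synthetic_stack(snapshot: Snapshot,
                           lateral_um_per_px: float = 0.25,
                           axial_um_per_px: float = 0.25,
                           intensity: float = 100.0,
                           blur_sigma_um: float = 0.0,
                           pad_um: float = 2.0) -> IntensityStack:
    """Rasterize a snapshot's spherocylinders into a synthetic intensity
    stack (uniform interior intensity, optional Gaussian blur).

    Deterministic given the snapshot and optics parameters.  Voxel sizes
    larger than the cell width are unresolvable and rejected.
    """
    if snapshot.n_cells == 0:
        raise ValueError("snapshot has no cells")
    w0 = snapshot.w0
    if lateral_um_per_px >= w0 or axial_um_per_px >= w0:
        raise ValueError("voxel size must be smaller than the cell width")
    r = snapshot.r
    l = snapshot.l
    n = snapshot.n
    half = 0.5 * l[:, None] * n
    caps_p = r + half
    caps_q = r - half
    lo = np.minimum(caps_p, caps_q).min(axis=0) - 0.5 * w0 - pad_um
    hi = np.maximum(caps_p, caps_q).max(axis=0) + 0.5 * w0 + pad_um
    lo[2] = min(lo[2], 0.0)
    nxp = int(math.ceil((hi[0] - lo[0]) / lateral_um_per_px))
    nyp = int(math.ceil((hi[1] - lo[1]) / lateral_um_per_px))
    nzp = int(math.ceil((hi[2] - lo[2]) / axial_um_per_px))
    data = np.zeros((nzp, nyp, nxp), dtype=float)
    rad = 0.5 * w0
    for i in range(snapshot.n_cells):
        p = caps_p[i]
        q = caps_q[i]
        blo = np.minimum(p, q) - rad
        bhi = np.maximum(p, q) + rad
        ix0 = max(int((blo[0] - lo[0]) / lateral_um_per_px), 0)
        ix1 = min(int((bhi[0] - lo[0]) / lateral_um_per_px) + 2, nxp)
        iy0 = max(int((blo[1] - lo[1]) / lateral_um_per_px), 0)
        iy1 = min(int((bhi[1] - lo[1]) / lateral_um_per_px) + 2, nyp)
        iz0 = max(int((blo[2] - lo[2]) / axial_um_per_px), 0)
        iz1 = min(int((bhi[2] - lo[2]) / axial_um_per_px) + 2, nzp)
        xs = lo[0] + (np.arange(ix0, ix1) + 0.5) * lateral_um_per_px
        ys = lo[1] + (np.arange(iy0, iy1) + 0.5) * lateral_um_per_px
        zs = lo[2] + (np.arange(iz0, iz1) + 0.5) * axial_um_per_px
        if not (len(xs) and len(ys) and len(zs)):
            continue
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        d = _dist_point_segment(X, Y, Z, p, q)
        data[iz0:iz1, iy0:iy1, ix0:ix1][d <= rad] = intensity
    if blur_sigma_um > 0:
        data = ndimage.gaussian_filter(
            data, sigma=(blur_sigma_um / axial_um_per_px,
                         blur_sigma_um / lateral_um_per_px,
                         blur_sigma_um / lateral_um_per_px),
            mode="constant")
    return IntensityStack(data=data,
                          lateral_um_per_px=lateral_um_per_px,
                          axial_um_per_px=axial_um_per_px)


def _dist_point_segment(X, Y, Z, p, q):
    """Vectorized distance from grid points to the segment [p, q]."""
    d = q - p
    dd = float(np.dot(d, d))
    if dd < 1e-18:
        return np.sqrt((X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2)
    t = ((X - p[0]) * d[0] + (Y - p[1]) * d[1] + (Z - p[2]) * d[2]) / dd
    t = np.clip(t, 0.0, 1.0)
    cx = p[0] + t * d[0]
    cy = p[1] + t * d[1]
    cz = p[2] + t * d[2]
    return np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)


def read_stack(path, lateral_um_per_px: float,
               axial_um_per_px: float) -> IntensityStack:
    """Read a multi-page TIFF stack (axis 0 = z)."""
    import tifffile
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return IntensityStack(np.asarray(data, float), lateral_um_per_px,
                          axial_um_per_px)


def write_stack(stack: IntensityStack, path) -> None:
    import tifffile
    tifffile.imwrite(path, stack.data.astype(np.float32))
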