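"""Trabecular and subchondral bone morphometry on binary micro-CT volumes.

Grayscale stacks are binarised slice-wise with Bernsen local thresholding
(the midpoint of the local min/max within a circular window, with a low
contrast rule), after which two scalar descriptors are computed per volume of
interest: the bone volume fraction BV/TV (%) and the model-independent
trabecular thickness Tb.Th, defined per foreground voxel as the diameter of
the largest sphere fully inside the structure that contains the voxel
(distance transform + distance ridge + sphere painting).

Two standard VOIs are supported: a subchondral slab immediately below the
cartilage-bone interface, and a centered trabecular core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy**2 + xx**2) <= radius**2


def bernsen_threshold(
    volume: np.ndarray,
    radius: int = 15,
    contrast_threshold: float = 15.0,
    midgray: float = 128.0,
) -> np.ndarray:
    """Bernsen local thresholding, computed per 2-D slice.

    Per voxel the local threshold is ``(local max + local min) / 2`` within a
    circular window of ``radius``; a voxel is foreground when its value is at
    least the local threshold.  Where the local contrast ``max - min`` falls
    below ``contrast_threshold`` the window is considered structureless and
    the voxel is foreground iff the local mid-gray is at least ``midgray``.

    2-D arrays are treated as a single slice; 3-D stacks are thresholded
    slice-by-slice along axis 0, matching common micro-CT practice.
    """
    vol = np.asarray(volume)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    squeeze = vol.ndim == 2
    if squeeze:
        vol = vol[None]
    if vol.ndim != 3:
        raise ValueError("expected a 2-D image or 3-D stack")
    if 2 * radius + 1 > min(vol.shape[1], vol.shape[2]):
        raise ValueError(f"window radius {radius} larger than slice extent")

    fp = _disk_footprint(radius)
    out = np.empty(vol.shape, dtype=np.uint8)
    for k in range(vol.shape[0]):
        sl = vol[k].astype(float)
        lmax = ndimage.maximum_filter(sl, footprint=fp, mode="reflect")
        lmin = ndimage.minimum_filter(sl, footprint=fp, mode="reflect")
        mid = 0.5 * (lmax + lmin)
        contrast = lmax - lmin
        fg = np.where(contrast >= contrast_threshold, sl >= mid, mid >= midgray)
        out[k] = fg.astype(np.uint8)
    return out[0] if squeeze else out


def _check_binary(vol: np.ndarray) -> np.ndarray:
    arr = np.asarray(vol)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError("volume must be binary (values 0/1)")
    return arr.astype(bool)


def bv_tv(binary: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Bone volume fraction: 100 * foreground voxels / voxels in mask."""
    arr = _check_binary(binary)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise ValueError("mask shape must match volume")
        if not mask.any():
            raise ValueError("mask selects no voxels")
        arr = arr[mask]
    return float(100.0 * arr.mean())


def _distance_ridge(edt: np.ndarray, fg: np.ndarray) -> np.ndarray:
    """Voxels whose maximal inscribed sphere is not contained in a
    neighbour's sphere (Dougherty-Kunzelmann distance ridge)."""
    covered = np.zeros_like(fg)
    # neighbour at offset distance d covers voxel c's sphere if
    # edt(n) >= edt(c) + d; check the 26-neighbourhood by offset class
    for d, fp in (
        (1.0, ndimage.generate_binary_structure(3, 1)),
        (np.sqrt(2.0), ndimage.generate_binary_structure(3, 2)
         & ~ndimage.generate_binary_structure(3, 1)),
        (np.sqrt(3.0), ndimage.generate_binary_structure(3, 3)
         & ~ndimage.generate_binary_structure(3, 2)),
    ):
        fp = fp.copy()
        fp[1, 1, 1] = False
        nmax = ndimage.maximum_filter(edt, footprint=fp, mode="constant", cval=0.0)
        covered |= nmax >= edt + d - 1e-9
    return fg & ~covered


def local_thickness(binary: np.ndarray) -> np.ndarray:
    """Per-voxel structure thickness (voxels): diameter of the largest
    inscribed sphere containing the voxel."""
    fg = _check_binary(binary)
    if fg.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if not fg.any():
        raise ValueError("volume contains no foreground")
    edt = ndimage.distance_transform_edt(fg)
    ridge = _distance_ridge(edt, fg)
    centers = np.argwhere(ridge)
    radii = edt[ridge]
    order = np.argsort(radii)[::-1]  # big spheres first; ties to larger sphere
    centers, radii = centers[order], radii[order]

    out = np.zeros(fg.shape, dtype=float)
    shape = fg.shape
    for (cz, cy, cx), r in zip(centers, radii):
        # EDT measures to the nearest background voxel *center*; the solid
        # surface sits half a voxel closer, hence diameter 2r - 1.  Painting
        # uses radius r so boundary voxels inherit their maximal sphere.
        thick = 2.0 * r - 1.0
        rr = r
        ir = int(np.floor(rr))
        z0, z1 = max(cz - ir, 0), min(cz + ir + 1, shape[0])
        y0, y1 = max(cy - ir, 0), min(cy + ir + 1, shape[1])
        x0, x1 = max(cx - ir, 0), min(cx + ir + 1, shape[2])
        sub = out[z0:z1, y0:y1, x0:x1]
        if np.all(sub >= thick):
            continue
        zz, yy, xx = np.ogrid[z0 - cz:z1 - cz, y0 - cy:y1 - cy, x0 - cx:x1 - cx]
        ball = (zz**2 + yy**2 + xx**2) <= rr**2
        np.maximum(sub, np.where(ball, thick, 0.0), out=sub)
    out[~fg] = 0.0
    return out


def trabecular_thickness(binary: np.ndarray, voxel_size_um: float = 1.0,
                         mask: np.ndarray | None = None):
    """Mean and SD of the local thickness over foreground voxels, in um.

    Returns ``(tbth_mean_um, tbth_sd_um, thickness_map_um)``.
    """
    if voxel_size_um <= 0:
        raise ValueError("voxel size must be positive")
    tmap = local_thickness(binary) * voxel_size_um
    fg = np.asarray(binary, dtype=bool)
    if mask is not None:
        fg = fg & np.asarray(mask, dtype=bool)
        if not fg.any():
            raise ValueError("no foreground inside mask")
    vals = tmap[fg]
    return float(vals.mean()), float(vals.std(ddof=1) if vals.size > 1 else 0.0), tmap


def extract_vois(binary: np.ndarray, subchondral_depth: float = 0.05,
                 trabecular_core: float = 0.4, interface_axis: int = 0):
    """Subchondral slab and centered trabecular-core masks.

    The subchondral VOI is a slab of depth ``subchondral_depth`` (fraction of
    the volume extent along ``interface_axis``) starting at the first slice
    that contains bone; the trabecular VOI is a centered box spanning
    ``trabecular_core`` of every dimension.  The two must not overlap.
    """
    fg = _check_binary(binary)
    if fg.ndim != 3:
        raise ValueError("expected a 3-D volume")
    ax = interface_axis
    n = fg.shape[ax]
    per_slice = fg.any(axis=tuple(i for i in range(3) if i != ax))
    if not per_slice.any():
        raise ValueError("no bone in volume")
    i0 = int(np.argmax(per_slice))
    depth = max(1, int(round(subchondral_depth * n)))

    sub = np.zeros(fg.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[ax] = slice(i0, min(i0 + depth, n))
    sub[tuple(sl)] = True

    core = np.ones(fg.shape, dtype=bool)
    core_ranges = []
    for axis, size in enumerate(fg.shape):
        half = trabecular_core / 2.0
        lo = int(round(size * (0.5 - half)))
        hi = int(round(size * (0.5 + half)))
        m = np.zeros(size, dtype=bool)
        m[lo:hi] = True
        shape = [1, 1, 1]
        shape[axis] = size
        core &= m.reshape(shape)
        core_ranges.append((lo, hi))

    if i0 + depth > core_ranges[ax][0]:
        raise ValueError(
            "subchondral slab and trabecular core overlap; shrink "
            "subchondral_depth and/or trabecular_core"
        )
    return sub, core


@dataclass(frozen=True)
class MorphometryResult:
    """BV/TV (%) and trabecular thickness (um) for one VOI."""

    bvtv_pct: float
    tbth_mean_um: float
    tbth_sd_um: float
    voi_label: str = "custom"

    def __post_init__(self):
        if not (0.0 <= self.bvtv_pct <= 100.0):
            raise ValueError("BV/TV must be in [0, 100]")


def morphometry_report(binary: np.ndarray, voxel_size_um: float = 20.0,
                       subchondral_depth: float = 0.05,
                       trabecular_core: float = 0.4,
                       interface_axis: int = 0) -> dict[str, MorphometryResult]:
    """BV/TV and Tb.Th for the subchondral and trabecular VOIs."""
    sub, core = extract_vois(binary, subchondral_depth, trabecular_core,
                             interface_axis)
    tmap = local_thickness(binary) * voxel_size_um
    fg = np.asarray(binary, dtype=bool)
    out = {}
    for label, mask in (("subchondral", sub), ("trabecular", core)):
        sel = fg & mask
        if sel.any():
            vals = tmap[sel]
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        else:
            mean, sd = 0.0, 0.0
        out[label] = MorphometryResult(
            bvtv_pct=bv_tv(binary, mask), tbth_mean_um=mean, tbth_sd_um=sd,
            voi_label=label,
        )
    return out
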