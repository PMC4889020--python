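"""Tissue/paraffin segmentation, mask smoothing, cropping, slice assembly.

The tissue segmentation protocol: the global threshold is the mean gray
value of a known paraffin region (nominally 1 mm^3), voxels strictly above
threshold (+ optional margin) are tissue, and a majority-vote smoothing
pass cleans speckle.  Sparse per-slice lesion annotations are assembled
into a dense label volume, reconstructing missing levels (e.g. ribbon
section breaks) by shape-based interpolation of signed Euclidean distance
maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GrayVolume, LabelVolume, SliceLabelStack, UM3_PER_MM3

logger = logging.getLogger("foci3d")

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class TissueMask:
    """Binary tissue mask on a GrayVolume grid, with segmentation provenance."""

    data: np.ndarray
    spacing_um: float
    threshold_used: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def estimate_paraffin_threshold(
    volume: GrayVolume,
    roi: Box,
    min_volume_mm3: float = 1.0,
) -> float:
    """Mean gray value of a paraffin region of interest.

    ``roi`` is ((z0, z1), (y0, y1), (x0, x1)) in voxels, half-open.  The ROI
    should nominally contain 1 mm^3 of paraffin; a smaller ROI is accepted
    with a warning (the mean is then noisier).
    """
    for (lo, hi), n in zip(roi, volume.shape):
        if not (0 <= lo < hi <= n):
            raise ValueError(f"roi range [{lo}, {hi}) outside volume of extent {n}")
    sub = volume.data[tuple(slice(lo, hi) for lo, hi in roi)]
    roi_mm3 = sub.size * volume.voxel_volume_um3 / UM3_PER_MM3
    if roi_mm3 < min_volume_mm3:
        warnings.warn(
            f"paraffin ROI is {roi_mm3:.3g} mm^3, below the nominal "
            f"{min_volume_mm3} mm^3; threshold estimate will be noisier",
            stacklevel=2)
    thr = float(sub.mean())
    logger.info("paraffin threshold %.3f from %.3g mm^3 ROI", thr, roi_mm3)
    return thr


def segment_tissue(volume: GrayVolume, threshold: float, margin: float = 0.0) -> TissueMask:
    """Global threshold: voxel is tissue iff gray > threshold + margin.

    The comparison is strict, so voxels exactly at the paraffin mean are
    classified paraffin (conservative for tissue volume).  ``margin`` lifts
    the cut above the paraffin mean when noise would otherwise send half the
    paraffin voxels over it.
    """
    return TissueMask(
        data=volume.data > (threshold + margin),
        spacing_um=volume.spacing_um,
        threshold_used=float(threshold + margin),
        origin_um=volume.origin_um,
    )


def smooth_mask(mask: TissueMask, radius: int = 1, passes: int = 1) -> TissueMask:
    """Majority-vote smoothing over the face-connected cross neighborhood.

    Each voxel takes the majority value of the 6r+1 voxels on the axis
    segments of half-length ``radius`` through it (ties keep the input
    value; the neighborhood is odd-sized, so ties cannot arise in a binary
    mask).  The cross neighborhood is chosen over the full (2r+1)^3 cube
    deliberately: cube-neighborhood majority erodes the corners of solid
    blocks, whereas the cross vote leaves faces, edges and corners of
    solids fixed while still removing isolated speckle and filling
    pinholes.  Voxels outside the volume count as background (zero-padded),
    matching the embedding of the sample in a paraffin bath.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    kernel = np.zeros((size, size, size), dtype=np.uint8)
    kernel[:, radius, radius] = 1
    kernel[radius, :, radius] = 1
    kernel[radius, radius, :] = 1
    n_kernel = int(kernel.sum())  # 6r + 1, odd
    data = mask.data
    for _ in range(passes):
        counts = ndimage.correlate(data.astype(np.uint8), kernel, mode="constant")
        out = data.copy()
        out[2 * counts > n_kernel] = True
        out[2 * counts < n_kernel] = False
        data = out
    return TissueMask(data=data, spacing_um=mask.spacing_um,
                      threshold_used=mask.threshold_used, origin_um=mask.origin_um)


def crop_subvolume(volume, z_range, y_range, x_range):
    """Crop to half-open voxel ranges, preserving grid metadata.

    Works on GrayVolume, LabelVolume and TissueMask; the origin shifts so
    cropped voxels keep their physical coordinates.
    """
    ranges = (tuple(z_range), tuple(y_range), tuple(x_range))
    for (lo, hi), n in zip(ranges, volume.data.shape):
        if not (0 <= lo < hi <= n):
            raise ValueError(f"crop range [{lo}, {hi}) invalid for axis of extent {n}")
    sl = tuple(slice(lo, hi) for lo, hi in ranges)
    new_origin = volume.origin_um + np.array([r[0] for r in ranges]) * volume.spacing_um
    if isinstance(volume, TissueMask):
        return TissueMask(volume.data[sl].copy(), spacing_um=volume.spacing_um,
                          threshold_used=volume.threshold_used, origin_um=new_origin)
    return type(volume)(volume.data[sl].copy(), spacing_um=volume.spacing_um,
                        origin_um=new_origin)


def _signed_distance(mask2d: np.ndarray) -> np.ndarray:
    """Signed EDT: negative inside the region, positive outside (pixel units)."""
    inside = ndimage.distance_transform_edt(mask2d)
    outside = ndimage.distance_transform_edt(~mask2d)
    return outside - inside


def interpolate_missing_slices(stack: SliceLabelStack, max_gap: int = 3) -> LabelVolume:
    """Assemble sparse slices into a dense label volume, filling small gaps.

    Present slices are copied verbatim.  For each missing slice inside a gap
    of at most ``max_gap`` slices, each label present in *both* bounding
    slices is reconstructed by linearly blending the two slices' signed
    Euclidean distance maps at the slice's fractional position and
    thresholding at zero (shape-based interpolation); this restores constant
    cross-sections exactly and interpolates radii of round cross-sections
    linearly.  A label absent from either bounding slice does not enter the
    gap.  Gaps wider than ``max_gap`` are left empty with a warning —
    bridging them would fabricate connectivity.
    """
    if not stack.entries:
        raise ValueError("empty slice stack")
    zs = stack.z_indices
    z0, z1 = zs[0], zs[-1]
    nz = z1 - z0 + 1
    dtype = stack.entries[0][1].dtype
    if not np.issubdtype(dtype, np.integer):
        dtype = np.int32
    out = np.zeros((nz,) + tuple(stack.target_shape), dtype=dtype)
    present = {z: img for z, img in stack.entries}
    for z, img in stack.entries:
        out[z - z0] = img

    # walk consecutive present pairs; fill the gap between them
    for (za, imga), (zb, imgb) in zip(stack.entries[:-1], stack.entries[1:]):
        gap = zb - za - 1
        if gap == 0:
            continue
        if gap > max_gap:
            warnings.warn(
                f"gap of {gap} slices between z={za} and z={zb} exceeds max_gap="
                f"{max_gap}; left empty", stacklevel=2)
            continue
        shared = np.intersect1d(np.unique(imga), np.unique(imgb))
        shared = shared[shared > 0]
        sd_a = {lab: _signed_distance(imga == lab) for lab in shared}
        sd_b = {lab: _signed_distance(imgb == lab) for lab in shared}
        for z in range(za + 1, zb):
            w = (z - za) / (zb - za)
            slab = np.zeros(tuple(stack.target_shape), dtype=dtype)
            for lab in shared:
                sd = (1 - w) * sd_a[lab] + w * sd_b[lab]
                slab[sd < 0] = lab
            out[z - z0] = slab
    return LabelVolume(out, spacing_um=stack.spacing_um,
                       origin_um=np.array([z0 * stack.spacing_um, 0.0, 0.0]))
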