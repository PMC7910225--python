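"""Four-step airway segmentation of a reconstructed lung volume.

1. Bone voxels are masked out with a single global threshold (bone is by
   far the brightest material).
2. Per-slice iso-thresholds (iterative intermeans, Ridler-Calvard) separate
   the remaining pixels into air and tissue inside a cylindrical mask that
   roughly bounds the animal body (rejecting outside-air at the image
   edges); airways are *below* threshold since reconstructed attenuation of
   air is lower than tissue.
3. Only 3D-connected air voxels attached to the trachea seed region (the
   largest component touching the top face) are kept.
4. A second slice-wise iso-threshold pass restricted to a dilated version of
   the mask, on a sharpened (unsharp-masked) copy of the volume, refines the
   boundary; the airway volume is the final voxel count times the voxel
   volume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import unsharp_mask
from skimage.morphology import ball

__all__ = [
    "SegmentationResult", "mask_bone", "intermeans_threshold",
    "iso_threshold_slicewise", "extract_connected_airways",
    "refine_segmentation", "segment_airways", "auto_cylinder_mask",
]

log = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    airway_mask: np.ndarray
    bone_mask: np.ndarray
    thresholds: np.ndarray          # per-slice final thresholds
    volume_cm3: float
    voxel_size_um: float
    meta: dict = field(default_factory=dict)


def mask_bone(volume: np.ndarray, global_threshold: float) -> np.ndarray:
    """Bone mask: voxels strictly above a single global threshold."""
    vol = np.asarray(volume)
    mask = vol > global_threshold
    if mask.all():
        log.warning("bone threshold below volume minimum: full mask "
                    "(suspicious)")
    return mask


def intermeans_threshold(values: np.ndarray, tol: float = 1e-4,
                         max_iter: int = 200) -> float:
    """Iterative intermeans (Ridler-Calvard) threshold of a value sample.

    Starting from the sample mean, iterate ``t <- (mean(x < t) +
    mean(x >= t)) / 2`` to its fixed point: the threshold halfway between
    the two class means.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 distinct values")
    t = float(x.mean())
    scale = float(np.ptp(x))
    for _ in range(max_iter):
        lo = x[x < t]
        hi = x[x >= t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < tol * scale:
            t = t_new
            break
        t = t_new
    return float(t)


def auto_cylinder_mask(volume: np.ndarray, body_threshold: float | None = None,
                       shrink: float = 0.97) -> np.ndarray:
    """Cylindrical mask fitted to the body outline of the middle slice.

    The body is tissue-or-denser material (well above air but below bone);
    the cylinder is centred on its centroid with radius set by the 99th
    percentile of body-pixel distances, slightly shrunk so outside-air at
    the image edges is rejected.
    """
    vol = np.asarray(volume)
    mid = vol[vol.shape[0] // 2]
    if body_threshold is None:
        # a robust mid-grey between air (~0) and tissue: tissue dominates
        # the upper half of the histogram, bone is too rare to matter
        body_threshold = 0.25 * float(np.percentile(mid, 90))
    body = mid > body_threshold
    if not body.any():
        raise ValueError("auto cylinder fit found no body voxels")
    yy, xx = np.nonzero(body)
    cy, cx = yy.mean(), xx.mean()
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    r = shrink * np.percentile(dist, 99)
    gy, gx = np.meshgrid(np.arange(vol.shape[1]), np.arange(vol.shape[2]),
                         indexing="ij")
    disk = (gy - cy) ** 2 + (gx - cx) ** 2 <= r ** 2
    return np.broadcast_to(disk, vol.shape).copy()


def iso_threshold_slicewise(volume: np.ndarray,
                            exclusion_masks: np.ndarray | list | None = None,
                            cylinder_mask: np.ndarray | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Initial air mask from per-slice intermeans thresholds.

    Thresholds are computed per z-slice on the pixels inside the cylinder
    and outside every exclusion mask; air is below threshold.  Degenerate
    slices (fewer than two distinct usable values) borrow the threshold of
    the nearest valid slice, with a warning.
    """
    vol = np.asarray(volume, dtype=np.float64)
    nz = vol.shape[0]
    excl = np.zeros(vol.shape, dtype=bool)
    if exclusion_masks is not None:
        masks = exclusion_masks if isinstance(exclusion_masks, (list, tuple)) \
            else [exclusion_masks]
        for m in masks:
            excl |= np.asarray(m, dtype=bool)
    include = ~excl
    if cylinder_mask is not None:
        include &= np.asarray(cylinder_mask, dtype=bool)

    thresholds = np.full(nz, np.nan)
    for z in range(nz):
        pix = vol[z][include[z]]
        if pix.size >= 2 and np.ptp(pix) > 0:
            thresholds[z] = intermeans_threshold(pix)
    bad = np.isnan(thresholds)
    if bad.all():
        raise ValueError("no slice has enough distinct values to threshold")
    if bad.any():
        warnings.warn(f"{int(bad.sum())} degenerate slices; borrowing "
                      "thresholds from nearest valid slices")
        good = np.flatnonzero(~bad)
        for z in np.flatnonzero(bad):
            thresholds[z] = thresholds[good[np.argmin(np.abs(good - z))]]
    air = (vol < thresholds[:, None, None]) & include
    return air, thresholds


def extract_connected_airways(initial_mask: np.ndarray,
                              seed: str = "top") -> np.ndarray:
    """Keep only air voxels 3D-connected (26-connectivity) to the trachea.

    The seed region is the top face of the volume (highest z index), where
    the trachea enters; the largest connected component touching it is
    retained.  If no component touches the top face the globally largest
    component is kept with a warning.
    """
    mask = np.asarray(initial_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty initial mask")
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    top = labels[-1] if seed == "top" else labels[0]
    touching = np.unique(top[top > 0])
    if touching.size == 0:
        warnings.warn("no component touches the seed face; keeping the "
                      "largest component")
        keep = int(np.argmax(sizes))
    else:
        keep = int(touching[np.argmax(sizes[touching])])
    return labels == keep


def refine_segmentation(volume: np.ndarray, airway_mask: np.ndarray,
                        voxel_size_um: float,
                        dilation_radius: int = 1,
                        sharpness_amount: float = 1.0,
                        sharpness_sigma: float = 2.0
                        ) -> tuple[np.ndarray, float, np.ndarray]:
    """Second-pass refinement and volume quantification.

    The airway mask is dilated by ``dilation_radius`` so both air and the
    adjacent tissue rim enter the second per-slice intermeans thresholding;
    the thresholds are computed on an unsharp-masked copy of the volume
    (``sharpness_amount = 0`` leaves the volume unchanged).  Returns
    ``(final_mask, volume_cm3, thresholds)``.
    """
    vol = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(airway_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty airway mask")
    if dilation_radius > 0:
        dilated = ndimage.binary_dilation(mask, structure=ball(dilation_radius))
    else:
        dilated = mask
    if sharpness_amount > 0:
        lo, hi = float(vol.min()), float(vol.max())
        span = max(hi - lo, 1e-12)
        sharp = unsharp_mask((vol - lo) / span, radius=sharpness_sigma,
                             amount=sharpness_amount)
        sharp = sharp * span + lo
    else:
        sharp = vol
    final, thresholds = iso_threshold_slicewise(sharp, exclusion_masks=~dilated)
    volume_cm3 = float(np.count_nonzero(final)) * (voxel_size_um * 1e-4) ** 3
    return final, volume_cm3, thresholds


def segment_airways(volume: np.ndarray, voxel_size_um: float,
                    bone_threshold: float,
                    cylinder_mask: np.ndarray | str | None = "auto",
                    dilation_radius: int = 1,
                    sharpness_amount: float = 1.0,
                    keep_connected: bool = True,
                    invalid_mask: np.ndarray | None = None) -> SegmentationResult:
    """Run the full four-step airway segmentation.

    ``invalid_mask`` marks voxels with no valid image data (e.g. mosaic
    voxels covered by no tile); they are excluded like bone so fill values
    are never mistaken for air.
    """
    vol = np.asarray(volume, dtype=np.float64)
    bone = mask_bone(vol, bone_threshold)
    excl = [bone]
    if invalid_mask is not None:
        excl.append(np.asarray(invalid_mask, dtype=bool))
    if isinstance(cylinder_mask, str) and cylinder_mask == "auto":
        cyl = auto_cylinder_mask(vol)
    else:
        cyl = cylinder_mask
    initial, thr0 = iso_threshold_slicewise(vol, exclusion_masks=excl,
                                            cylinder_mask=cyl)
    airways = extract_connected_airways(initial) if keep_connected else initial
    final, volume_cm3, thr = refine_segmentation(
        vol, airways, voxel_size_um,
        dilation_radius=dilation_radius, sharpness_amount=sharpness_amount)
    final &= ~bone
    if invalid_mask is not None:
        final &= ~np.asarray(invalid_mask, dtype=bool)
    volume_cm3 = float(np.count_nonzero(final)) * (voxel_size_um * 1e-4) ** 3
    return SegmentationResult(airway_mask=final, bone_mask=bone,
                              thresholds=thr, volume_cm3=volume_cm3,
                              voxel_size_um=voxel_size_um,
                              meta={"initial_thresholds": thr0.tolist()})
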