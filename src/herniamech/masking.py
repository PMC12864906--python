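"""Body-outline extraction from CT and mask downscaling.

The registration operates on body outlines, not on raw HU: each scan is
thresholded, the patient table (always disconnected from the body above
the air/tissue threshold) is discarded as a smaller connected component,
and interior air (lungs, bowel gas) is filled so the mask is a solid body.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import BinaryMask, MaskProvenance, ScanVolume, replace

#: Default HU threshold separating soft tissue/skin from air across the
#: 80-130 kVp range used clinically.
DEFAULT_HU_THRESHOLD = -300.0

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class EmptyMaskError(ValueError):
    """No voxel exceeded the HU threshold."""


class ImplausibleBodyError(ValueError):
    """The largest connected component is too small to be a torso."""


def body_mask(
    scan: ScanVolume,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    min_component_mm3: float = 1e5,
) -> BinaryMask:
    """Threshold a CT scan into a solid single-component body outline.

    Voxels above ``hu_threshold`` are candidates; only the largest
    26-connected component is kept (removing the table, cables and other
    detached objects), then internal cavities are closed by a 3D
    morphological fill followed by a per-axial-slice 2D fill.

    Raises
    ------
    EmptyMaskError
        if nothing exceeds the threshold.
    ImplausibleBodyError
        if the largest component is smaller than ``min_component_mm3``.
    """
    candidates = scan.voxels > hu_threshold
    if not candidates.any():
        raise EmptyMaskError(f"no voxel above {hu_threshold} HU")

    labels, n = ndimage.label(candidates, structure=_CONN26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    body = labels == largest
    if sizes[largest - 1] * scan.voxel_volume_mm3 < min_component_mm3:
        raise ImplausibleBodyError(
            f"largest component is {sizes[largest - 1] * scan.voxel_volume_mm3:.0f} mm^3, "
            f"below the plausibility floor of {min_component_mm3:.0f} mm^3"
        )

    body = ndimage.binary_fill_holes(body)
    # 2D fill per axial slice: gas pockets open to the volume top/bottom
    # survive the 3D fill but must not punch holes in the outline.
    for k in range(body.shape[2]):
        body[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])

    return BinaryMask(
        voxels=body,
        spacing=scan.spacing,
        origin=scan.origin,
        axis_codes=scan.axis_codes,
        provenance=MaskProvenance.BODY_OUTLINE,
    )


def qc_content_mask(
    scan: ScanVolume,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    min_component_mm3: float = 1_000.0,
) -> BinaryMask:
    """Thresholded raster for content QC, keeping detached objects.

    Unlike :func:`body_mask` this does NOT reduce to the largest
    component: the content checks must still see arms or other foreign
    objects in the field of view. Two kinds of components are dropped:
    specks below ``min_component_mm3`` (noise), and components touching
    the posterior image border, which is where the patient table sits
    (the table extends below the field of view and is irrelevant to the
    body surface).
    """
    candidates = scan.voxels > hu_threshold
    if not candidates.any():
        raise EmptyMaskError(f"no voxel above {hu_threshold} HU")
    labels, n = ndimage.label(candidates, structure=_CONN26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    posterior = np.unique(labels[:, 0, :])
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    keep[posterior] = False
    keep[1:] &= sizes * scan.voxel_volume_mm3 >= min_component_mm3
    return BinaryMask(
        voxels=keep[labels],
        spacing=scan.spacing,
        origin=scan.origin,
        axis_codes=scan.axis_codes,
        provenance=MaskProvenance.BODY_OUTLINE,
    )


def downscale_mask(mask: BinaryMask, factor: int = 3) -> BinaryMask:
    """Block-reduce a mask by an integer factor with per-block majority vote.

    Spacing is multiplied by the factor and the origin shifted so each
    coarse voxel centre sits at the centre of the fine block it replaces.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return replace(mask, voxels=mask.voxels.copy())

    v = mask.voxels
    pad = [(0, (-s) % factor) for s in v.shape]
    v = np.pad(v, pad, mode="constant", constant_values=False)
    nx, ny, nz = (s // factor for s in v.shape)
    blocks = v.reshape(nx, factor, ny, factor, nz, factor)
    counts = blocks.sum(axis=(1, 3, 5))
    coarse = counts * 2 > factor**3  # strict majority

    new_origin = mask.origin + (factor - 1) / 2.0 * mask.spacing
    return replace(
        mask, voxels=coarse, spacing=mask.spacing * factor, origin=new_origin
    )
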