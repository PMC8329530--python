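"""Intracranial segmentation of head NCCT by thresholding and morphology.

The intracranial mask excludes bone, air, and extracranial soft tissue.  It is
advisory: it conditions the symmetry search and QC, while the density
measurements themselves use only the lesion and mirrored-lesion ROIs, so small
segmentation inaccuracies do not propagate into NWU.

Procedure: threshold candidate tissue to [air, bone] HU, binary opening to break
skull-scalp bridges, keep the largest connected component, then close and fill
holes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import SegmentationFailureError
from .volume_io import BinaryMask, CTVolume

log = logging.getLogger(__name__)


def _ball(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (xx ** 2 + yy ** 2 + zz ** 2) <= r ** 2


@dataclass
class IntracranialParams:
    """Thresholds (HU) and morphology radii (voxels) for brain extraction."""

    air_thresh: float = -200.0
    bone_thresh: float = 100.0
    opening_radius: int = 1
    closing_radius: int = 2
    #: minimum plausible intracranial volume; lower it for small phantoms
    min_volume_ml: float = 200.0


@dataclass
class IntracranialMask:
    mask: BinaryMask
    method_params: IntracranialParams
    n_hole_filled: int = 0


def segment_intracranial(volume: CTVolume,
                         params: IntracranialParams | None = None) -> IntracranialMask:
    """Extract the intracranial region (parenchyma + internal CSF spaces).

    Raises :class:`SegmentationFailureError` when no connected component of
    plausible size survives thresholding.
    """
    p = params or IntracranialParams()
    cand = (volume.data >= p.air_thresh) & (volume.data <= p.bone_thresh)
    if p.opening_radius > 0:
        cand = ndimage.binary_opening(cand, structure=_ball(p.opening_radius))
    labels, n_labels = ndimage.label(cand)
    if n_labels == 0:
        raise SegmentationFailureError("no candidate tissue in the HU window")
    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels,
                               index=np.arange(1, n_labels + 1))
    largest = int(np.argmax(sizes)) + 1
    comp = labels == largest
    vol_ml = comp.sum() * volume.voxel_volume_mm3 / 1000.0
    if vol_ml < p.min_volume_ml:
        raise SegmentationFailureError(
            f"largest component is {vol_ml:.1f} ml < minimum {p.min_volume_ml:.1f} ml"
        )
    # out-of-band voxels may only enter via closing/hole-filling, and are counted
    n_before = int(comp.sum())
    if p.closing_radius > 0:
        comp = ndimage.binary_closing(comp, structure=_ball(p.closing_radius))
    comp = ndimage.binary_fill_holes(comp)
    n_filled = int(comp.sum()) - n_before
    if n_filled:
        log.info("intracranial segmentation filled %d voxels", n_filled)
    return IntracranialMask(BinaryMask(comp, volume.affine), p, n_filled)


def check_lesion_coverage(icm: IntracranialMask, lesion: BinaryMask) -> int:
    """Warn when lesion voxels fall outside the intracranial mask; return the count."""
    outside = int(np.sum(lesion.data & ~icm.mask.data))
    if outside:
        log.warning("%d lesion voxels fall outside the intracranial mask", outside)
    return outside
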