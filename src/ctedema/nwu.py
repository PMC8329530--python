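"""Net water uptake (NWU) and the edema / infarct / hemorrhage decomposition.

For one scan, with D_ischemic the mean density of the (non-hemorrhagic)
lesion and D_normal the mean density of its mirror image in the contralateral
hemisphere:

    NWU  = (D_normal - D_ischemic) / D_normal
    EV   = NWU x (TILV - HV)          (reduces to NWU x TILV without hemorrhage)
    ecIV = TILV - EV - HV

so that TILV = EV + ecIV + HV holds identically.  Progression of any metric is
its 1-week value minus its 24-h value.

The 20-80 HU density filter excludes CSF and calcifications from the mirrored
(contralateral) reference; it can optionally be applied to the ipsilateral
lesion as well (``filter_ipsilateral``), which however truncates the lesion's
own density distribution once edema pushes it near 20 HU and thereby biases
NWU downward — see the methods note.  Bounds are inclusive: integer-valued HU
make boundary voxels common.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import EmptyROIError, NonPhysicalDensityError
from .mirroring import SymmetryPlane, mirror_mask
from .volume_io import BinaryMask, CTVolume, LesionSet, Timepoint, mask_volume_ml

log = logging.getLogger(__name__)

HU_LOW_DEFAULT = 20.0
HU_HIGH_DEFAULT = 80.0
#: warn when more than this fraction of the mirrored ROI overlaps the lesion
OVERLAP_WARN_FRACTION = 0.20


@dataclass
class DensityStats:
    """Mean densities and voxel counts entering the NWU formula."""

    d_ischemic: float
    d_normal: float
    n_ipsi: int
    n_contra: int
    n_excluded_overlap: int = 0


@dataclass
class LesionMetrics:
    """Volumetric decomposition of one scan's ischemic lesion."""

    tilv: float          #: total ischemic lesion volume, ml
    hv: float            #: hemorrhage volume, ml
    nwu: float           #: net water uptake, dimensionless fraction
    ev: float            #: edema volume, ml
    eciv: float          #: edema-corrected infarct volume, ml
    timepoint: Timepoint = "24h"
    scan_id: str = "scan"
    stats: DensityStats | None = None

    def as_row(self) -> dict:
        d = {"id": self.scan_id, "timepoint": self.timepoint,
             "tilv_ml": self.tilv, "hv_ml": self.hv, "nwu": self.nwu,
             "ev_ml": self.ev, "eciv_ml": self.eciv}
        if self.stats is not None:
            d.update(n_ipsi=self.stats.n_ipsi, n_contra=self.stats.n_contra,
                     n_excluded_overlap=self.stats.n_excluded_overlap)
        return d


@dataclass
class ProgressionMetrics:
    """1-week minus 24-h differences of the lesion metrics."""

    d_tilv: float
    d_ev: float
    d_eciv: float
    d_hv: float
    d_nwu: float
    scan_id: str = "scan"

    def as_row(self) -> dict:
        return {"id": self.scan_id, "d_tilv_ml": self.d_tilv,
                "d_ev_ml": self.d_ev, "d_eciv_ml": self.d_eciv,
                "d_hv_ml": self.d_hv, "d_nwu": self.d_nwu}


def filter_density_voxels(volume: CTVolume, roi: BinaryMask,
                          low: float = HU_LOW_DEFAULT,
                          high: float = HU_HIGH_DEFAULT) -> BinaryMask:
    """Subset of ``roi`` with ``low <= HU <= high`` (inclusive bounds)."""
    keep = roi.data & (volume.data >= low) & (volume.data <= high)
    return BinaryMask(keep, roi.affine)


def compute_density_stats(volume: CTVolume, lesionset: LesionSet,
                          plane: SymmetryPlane,
                          low: float = HU_LOW_DEFAULT,
                          high: float = HU_HIGH_DEFAULT,
                          filter_ipsilateral: bool = False) -> DensityStats:
    """Mean HU of the non-hemorrhagic lesion and of its contralateral mirror.

    The ipsilateral ROI is the lesion minus any hemorrhage sub-mask.  The
    contralateral ROI is its mirror across ``plane`` minus any overlap with
    the original lesion (midline-crossing lesions; the excluded count is
    recorded), HU-filtered to [low, high].
    """
    ipsi = lesionset.non_hemorrhagic
    ipsi_mask = BinaryMask(ipsi, volume.affine)
    mirrored = mirror_mask(ipsi_mask, plane)
    overlap = mirrored.data & lesionset.lesion.data
    n_overlap = int(overlap.sum())
    n_mirrored = mirrored.n_voxels
    if n_mirrored and n_overlap / n_mirrored > OVERLAP_WARN_FRACTION:
        warnings.warn(
            f"mirrored ROI overlaps the lesion by {n_overlap / n_mirrored:.0%};"
            " contralateral reference may be unreliable", stacklevel=2)
    contra = BinaryMask(mirrored.data & ~lesionset.lesion.data, volume.affine)
    contra = filter_density_voxels(volume, contra, low, high)
    if filter_ipsilateral:
        ipsi_mask = filter_density_voxels(volume, ipsi_mask, low, high)

    n_ipsi, n_contra = ipsi_mask.n_voxels, contra.n_voxels
    if n_ipsi == 0:
        raise EmptyROIError("ipsilateral ROI empty after masking/filtering")
    if n_contra == 0:
        raise EmptyROIError("contralateral ROI empty after masking/filtering")
    d_isch = float(volume.data[ipsi_mask.data].mean())
    d_norm = float(volume.data[contra.data].mean())
    if d_norm <= 0:
        raise NonPhysicalDensityError(
            f"contralateral mean density {d_norm:.2f} HU is non-positive")
    return DensityStats(d_isch, d_norm, n_ipsi, n_contra, n_overlap)


def compute_nwu(stats: DensityStats) -> float:
    """NWU = (D_normal - D_ischemic) / D_normal; negative values are warned, not clipped."""
    if stats.d_normal <= 0:
        raise NonPhysicalDensityError("d_normal must be positive")
    nwu = (stats.d_normal - stats.d_ischemic) / stats.d_normal
    if nwu < 0:
        warnings.warn(f"negative NWU ({nwu:.3f}): lesion denser than its "
                      "contralateral reference", stacklevel=2)
    return nwu


def compute_lesion_metrics(volume: CTVolume, lesionset: LesionSet,
                           plane: SymmetryPlane,
                           low: float = HU_LOW_DEFAULT,
                           high: float = HU_HIGH_DEFAULT,
                           filter_ipsilateral: bool = False) -> LesionMetrics:
    """TILV, HV, NWU, EV, ecIV for one scan.

    EV = NWU x (TILV - HV): NWU is measured over the non-hemorrhagic lesion
    and multiplied by the non-hemorrhagic volume, which covers both the
    with- and without-hemorrhage rules in a single formula.
    """
    stats = compute_density_stats(volume, lesionset, plane, low, high,
                                  filter_ipsilateral)
    nwu = compute_nwu(stats)
    tilv = mask_volume_ml(lesionset.lesion)
    hv = mask_volume_ml(lesionset.hemorrhage) if lesionset.hemorrhage else 0.0
    ev = nwu * (tilv - hv)
    eciv = tilv - ev - hv
    return LesionMetrics(tilv=tilv, hv=hv, nwu=nwu, ev=ev, eciv=eciv,
                         timepoint=volume.timepoint, scan_id=volume.scan_id,
                         stats=stats)


def compute_progression(m24: LesionMetrics, m1w: LesionMetrics) -> ProgressionMetrics:
    """Fieldwise 1-week minus 24-h differences for one patient."""
    if m24.timepoint != "24h" or m1w.timepoint != "1week":
        raise ValueError(
            f"timepoint mismatch: got ({m24.timepoint}, {m1w.timepoint}), "
            "expected (24h, 1week)")
    return ProgressionMetrics(
        d_tilv=m1w.tilv - m24.tilv,
        d_ev=m1w.ev - m24.ev,
        d_eciv=m1w.eciv - m24.eciv,
        d_hv=m1w.hv - m24.hv,
        d_nwu=m1w.nwu - m24.nwu,
        scan_id=m24.scan_id,
    )
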