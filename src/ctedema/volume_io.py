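"""NIfTI volume/mask I/O, grid bookkeeping, and physical volume computation.

All geometry downstream is computed in world millimetres through the affine, so
axis order and flips in the NIfTI header never change results.  Masks are stored
on disk as unsigned 8-bit; any nonzero voxel is true.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, LoadError

log = logging.getLogger(__name__)

#: Plausible Hounsfield range for head CT; values outside reject the scan at load.
HU_MIN = -1400.0
HU_MAX = 4000.0

Timepoint = Literal["24h", "1week"]


@dataclass
class CTVolume:
    """A 3D non-contrast CT volume in Hounsfield units.

    Parameters
    ----------
    data
        3D float array of HU values.
    affine
        4x4 voxel-index -> world-mm transform (NIfTI convention, RAS+).
    scan_id
        Identifier used to tag all downstream outputs.
    timepoint
        ``"24h"`` or ``"1week"``.
    """

    data: np.ndarray
    affine: np.ndarray
    scan_id: str = "scan"
    timepoint: Timepoint = "24h"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise LoadError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise LoadError("affine must be 4x4")
        if not np.all(self.spacing > 0):
            raise LoadError(f"non-positive spacing {tuple(self.spacing)}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise LoadError("non-invertible affine")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world-mm coordinates."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine[:3, :3])
        return (xyz - self.affine[:3, 3]) @ inv.T


@dataclass
class BinaryMask:
    """A boolean mask sharing its parent CT grid (shape + affine)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise GridMismatchError(f"mask must be 3D, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid_as(self, other: "BinaryMask | CTVolume", atol: float = 1e-3) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class LesionSet:
    """Lesion delineation for one scan: lesion mask, optional hemorrhage sub-mask.

    The hemorrhage mask, when present, must be a subset of the lesion (hyperdense
    hemorrhagic transformation lies inside the delineated lesion).
    """

    lesion: BinaryMask
    hemorrhage: Optional[BinaryMask] = None
    symptomatic_side: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        if self.hemorrhage is not None:
            if not self.hemorrhage.same_grid_as(self.lesion):
                raise GridMismatchError("hemorrhage mask not on the lesion grid")
            if np.any(self.hemorrhage.data & ~self.lesion.data):
                raise ValueError("hemorrhage mask is not a subset of the lesion mask")

    @property
    def non_hemorrhagic(self) -> np.ndarray:
        """Boolean array: lesion voxels excluding hemorrhage."""
        if self.hemorrhage is None:
            return self.lesion.data
        return self.lesion.data & ~self.hemorrhage.data


def read_volume(path: str | Path, scan_id: str | None = None,
                timepoint: Timepoint = "24h") -> CTVolume:
    """Load a NIfTI-1 CT volume (.nii/.nii.gz) as HU.

    Rescale slope/intercept from the header are applied by nibabel.  Raises
    :class:`LoadError` for missing files, non-positive spacing, non-invertible
    affines, or HU outside the plausible [-1400, 4000] range, naming the
    offending statistic.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float32))
    lo, hi = float(np.min(data)), float(np.max(data))
    if lo < HU_MIN or hi > HU_MAX:
        raise LoadError(
            f"HU out of plausible range [{HU_MIN:g}, {HU_MAX:g}]: min={lo:g}, max={hi:g}"
        )
    vol = CTVolume(data, img.affine, scan_id=scan_id or path.name.split(".")[0],
                   timepoint=timepoint)
    log.info("loaded %s: shape=%s spacing=%s", vol.scan_id, vol.shape,
             tuple(np.round(vol.spacing, 4)))
    return vol


def write_volume(vol: CTVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def read_mask(path: str | Path, parent: CTVolume) -> BinaryMask:
    """Load a mask NIfTI on the parent grid; any nonzero voxel becomes true."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.shape != parent.shape or not np.allclose(img.affine, parent.affine,
                                                     atol=1e-3):
        raise GridMismatchError(
            f"mask grid {data.shape} does not match parent grid {parent.shape} "
            "(or affines differ)"
        )
    mask = BinaryMask(data != 0, parent.affine)
    if mask.n_voxels == 0:
        log.warning("mask %s is empty", path.name)
    return mask


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


def mask_volume_ml(mask: BinaryMask) -> float:
    """Physical volume of the mask: true-voxel count x voxel volume, in ml."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0
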