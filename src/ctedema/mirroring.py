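"""Mid-sagittal symmetry plane estimation and contralateral mask mirroring.

Instead of registering to an external straight-head atlas, the head's own
reflective symmetry is estimated directly: the plane maximising the normalized
cross-correlation (NCC) between the volume and its reflection, evaluated over
the intracranial mask, defines the mirroring geometry in patient space.  For
the purpose of sampling homologous contralateral tissue this is equivalent to
atlas-space mirroring, without the atlas.

The plane has 3 degrees of freedom: an offset along its normal plus two tilt
angles (yaw about the superior-inferior axis, roll about the
anterior-posterior axis).  Pitch is excluded — the reflection plane always
contains the superior-inferior/anterior-posterior axis family — which keeps
the search well-conditioned.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .errors import OutOfFieldError, SymmetryFailureError
from .intracranial import IntracranialMask
from .volume_io import BinaryMask, CTVolume

log = logging.getLogger(__name__)


@dataclass
class SymmetryPlane:
    """A reflection plane in world mm: ``{x : normal . (x - point) = 0}``."""

    point: np.ndarray
    normal: np.ndarray
    fit_score: float = float("nan")

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal must be nonzero")
        self.normal = n / nn

    def reflect(self, xyz: np.ndarray) -> np.ndarray:
        """Reflect (N, 3) world points across the plane (involutive isometry)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        d = (xyz - self.point) @ self.normal
        return xyz - 2.0 * d[:, None] * self.normal

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "point": self.point.tolist(),
            "normal": self.normal.tolist(),
            "fit_score": self.fit_score,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SymmetryPlane":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["point"]), np.array(d["normal"]),
                   float(d.get("fit_score", float("nan"))))


@dataclass
class SymmetrySearch:
    """Optimizer settings for the symmetry-plane search."""

    max_points: int = 15000       #: subsample of mask voxels used in the objective
    offset_bound_mm: float = 25.0
    angle_bound_deg: float = 15.0
    xtol: float = 1e-4
    score_floor: float = 0.2      #: below this NCC with no improvement -> failure
    #: HU clip window for the objective: suppresses bone/air so that partial
    #: volume blending at the inner skull cannot dominate the correlation
    clip_low: float = 0.0
    clip_high: float = 100.0
    #: Gaussian pre-smoothing (voxels) of the clipped volume; suppresses the
    #: voxelization staircase that otherwise locks the plane to the grid
    smooth_sigma_vox: float = 1.0


def _normal_from_angles(yaw: float, roll: float) -> np.ndarray:
    """Unit normal tilted from the world left-right (+x) axis.

    yaw rotates within the axial plane (about z), roll within the coronal plane
    (about y); both in radians.
    """
    cy, sy = np.cos(yaw), np.sin(yaw)
    cr, sr = np.cos(roll), np.sin(roll)
    return np.array([cy * cr, sy * cr, sr])


def estimate_symmetry(volume: CTVolume, intracranial: IntracranialMask,
                      search: SymmetrySearch | None = None,
                      exclude: BinaryMask | None = None) -> SymmetryPlane:
    """Estimate the mid-sagittal reflection plane of a head NCCT.

    The objective is the NCC between the HU values at intracranial voxels and
    the trilinearly-sampled HU values at their reflections; it is maximised
    with Powell's method over (offset, yaw, roll) from an initial guess at the
    mask centroid with normal along the world left-right axis.  Deterministic
    given settings.

    ``exclude`` (typically the lesion mask) removes known-asymmetric
    pathology from the sampled points so it cannot tug the plane towards
    itself.

    Raises :class:`SymmetryFailureError` when the optimizer cannot improve on
    the initial guess and the fit score is below ``search.score_floor``
    (manual plane input is then required).
    """
    s = search or SymmetrySearch()
    sel = intracranial.mask.data
    if exclude is not None:
        sel = sel & ~exclude.data
    idx = np.argwhere(sel)
    if idx.shape[0] == 0:
        raise SymmetryFailureError("empty intracranial mask")
    stride = max(1, idx.shape[0] // s.max_points)
    idx = idx[::stride]
    pts = volume.voxel_to_world(idx)
    clipped = np.clip(volume.data, s.clip_low, s.clip_high).astype(np.float64)
    if s.smooth_sigma_vox > 0:
        clipped = ndimage.gaussian_filter(clipped, s.smooth_sigma_vox)
    vals = clipped[tuple(idx.T)]
    centroid = pts.mean(axis=0)

    raw_std = volume.data[tuple(idx.T)].std()
    if raw_std < 1e-9:
        warnings.warn("degenerate symmetry: uniform intensities, returning "
                      "initial-guess plane", stacklevel=2)
        return SymmetryPlane(centroid, np.array([1.0, 0.0, 0.0]), fit_score=1.0)

    inv3 = np.linalg.inv(volume.affine[:3, :3])
    t3 = volume.affine[:3, 3]
    vc = vals - vals.mean()
    v_norm = np.linalg.norm(vc)

    def neg_ncc(params: np.ndarray) -> float:
        off, yaw_deg, roll_deg = params
        n = _normal_from_angles(np.deg2rad(yaw_deg), np.deg2rad(roll_deg))
        p0 = centroid + off * n
        d = (pts - p0) @ n
        refl = pts - 2.0 * d[:, None] * n
        ijk = (refl - t3) @ inv3.T
        samp = ndimage.map_coordinates(clipped, ijk.T, order=1,
                                       mode="constant", cval=s.clip_low)
        sc = samp - samp.mean()
        s_norm = np.linalg.norm(sc)
        if s_norm < 1e-12:
            return 0.0
        return -float(vc @ sc / (v_norm * s_norm))

    x0 = np.zeros(3)
    f0 = neg_ncc(x0)
    bounds = [(-s.offset_bound_mm, s.offset_bound_mm),
              (-s.angle_bound_deg, s.angle_bound_deg),
              (-s.angle_bound_deg, s.angle_bound_deg)]
    res = optimize.minimize(neg_ncc, x0, method="Powell", bounds=bounds,
                            options={"xtol": s.xtol, "ftol": 1e-10,
                                     "maxiter": 200})
    if res.fun >= f0 - 1e-12:
        # no improvement over the initial guess
        if -f0 < s.score_floor:
            raise SymmetryFailureError(
                f"symmetry search failed (NCC={-f0:.3f} < floor "
                f"{s.score_floor}); supply a manual plane"
            )
        if not np.allclose(res.x, x0):
            warnings.warn("degenerate symmetry: objective flat, returning "
                          "initial-guess plane", stacklevel=2)
        best, score = x0, -f0
    else:
        best, score = res.x, -res.fun
    n = _normal_from_angles(np.deg2rad(best[1]), np.deg2rad(best[2]))
    plane = SymmetryPlane(centroid + best[0] * n, n, fit_score=float(score))
    log.info("symmetry plane: offset=%.3f mm yaw=%.3f deg roll=%.3f deg "
             "NCC=%.5f", best[0], best[1], best[2], score)
    return plane


def mirror_mask(mask: BinaryMask, plane: SymmetryPlane) -> BinaryMask:
    """Mirror a binary mask across the symmetry plane, on its own grid.

    Implemented as a pull-resampling: every grid voxel takes the value of the
    mask at the reflection of its centre (nearest neighbour, preserving
    binarity and avoiding holes).  For a plane lying exactly between grid
    columns the result is the exact voxel-for-voxel reflection and the
    operation is an involution.

    Raises :class:`OutOfFieldError` when >= 10% of the mask's voxels reflect
    outside the volume bounds (an implausible plane).
    """
    shape = mask.shape
    inv3 = np.linalg.inv(mask.affine[:3, :3])
    t3 = mask.affine[:3, 3]

    src = np.argwhere(mask.data)
    if src.shape[0] > 0:
        world = src @ mask.affine[:3, :3].T + t3
        refl = plane.reflect(world)
        ijk = (refl - t3) @ inv3.T
        outside = np.any((ijk < -0.5) | (ijk > np.array(shape) - 0.5), axis=1)
        frac = outside.mean()
        if frac >= 0.10:
            raise OutOfFieldError(
                f"{frac:.0%} of mirrored voxels fall outside the field of view"
            )

    ii, jj, kk = np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                             indexing="ij")
    grid = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = grid @ mask.affine[:3, :3].T + t3
    refl = plane.reflect(world)
    ijk = (refl - t3) @ inv3.T
    samp = ndimage.map_coordinates(mask.data.astype(np.uint8), ijk.T, order=0,
                                   mode="constant", cval=0)
    return BinaryMask(samp.reshape(shape).astype(bool), mask.affine)
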