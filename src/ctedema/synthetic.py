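"""Synthetic head phantoms and synthetic stroke cohorts with known ground truth.

The phantom is an analytic ellipsoid head evaluated at voxel centres in world
mm: scalp soft tissue, skull shell, brain parenchyma, symmetric CSF
ventricles, an ellipsoidal ischemic lesion whose density is reduced
multiplicatively by a known water-uptake fraction w — the exact relationship
the NWU formula inverts, so noise-free recovery is exact and any residual
error in tests isolates mirroring/filter effects — and an optional hyperdense
hemorrhagic inclusion.  Rigid head tilt is applied by evaluating the anatomy
in a rotated frame, so a tilted phantom is genuinely off-grid.

The cohort generator draws per-patient lesion metrics at 24 h and 1 week
(satisfying the TILV = EV + ecIV + HV identity by construction), covariates,
a recanalization subgroup that shifts edema progression, and a logistic
90-day outcome, and returns its parameter record alongside the data as the
recovery oracle.  All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import SpecError
from .mirroring import SymmetryPlane
from .volume_io import BinaryMask, CTVolume, LesionSet

# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry, densities (HU), pose and noise of a synthetic head CT."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # ellipsoid semi-axes in mm, centred at world origin
    scalp_semiaxes: tuple[float, float, float] = (53.0, 61.0, 51.0)
    skull_semiaxes: tuple[float, float, float] = (50.0, 58.0, 48.0)
    skull_thickness_mm: float = 4.0
    scalp_hu: float = 40.0
    skull_hu: float = 1000.0
    brain_hu: float = 35.0
    csf_hu: float = 5.0
    ventricle_centers: tuple = ((-8.0, -8.0, 0.0), (8.0, -8.0, 0.0))
    ventricle_semiaxes: tuple[float, float, float] = (5.0, 12.0, 7.0)
    lesion_center: tuple[float, float, float] = (-27.0, 12.0, 4.0)
    lesion_semiaxes: tuple[float, float, float] = (13.0, 15.0, 11.0)
    water_uptake: float = 0.2      #: w in [0, 0.6]
    hemorrhage: bool = False
    hemorrhage_center: Optional[tuple[float, float, float]] = None
    hemorrhage_semiaxes: tuple[float, float, float] = (5.0, 6.0, 5.0)
    hemorrhage_hu: float = 65.0    #: inside the 20-80 window: mask-based exclusion is exercised
    tilt_yaw_deg: float = 0.0      #: rotation about the superior-inferior axis
    tilt_roll_deg: float = 0.0     #: rotation about the anterior-posterior axis
    noise_sigma: float = 0.0
    midline_crossing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.water_uptake <= 0.6):
            raise SpecError(f"water_uptake {self.water_uptake} outside [0, 0.6]")


@dataclass
class PhantomTruth:
    """Generator-side ground truth: the oracle for every pipeline stage."""

    plane: SymmetryPlane
    interior: BinaryMask          #: brain + CSF + lesion (inside inner skull)
    lesion: BinaryMask
    hemorrhage: Optional[BinaryMask]
    water_uptake: float
    expected_nwu: float
    brain_hu: float


def _rotation(yaw_deg: float, roll_deg: float) -> np.ndarray:
    """Rigid head pose: roll about y after yaw about z."""
    a, b = np.deg2rad(yaw_deg), np.deg2rad(roll_deg)
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0],
                   [0, 0, 1.0]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1.0, 0],
                   [-np.sin(b), 0, np.cos(b)]])
    return ry @ rz


def _inside(u: np.ndarray, center, semiaxes) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    s = np.asarray(semiaxes, dtype=float)
    return np.sum(((u - c) / s) ** 2, axis=-1) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LesionSet, PhantomTruth]:
    """Build a head phantom; deterministic given ``spec`` (incl. its seed)."""
    shape = np.array(spec.shape)
    spacing = np.array(spec.spacing, dtype=float)
    # grid centred on the world origin; +x is the patient's right
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(shape - 1) / 2.0 * spacing

    ii, jj, kk = np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                             indexing="ij")
    world = (np.stack([ii, jj, kk], axis=-1) * spacing
             + affine[:3, 3])                       # (X, Y, Z, 3)
    rot = _rotation(spec.tilt_yaw_deg, spec.tilt_roll_deg)
    u = world @ rot                                  # anatomy frame = rot^T @ world

    inner = np.asarray(spec.skull_semiaxes) - spec.skull_thickness_mm
    in_scalp = _inside(u, (0, 0, 0), spec.scalp_semiaxes)
    in_skull = _inside(u, (0, 0, 0), spec.skull_semiaxes)
    in_brain = _inside(u, (0, 0, 0), inner)

    vol = np.full(tuple(shape), -1000.0)
    vol[in_scalp] = spec.scalp_hu
    vol[in_skull] = spec.skull_hu
    vol[in_brain] = spec.brain_hu
    for c in spec.ventricle_centers:
        vol[_inside(u, c, spec.ventricle_semiaxes) & in_brain] = spec.csf_hu

    lesion = _inside(u, spec.lesion_center, spec.lesion_semiaxes)
    if not np.all(in_brain[lesion]):
        raise SpecError("lesion extends outside the skull interior")
    if not spec.midline_crossing:
        side = -1.0 if spec.lesion_center[0] < 0 else 1.0
        if np.any(side * u[..., 0][lesion] <= 0):
            raise SpecError("lesion crosses the midline but midline_crossing "
                            "is not set")
    vol[lesion] = (1.0 - spec.water_uptake) * spec.brain_hu

    hem_mask = None
    if spec.hemorrhage:
        hc = spec.hemorrhage_center or spec.lesion_center
        hem = _inside(u, hc, spec.hemorrhage_semiaxes)
        if not np.all(lesion[hem]):
            raise SpecError("hemorrhage extends outside the lesion")
        vol[hem] = spec.hemorrhage_hu
        hem_mask = BinaryMask(hem, affine)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)

    ct = CTVolume(vol, affine, scan_id=f"phantom-{spec.seed}", timepoint="24h")
    side = "left" if spec.lesion_center[0] < 0 else "right"
    lesions = LesionSet(BinaryMask(lesion, affine), hem_mask, side)
    # the anatomy's mirror plane is x=0 in the anatomy frame, rotated into world
    truth = PhantomTruth(
        plane=SymmetryPlane(np.zeros(3), rot @ np.array([1.0, 0.0, 0.0])),
        interior=BinaryMask(in_brain, affine),
        lesion=BinaryMask(lesion, affine),
        hemorrhage=hem_mask,
        water_uptake=spec.water_uptake,
        expected_nwu=spec.water_uptake,
        brain_hu=spec.brain_hu,
    )
    return ct, lesions, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Distributional parameters of a synthetic two-timepoint stroke cohort.

    Defaults emulate the marginals of a subacute large-vessel-occlusion
    cohort: log-normal 24-h lesion volume with median 37 ml, normal 24-h NWU
    around 0.22, log-normal edema progression whose median is lower under
    successful recanalization (5.2 vs 8.0 ml), edema-corrected infarct
    progression independent of the 24-h state, and a logistic favorable
    90-day outcome with true odds ratio 0.53 per 10 ml edema progression.
    """

    n_patients: int = 186
    # 24-h state
    tilv_median_ml: float = 37.0
    tilv_sigma_log: float = 1.1
    nwu_mean: float = 0.22
    nwu_sd: float = 0.074
    ht_rate: float = 0.35                 #: fraction with hemorrhagic transformation
    hv_median_ml: float = 1.5
    hv_sigma_log: float = 0.8
    # recanalization subgroup
    p_recanalization: float = 100.0 / 171.0
    exact_split: bool = False             #: force exactly round(n*p) successes
    maol_missing_rate: float = 0.085
    # progression
    d_ev_median_recan_ml: float = 5.2
    d_ev_median_norecan_ml: float = 8.0
    d_ev_sigma_log: float = 1.2
    ev24_dependence: float = 0.5          #: elasticity of d_ev on the 24-h EV
    d_eciv_median_ml: float = 12.0
    d_eciv_sigma_log: float = 1.2
    eciv24_dependence: float = 0.0        #: null by default
    d_hv_rate: float = 0.15
    d_hv_median_ml: float = 1.0
    d_hv_sigma_log: float = 0.7
    # outcome model (log-odds scale; ORs per stated unit)
    true_or_d_ev_per_10ml: float = 0.53
    outcome_term: str = "d_ev"
    favorable_rate: float = 0.40
    beta_tilv24_per_10ml: float = np.log(0.83)
    beta_age_per_year: float = np.log(0.96)
    beta_coumarins: float = -1.0
    beta_sbp_per_mmhg: float = -0.01
    beta_nihss_per_point: float = -0.06
    beta_proximal: float = np.log(0.42)
    beta_collaterals: float = 0.0
    beta_evt: float = np.log(2.29)
    # covariate marginals
    age_mean: float = 66.0
    age_sd: float = 12.0
    nihss_mean: float = 17.0
    sbp_mean: float = 145.0
    sbp_sd: float = 22.0
    p_coumarins: float = 0.08
    p_proximal: float = 0.65
    p_collaterals: tuple = (0.06, 0.30, 0.39, 0.25)
    p_evt: float = 0.49
    mrs_missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise SpecError("n_patients must be >= 2")
        for name in ("tilv_median_ml", "d_ev_median_recan_ml",
                     "d_ev_median_norecan_ml", "d_eciv_median_ml"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.nwu_mean < 1:
            raise SpecError(f"nwu_mean {self.nwu_mean} outside (0, 1)")
        if self.true_or_d_ev_per_10ml <= 0:
            raise SpecError("true odds ratio must be positive")


COHORT_COLUMNS = [
    "id", "tilv_24h", "ev_24h", "eciv_24h", "hv_24h", "nwu_24h",
    "tilv_1week", "ev_1week", "eciv_1week", "hv_1week", "nwu_1week",
    "d_tilv", "d_ev", "d_eciv", "d_hv", "d_nwu",
    "age", "baseline_nihss", "systolic_bp", "coumarins",
    "proximal_occlusion", "collaterals", "evt_allocated", "maol", "mrs_90d",
]


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic cohort; returns (records, parameter record).

    Deterministic given the spec's seed.  Every record satisfies
    TILV = EV + ecIV + HV at both timepoints by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    if spec.exact_split:
        n_yes = int(round(n * spec.p_recanalization))
        recan = np.zeros(n, dtype=bool)
        recan[rng.permutation(n)[:n_yes]] = True
    else:
        recan = rng.random(n) < spec.p_recanalization

    tilv24 = np.exp(rng.normal(np.log(spec.tilv_median_ml), spec.tilv_sigma_log, n))
    nwu24 = np.clip(rng.normal(spec.nwu_mean, spec.nwu_sd, n), 0.01, 0.60)
    ht = rng.random(n) < spec.ht_rate
    hv24 = np.where(
        ht, np.minimum(np.exp(rng.normal(np.log(spec.hv_median_ml),
                                         spec.hv_sigma_log, n)), 0.2 * tilv24),
        0.0)
    ev24 = nwu24 * (tilv24 - hv24)
    eciv24 = tilv24 - ev24 - hv24

    med_dev = np.where(recan, spec.d_ev_median_recan_ml, spec.d_ev_median_norecan_ml)
    rel_ev = ev24 / np.median(ev24)
    d_ev = (med_dev * rel_ev ** spec.ev24_dependence
            * np.exp(rng.normal(0.0, spec.d_ev_sigma_log, n)))
    rel_eciv = eciv24 / np.median(eciv24)
    d_eciv = (spec.d_eciv_median_ml * rel_eciv ** spec.eciv24_dependence
              * np.exp(rng.normal(0.0, spec.d_eciv_sigma_log, n)))
    d_hv = np.where(ht & (rng.random(n) < spec.d_hv_rate),
                    np.exp(rng.normal(np.log(spec.d_hv_median_ml),
                                      spec.d_hv_sigma_log, n)), 0.0)
    d_tilv = d_ev + d_eciv + d_hv

    tilv1w, ev1w = tilv24 + d_tilv, ev24 + d_ev
    hv1w, eciv1w = hv24 + d_hv, eciv24 + d_eciv
    nwu1w = ev1w / (tilv1w - hv1w)

    age = rng.normal(spec.age_mean, spec.age_sd, n)
    nihss = np.clip(rng.poisson(spec.nihss_mean, n), 0, 42)
    sbp = rng.normal(spec.sbp_mean, spec.sbp_sd, n)
    coum = rng.random(n) < spec.p_coumarins
    prox = rng.random(n) < spec.p_proximal
    coll = rng.choice(4, size=n, p=np.asarray(spec.p_collaterals) /
                      np.sum(spec.p_collaterals))
    evt = rng.random(n) < spec.p_evt

    term = {"d_ev": d_ev, "d_eciv": d_eciv}[spec.outcome_term]
    lp = (np.log(spec.true_or_d_ev_per_10ml) * term / 10.0
          + spec.beta_tilv24_per_10ml * (tilv24 - spec.tilv_median_ml) / 10.0
          + spec.beta_age_per_year * (age - spec.age_mean)
          + spec.beta_coumarins * coum
          + spec.beta_sbp_per_mmhg * (sbp - spec.sbp_mean)
          + spec.beta_nihss_per_point * (nihss - spec.nihss_mean)
          + spec.beta_proximal * prox
          + spec.beta_collaterals * (coll - 2)
          + spec.beta_evt * evt)
    # intercept calibrated so the realized favorable rate matches the spec
    alpha = brentq(lambda a: expit(lp + a).mean() - spec.favorable_rate, -40, 40)
    favorable = rng.random(n) < expit(lp + alpha)
    mrs = np.where(favorable, rng.integers(0, 3, n), rng.integers(3, 7, n))

    maol = np.where(recan, 3, rng.integers(0, 3, n)).astype(float)
    maol[rng.random(n) < spec.maol_missing_rate] = np.nan
    mrs = mrs.astype(float)
    mrs[rng.random(n) < spec.mrs_missing_rate] = np.nan

    df = pd.DataFrame({
        "id": [f"pt{i:04d}" for i in range(n)],
        "tilv_24h": tilv24, "ev_24h": ev24, "eciv_24h": eciv24,
        "hv_24h": hv24, "nwu_24h": nwu24,
        "tilv_1week": tilv1w, "ev_1week": ev1w, "eciv_1week": eciv1w,
        "hv_1week": hv1w, "nwu_1week": nwu1w,
        "d_tilv": d_tilv, "d_ev": d_ev, "d_eciv": d_eciv, "d_hv": d_hv,
        "d_nwu": nwu1w - nwu24,
        "age": age, "baseline_nihss": nihss, "systolic_bp": sbp,
        "coumarins": coum.astype(int), "proximal_occlusion": prox.astype(int),
        "collaterals": coll, "evt_allocated": evt.astype(int),
        "maol": maol, "mrs_90d": mrs,
    })
    truth = asdict(spec)
    truth["alpha"] = float(alpha)
    truth["latent_recanalization"] = recan.tolist()
    return df, truth
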