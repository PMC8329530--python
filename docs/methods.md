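# Methods

## The density model behind net water uptake

Vasogenic edema dilutes tissue: a voxel whose healthy density is D acquires
density (1 − w)·D when a water fraction w replaces tissue volume. Net water
uptake inverts this relationship using the patient's own contralateral
hemisphere as the healthy reference:

    NWU = (D_normal − D_ischemic) / D_normal

D_ischemic is the mean HU over the non-hemorrhagic lesion; D_normal is the
mean HU over the lesion's mirror image in the opposite hemisphere. Multiplied
by the non-hemorrhagic lesion volume, NWU yields the edema volume EV; the
remainder TILV − EV − HV is the edema-corrected infarct volume ecIV. The
decomposition is exact by construction (TILV = EV + ecIV + HV to numerical
precision), which the test suite asserts on every measured scan and every
synthetic record.

Assumptions worth stating explicitly:

* Homologous contralateral tissue is a valid density reference — violated by
  bilateral pathology or prior contralateral infarcts, which are not modelled.
* Edema is the only cause of hypodensity within the lesion; chronic changes,
  leukoaraiosis and partial-volume CSF all masquerade as water uptake.
* NWU captures density-visible (vasogenic) water; cytotoxic water shifts do
  not change density and remain inside ecIV.

## Mirroring without an atlas

Classical implementations register the head to a straight, centered atlas and
flip the lesion across the volume midline. Functionally that defines a
reflection across the head's mid-sagittal plane expressed in patient space,
so this package estimates that plane directly: the reflection maximizing the
normalized cross-correlation (NCC) between the volume and its reflection over
the intracranial mask. The two approaches sample the same homologous tissue;
the direct estimate removes the atlas and registration dependencies. The
equivalence is exercised on phantoms whose true plane is known analytically.

The plane has 3 degrees of freedom — offset along its normal, yaw, roll —
with pitch excluded since a mid-sagittal plane contains the
superior–inferior axis family. The search starts at the intracranial
centroid with the normal along the world left–right axis and uses Powell's
method (bounded: ±25 mm, ±15°), which is derivative-free and deterministic.

Two numerical details matter:

* **Brain windowing.** The objective samples a copy of the volume clipped to
  [0, 100] HU. Without clipping, trilinear samples near the inner skull blend
  with ~1000 HU bone; these outliers dominate the correlation and swamp the
  soft-tissue signal.
* **Pre-smoothing.** The clipped volume is Gaussian-smoothed (σ = 1 voxel)
  before sampling. The voxelized boundary of any discrete mask is a staircase
  aligned with the grid, and an unsmoothed NCC is measurably biased toward
  grid-aligned planes (~2° at 5° head tilt on phantoms); smoothing removes
  the staircase and restores sub-degree accuracy. Smoothing is used only
  inside the plane search — density statistics always read the raw volume.
* **Lesion exclusion.** The lesion mask is removed from the sampled points
  (`exclude=`): a strongly hypodense lesion is an asymmetric signal that
  otherwise tugs the plane toward configurations that hide it, worth ~0.5°
  at high water uptake on noisy tilted phantoms.

Degenerate inputs (uniform intensity in the mask, or an objective flat in the
plane parameters) return the initial-guess plane with a warning rather than
an arbitrary optimum; a failed search with a fit score below a configurable
floor (default NCC 0.2) raises and asks for a manual plane, which can be
supplied as JSON (`--plane`) for heavily asymmetric pathology.

Masks are mirrored by pull-resampling with nearest-neighbour interpolation:
every grid voxel takes the mask value at the reflection of its centre. This
preserves binarity, cannot create holes, and is an exact involution for
planes lying midway between grid columns. For off-grid planes the mirrored
voxel count differs from the original by < 5% for masks of ≥ 100 voxels
(property-tested).

## The density filter

The 20–80 HU window (inclusive — HU are integer-valued in practice, so
boundary voxels are common) excludes CSF and calcifications. It is applied
to the mirrored, contralateral ROI. Applying it to the ipsilateral lesion as
well is available (`filter_ipsilateral=True`) but is **off** by default, for
a quantitative reason: the filter truncates the lesion's own density
distribution. With parenchyma at 35 HU, a lesion at water uptake w = 0.35
sits at 22.75 HU; under σ = 3 HU noise, discarding lesion voxels below 20 HU
biases the ipsilateral mean by ≈ +0.96 HU and hence NWU by ≈ −0.027 —
larger than the pipeline's entire remaining error budget — and at w > 0.43
the whole lesion falls below the window. The contralateral reference (≈ 35
HU) is far from both bounds, so filtering it costs nothing and removes
mirrored CSF/bone as intended. Hemorrhage never reaches the density ROI
regardless of the filter: the sub-mask is removed from the lesion before
mirroring (tested with a 65 HU bleed *inside* the window).

Midline-crossing lesions: mirrored voxels falling inside the lesion itself
are excluded from the reference and counted (`n_excluded_overlap`), with a
warning above 20% overlap. Negative NWU is propagated with a warning, never
clipped, since real follow-up cohorts contain scans whose lesion is denser
than its mirror.

## Intracranial segmentation

Candidate tissue is thresholded to [−200, 100] HU, opened (radius 1 voxel)
to break skull–scalp bridges, reduced to the largest connected component,
closed and hole-filled; components below a minimum plausible volume (default
200 ml, configurable for small phantoms) raise a segmentation failure. The
mask conditions the symmetry search and QC only — NWU itself uses the lesion
and mirrored-lesion ROIs, so modest segmentation error does not propagate.

## Synthetic data

**Phantoms** are analytic ellipsoid heads (scalp 40 HU, skull 1000 HU, brain
35 HU, symmetric 5 HU ventricles) evaluated at voxel centres in world mm. The
lesion multiplies local tissue density by (1 − w) — exactly the relationship
NWU inverts, so noise-free recovery is exact to machine precision and any
residual test error isolates mirroring/filter effects. Head tilt is applied
by evaluating the anatomy in a rotated frame (genuinely off-grid, not an
affine relabeling); noise is additive Gaussian. The default hemorrhage is 65
HU — inside the density window — so tests exercise mask-based exclusion, the
stricter path; a > 80 HU variant exercises the filter path. The generator
returns its symmetry plane, interior/lesion/hemorrhage masks and w as the
oracle for every stage. What phantoms do **not** model: beam hardening,
scatter, partial-volume gradients at tissue interfaces, anatomical texture —
so passing recovery tests demonstrates correctness of the geometry and
estimators, not robustness to scanner physics.

**Cohorts** draw per-patient records satisfying the decomposition identity
at both timepoints by construction. Defaults: 186 patients; 24-h lesion
volume log-normal with median 37 ml (σ_log 1.1, matching a subacute
large-vessel-occlusion population's wide IQR); 24-h NWU normal (0.22 ±
0.074, clipped to (0.01, 0.6)); hemorrhagic transformation in 35% with small
log-normal volumes capped at 20% of TILV. Edema progression is log-normal
with median 8.0 ml without vs 5.2 ml with successful recanalization (mAOL
3; prevalence 100/171), coupled to 24-h EV with elasticity 0.5;
edema-corrected infarct progression (median 12 ml) is independent of the
24-h state by default — both dependencies configurable. The favorable
90-day outcome (mRS 0–2, rate 0.40) is logistic with a true odds ratio of
0.53 per 10 ml edema progression plus plausible confounder effects; the
intercept is calibrated by root-finding so the realized outcome rate matches
the specification. Progression components are non-negative by default, so
occasional real-world negative NWU progression is not emulated. All
randomness flows from a single seed; the parameter record is returned
alongside the data as the recovery oracle.

## Statistical conventions

* Wilcoxon signed-rank: zeros dropped and counted; exact, tie-tolerant null
  (midrank characteristic-polynomial convolution) for ≤ 25 nonzero pairs,
  tie-corrected normal approximation beyond. Verified against full 2ⁿ
  enumeration to 1e−12.
* Mann–Whitney U: exact for min group size ≤ 8 without ties, tie-corrected
  normal approximation (with continuity correction) otherwise; verified
  against C(n, n_a) enumeration. The approximation's null rejection rate at
  α = 0.05 measures ≈ 4.8% at group sizes 71/100.
* Two-sided p-values are 2·min(lower, upper tail), capped at 1.
* Odds-ratio CIs are Wald intervals on the log-odds scale; logistic fits use
  Newton iterations to tolerance 1e−10, so a single binary predictor's OR
  reproduces the contingency cross-product ratio to ~1e−10. Separation is
  detected (fitted probabilities at 0/1 with diverging coefficients) and
  raised, not silently reported.
* Complete-case analysis per model; each analysis reports its n. The 24-h
  lesion volume stays in the outcome model alongside progression despite
  their collinearity (both are of substantive interest); an ill-conditioned
  design triggers a warning, not an error.
* Significance is two-sided p ≤ 0.05 with no multiplicity correction, by
  design of the analysis plan being reproduced.

## Problem sizes in the test suite

Phantom tests run at 64³ voxels, 2 mm spacing (≈ 0.6 L intracranial volume),
which keeps the full 30-condition recovery grid under a minute while leaving
> 1000 lesion voxels for stable density means. Cohort property tests use
n = 2000 records; the marginal-convergence check of the wide log-normal
volume distribution uses n = 20000 so that the sample median's ~1% sampling
error sits well inside its 5% tolerance. CI-coverage and type-I-error
simulations use 100 and 400 replicates respectively.

## Known limitations

* The symmetry estimate assumes an approximately rigid, reflectively
  symmetric head; severe midline shift can bias the plane toward the shifted
  midline (a manual plane is the escape hatch).
* Pitch is not estimated; heads acquired with strong pitch relative to the
  scanner axis violate the 3-DOF parameterization.
* DICOM ingestion, HU calibration auditing, lesion/hemorrhage segmentation
  and midline-shift measurement are out of scope; masks are inputs.
* Phantom realism is deliberately minimal (see above); clinical validation
  of the pipeline cannot be inferred from synthetic recovery alone.
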