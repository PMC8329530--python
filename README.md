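# ctedema

Quantification of cerebral edema inside ischemic stroke lesions on
non-contrast head CT (NCCT), and the cohort statistics built on it.

After a large-vessel-occlusion stroke, the visible lesion on follow-up NCCT
grows through two distinct processes: accumulation of water (vasogenic edema,
which lowers CT density) and growth of the infarct itself. Separating the two
matters because they respond differently to recanalization and carry
different prognostic weight. `ctedema` implements the densitometric
decomposition of a delineated lesion into edema, edema-corrected infarct, and
hemorrhage volumes, using the patient's own contralateral hemisphere as the
density reference, plus the statistical analysis plan typically applied to
such measurements in two-timepoint (24 h / 1 week) cohorts.

## Method

For one scan with lesion mask *L* (and optional hemorrhage sub-mask *H*):

1. The intracranial region is extracted by HU thresholding and morphology.
2. The head's mid-sagittal reflection plane is estimated by maximizing the
   normalized cross-correlation between the (brain-windowed) volume and its
   reflection over the intracranial mask — no atlas registration required.
3. The non-hemorrhagic lesion *L \ H* is mirrored across that plane;
   contralateral voxels overlapping the lesion itself are excluded, and the
   mirrored reference is restricted to 20–80 HU to exclude CSF and
   calcifications.
4. With mean densities D_ischemic (lesion) and D_normal (mirrored reference):

   ```
   NWU  = (D_normal − D_ischemic) / D_normal        net water uptake
   TILV = volume(L)                                 total ischemic lesion volume
   HV   = volume(H)                                 hemorrhage volume
   EV   = NWU × (TILV − HV)                         edema volume
   ecIV = TILV − EV − HV                            edema-corrected infarct volume
   ```

   so TILV = EV + ecIV + HV holds identically. Progression of any metric is
   its 1-week value minus its 24-h value.

Cohort-level routines provide Wilcoxon signed-rank (24 h vs 1 week) and
Mann–Whitney U (recanalization subgroups) tests with exact small-sample
branches, univariable linear regressions of progression on 24-h lesion
characteristics, and logistic models of favorable 90-day outcome (mRS 0–2)
per 10 ml of progression with Wald odds-ratio CIs and AIC comparison.

Because clinical NCCT datasets of this kind are not publicly shareable, the
package ships a first-class synthetic-data module: analytic head phantoms
whose lesion density is reduced by a known water-uptake fraction (the exact
relationship the NWU formula inverts), and synthetic cohorts with known
distributional parameters and outcome odds ratios, so every pipeline stage is
testable against ground truth.

## Worked example

Simulate a noisy phantom with 25% water uptake and measure it:

```bash
ctedema simulate phantom --seed 7 --water-uptake 0.25 --noise-sigma 2 --out phantom
ctedema measure phantom/volume.nii.gz phantom/lesion.nii.gz --out measured --no-qc
```

prints

```json
{"id": "volume", "timepoint": "24h", "tilv_ml": 8.927999999999999, "hv_ml": 0.0,
 "nwu": 0.25029860661155945, "ev_ml": 2.2346659598280025,
 "eciv_ml": 6.6933340401719965, "n_ipsi": 1116, "n_contra": 1116,
 "n_excluded_overlap": 0}
```

The 8.9 ml lesion's net water uptake is recovered as 0.2503 against the
constructed 0.25 (the residual 0.0003 is the noise's effect on the two ROI
means); edema accounts for 2.23 ml of the lesion and the edema-corrected
infarct for 6.69 ml, summing exactly to TILV.

A synthetic cohort run:

```bash
ctedema simulate cohort --seed 7 --n 186 --out sim
ctedema cohort sim/cohort.csv --out results
```

writes Table-shaped CSVs (`summary.csv`, `paired_tests.csv`,
`subgroup_tests.csv`, `regressions.csv`, `outcome_models.csv`) plus a
`results.json` bundle embedding the exact configuration. For instance
`paired_tests.csv` starts

```
variable,median_24h,median_1week,median_progression,p_value,n
tilv,36.74,74.11,22.71,2.8e-32,186
ev,7.29,15.98,5.76,2.8e-32,186
```

(medians in ml; lesion and edema volumes grow significantly over the first
week), and `outcome_models.csv` reports an adjusted odds ratio of 0.65
(95% CI 0.46–0.92) per 10 ml of edema progression for favorable outcome in
this draw (generated with a true OR of 0.53 plus confounder effects).

As a library, the same pipeline is three calls:

```python
from ctedema import (PhantomSpec, generate_phantom, segment_intracranial,
                     estimate_symmetry, compute_lesion_metrics)

vol, lesions, truth = generate_phantom(PhantomSpec(water_uptake=0.2))
plane = estimate_symmetry(vol, segment_intracranial(vol),
                          exclude=lesions.lesion)
metrics = compute_lesion_metrics(vol, lesions, plane)   # metrics.nwu == 0.2
```

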