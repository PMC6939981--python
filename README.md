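# tiltcal

Estimating **anterior pelvic plane tilt (APPt)** from a single
anteroposterior (AP) pelvic radiograph.

AP pelvic films remain the standard pre- and postoperative imaging for
total hip arthroplasty, but an undetected pelvic tilt distorts every
measurement taken from them — most importantly acetabular cup anteversion.
`tiltcal` implements, and lets you stress-test end to end, a tilt-correction
method built entirely on landmarks that are reliably visible on AP films:

1. **Simulate** AP radiographic projections of a 3D pelvis at a known,
   exactly controlled APPt (parallel-beam or point-source perspective
   geometry with realistic magnification). A parametric, gender-dimorphic
   landmark model with seeded inter-subject variation stands in for
   segmented CT anatomy, so no imaging data is required.
2. **Measure** eight candidate tilt-sensitive distances on each synthetic
   film — PSTI, PSSI, OFH, OFR, TISI, PSTA, TITA, SITA — plus the pelvic
   outlet distance (POD) used as a scaling denominator, with an optional
   triplicate manual-measurement noise model.
3. **Calibrate** a per-sex *nomogram*: a least-squares fit of true tilt on
   the scale-free ratio PSTI/POD over a sweep of −30°…+30° in 5° steps
   (13 orientations per pelvis, 260 pooled images for a 20-pelvis cohort),

   &nbsp;&nbsp;&nbsp;&nbsp;APPt ≈ f(PSTI / POD),&nbsp;&nbsp; f linear or (monotone) quadratic,

   where PSTI is the vertical distance from the transischial line to the
   superior pubic-symphysis margin and POD the longest horizontal outlet
   distance parallel to the transischial line. Dividing by POD removes
   radiographic magnification, so the nomogram transfers across imaging
   geometries.
4. **Validate**: fresh random-tilt images, tilt estimated by inverting the
   nomogram, and a full agreement-statistics suite — Pearson r, ICC(2,1),
   Student's t-test, single-factor ANOVA, mean (sd) differences, % of
   errors under 5°, direction accuracy — with subgrouping by sex and by
   exclusion of the calibration orientations.

The calibration core follows the statsmodels model/results convention:
`NomogramModel(...).fit()` returns a `NomogramResults` with coefficients,
diagnostics, `summary()`, `predict()`, `estimate_tilt()` and a diagnostic
`plot()`.

## Worked example

```python
from tiltcal import (generate_cohort, build_calibration_table, fit_nomogram,
                     synthesize_image, measure_parameters, ProjectionGeometry)

cohort = generate_cohort(5, 5, seed=1)            # 5 male + 5 female pelvises
table = build_calibration_table(cohort)           # 13-tilt sweep, 130 rows
nom = fit_nomogram(table, "female", form="quadratic")
print(nom.summary())

lm = [s for s in cohort if s.sex == "female"][0]  # truth: +12 deg of tilt
img = synthesize_image(lm, 12.0, ProjectionGeometry())
ps = measure_parameters(img)
print(f"PSTI = {ps.psti:.1f} mm, POD = {ps.pod:.1f} mm")
est = nom.estimate_tilt(ps.psti, ps.pod)
print(f"estimated APPt = {est.appt_deg:+.2f} deg (extrapolated: {est.extrapolated})")
```

prints

```
PSTI/POD tilt nomogram
============================================
sex:              female
form:             quadratic
n images:         65
coefficients:     -17.0148, -72.2161, 21.3507  (highest degree first)
ratio range:      [-0.1518, 0.6318]
tilt range (deg): [-30, 30]
Pearson r:        -0.9953
residual sd:      1.666 deg

PSTI = 21.4 mm, POD = 150.3 mm
estimated APPt = +10.71 deg (extrapolated: False)
```

The strong negative r confirms that PSTI/POD falls as the pelvis tilts
anteriorly; the 65-image female calibration recovers a fresh +12° film to
within ~1.3°, and the estimate is flagged if the measured ratio ever leaves
the calibrated range (no silent clamping).

## Command line

```bash
tiltcal generate  --out cohort/                 # landmark files + manifest
tiltcal calibrate --out cal/                    # table, screening, nomograms
tiltcal estimate  --nomogram cal/nomogram_female.json \
                  --measurements films.csv --out estimates.csv
tiltcal validate  --out val/ --noise-sd 0       # round-trip agreement report
```

All stages are seeded through a JSON/YAML `RunConfig`; identical
configurations reproduce identical outputs byte for byte.

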