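# Methods

## Problem and coordinate conventions

Pelvic tilt is defined as the angle of the anterior pelvic plane (APP — the
plane through both anterior superior iliac spines and the anterior border
of the pubic symphysis) relative to the vertical; APPt = 0° means the APP
is vertical, and positive (anterior) tilt moves the ASIS anteriorly
relative to the symphysis. The world frame is x = patient left (+),
y = anterior (+), z = superior (+), all lengths in mm. On the detector,
u is horizontal (toward patient left) and v vertical (superior +).

Tilt is applied as a rigid rotation about the mediolateral (x) axis through
the centroid of the three APP landmarks. The pivot choice is irrelevant to
distances under parallel projection and perturbs perspective magnification
only at second order; it is configurable in principle but fixed here for
reproducibility.

## Parametric anatomy

The package replaces segmented CT anatomy with one hand-placed landmark
template per sex, in canonical pose (APPt = 0 to 1e−9°). The templates
encode the gross sexual dimorphism that matters to the method: the female
pelvis is wider (ASIS span 258 vs 228 mm, pelvic outlet 140 vs 124 mm,
broader obturator foramina) and proportionally slightly deeper. Template
proportions were designed against the forward model's qualitative
requirements — a positive PSTI at neutral pose, a near-linear and strongly
monotone PSTI/POD–tilt relation over ±30°, the expected association signs
of all eight candidate parameters, and round-trip recoverability — not fit
to any dataset; absolute parameter values in mm are therefore fixture
properties, and only signs, monotonicity and recovery behavior are
meaningful.

Each obturator foramen is a planar ellipse rim sampled at 24 points. The
rim plane contains the mediolateral axis and an oblique 45° axis running
anteroinferior–posterosuperior, so the *projected* foramen height grows as
the pelvis tilts anteriorly (approaching edge-on at −30°, where manual
measurement of foramen height is hardest in practice) while the projected
width is nearly constant. Dense rim sampling matters because the
height/width extremes travel along the rim as tilt changes.

Subject generation draws one global isotropic scale factor
(N(1, scale_sd), truncated to [0.8, 1.2]; default scale_sd = 0.05) and
independent per-landmark Gaussian shape perturbations (default
sd = 1.5 mm), *mirrored* across the midsagittal plane. Mirroring is
deliberate: the measurement model assumes no pelvic obliquity or axial
rotation, and asymmetric noise would alias obliquity into tilt. Because
mirrored noise keeps the inter-ASIS axis parallel to x, a single rotation
about x restores the canonical pose exactly after perturbation; every
generated subject therefore satisfies APPt = 0 at machine precision.
Defaults produce POD values of roughly 115–180 mm across subjects,
consistent with adult AP films.

## Projection model

Two beam geometries are provided, because the imaging simulator being
emulated does not document its geometry:

- **parallel**: (u, v) = (x, z) exactly; POD is then *exactly*
  tilt-invariant (rotation about x never changes u).
- **perspective** (default): central projection from a point source on the
  +y axis onto a detector plane behind the patient; defaults
  source–image distance 1000 mm, object–image distance 150 mm, typical of
  AP pelvis radiography. A point in the rotation-center plane magnifies by
  SID/(SID − OID) = 1.18; structures at different depths magnify
  differently, which is the realistic distortion the POD normalization has
  to absorb.

Perspective converges to parallel as SID → ∞ at fixed OID (residual
∝ (OID − y)/SID, i.e. ≈ 0.03 mm at SID = 10⁶ mm for this anatomy and
< 0.01 mm by 10⁸ mm). The acceptance experiments run under the default
perspective geometry; the test suite exercises the round trip under both.

## Measurement model

All reference lines are straight lines through landmark pairs (transischial,
trans-SI, trans-ASIS). Distances are *signed* vertical (v-axis) separations
evaluated at a stated u position (the symphysis u for PSTI/PSSI/PSTA, the
mean u of the involved landmarks for the line–line distances). Two
conventions deserve note:

- "Vertical" means along the image v axis, not perpendicular to the
  transischial line. With tilt-only motion and mirrored anatomy the
  reference lines are horizontal, so the two readings coincide; the v-axis
  reading is the one that stays well defined on real, slightly oblique
  films.
- SITA is measured as v(trans-SI) − v(trans-ASIS). The SI joints are the
  deepest (most posterior) landmarks, so anterior tilt elevates their
  projection much faster than the ASIS; this orientation makes SITA
  *increase* with anterior tilt, matching the positive association the
  parameter is known for. The opposite subtraction order cannot correlate
  positively with tilt for any anatomy in which the SI joints lie behind
  the ASIS.

PSTI is signed and never clamped: past ≈ +22° of anterior tilt the
symphysis projects below the transischial line and PSTI crosses zero;
clamping would destroy the monotone inversion. OFH and the foramen width
are averaged over the left and right rims. POD is the separation of the two
outlet extremes measured parallel to the transischial line.

A parameter whose defining landmarks are missing from an image is flagged
and carries NaN; the remaining parameters are still computed (mirroring
missed measurements in manual reading). An image with no measurable
parameter at all is rejected.

Manual digitization is emulated by isotropic Gaussian noise (default
sd 0.5 mm — a plausible on-screen digitization jitter; configurable and
swept 0–2 mm in tests) added to every landmark and rim sample, re-measured
per replicate and averaged over 3 replicates, emulating triplicate
measurement. Averaging reduces the measurement variance by ≈ 1/3, which the
test suite verifies by Monte Carlo.

## Nomogram

Per sex, true tilt is regressed on the ratio PSTI/POD pooled over all
same-sex calibration rows (13 orientations × subjects). The ratio
formulation collapses the two-axis (POD, PSTI) chart into one calibrated,
scale-exact function: any global magnification multiplies both numerator
and denominator and cancels, which the magnification-robustness test
(calibrate at SID 1000 mm, estimate at 1200 mm, shift < 1°) confirms.

The exact forward relation is trigonometric,
PSTI(θ) = Δz·cos θ − Δy·sin θ with Δz the neutral-pose PSTI and Δy the
anteroposterior symphysis–ischium offset. Over ±30° this is dominated by
the odd (sin) term — a straight line fits a single pelvis with residual
sd ≈ 0.8° — but the even (cos) component leaves a small systematic bias
near 0° that a line cannot remove. `fit_nomogram` therefore defaults to the
linear form (the classical "equation of each line") while the end-to-end
pipeline defaults to the quadratic form, which captures the even component;
quadratic fits are accepted only if monotone over the calibrated ratio
range, and both forms expose `residual_sd_deg` so the approximation error
is always visible. Estimates for ratios outside the calibrated range are
returned but flagged `extrapolated`, never clamped.

Screening of the eight candidates reports, per parameter: the pooled
Pearson correlation between true tilt and the POD-normalized parameter
(OFR, already dimensionless, is used raw; constant columns are reported as
undefined, never as zero), the ICC(2,1) repeatability across noisy
replicate readings of the same images, and the miss rate under a
caller-supplied landmark-availability scenario. In simulation PSTI, PSSI
and SITA correlate at |r| > 0.95 (PSTI negative), TITA negatively, OFH/OFR
and TISI positively at |r| > 0.8, and PSTA — whose two defining landmark
sets sit at nearly the same depth — is the designed-in weak parameter
(|r| ≈ 0.1–0.6 depending on cohort). PSTI is preferred because its
landmarks are the most reliably visible on real films and its ICC is
highest under noise.

## Statistics

- `pearson_r`: product-moment correlation; constant input is an explicit
  error, not a silent zero.
- `icc_2_1`: two-way random effects, absolute agreement, single measures —
  (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n). The ICC variant is a
  genuine open choice in agreement work; (2,1) is fixed here because the
  raters (replicate readings) are interchangeable random draws.
- `t_test_two_sample`: Student (equal-variance) by default, Welch behind a
  flag; two-sided. Zero-variance inputs with equal means return p = 1 by
  convention; with unequal means they are rejected as degenerate.
- `one_way_anova`: standard between/within F; with two groups F = t²
  exactly.
- `validation_report` / `validation_table`: means (sd) of actual and
  measured tilt, measured−actual difference and absolute difference,
  strict % of |errors| < 5°, direction accuracy over cases with
  |actual| ≥ 2° (near-zero tilts carry no meaningful direction; the
  threshold is recorded in the report and adjustable, e.g. to the stricter
  |actual| > 5° stratum), Pearson r, and the two-sided t-test p between the
  actual and measured means. Subgroups: all, per sex, non-multiples-of-5°
  (excluding the calibration orientations), and their crossings.

Sub-seeds for cohorts, per-row noise and validation draws are derived via
`numpy.random.SeedSequence`, so one top-level seed reproduces the entire
pipeline deterministically.

## Problem sizes and defaults

The default configuration is the full study design: 20 pelvises
(10 male / 10 female), 13 calibration orientations each (260 pooled rows),
and 50 validation images (5 each from 10 pelvises). The test suite and the
acceptance script calibrate on a 5 + 5 cohort — the round-trip behavior is
driven by the per-sex pooling, not the cohort size — and use 50 validation
images; Monte-Carlo property checks use 800 images per noise level (noise
monotonicity), 2000 seeds (triplicate variance reduction) and 10,000
simulations (type-I error calibration).

## What the synthetic validation does and does not show

The generator reproduces the *structure* of the problem — projective
geometry, magnification, sexual dimorphism, inter-subject size/shape
variation, digitization noise, triplicate averaging, missing landmarks —
so passing tests demonstrate that the PSTI/POD nomogram is geometrically
sound, scale-invariant and invertible, and that the validation statistics
are computed correctly. It does not reproduce real anatomical shape
statistics (templates are stylized, shape noise is landmark-independent
and mirrored), real radiographic appearance (no pixels, no occlusion, no
reader bias — landmark "visibility" is an explicit deletion scenario, not
an image property), pelvic obliquity or axial rotation, or the patient
populations behind any published agreement figures. Noiseless round-trip
accuracy here (mean |error| ≈ 1.4°, ≥ 90% of errors < 5°, direction
recovery ≈ 100% at |tilt| ≥ 2°) is an upper bound on what manual
measurement of real films can achieve, not a clinical claim.

## Known limitations

- Tilt only: obliquity (rotation about y) and axial rotation (about z) are
  out of scope by construction.
- Per-subject anatomy offsets put a floor (~1–1.5° sd) under pooled-nomogram
  accuracy even with perfect measurement; per-patient calibration would
  remove it but has no counterpart in single-film practice.
- The linear form carries a small systematic bias near 0° tilt (see above);
  use the quadratic form when unbiased small-tilt direction calls matter.
- EOS/DICOM ingestion, pixel rendering and automated landmark detection are
  out of scope; inputs are landmark coordinates.
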