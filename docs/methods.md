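# Methods

## Surveillance model

`epidwatch` monitors per-fraction transit portal images relative to a
first-fraction baseline. The underlying assumptions are:

* the first fraction is correct — the method detects *change*, not
  absolute error, so a setup or planning error present at fraction 1 is
  invisible by construction;
* image values are in calibrated units (CU, 1 CU per monitor unit for a
  10 × 10 cm open field), flood-field and dark-field corrected, so the
  per-pixel *relative* difference is meaningful across days;
* fraction identity is the acquisition calendar date within one
  (patient, plan) pair; two sessions on one date collapse into one
  fraction (a known limitation for twice-daily treatments — the latest
  acquisition per field wins);
* a fraction whose imaged field set differs from the baseline's
  (typically a beam interruption) would score a falsely high mean and is
  therefore omitted from flags, daily statistics and rule evaluation.

## GDSA metric and ROI construction

The score of fraction *f* is the mean over a frozen baseline ROI of
`100 · (I_f − I_1)/I_1` (percent). Two details are deliberately fixed
here because the GDSA literature leaves them open:

* **Per-pixel relative difference averaged over the ROI**, not the
  difference of ROI means. The two differ under non-uniform change; the
  pixel-wise reading matches the intent of averaging "mean image
  differences … from the pixels".
* **Multi-field fractions combine as an unweighted mean** across fields
  paired by field id. Unweighted is the simplest defensible contract and
  is recorded per record (`n_fields`).

The ROI is the high-dose, low-gradient region of the baseline:

| parameter | default | unit | rationale |
|---|---|---|---|
| dose threshold | 0.5 | fraction of plateau max | conventional half-maximum field core |
| gradient limit | 3.0 | % of local value per mm (panel plane) | excludes penumbra and steep modulation |
| pre-smoothing σ | 2 | pixels | a single hot pixel must not define the plateau maximum |
| minimum ROI size | 100 | pixels | guards the mean against tiny, unstable regions |

These are conventions of this implementation, configurable through
`RoiParams`, not facts of the clinical method; whether the gradient is
normalized per millimeter or per pixel is likewise a convention (per-mm
here, using the panel-plane pitch `panel_size / matrix`). Gradients are
central differences (one-sided at borders) of the smoothed image,
normalized by the local smoothed value. The ROI is segmented once on
fraction 1 and never re-segmented, because the baseline defines the
course.

Degenerate inputs: an all-zero baseline, or one whose qualifying region
is smaller than `min_roi_pixels`, raises a degenerate-field error and the
course is skipped (logged, not fatal) by the nightly batch. A zero
baseline pixel inside the ROI is a hard error rather than silently
dropped, since it signals a segmentation fault upstream.

## Flag semantics

* "Deviation of ±X %" is **strict magnitude exceedance** |GDSA| > X;
  boundary equality never flags. One convention everywhere.
* **Type-A** (default 10 %): one flag per offending fraction. Fraction 1
  is identically zero and can never flag.
* **Type-B** (default 3 %, run length 3): consecutiveness is counted
  over complete fractions in date order after removing omitted ones
  (the unit of the rule is the treated fraction, not the calendar day).
  One flag per *maximal* qualifying run — a 6-fraction trend is one
  alert, not four sliding windows — and the flag carries every fraction
  of the run. The run may mix signs by default (the rule is written
  ±3 %); a same-sign mode exists behind `FlagConfig(type_b_same_sign=True)`
  for sensitivity studies. Note one consequence of maximal-run
  semantics: lowering the threshold can merge two runs into one, so the
  *count* of Type-B flags is not monotone in the threshold, while the
  set of flagged fractions is.
* **MACHINE** (default 1 %): the daily mean over all complete fractions
  of all patients, compared between *adjacent treated days* (a Friday
  and the following Monday are consecutive treatment days). Daily SD is
  the sample SD (n−1); undefined and reported as missing when a single
  fraction was treated.
* Reports replace e-mail/portal upload: each flag writes a bundle
  (deterministic `summary.json` with the full trace, a trace plot, and
  baseline/trigger difference panels when images are at hand) into an
  outbox directory. A notification hook can be layered on top; none is
  built in.

## Replan-trigger rule evaluation

Rules A–E (thresholds 3 % or 2 %; one or two qualifying fractions;
optionally excluding the last five fractions) are evaluated per patient
trace and cross-tabulated against binary replan labels.

* **Exceedance is signed positive** (GDSA > threshold): anatomy loss
  raises the transit signal, so positive deviations are the
  replan-relevant ones. A magnitude mode exists via `RuleSpec(signed=False)`.
* "Two fractions" means any two qualifying fractions, not consecutive.
* "Not last 5 fractions" means qualifying exceedances must occur before
  the final five fractions (a late deviation cannot justify a replan);
  a trace no longer than the exclusion window evaluates to False.
* Tabulated proportions use **two-decimal truncation** (floor), the
  convention under which every published proportion reproduces from its
  printed counts (e.g. 105/133 = 0.789 → 0.78). The prospective
  trend-rate uses one-decimal truncation (13/345 → 3.7 %), the
  retrospective one two-decimal rounding (45/1633 → 2.76 %); each helper
  in `clinical_tallies` states its convention.

## Synthetic transit images

The generator emulates exactly the phenomena the flags must catch and no
more. Pixel model, on the isocenter-projected grid:

```
I(p) = CU_open · s · exp(−μ · t(p))  inside the aperture,  0 outside,
```

Gaussian-blurred at the field edge (penumbra σ, default 3 mm), then
multiplied by truncated Gaussian noise (default SD 0.5 % of pixel value —
portal images are flood-field corrected, so relative noise is
approximately uniform). `s` is the per-fraction output scale
(`(1+drift)^(f−1)` times any injected spike/trend/step factors) and
`t(p)` the water-equivalent path (uniform `thickness + delta` inside an
elliptical shadow, default 10 cm at μ = 0.05 cm⁻¹ ≈ water at 6 MV).

By default the collimated aperture (10 × 10 cm at isocenter) lies fully
inside the phantom ellipse (12 × 10 cm semi-axes), so the segmented ROI
sits on the in-shadow plateau and the expected GDSA of fraction *f* has
the closed form `100·(s_f/s_1 · e^(−μ(Δt_f−Δt_1)) − 1)`, recorded per
fraction in the ground-truth log (exactly 0 at fraction 1). Because a
uniform thickness change and output scale multiply the *whole* image by
one constant, and Gaussian blur is linear, the noise-free rendered
fraction is exactly proportional to the baseline — the closed form holds
to machine precision regardless of the ROI, which is what makes the
generator a usable oracle.

What the generator does **not** emulate: scatter, MLC/aperture
modulation, imager lag or ghosting, setup shifts, localized anatomy
change (an optional shrinking-ellipse variant exists but uniform
thickness drift is the tested path). Passing tests therefore demonstrate
that the *pipeline* detects output- and attenuation-scale changes at the
stated noise levels; they do not certify sensitivity to spatially
structured clinical change.

Determinism: one integer seed fixes every pixel of a course; per-fraction
and per-field streams are spawned as `(seed, fraction, field)` seed
sequences, and clinic patients get independent streams derived from the
clinic seed.

## Image interchange

Images travel as DICOM RTIMAGE files: 16-bit unsigned stored values with
per-file rescale slope `max_CU/65535` (quantization error ≤ half a step),
identity in PatientID / SeriesDescription / RTImageLabel /
AcquisitionDate+Time, geometry in RTImageSID and ImagePlanePixelSpacing.
The SOP instance UID is derived deterministically from the identity
tuple, so the writer is a pure function and re-simulation rewrites
byte-identical files. A plain-text fallback (matrix + JSON sidecar) is
accepted for portable fixtures. On read, the isocenter projection is
reconstructed as `panel × 100/SID` (≈ 27.9 cm for the default panel);
the nominal 28 cm default is retained for construction. Sorting uses
tags only, never filenames.

## Problem sizes in tests

The test suite and the acceptance script run the simulator on a 96 × 96
panel matrix (same 43 cm panel and 154 cm source-imager distance as the
clinical 1280 × 1280 default). The GDSA mean is a per-pixel relative
average and is resolution-independent; the ROI at this size is ~900
pixels, large enough that 0.5–1 % pixel noise leaves the per-fraction
score noise below 0.05 %. Detection studies use 10-fraction courses
(50 seeds) and 20-patient clinic days over 3 days (100 seeds).

## Known limitations

* Changes between simulation/planning and fraction 1, or errors in
  fraction 1 itself, are undetectable by a baseline-relative metric.
* One fraction per calendar date; twice-daily courses are mis-grouped.
* The daily machine mean is confounded by small clinics: a few strongly
  deviating patients can move the mean by more than the 1 % threshold
  (a known false-positive mode of the clinical rule as well).
* The replan-rule study conventions (signed exceedance, non-consecutive
  fractions, truncation) are choices where the published description is
  ambiguous; each is configurable.
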