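# Methods

## Colour model

All thresholding happens in 8-bit HSB space, the convention of ImageJ-style
threshold tools. Conversion from 8-bit RGB uses the standard hexagonal hue
angle scaled by 255/360 and truncated (floored), saturation
`floor(255·(max−min)/max)`, and brightness equal to the maximum channel.
The implementation does this in exact integer arithmetic
(`h8 = (255·t) // (6·d)`), so quantization is bit-reproducible and, e.g.,
pure blue lands exactly on hue 170. Achromatic pixels (including black) get
hue 0 and saturation 0, which keeps them out of every stain bin: the red
bin deliberately starts at hue 1, and hues 111–255 are unclassified for the
birefringence bins — there is no red wraparound at the top of the wheel,
matching the printed bin definitions. All range bounds are inclusive on
every axis, which is what makes bin disjointness a checkable invariant.

The four birefringence bins (red 1–13, orange 14–25, yellow 26–52, green
53–110; S 10–255, B 20–255) and the trichrome blue box (121–179, 20–255,
10–255) ship as YAML defaults and can be overridden per run; overlapping
hue intervals are rejected at configuration load.

## Preprocessing

The original workflow removed background coloration interactively and drew
regions of interest by hand. Both steps are replaced with deterministic,
parameterized rules:

* **Background estimation** — per-channel median of the darkest
  `dark_quantile` fraction of pixels (ranked by HSB brightness), subtracted
  with clamping at 0. Default `dark_quantile = 0.25`; values above 0.5 are
  rejected because the estimate must come from a definitely-background
  minority. The rule is idempotent: re-estimating on corrected output gives
  zero offsets.
* **Automatic ROI** — a pixel of the brightfield partner image is "empty or
  lumen" when its brightness ≥ `white_cut` (default 230) *and* saturation ≤
  `min_sat` (default 25); the ROI is the complement. The ROI is built on the
  brightfield image and applied to the pixel-registered polarized image,
  because lumens are dark (invisible) under polarization. A user-supplied
  mask file (nonzero = inside) bypasses the automatic rule. No image
  registration is attempted; partner images are assumed aligned.

These parameter defaults are declared stand-ins for an interactive
procedure whose original settings are unknowable; they are exact on the
synthetic fixtures and tunable in config for real material.

## Picrosirius red quantification

Two denominators coexist by design. *Total collagen content* is
birefringent pixels (any bin) over ROI pixels. *Colour proportions* are
per-bin counts over total birefringent pixels. Group comparisons divide
each sample's proportion by the reference group's mean proportion, so the
reference group reports exactly 1.000 per bin; the reference label is an
explicit parameter, never inferred from the data. Per-patient values are
unweighted means over replicates; replicates with zero birefringent pixels
have undefined proportions and are excluded from the proportion mean (but
kept for total collagen), avoiding silent 0/0 bias. Aggregation can be run
at core or patient level via config.

## Trichrome and SHG scoring

"Mean blue intensity per tissue area" is operationalized as the sum of HSB
brightness over blue-thresholded pixels divided by tissue pixel count — an
intensity-weighted area measure on the 0–255 scale; the plain blue area
fraction is emitted alongside as a secondary column since the original
intensity definition is not fully specified. SHG stacks (12–15 sections
typically; ≤32 accepted) are projected by elementwise maximum and scored
as the arithmetic mean of the projection, over the whole field by default
or within an optional mask for core-boundary exclusion.

## Statistics

The two-sample test is the pooled-variance (Student's) t-test with
df = n1+n2−2 and two-sided p; the unequal-variance variant is deliberately
not used. The summary-statistic route reconstructs sd = SEM·√n and is
algebraically identical to the raw route (verified to 1e-12 in tests).
Zero pooled variance is resolved explicitly: equal means → t = 0, p = 1;
unequal means → p = 0, flagged degenerate. Regressions are univariate OLS
with the slope standard error from the usual t-based formula. Missing
clinical values are dropped listwise per analysis, so every association row
carries its own n. No multiple-testing correction is applied by default
(the association table is reported covariate-by-covariate);
Benjamini–Hochberg is available behind a flag.

## Synthetic data

The generators are pure functions of seed and parameters.

* **PSR pairs.** Fibres are random polylines with integer stroke widths,
  painted per bin until the bin's target pixel count (default image-area
  fractions red 0.05, orange 0.12, yellow 0.15, green 0.10 — ~42%
  birefringent area with thin fibres dominating, realistic for benign
  glandular tissue) is reached. Crossing fibres are resolved by draw order
  and the ground truth records final per-pixel ownership; a second pass
  tops up bins that lost pixels to later strokes. Painted colours are fully
  saturated, brightness 240, with hue at least 2 units inside the bin
  boundary, so RGB↔HSB quantization cannot move a pixel across a bin edge
  (the generator additionally verifies each painted colour classifies back
  into its bin). Fibre pixels carry the uniform near-black background
  offset additively, so background subtraction restores the painted colours
  exactly — this is what makes zero-tolerance recovery a legitimate test.
  Optional noise applies to background pixels only. The brightfield partner
  is a uniform pink tissue field with near-white elliptical lumens at
  locations fibres never occupy.
* **Trichrome images.** Blue strokes (hue 150, saturation 200, brightness
  200) on red-pink cytoplasm, trimmed to the target pixel count exactly, so
  the expected score has the closed form `count·brightness/area`.
* **SHG stacks.** Each fibre has a centre slice where it reaches its full
  amplitude, with Gaussian falloff (σ_z = 1.5 slices) on neighbours;
  overlaps combine by maximum. The expected projection is computed
  analytically as the per-pixel maximum of fibre amplitudes, independent of
  the stack assembly.
* **Cohorts.** Covariates are drawn so their medians land near typical
  TURP-population values (log-normal PSA around 4 ng/ml, prostate size
  ~35 g, AUASI ~21, log-normal post-void residuals), with per-covariate
  missingness matching retrospective chart availability (32–72%). The
  collagen metric is intercept 56 plus configurable linear covariate
  effects plus Gaussian noise (sd 10); effects are computed before
  missingness is applied. Default slopes and treatment effects are zero —
  the null cohort mirroring the study's null findings.

What the fixtures do *not* emulate: polarization optics, stain variability,
focus/illumination gradients, chromatic noise on tissue, or spatial
correlation between collagen and clinical covariates. Passing the
zero-tolerance tests therefore demonstrates correctness of the measurement
arithmetic and plumbing, not robustness to real-world staining variation —
that is what the configurable thresholds are for.

## Simulation sizes and numerical choices

The end-to-end power study uses 64×64-pixel fields, one replicate per
patient, 24 reference vs 48 comparison patients, between-patient bin-fraction
dispersion 0.18 (log-scale SD), and a +25% shift of the orange proportion;
the comparison group's orange image fraction is solved from the shifted
proportion with the other bins held fixed. These sizes keep a 100-seed power
sweep to about two minutes while leaving the planted effect comfortably
detectable. Null calibration uses 10,000 pairs of n = 20; regression
coverage uses 500 cohorts of n = 100 with slope 0.5 on age and metric noise
sd 4. Sub-seeds are always spawned from a single entry seed via
`numpy.random.SeedSequence`.

Degenerate inputs are handled loudly rather than silently: empty ROIs and
empty tissue masks raise an unquantifiable-image error (per-file errors in
batch runs become error rows and the run continues), constant-x regressions
raise, and single-value summaries flag their undefined SEM.

## Known limitations

* HSB box thresholds only; no stain deconvolution or colour unmixing.
* No fibre tracing or orientation analysis — hue bins are the only fibre
  thickness proxy.
* No whole-slide pyramidal formats; images must fit in memory.
* Brightfield/polarized pairs must be pixel-registered upstream.
* Deep-red birefringence with hue above 230 is left unclassified by the
  default bins (red starts at hue 1 with no wraparound); a custom bin set
  can fold it in if desired.
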