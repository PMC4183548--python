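# fibroquant

Quantification of fibrillar collagen and extracellular matrix (ECM) in
histology images of glandular prostate tissue — and, more generally, of any
tissue scored with the same three modalities:

* **Picrosirius red (PSR) under circularly polarized light.** Birefringent
  collagen pixels are classified into four hue bins on the 8-bit hue wheel —
  red (H 1–13), orange (H 14–25), yellow (H 26–52), green (H 53–110), all with
  S 10–255 and B 20–255 — where hue tracks fibre thickness (green = thin
  fibrils, red = thick bundles). Total collagen content is the fraction of
  birefringent pixels within the region of interest (tissue area, excluding
  empty and glandular lumen space); the colour *proportions* are computed
  within birefringent pixels and normalized to a reference group's mean.
* **Masson's trichrome (MTC).** Blue ECM is thresholded at H 121–179,
  S 20–255, B 10–255 and scored as mean blue intensity per tissue area
  (sum of blue-pixel brightness / tissue pixel count).
* **Second harmonic generation (SHG).** Optical-section stacks are flattened
  into maximum-intensity z-projections and scored as mean gray intensity.

On top of the measurements sit the study statistics: group summaries
(mean ± SEM), pooled-variance two-sample t-tests (from raw values *or* from
printed summary statistics, via sd = SEM·√n), and univariate ordinary
least squares of a collagen metric on clinical covariates (slope ± SEM, R²,
two-sided p with df = n−2), with listwise missing-data handling per
covariate.

Because archival tissue images are rarely shareable, the package ships a
seed-deterministic synthetic generator (`fibroquant.synthetic_data`) that
emulates every input — registered brightfield/polarized PSR pairs, trichrome
fields, SHG stacks, and clinical cohorts — while recording exact painted
ground truth, so the measurement code is testable to zero tolerance.

## Worked example

Generate a small synthetic fixture set and score one patient:

```bash
$ fibroquant simulate --out-dir demo --seed 3 --n-patients 2
wrote fixtures for 2 patients to demo

$ fibroquant psr --brightfield demo/P000_brightfield.png --polarized demo/P000_polarized.png
roi_size          8435
total_positive    3909
total_fraction    0.4634
red      count      473   proportion 0.1210
orange   count     1109   proportion 0.2837
yellow   count     1389   proportion 0.3553
green    count      938   proportion 0.2400

$ fibroquant mtc --image demo/P000_mtc.png
tissue_area        9216
blue_pixel_count   1106
mean_blue_intensity 24.0017
blue_area_fraction  0.1200

$ fibroquant shg --stack demo/P000_shg.tif
slices     15
mean_gray  30.4974
```

Reading the PSR output: 8435 of the 96×96 pixels are tissue (the rest are
glandular lumens excluded from the ROI), 46.3% of the tissue is birefringent
collagen, and within that collagen 28.4% falls in the orange (thick-bundle)
bin. The trichrome image has 12% of its area blue at brightness 200, giving
a mean blue intensity per tissue area of 24.0. `demo/ground_truth.json`
holds the generator's painted counts for comparison.

Two-group comparisons run from a manifest CSV (columns `path, patient_id,
group, modality, replicate`):

```bash
fibroquant --config cfg.yaml compare --manifest demo/manifest.csv --out-dir results/
fibroquant associate --quant quant.csv --clinical clinical.csv --out assoc.csv
```

where `cfg.yaml` sets `reference_group` (the group normalized to 1.000).
All thresholds are configurable via YAML; the shipped defaults are the
published bin definitions above.

A t-test from printed summary statistics, in Python:

```python
>>> from fibroquant import ttest_from_summary
>>> ttest_from_summary(62.52, 2.74, 11, 51.77, 3.49, 10).p   # SHG: BPH vs normal
0.0243421879546044
```

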