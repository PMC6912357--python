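# Methods

This note documents the models and numerical choices behind
`bluesclera`: what each stage computes, what the synthetic generators do
and do not emulate, and where the design was genuinely open.

## The blue-percentile score

The score of an eye photograph is the 75th percentile, over the
delineated scleral region of a white-corrected linear image, of the
per-pixel blue fraction 100·B/(R+G+B) — the *blue percentile* (BP).  The
blue fraction is scale-free, which gives the pipeline its two defining
invariances: BP is unchanged by any consistent rescaling of exposure
times and pixel values, and (after white correction) by any positive
diagonal illuminant gain.  A neutral gray region scores exactly
100/3 ≈ 33.33; real scleras score in the high 20s to low 30s, with
bluer scleras higher.

### Exposure fusion

Bracketed frames are fused per pixel and channel as a weighted mean of
the per-frame radiance estimates p/t.  The weight is a hat function of
the normalized pixel value that is zero in the extreme 2% of the
representable range, so saturated and near-black samples never bias the
estimate.  An identity camera response is assumed; response-curve
recovery is out of scope.  When every sample is unusable the shortest
exposure supplies the estimate if the pixel saturates there, otherwise
the longest does.  Under a consistent unclipped scene any weighting
reproduces the true radiance exactly, which is what the invariance
suite exploits.

All processing is in linear light.  16-bit files declared linear pass
through at load; 8-bit files are assumed sRGB-encoded and pass through
the inverse transfer function.  Frames are written as 16-bit TIFFs with
the linear convention declared in the stack manifest, avoiding any gamma
ambiguity.

### Region growing

Both the white patch and the sclera (FS and SAS modes) are extracted by
seeded region growing on *chromaticity* (channel fractions of R+G+B),
not absolute RGB, so shading gradients do not break the region.  A
candidate pixel joins when the Euclidean distance between its
chromaticity and the running region-mean chromaticity is at most the
tolerance.  Determinism is fixed by breadth-first visiting under
4-connectivity with row-major tie-breaking, rejected candidates never
revisited, and an incrementally updated mean.  Defaults: 0.08 for the
wide (FS/patch) tolerance and 0.02 for the tight SAS tolerance, tuned
once on synthetic fixtures (FS Jaccard ≥ 0.98 against ground truth on
noise-free renders) and configurable.  Pixels with zero channel sum
carry no chromaticity and are rejected (a seed there is an error).

Manual (MS) delineation takes the pixels whose centers fall inside the
physician's polygon under the even-odd rule; coordinates are 0-based
(row, col) with the center of pixel (r, c) at (r, c).

### Percentile convention

The BP percentile interpolates linearly between closest order
statistics (the common statistical convention; the underlying
acquisition software's estimator is not documented anywhere, and the
choice moves BP by far less than between-patient spread).  BP is
monotone nondecreasing in every input value.

## Synthetic scenes

The renderer composes a linear reflectance map — skin background,
scleral ellipse minus iris disc, anti-aliased red vessel polylines
confined to the sclera, and a white patch (reflectance 0.95) — then
exposes it as clip(reflectance · gains · t + noise) per frame.
Scleral reflectance is (1−β)·base + β·(0.05, 0.15, 0.80) with the warm
base (0.82, 0.75, 0.60), so the ground-truth blue fraction is strictly
increasing in the blueness β and β ∈ [0, 0.2] sweeps BP through
≈ 27.5–33, the range seen in scored photographs.  The exact sclera and
patch masks and the pre-illuminant mean blue fraction are returned as
ground truth.

What the renderer does *not* emulate: specular highlights, eyelashes
and eyelid occlusion, defocus, demosaicing artifacts, camera response
nonlinearity, and JPEG compression.  Passing tests therefore validate
the computational chain, not robustness to real acquisition artifacts.

## Synthetic cohorts

Each patient draws a true ID status (default prevalence 51/67), arm-
specific biomarkers (log-normal ferritin with medians 12 vs 180 µg/L,
transferrin saturation 8 vs 25%, shared log-normal CRP with median
5 mg/L, Gaussian hemoglobin 10.4 vs 12.6 g/dL plus +0.8 for men, and a
female-predominant ID arm), and a latent blueness
β | arm ~ N(0.35 or 0.65, 0.12) clipped to [0, 1].

Raters grade by thresholding β + ε with rater-specific Gaussian noise;
grade bands of half-width 0.15 around the blue threshold produce the
1–4 scale, and "blue" (grade ≥ 3) means crossing the threshold.  Given
a target (sensitivity, specificity) the threshold and noise are solved
in closed form from the two Gaussian tail equations, so simulated
cohorts converge to the target operating point as n grows; the default
three raters sit at (0.61, 0.69), (0.45, 0.81), (0.29, 0.94) — the
operating points observed in the bundled pilot counts.  Because the
clip at [0, 1] is ≈ 3 sd from both arm means, its distortion of the
analytic operating point is far below the ±0.01 Monte-Carlo tolerance
used in the recovery checks.

Per-method BP values use the affine shortcut BP = 27 + 6·β + N(0, 1.5),
independently per method, placing group means near 29 (no ID) vs 31
(ID) — matching the observed BP range — without rendering 10⁴ images.
The shortcut intentionally shares one latent β across methods, which is
what makes between-method concordance (Lin's coefficient) positive.

The serum-marker classification applied to the simulated biomarkers
agrees with the true arm for ≈ 96% of patients; recovery checks
therefore measure rater operating points against the ground-truth arm,
while the study model can use either reference.

## Diagnostic statistics

* **Proportion CIs** are exact Clopper–Pearson (beta quantiles), which
  reproduces the bundled study's printed intervals to one decimal —
  treated as identification of the original method.  Degenerate
  denominators (e.g. NPV when nobody tests negative) are flagged
  non-computable rather than returned as 0/0.
* **Likelihood-ratio CIs** use the Simel log method,
  exp(ln LR ± z·√((1−sens)/tp + spec/fp)); non-computable when tp or fp
  is zero.
* **Association**: Pearson χ² without continuity correction when all
  expected counts are ≥ 5, otherwise the two-sided Fisher exact test;
  the result names the test used.
* **ROC**: every distinct score is a candidate threshold under the
  "score ≥ threshold → positive" orientation (higher BP indicates ID);
  AUC by midranks (= tie-corrected Mann–Whitney), variance by DeLong
  placements.  The Youden (max sens+spec−1), Liu (max sens·spec) and
  efficiency (max accuracy) optima are reported with ties resolved to
  the smallest threshold.
* **Agreement**: Fleiss' κ on the blue/not-blue dichotomy by default
  (that dichotomy drives the 2×2 analysis), with the 4-grade variant
  also reported; the qualitative bands are 0–0.20 poor, 0.21–0.40 fair,
  0.41–0.60 moderate, 0.61–0.80 good, > 0.80 very good.  Lin's
  concordance coefficient uses population (1/n) moments.
* **Adjusted odds ratios**: maximum-likelihood logit (Newton scoring,
  tolerance 1e−8) of ID on the blue classification with age, sex,
  hemoglobin and CRP as default confounders; Wald CIs; complete or
  quasi-separation raises an explicit error.
* **Inflammation**, where no explicit flag exists, is operationalized
  as CRP > 5 mg/L for the ferritin ≤ 100 µg/L clause.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical parameters and seed give
bit-identical scenes, cohorts and results.  The validation suite uses
scenes of 120×160 px, 50 random 32×32 images for the region-growing
oracle, cohorts of 50,000 for operating-point recovery (binomial
standard error ≈ 0.0025, comfortably inside the ±0.01 check), 20,000
for logistic-effect recovery (±5% of e^0.7 is ≈ 1.7 standard errors),
and 2,000 for the null-AUC check — sizes chosen to keep Monte-Carlo
error well inside each tolerance while the whole suite runs in well
under a minute of compute.

## Known limitations

* FS segmentation quality is only demonstrated on synthetic scenes; the
  default tolerances may need retuning on real photographs.
* The BP-from-β cohort shortcut bypasses the imaging chain; end-to-end
  image→cohort consistency is validated only through the monotonicity
  of BP in β.
* The DeLong CI is asymptotic and degenerates at AUC = 1 (zero
  variance).
* No multiple-testing correction is applied anywhere, matching the
  single-endpoint design the battery mirrors.
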