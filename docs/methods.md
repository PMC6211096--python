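# Methods

## Model and workflow

The package estimates defoliation severity by change detection between two
co-registered 30 m surface-reflectance acquisitions bracketing an outbreak.
Five vegetation indices are computed per date from the red (B4), NIR (B5),
SWIR1 (B6) and SWIR2 (B7) bands; the predictor is the per-pixel difference
`X = VI(pre) − VI(post)`. Moisture-stress-type indices (MID = B6+B7,
MSI = B6/B5) rise with canopy loss, so their change is negative under
defoliation; the normalized differences (NDMI, NDVI, NBR) fall, so their
change is positive. The observed response is the defoliated fraction
`Y ∈ [0, 1]` of a 30 m ground-truth cell, photo-interpreted at 5%
intervals and binned as nil (0–5%), low (10–30%), medium (35–65%),
high (70–100%).

The calibration per index is the two-parameter logistic
`Y = 1/(1 + exp(−(a + bX)))` with additive intercept `a` and slope `b`
(multiplier of X). Class thresholds in X are obtained by inverting the
fitted curve at the boundary fractions Y ∈ {0.10, 0.35, 0.70}:
`X = (ln(Y/(1−Y)) − a)/b`. Because the logistic is strictly monotone,
cutting X at these limits is equivalent to cutting the predicted fraction
at the boundary fractions; a value exactly on a limit is assigned to the
more severe class (consistent with the strict inequality that defines the
nil class). Classification always uses the unrounded limits; rounding
(ties away from zero) is applied only when limits are displayed or
serialized for reporting.

## Fitting and goodness of fit

Because Y is a fraction, not a 0/1 outcome, the fit maximizes the
fractional-response Bernoulli quasi-log-likelihood
`ℓ(a,b) = Σ yᵢ ln pᵢ + (1−yᵢ) ln(1−pᵢ)`, which is well defined at
y ∈ {0, 1} and globally concave in (a, b) (the Hessian,
`−Σ pᵢ(1−pᵢ) zᵢzᵢᵀ`, does not depend on y). The optimizer is a damped
Newton iteration on an internally x-standardized scale, started at
(logit(mean y), 0), with gradient tolerance 10⁻⁸ and step halving; it is
fully deterministic and typically converges in fewer than ten iterations.
Degenerate inputs (fewer than 4 samples, constant x, constant y) are
rejected rather than fitted. In tests the fitter agrees with an
independent GLM implementation (statsmodels, binomial family) to ~10⁻⁹ in
both coefficients and with a brute-force 400×400 likelihood-grid argmax to
within grid resolution.

Goodness of fit is McFadden's pseudo-R² on the deviance scale,

    R² = 1 − (ℓ_sat − ℓ_full) / (ℓ_sat − ℓ_null),

with ℓ_null the intercept-only model (constant p = mean y) and ℓ_sat the
saturated quasi-likelihood (pᵢ = yᵢ). For binary outcomes ℓ_sat = 0 and
this reduces to the classical `1 − ℓ_full/ℓ_null`. The saturated term
matters for fractional responses: interpreted fractions carry irreducible
entropy that no fit can explain, which caps the unnormalized ratio at
roughly 0.38 under the default class mix even for a perfect fit, whereas
the deviance form correctly reports ≈1 there. R² values from the two
conventions are therefore not comparable.

One published coefficient anomaly is handled generically rather than
special-cased: each index carries an expected slope sign (negative for
MID/MSI changes, positive for NDMI/NDVI/NBR changes), and a fit whose
slope contradicts it triggers a warning, because the derived thresholds
then flip orientation while keeping their magnitudes. The burn-ratio
change (dNBR) reference coefficients exhibit exactly this inconsistency,
so reproduction tests compare dNBR threshold magnitudes only.

## Accuracy assessment

Map-versus-observation agreement on the ground-truth cells is a 4×4
confusion matrix (rows observed, columns predicted, class order
nil→high). Producer's accuracy (diagonal over row total) measures omission
error, user's accuracy (diagonal over column total) commission error, and
overall accuracy is the trace over the total. A class absent from a margin
has undefined accuracy and is reported as missing, not zero.

## Synthetic scenes

The generator emulates the structure of the study data, not its radiative
physics. A latent defoliation fraction field f ∈ [0, 1] (sum of Gaussian
outbreak foci clipped to [0, 1] by default; a linear gradient and a
constant are also available — the first focus always reaches full
amplitude so every severity class is populated) drives the post-outbreak
bands through `post_b = pre_b·(1 + coef_b·f) + noise`, clamped to
[0, 10000]. Defaults, chosen once as plausible values for pine stands on
the ×10⁴ reflectance scale: healthy baselines B4 = 300, B5 = 2800,
B6 = 1600, B7 = 900; full-defoliation responses +0.40, −0.50, +0.30,
+0.35; additive white reflectance noise with sd 50; 5% cloud cover
(bright pixels, QA-masked) and 10% non-forest (soil-like reflectance,
f = 0, excluded by the forest mask). Ground truth mimics photo
interpretation: true fractions at drawn pixels are rounded to the 5% grid
and cells are drawn without replacement to per-class quotas (default
10/23/8/9, n = 50). All randomness flows through one seeded generator;
identical parameters and seed reproduce bit-identical scenes.

What the generator does not emulate: spatial autocorrelation of noise,
illumination/topography, phenology between dates, mixed pixels, understory
green-up, or geolocation error. Passing tests therefore demonstrate the
correctness and statistical behaviour of the pipeline, not sensor-level
realism.

## Numerical choices and conventions

- Ratio and normalized-difference indices are scaled by 10⁴ and stored as
  integers (rounding ties away from zero); MID is already on that scale.
  This makes index rasters, thresholds and the published limit table share
  one integer scale.
- Zero denominators at a pixel yield nodata (and a count), never an
  exception mid-raster; nodata propagates through every operation and is
  never resurrected.
- Grids are row-major, 0-based, pixel-is-area, 30 m pixels, georeferenced
  by a six-coefficient affine transform. Rasters are plain TIFFs with a
  JSON sidecar carrying transform, nodata, band ids and date tag.
- The multi-date stability screen flags a pre-outbreak series when any
  pairwise relative change of the masked mean exceeds a tolerance
  (default 0.10, configurable) — a conservative screen for abrupt change
  before the outbreak year.
- Interpreted percentages are validated against the 5% grid; off-grid
  values are rejected at the binning stage rather than silently rounded.
- The pipeline is a pure function of (inputs, config, seed); reruns
  reproduce all tabular outputs byte for byte, and the manifest records
  per-stage counts and warnings.

## Problem sizes

Test and demonstration runs use a 60×60-pixel scene for unit-level checks
and a 300×300-pixel scene (about the extent of a small study landscape at
30 m) for pipeline-scale experiments; calibration experiments use n = 50
cells (the reference campaign size) and n = 500 for consistency checks,
with 200 replicates for recovery statistics and 20 seeds per noise level
for the degradation experiment.

## Known limitations

- The logistic is a calibration curve, not a mechanistic model; when the
  true X–Y link deviates from logistic shape (as it does for the synthetic
  band-response model), the inverted thresholds sit near, but not exactly
  on, the true class cuts. Combined with 5% interpreter rounding this
  bounds achievable cell-level accuracy below 100% even without noise.
- Quasi-likelihood standard errors are not reported; the package ranks
  models by R² only, as the workflow requires.
- Inputs are assumed co-registered on a common grid; no reprojection or
  atmospheric correction is performed.
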