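# Methods

## Problem and model

Grain protein content (GPC, % of dry matter) of winter wheat can be
estimated at flowering from four-band (blue, green, red, NIR) satellite
surface reflectance. The estimation chain implemented here is:

1. convert raw digital numbers (DN) to reflectance with the
   empirical-line method;
2. compute ten vegetation indices from the four bands, giving 14
   candidate remote-sensing variables;
3. regress GPC on the candidates with PLS1 (partial least squares with
   a scalar response), choosing the number of latent components at the
   minimum of a leave-one-out PRESS curve;
4. score the model on a held-out verification set via the 1:1
   predicted-vs-measured plot (R², RMSE, relative accuracy), against
   ordinary least squares (LR) and principal-components regression
   (PCR) baselines;
5. apply the fitted linear form cell-wise over index grids under a
   wheat mask and bin the result into GPC classes for map rendering.

The final fitted model is reported in the original variable scale,

    GPC = a0 + a1·NDVI + a2·SIPI + a3·PSRI + a4·EVI,

so it can be applied directly to index grids without carrying the
autoscaling constants.

### PLS1 core

Predictors are autoscaled (centered, unit variance) and the response
centered. Components are extracted by the NIPALS recursion, which for a
scalar response needs no inner iteration: per component the weight
vector is `w = X'y/‖X'y‖`, scores `t = Xw`, loadings `p = X't/t't`,
`q = y't/t't`, followed by deflation `X ← X − tp'`, `y ← y − qt`.
Regression coefficients on the scaled data are `B = W(P'W)⁻¹q`
(`P'W` is unit upper triangular, hence always invertible), then
back-transformed. Score vectors are mutually orthogonal by
construction; the test suite verifies orthogonality to 1e-8, exact
agreement with OLS at full component count, and coefficient agreement
with an independent reference implementation.

A degenerate weight norm below 1e-12 (no X–y covariance left) stops
extraction with an error; requesting more components than the rank of
the centered design is refused up front.

### PRESS and component selection

PRESS(a) = Σᵢ (yᵢ − ŷᵢ,₋ᵢ)² over leave-one-out folds, for candidate
counts a = 1…a_max. Leave-one-out is used because the study design
reports a single deterministic curve; k = n makes PRESS reproducible
without a fold seed. Centering and scaling are re-estimated inside
every fold (no leakage). All truncations a are evaluated in one NIPALS
pass per fold. The selected count is the argmin, ties broken to the
smallest count (parsimony). Too few components underfit and too many
chase noise, so the curve is high at both ends; a pure-noise response
shows the rising right branch in ≈90 % of replicates in the tests.

### Variable importance

VIP_j = √( p · Σₐ SSₐ w²ⱼₐ / Σₐ SSₐ ), with SSₐ = q²ₐ·t'ₐtₐ the response
variance captured by component a. Squared VIPs average to exactly 1, so
predictors above 1 carry more than their share; this supports the
choice of NDVI, SIPI, PSRI and EVI as the sensitive variables.

### Baselines

LR is ordinary least squares via the normal equations, refusing
rank-deficient designs and naming the offending columns. Note the full
14-variable candidate set is *exactly* rank-deficient by construction
(DVI = R_nir − R_red is a linear identity), so LR defaults to the four
sensitive indices. PCR eigendecomposes the predictor correlation
matrix, regresses the response on the leading component scores
(default 5 retained, on all 14 variables) and back-transforms. With
all p components PCR reproduces OLS exactly.

In the packaged algorithm benchmark, PLS runs on the full 14-variable
candidate set with the PRESS-selected count (candidates 1…10 — a curve
over ~10 counts requires more than four predictors). Under the
generator's multicollinearity the verification-RMSE ordering
PLS ≤ PCR ≤ LR holds in roughly three quarters of replicates. It is
directional, not dramatic: when pairwise predictor correlations sit in
the 0.8–0.99 range, five principal components already capture nearly
all predictor variance, so PCR cannot lose badly to PLS on such data —
a structural fact worth keeping in mind when comparing against field
studies that report much larger gaps.

### Evaluation conventions

RMSE = √(Σ(yᵢ−ŷᵢ)²/n). Two R² values are reported: the R² of the
fitted predicted-vs-measured line (squared Pearson correlation — the
1:1-plot convention) and 1 − SSE/SST about the identity line; they
coincide only when the calibration line is the identity. Accuracy has
two selectable definitions: `relative` (default) is
(1 − MAE/mean(y))·100, a percentage score; `mae` is the mean absolute
error itself in % GPC. The MAE formula is retained verbatim because
sources in this area sometimes print it under the name "accuracy"
although it is not a percentage; the package never converts one into
the other silently. Correlation significance flags use the two-sided
t approximation for Pearson r at 0.05 and 0.01.

The 3:2 modeling/verification split assigns round(0.6·n) samples to
the modeling set and always forces the global minimum- and maximum-GPC
samples into it, so models are never asked to extrapolate beyond the
calibration range.

## Synthetic scenes

The generator emulates a flowering-stage winter-wheat field population
with a linear latent model per band:

    band_b = base_b + loading_b·z + brightness_b·c + ε_b,

where z is standardized GPC, c ~ N(0,1) is a shared canopy-brightness
factor, and ε_b is small independent band noise. GPC is drawn from a
truncated normal (defaults: mean 12.1 %, SD 1.4 %, bounds 9.3–14.6 %)
by rejection sampling — exact for these mild truncations. Note the
truncated distribution's own SD is ≈1.20 %; tests check empirical
moments against the truncated-normal moments, not the untruncated
parameters.

The brightness factor is essential: with independent band noise alone,
band–GPC correlations of (−0.22, −0.08, −0.46, +0.51) mathematically
cap corr(GPC, NDVI) near 0.6. A shared factor that ratio indices
largely cancel reproduces both the weak band-level correlations and a
strong index–GPC correlation (defaults give corr(GPC, NDVI) ≈ 0.78)
along with heavy inter-index multicollinearity. Default loadings were
derived analytically from the target per-band correlations given the
chosen brightness and noise scales (band_base (0.06, 0.09, 0.07,
0.45); brightness (0.010, 0.011, 0.012, 0.036); noise 0.002 per band).

Gridded scenes use Gaussian-smoothed white noise (kernel width 5
cells) rescaled to the GPC distribution as the spatial field, and a
second smoothed field thresholded at a quantile as the wheat mask, so
wheat forms contiguous patches covering the requested fraction. DN
synthesis applies an affine gain/offset with optional noise and emits
known-reflectance calibration targets for the empirical-line module.

What the generator does *not* emulate: variety strata, spatial
autocorrelation of residuals, atmospheric/sensor artifacts beyond the
affine DN model, and any nonlinear canopy radiative transfer. Its
noise is benign and low-dimensional, so absolute fit statistics on
synthetic data (R² ≈ 0.93 at the defaults) say nothing about skill on
real imagery; passing tests demonstrate correctness of the machinery
and directional behavior of the estimators, not field performance.
One structural consequence: a positive PSRI–GPC correlation cannot be
produced jointly with the band-level correlation pattern by any model
of this class, since the red band falls faster with GPC than the blue
band; the generated PSRI–GPC correlation is therefore negative.

## Numerical and design choices

- Autoscaling before PLS/PCR: the chemometrics default; makes
  coefficient magnitudes comparable across indices of very different
  ranges (e.g. RVI vs PSRI).
- EVI as implemented keeps the green band in the 7.5 aerosol term
  (`evi_variant="paper"`); the conventional blue-band form is a switch.
  The PSRI denominator is the NIR band.
- Division-by-zero in index algebra flags the sample (scalar API
  raises; table construction excludes with a logged count; grids mask
  the cell) — downstream matrices stay dense and finite.
- Out-of-range reflectance after calibration is clipped to [0, 1] with
  a logged count, not an error; slightly negative DN-derived
  reflectances are routine.
- GPC class bins are half-open [low, high): a value equal to an edge
  belongs to the class whose lower bound it is; default edges
  (11.3, 11.8, 12.5) %.
- Map layers are plain-text matrices (predictions to 6 decimals,
  nodata −9999; classes uint8, nodata 255) or single-page TIFF; a JSON
  legend records edges, labels and per-class cell counts.
- Problem sizes in tests: Monte-Carlo checks of the generator use
  n = 5000; benchmark replicates use the study-sized n = 255 with 20
  seeds — large enough for stable directional statements while keeping
  the whole suite in seconds.
- Every pipeline artifact is stamped with a 16-hex-digit SHA-256 hash
  of the canonical config; a rerun with the same config is
  byte-identical.

## Known limitations

- PLS1 only (scalar response); no PLS2, kernel or sparse variants.
- No uncertainty quantification on coefficients or predictions.
- The empirical-line fit is plain OLS per band; no robust option.
- Geometric correction, supervised crop classification and actual
  satellite imagery ingestion are out of scope; the wheat mask is an
  input.
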