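# Methods

## Data model

Spectra are sample × wavelength matrices of log(1/R) absorbance on a
strictly increasing grid; the default is the common scanning-instrument
grid of 680–2,500 nm at 2 nm, i.e. 911 channels. Any other strictly
increasing grid is accepted with a logged warning. Reference chemistry is
sample × analyte over {DM, CP, NDF, ADF, IVDMD}, in g/kg or percent (the
conversion is a factor of exactly 10). Missing reference cells are allowed
and excluded analyte-wise, so per-analyte selected-sample counts can
differ, as they do in routine calibration reports. Spectra and reference
tables are aligned on the sample-ID intersection in spectral order.

## Preprocessing

The pipeline order is: absorbance → SNV → detrend → gap-segment derivative.

* **log(1/R)** is taken base-10 by default (the dominant NIRS convention),
  with natural log selectable. The choice only rescales the PLS
  coefficients, so calibration statistics are base-invariant.
* **SNV** centres each spectrum and scales it to unit sample SD (ddof = 1),
  removing per-sample multiplicative scatter and offsets.
* **Detrend** subtracts a least-squares polynomial (order 2 by default) of
  absorbance on wavelength, removing smooth baseline curvature. Wavelengths
  are rescaled to [−1, 1] internally for conditioning.
* **Gap-segment derivative** with code (d, g, s): a valid-mode boxcar of
  width s channels, then the gap difference (span g, symmetric offsets
  ⌊g/2⌋ / ⌈g/2⌉ around the centre) applied d times. Margins consumed by the
  windows are dropped — no padding, so no fabricated boundary values enter
  the model — and the wavelength bookkeeping follows the value pipeline
  (window means / midpoints). A fourth code number (second smoothing pass,
  after the derivative) is accepted for compatibility with four-number
  conventions and defaults to 1 (no-op). The 3-number code is interpreted
  as a single smoothing pass.

The default treatment grid is the conventional 12 recipes
{1,2,3,4} × {(4,4), (8,8), (16,16)} with SNV + detrend on.

## PLS and factor selection

PLS1 via NIPALS, one model per analyte: factors extracted in order of
covariance with the response, with X-deflation; for a single response the
inner loop converges in one pass, so extraction is deterministic.
Predictors are mean-centred; autoscaling is available but off by default,
the usual choice for NIR absorbance. The factor cap is 16, further limited
by n − 1 and the channel count; rank exhaustion truncates with a warning.
The factor count is selected by minimising SECV over the nested sub-models
(one NIPALS fit per fold yields predictions at every depth), with ties
broken toward fewer factors. SEC uses denominator n − k − 1 (the
standard-error-of-calibration convention; users wanting n − 1 can divide
out the ratio), SECV uses n.

## Outlier screening

Spectral screening uses the GH statistic, GH = D²/k, where D² is the
squared Mahalanobis distance of a sample's scores from the score centroid
under the sample (ddof = 1) score covariance. The set mean of GH is
identically (n−1)/n, so the cutoff 3.0 reads as three times the average
leverage; interpreting the cutoff on GH rather than raw D matters because
raw D > 3 would flag almost nothing in high-dimensional score spaces.
Scores come from PCA of the treated spectra (10 components by default)
when no model exists yet, or from a PLS decomposition when a response is
supplied. Screening iterates at most 2 rounds, removing flagged samples
and re-deriving scores.

Laboratory screening flags samples with |ŷ − y| > 2.5 × SEC (strict
inequality, so a residual of exactly 2.5 SEC is kept). The workflow order
is: spectral screening → initial cross-validated calibration → lab
screening with that model's SEC → one refit. SEC is recomputed after
removal; both values are kept in provenance.

## Cross-validation and statistics

Default 10-fold cross-validation with a seeded shuffle;
leave-one-out is available. The scheme is logged prominently because SECV
depends on it. All per-spectrum preprocessing (SNV, detrend, derivatives)
is fold-safe by construction; PLS centring and fitting use training folds
only, and out-of-fold predictions are pooled. RPD uses the SD (ddof = 1)
of the post-screening selected set by default. R² is 1 − SSE/SST and is
*not* clamped: negative values (predictions worse than the mean) are
reported with a warning. Reports round R²/SE/RPD to 2 decimals; full
precision is kept in machine-readable output. Acceptance: R²cv > 0.80 and
RPD > 2 (both strict); the SECV/SEC ratio is logged with a warning above
1.3.

Grid search over treatments minimises SECV, breaking ties by higher R²cv
and then lower derivative order; the full per-treatment table is retained.

## Synthetic hay generator

The generator emulates the two hay populations this workflow targets.

* **Chemistry.** Analyte values are drawn from truncated normals matching
  published-style descriptive statistics per species (alfalfa: DM
  918 ± 12.4, CP 155 ± 26.3, NDF 502 ± 37.1, ADF 349 ± 35.8, IVDMD
  692 ± 42.1 g/kg; timothy: 922 ± 14.6, 53.8 ± 16.6, 674 ± 17.6,
  383 ± 21.5, 673 ± 17.6), with min–max truncation by joint rejection. A
  single latent "fiber" factor (loadings NDF/ADF +0.92, CP −0.45, IVDMD
  −0.78) induces the field-typical correlations. CP is realised as
  6.25 × a latent nitrogen draw.
* **Clean spectra.** Absorbance is a smooth rising baseline plus a sum of
  Gaussian bands weighted by constituent mass fractions: water O–H bands at
  1,190/1,450/1,940 nm on moisture (1000 − DM), protein N–H bands at
  1,510/2,054/2,180 nm on CP, carbohydrate/cellulose bands at
  1,210/1,725/2,270 nm (NDF) and 1,680/2,270/2,330 nm (ADF), and small
  negative digestibility loadings at 1,672/2,270 nm (more digestible
  material has less lignified cell wall absorbing in the cellulose/lignin
  region). Band positions cover the peak regions seen in real hay spectra
  (~1,200, 1,400–1,500, 1,900–2,000 nm); widths 30–60 nm. These are
  modelling conventions for realism, not measurements. Clean absorbance is
  exactly linear in the concentrations.
* **Distortion (sample presentation).** Four per-sample scatter components,
  scaled by prep state: multiplicative (1 + a), additive offset b, linear
  tilt c·u, and a *structured* smooth baseline — white noise convolved to a
  60 nm correlation length, unit marginal SD. The first three are exactly
  the distortions SNV + quadratic detrend remove; the structured component
  is deliberately full-rank and sample-specific, because during development
  a fixed low-dimensional scatter basis proved learnable by PLS at n = 200
  (the model simply projects a known nuisance subspace out), which would
  erase any preparation contrast. Physically it stands for packing-density
  and particle-size heterogeneity, which perturb the diffuse-reflectance
  path length in a wavelength-dependent, sample-specific way. Defaults:
  ground (0.02, 0.01, 0.01, 0.004), unground (0.08, 0.05, 0.05, 0.04) —
  magnitudes chosen once so that default pipelines land in the expected
  qualitative regime (ground calibrations accepted, unground mostly
  rejected); they are conventions, tunable in `ScatterParams`, not fitted
  quantities. I.i.d. channel noise (SD 0.0005 AU) is added last.
* **Paired prep states.** `paired_prep_states` shares the chemistry, clean
  spectra, underlying distortion draws and channel noise between the two
  outputs; only the scatter magnitudes differ. Equal magnitudes give
  byte-identical datasets, so the preparation contrast is exactly isolated.

What passing simulation tests show — and what they do not: the pipeline
recovers known linear spectral encodings under realistic scatter, and
degrades under unground-level scatter, reproducing the qualitative
ground-versus-unground finding. Real hay adds effects the generator omits:
nonlinear moisture–band interactions, instrument-specific noise spectra,
batch and origin structure, and reference-method error in the wet
chemistry; quantitative statistics on real spectra will differ.

## Problem sizes and numerical choices

Simulation studies use n = 200 samples per dataset, the representative
treatment 1,4,4, 10-fold CV, and 5–10 seeds; these sizes make the contrast
stable while keeping runs fast. NIPALS stops a factor when the weight norm
falls below 1e−10 of the centred-matrix norm. Fold layouts with a
zero-variance training response are reshuffled once, then rejected.
Degenerate inputs (constant spectra under SNV, zero-variance responses,
singular score covariances) raise typed errors rather than propagating
NaNs. Determinism: every stochastic step (chemistry draws, scatter, fold
shuffles) flows from explicit seeds, and identical configurations produce
byte-identical CSV/JSON outputs.

## Known limitations

* Gap-segment derivatives only; Savitzky–Golay, MSC, and wavelet filtering
  are out of scope, as are PLS2, SIMPLS and variable selection.
* No external validation-set (SEP) workflow or calibration transfer
  between instruments.
* The spectral reader handles wide CSV only; proprietary instrument
  formats and spectral resampling between grids are not implemented.
* The published timothy IVDMD RPD values are not reproducible from the
  corresponding SD and SECV under the SD/SECV definition that fits every
  other analyte; the worked-example checks therefore omit those two cells.
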