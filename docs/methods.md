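# Methods

`tracheidnir` re-creates, on synthetic data, a complete Vis-NIR calibration
study for wood tracheid length: spectral de-noising by a lifting wavelet
transform (LWT) with a global fixed threshold, a per-wavelength hybrid-
spectrum construction (local correlation maximization, LCM), four classical
smoothers as comparators, and partial least squares (PLS) calibration with
the standard chemometrics diagnostics. This note records the models, the
defaults and the design choices.

## Wavelet transform and de-noising

The decimated wavelet transform uses **periodic (circular) boundary
handling** throughout. The spectrometer grid has 2048 = 2^11 channels, so
periodization is exact, every coefficient band stays dyadic, and the
transform is perfectly invertible. Odd lengths occurring mid-cascade (only
possible for non-dyadic inputs) are edge-padded to even and the pad is
undone on reconstruction.

Two computational paths produce identical coefficients to machine
precision:

* **Lifting path** (db1, db2): split into even/odd polyphase components,
  then predict/update/scale steps. The db2 factorization was derived from
  the polyphase matrix of the analysis bank under our periodized
  convention; because the determinant of that matrix is `-z`, the final
  scaling stage carries a one-sample advance on the detail channel.
* **Filter-bank path** (all families): circular convolution + decimation
  with the analysis pair, transpose-style synthesis operators for
  reconstruction. With analysis offset `L/2` and synthesis offset
  `L/2 - 1` (L = filter length) this reproduces the periodized transform
  of PyWavelets coefficient-for-coefficient, which the test suite uses as
  an independent oracle.

Daubechies filters db1–db8 are constructed by spectral factorization of the
half-band Daubechies polynomial (minimum-phase root selection), not from
tables; sym5 and bior5.5/rbio5.5 use the standard published coefficient
tables with the quadrature-mirror relations generating the high-pass
filters. Detail bands are stored finest-first.

**Threshold rule.** De-noising uses the universal ("fixed form") threshold
`lambda = sigma_hat * sqrt(2 ln n)` with `sigma_hat = median(|d1|)/0.6745`
estimated from the finest detail band, one shared lambda for all detail
levels, and hard thresholding by default (`|w| <= lambda -> 0`; ties map to
zero). Soft thresholding is available. The approximation band is never
thresholded. Per-spectrum sigma estimates are used when de-noising a
matrix of spectra.

## Local correlation maximization

"Spectra under different decomposition levels" are the full-length
de-noised reconstructions at levels 1..k (k = 4 by default), not raw
coefficient vectors — the only reading that yields per-wavelength
absorbances of common length. For each wavelength the level with the
largest **absolute** Pearson correlation against the calibration targets
is selected (a strongly negative correlation is equally informative for a
linear model); a signed criterion is available behind a flag. Ties resolve
to the smallest, least-processed level. The selection map is fitted on
calibration samples only and applied unchanged to held-out samples, so no
held-out target is ever read before scoring. Zero-variance columns get
r = 0 with a warning.

## Smoothers

* moving average: centered mean, window shrinking at the edges;
* Savitzky-Golay: local polynomial of order 2 (the common chemometrics
  default, and the largest order valid at the smallest window), edge
  points evaluated from the boundary polynomial fit;
* loess/lowess: tricube-weighted local regression over the
  `segment_size` nearest grid points, local quadratic (loess) versus
  local linear (lowess), zero robustness iterations.

For the local-regression smoothers the tricube distances are scaled by
(half-window + 1) rather than by the distance of the farthest window point.
With the conventional scaling the farthest points receive exactly zero
weight, which makes the local quadratic fit singular at the minimum window
of 3; the +1 scaling keeps every window point strictly positive-weighted
and the fit well-posed everywhere. (This differs slightly from, e.g., the
statsmodels lowess weighting; the test suite therefore validates the
smoothers against a naive per-point weighted-polyfit oracle instead.)
Segment sizes sweep over odd values 3, 5, ..., 25 to keep windows centered.

## PLS and diagnostics

PLS1 by NIPALS: mean-centering only (absorbance columns share units),
weight vector `w = X'y` normalized, scores `t = Xw`, loading deflation per
component, prediction through the accumulated regression vector
`b = W (P'W)^{-1} q`. Components whose weight norm collapses below 1e-12
truncate the model with a warning. The default component count is 7.

Diagnostics for a scored set: `R2 = 1 - SSE/SST`; `RMSE = sqrt(SSE/n)`
(divisor n); `MAPE` in percent; `SEC` = standard deviation of the
bias-corrected residuals with divisor n-1; `RPD = SD/SEC` where SD is the
reference standard deviation **of the set being scored** (calibration SD
for RPDc, prediction SD for RPDp). Equivalent statistics on the validation
set are reported as Rp2/RMSEP/SEP/RPDp.

Model ranking in all sweeps is lexicographic: highest Rc2, then lowest
RMSEC, then lowest MAPEc.

## Synthetic cohort generator

The generator emulates a ring-resolved sampling campaign on seven larch
trees (per-tree ring counts uniform in 39–43): every annual ring is
sampled up to ring 20 and every second ring beyond. That rule yields ~215
candidate rings; since not every ring produces a usable measurement, the
candidates are subsampled uniformly to 164 samples, split at random into
117 calibration and 47 prediction samples (`calibration =
round(0.713 * n)`).

**Tracheid length** follows a Gompertz curve from a pith value of 2.05 mm
toward a per-tree asymptote (mean 4.04 mm, between-tree sd 0.15 mm) with
rate 0.16/ring and inflection at ring 8.5, plus 0.13 mm observation noise.
These values were solved numerically so the default cohort reproduces the
reference moments of the emulated study design (grand mean ~3.32 mm, sd
~0.67 mm, mild negative skewness) and a ring-length Pearson correlation
near 0.89. The noise-free curve is strictly increasing and levels off
beyond roughly ring 23.

**Spectra** live on the 350–2397 nm, 1 nm grid (2048 channels, log(1/R)):
a smooth baseline, five Gaussian absorption bands (1415, 1965, 2315, 1210,
980 nm; widths 30–55 nm), of which the 1415 and 2315 nm bands respond
affinely — with opposite signs — to the trait. Nuisance terms per sample:
a multiplicative scatter factor (sd 1%), a random quadratic baseline drift
(amplitude 0.008 AU), structured instrument noise, and 0.0008 AU white
channel noise.

Two generator choices deserve emphasis because they depart from the
simplest textbook setup, in both cases because PLS1 in the p >> n regime
makes the simple setup degenerate:

1. **Latent chemical trait.** Band amplitudes respond to
   `chem = target + N(0, 0.30 mm)`, not to the target itself. If the
   spectra encoded the target exactly, PLS would recover it with Rc2 ~ 1
   and every pretreatment comparison would be vacuous. The 0.30 mm
   coupling noise caps the achievable calibration accuracy at the level
   typical of wood NIR studies (Rc2 ~ 0.83). With all noise switched off
   the deterministic core is affine in the target and PLS recovers it to
   R2 >= 0.999 (a tested property).
2. **Structured instrument noise.** The dominant spectral noise is a
   random combination of 24 smooth artifact shapes (8 nm scale) shared by
   all spectra of a cohort, with per-channel sd 0.005 AU, plus the small
   white component above. Independent wide-band noise of any amplitude
   cannot be the default: with 2048 channels and 117 calibration samples,
   the deflated data matrix becomes effectively white and a single NIPALS
   component `t = NN'r` is proportional to the current residual, so PLS
   interpolates the calibration targets exactly (Rc2 = 1.000 even at
   sigma = 1e-3). Rank-limited noise shared across samples is both the
   realistic description of scan-averaged spectrometer artifacts and the
   mechanism that keeps calibration statistics honest. The small white
   component is what gives wavelet de-noising and the smoother sweep
   measurable effects, as published wood NIR calibrations show.

What the generator does **not** emulate: radiative transfer or real wood
chemistry, earlywood/latewood optics, instrument response functions, or
inter-band covariance structure of real lignocellulose spectra. Passing
tests therefore demonstrate correctness of the algorithms and the
qualitative reproduction of the study's trends, not predictive validity on
real spectra.

## Problem sizes and determinism

Default problem sizes: cohorts of 164 x 2048; sweeps over 4 wavelets,
8 Daubechies orders, 5 levels and 4 x 12 smoother configurations; 20-seed
replications for stochastic properties and 100 trials for the de-noising
efficacy check. The full analysis sequence runs in well under a minute on
one CPU. Every random quantity flows from one `numpy` Generator seeded in
`CohortConfig`; a fixed seed makes cohorts bit-identical, and all pipeline
stages are deterministic functions of their inputs.

## Known limitations

* Lifting factorizations are implemented for db1 and db2 (the wavelets the
  de-noising study selects); the other families run on the equivalent
  filter-bank path behind the same interface.
* The universal threshold with MAD sigma assumes the finest detail band is
  noise-dominated; on essentially noise-free smooth spectra the estimate
  collapses and de-noising is a near-identity (by design).
* `bior5.5` has a zero leading analysis tap pair (standard table); energy
  is not preserved for the biorthogonal families, and their reconstruction
  tolerance is 1e-6 rather than 1e-8.
* MAPE is undefined for zero reference values and the generator guarantees
  positive tracheid lengths; RPD is reported as infinity when SEC = 0.
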