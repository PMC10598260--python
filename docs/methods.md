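# Methods

This note documents the statistical model behind `pollenscale`, the
conventions and tolerances the implementation fixes where practice varies,
and what the synthetic-data generator does and does not emulate.

## Compositional reduction

A record's counts matrix (n samples × p taxa) is divided by row totals to
give proportions (rows sum to 1 by construction) and square-root
transformed before ordination. The Hellinger transform damps the dominance
of abundant taxa and weakens the unit-sum interdependence of proportions;
all downstream fluctuation amplitudes are therefore unitless
sqrt-proportion composites. PCA is performed on the column-centred
covariance matrix (no standardization), via SVD; eigenvalues use the n−1
divisor. Eigenvectors are oriented so that the largest-|loading| entry is
positive — a deterministic, record-local convention; the Haar analysis is
sign-invariant, so this only affects reporting. Degenerate inputs
(constant assemblages, fewer than 3 samples, fewer than 2 varying taxa)
raise typed errors rather than returning NaNs.

## Haar structure function

For a window [t0, t0 + τ) the first-order Haar fluctuation is
|mean(second half) − mean(first half)|; S(τ) averages this over windows.
Conventions fixed here (each exposed as a parameter):

- windows start at the first sample and advance by τ/2 (50% overlap);
  overlap increases the number of windows at large τ where data are
  scarce, inflating only the correlation between windows, not the mean;
- half-windows are half-open, [t0, t0 + τ/2) and [t0 + τ/2, t0 + τ);
- a window is accepted when each half holds ≥ 1 sample (stricter
  occupancy discards too much near the record resolution); half-window
  means are unweighted;
- scales with no accepted window are omitted; no Gaussian calibration
  constant is applied, so comparisons are internally consistent.

Per-record scale grids are log-spaced at 10 points per decade from twice
the median sample spacing to the record span. For aggregation, structure
functions are re-binned (nearest log-scale bin, window-count-weighted
within a bin) to a shared anchored grid, 10^(k/10) yr from 10 yr to 20 ka.
Aggregate confidence half-widths are the central-68% inter-quantile
half-range of the per-record estimates divided by sqrt(min(n, n_max));
n_max = 100 by default, capping the effective number of degrees of freedom
to acknowledge spatial correlation between records.

## Scaling summaries

Under power-law scaling S(τ) ∝ τ^H the exponent is estimated by a
gamma-family GLM with log link, E[S] = exp(c + H log τ), with per-scale
window counts as variance weights. The log link makes the multiplicative
power law linear, so a noiseless power law is recovered exactly (to IRLS
convergence, < 1e-6); the gamma family matches the roughly constant
relative dispersion of fluctuation estimates. Scales with zero fluctuation
are dropped from the fit (all-zero bands raise a degenerate-input error).
Defaults follow the study design: S_C over τ ∈ [50, 200] yr, S_M over
[500, 2000] yr, H_CM over [200, 3000] yr; the fit band is a parameter.
Band means are unweighted and flagged missing (NaN) when no scale falls
inside — records whose resolution is coarser than ~100 yr never acquire an
S_C, by design.

H converts to the spectral exponent by β = 1 + 2H (exact for Gaussian
processes). The independent spectral route (`spectral_oracle`) fits the
negative least-squares slope of log power vs log frequency: FFT
periodogram on regular grids; Lomb–Scargle on irregular ones, fitted from
1/span up to half the pseudo-Nyquist frequency because spectral leakage
near the pseudo-Nyquist flattens steep spectra. Under strong irregularity
Lomb–Scargle slopes remain mildly biased toward zero for steep spectra;
the oracle is a cross-check, not the primary estimator.

The 23-ka sinusoidal detrend (approximate orbital-precession period) is a
linear least-squares fit of a·cos(2πt/P) + b·sin(2πt/P) + c per record —
amplitude and phase free, no nonlinear optimizer. Removing it lowers the
fitted exponent at multi-millennial scales on slow-trend inputs; with few
samples the free phase/amplitude can over-detrend, which is why it is off
by default and a config switch in the pipeline.

### Calibration protocol

Ensemble calibrations generate regular unit-spacing Gaussian series
(n = 512) by spectral synthesis and fit H per series over τ ∈ [8, 64]
sampling intervals: the lower edge keeps ~4 samples per half-window, where
the discretization bias of the white-noise expectation is below 0.001 in
the exponent; the upper edge (n/8) keeps ≥ 15 windows per series. With 200
series the ensemble mean recovers H = −0.5 (white noise) and H = 0 (1/f)
to within ±0.03 across seeds, and periodogram slopes recover β to ±0.01.

## Biome axes and classification

Typical assemblages average the sqrt assemblages of labelled recent
samples (ages in [−60, 500] BP). Within a record, recent proportions are
averaged **before** square-rooting by default; the alternative order
(sqrt, then average) is a documented switch, as the two differ slightly
for heterogeneous recent samples. With group weights (e.g. 50/50 boreal
evergreen vs deciduous), class means are combined with the stated weights
regardless of group sizes, preventing an over-represented sub-type from
dominating.

Projection onto a difference axis is the **uncentred** dot product of a
sample's sqrt-proportion row with the axis values on the taxon union
(zero fill): the sign of the score at zero carries the biome identity, so
PCA-style centring would destroy the decision rule. ū = 0 falls to the
j side (logged). Quantile groups are rank-based equal-count bins with
stable tie-breaking; the upper-q filter takes floor(q·n) sites by rank;
the regional split at 60°E follows the record longitude.

## Spatial statistics

Moran's I uses row-standardized inverse great-circle-distance weights
(self-weight 0, distances floored at 1 m to guard against duplicate
coordinates; a binary-radius alternative is available). Expected value
under randomness is −1/(n−1); significance is reported both from the
classical normality-approximation variance and from a seeded permutation
null (999 permutations by default). Weighted Pearson correlations use
weighted means, variances and covariance, with the per-site weight equal
to the fraction of the fit band covered in log τ; p-values come from
seeded permutations of y with weights kept attached to the x positions,
since the weights describe per-site data quality. Grid cells are anchored
at 0° with half-open [edge, edge + 4°) membership.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions end to end:

- **Latent driver.** Fourier filtering of white noise: amplitudes scaled
  by f^(−β/2) with β = 1 + 2H, DC removed, standardized to unit variance.
  The expected periodogram is exactly f^(−β); H = −0.5 reproduces white
  noise. Supported range H ∈ [−0.5, 1].
- **Sediment-slice integration.** The driver is synthesized on a grid at
  1/4 of the record's mean resolution, spanning twice the record coverage
  (avoiding wrap-around of the periodic synthesis), and each sample
  receives the mean over a slice of width equal to the mean resolution.
  Real samples integrate deposition over the sampled slice, so observed
  series carry essentially no variance from far below the sampling
  resolution; omitting this integration inflates small-τ fluctuations and
  biases recovered exponents downward by ~0.2.
- **Record-mean centring.** The driver is centred over the record's
  samples before being applied: fluctuations are anomalies around the
  site's characteristic composition, so its record-mean state equals its
  mixture coordinate. Haar fluctuations are invariant to the shift, so
  scaling recovery is unaffected.
- **Composition and counts.** The base composition interpolates two biome
  profiles linearly in sqrt-proportion (Hellinger) space — the analysis
  space of the pipeline — so the sign boundary of the difference-axis
  score sits exactly at mixture 0.5 for any profile pair. The driver
  perturbs the base in logit space along the profile-difference direction
  (softmax link keeps proportions in the simplex at any amplitude);
  counts are multinomial with 300 grains per sample, a typical pollen sum.
  Default driver amplitude 1.0 in logit units makes the induced
  sqrt-proportion signal ≈ 3× the multinomial noise.
- **Sampling geometry.** Gamma-distributed spacings, rescaled to the exact
  target mean; the shape parameter is inverted from the target
  largest-gap/mean ratio (default 2, matching ≈ 500-yr largest gaps at
  260-yr mean resolution) within the shape range where the quantile-based
  inversion is monotone (shape ≥ 0.3). Records start at 2100 BP with
  ≈ 4700-yr coverage, inside the 8–2 ka BP analysis window. In the bundled
  two-biome world, per-record mean resolutions are lognormal (mean 260 yr,
  log-sd 0.6, clipped to [60, 600] yr), so — as in compiled fossil
  datasets — only a minority of records resolve the centennial band.
- **Two-biome world.** Mixtures are drawn uniformly over
  [0.05, 0.45] ∪ [0.55, 0.95]: landscapes perched exactly at the
  forest/open-land tipping point are ecologically unstable (vegetation and
  fire feedbacks push them to one side), so sites carry a definite biome
  identity with at least a 10% compositional margin. Without the gap,
  mixtures within ~0.02 of 0.5 flip sign under multinomial noise alone.
- **Surface samples.** 1–5 samples per record, ages in [−60, 500] BP,
  constant per-class composition, class labels attached.

Not emulated: age-model (chronology) uncertainty; taxonomic-harmonization
error; pollen-productivity and dispersal biases; spatially correlated
drivers between nearby sites (each record's driver is independent, so
Moran's I on the synthetic world is only significant when a spatial signal
is constructed explicitly); human disturbance. Passing tests therefore
demonstrate the estimators' behaviour under irregular sampling,
compositional closure and multinomial noise — not robustness to dating
error or proxy biases.

One emergent property worth knowing: with a fixed logit-space driver
amplitude, more even (open-land-like) compositions move farther in
sqrt-proportion space than strongly dominated (forest-like) ones, so
synthetic open sites are intrinsically somewhat more variable on S_M even
when all sites share identical driver dynamics. Directional experiments
that mimic differential biome dynamics should therefore set amplitudes
explicitly per site (as the pipeline tests do) rather than rely on this
geometric effect.

## Numerical conventions and degenerate inputs

- Ages are calendar years BP (present = 1950 CE), positive into the past.
- Closed analysis windows: [2000, 8000] BP for fossil means, [−60, 500] BP
  for recent samples. The six-sample minimum is applied to in-window
  samples, since variability is computed only there.
- Proportion rows sum to 1 within 1e-9 (validated); noiseless power-law
  fits recover exponents to 1e-6; sinusoid residual tolerance 1e-9.
- Ties: best-correlated taxon and quantile grouping break ties by stable
  input order; ū = 0 classifies to the negative (j) side.
- Typed exceptions (`FormatError`, `DegenerateInputError`,
  `InsufficientDataError`, `EmptySelectionError`) separate malformed
  inputs from genuinely information-free ones; batch summaries flag
  missing band means as NaN instead of failing a whole run.

## Problem sizes

Default test and calibration sizes — 200-series ensembles of length 512,
50-record synthetic worlds, 999–9999 permutations — run the full suite in
well under a minute on one CPU while keeping ensemble standard errors
(≈ 0.007 on calibration means) far below the tolerances they are checked
against.

## Known limitations

- The Haar exponent of very sparse records (≈ 1 sample per half-window
  across much of the fit band) mixes point-difference and half-mean
  fluctuation regimes; per-record estimates carry sd ≈ 0.3–0.4 and only
  ensemble or quantile-group means are interpretable.
- The gamma GLM standard error does not account for correlation between
  overlapping windows; it is a within-fit dispersion, not a full
  sampling error.
- Lomb–Scargle slope estimates flatten for steep spectra under strong
  irregularity even with the pseudo-Nyquist guard.
- Moran's I normality p-values assume fixed weights and Gaussian-ish
  values; the permutation p is the primary figure.
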