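# Methods

## The variance slope

For a leg of `n = 500` consecutive minute samples, the scale-dependent
variance at window size `w` partitions the leg into `floor(n/w)`
consecutive non-overlapping blocks of `w` slots (trailing remainder
discarded), computes the variance within each block, and averages over
blocks. Eleven window sizes are log-uniformly spaced from 3 to 500 samples
and rounded to integers (3, 5, 8, 14, 23, 39, 65, 108, 180, 300, 500). The
variance slope Γ is the ordinary least-squares slope of `log10 V` on
`log10 w` over the scales with positive, non-missing `V`; fewer than two
usable scales yields an invalid (flagged, not raised) result.

Key numerical choices:

* **Block variance uses the unbiased (ddof = 1) estimator by default.**
  With the population (1/n) convention, `E[V(w)] = σ²(1 − 1/w)` for white
  noise, which tilts the white-noise ensemble-mean Γ to ≈ +0.06; with
  ddof = 1 the white-noise null is exact in expectation (measured ensemble
  mean |Γ| < 0.001 at 500 legs). The population convention remains
  available (`variance_ddof=0`); it is also what makes the unit-ramp
  closed form `V(w) = (w² − 1)/12` exact, which the test suite uses as a
  machine-precision oracle.
* **Gap handling.** Missing samples occupy slots; a block contributes to
  `V(w)` only if at least 80% of its slots are valid (one consistent
  constant with the leg-level 80% coverage rule), and its variance is taken
  over the valid samples only. Measured on power-law legs (β = 5/3), the
  median |ΔΓ| is below 0.03 at 15–20% missing data.
* **No detrending** inside blocks; the statistic is the raw variance.
* The fit is unweighted in log10 space. Window length converts to spatial
  scale via the leg's median along-track step when kilometres are wanted;
  the slope itself is unit-free.

Γ is exactly invariant under affine maps `x → a·x + b` (every block
variance scales by `a²`, shifting the log-log line vertically only). For a
lognormal field, Γ of the raw and of the log-transformed values agree only
approximately; at a chlorophyll-like coefficient of variation of 0.4 the
ensemble-mean |difference| is ≈ 0.04 at β = 5/3, growing with CV.

## The Fourier cross-check and the −5/3 anchor

For gapless legs a conventional estimator is provided: the periodogram of
the mean-removed series, fit by OLS of `log10 P` on `log10 f` over the
frequency band matched to the window scheme (periods of 3–500 samples).
The linear map between per-leg Γ and per-leg periodogram slope, fitted
across an ensemble spanning PSD exponents β ∈ [1, 3], evaluates at −5/3 to
Γ ≈ 0.79–0.85 (seed-dependent, 400 legs).

The ensemble for this calibration cuts legs out of longer (2000-sample)
synthesized transects rather than synthesizing each leg at n = 500.
Spectral synthesis produces circularly periodic series; a full synthesis
period has a leakage-free periodogram, which is not how a ship leg samples
the ocean. Windowed legs behave like real legs: their periodogram slopes
carry leakage noise, which attenuates the fitted Γ-vs-slope regression and
moves its value at −5/3 up from the asymptotic Γ = −s − 1 (≈ 0.67) to
≈ 0.8. On directly synthesized (periodic) legs the two estimators correlate
at |r| ≈ 0.99; on windowed legs |r| ≈ 0.75–0.83.

## Synthetic data: what it emulates, what it does not

**Power-law fields.** rFFT amplitudes ∝ `k^(−β/2)`, independent uniform
phases, inverse transform, standardized; the DC amplitude is zeroed so the
mean is decoupled from the spectral shape. This gives the exact target
spectrum in expectation at O(n log n). Marginals: Gaussian (affine map to
`mean_level`, `amplitude`) or lognormal, constructed as
`exp(μ + σ·z)` with μ, σ solved so the mean and standard deviation hit
`mean_level` and `amplitude` exactly — guaranteeing positivity for
concentration-like variables. Additive white noise is injected as a stated
fraction of signal variance before the marginal transform. Gaps are either
independent single samples or geometric blocks (mean 10 samples,
instrument-dropout-like), always totalling `round(gap_fraction · n)`
samples exactly.

**Default study conditions.** Legs are 500 samples at a median along-track
step of 0.21 km; gap fractions up to 0.2; chlorophyll-like variables use a
lognormal marginal with CV = 0.4 (≈ 0.17 standard deviations of log10
chlorophyll within a 100-km leg, mid-range of open-ocean variability);
physical variables are Gaussian. Spectral exponents between 1 and 3 cover
the observed range from very patchy to very smooth.

**Cross-variable correlation** is imposed per Fourier frequency by mixing
the unit phasors of the two Gaussian precursors, never their amplitude
envelopes. This matters: mixing in the time domain would blend the two
spectra and leak one variable's spectral exponent — hence its Γ — into the
other, destroying the very independence the generator must be able to
prescribe. Phasor mixing keeps each variable's amplitude spectrum exact
while correlating their values; because correlation is attenuated by the
cosine overlap of the two amplitude envelopes, the mixing coefficient is
compensated by that (exactly computable) factor, capped at full mixing, so
the realized correlation approaches the target. A lognormal marginal
attenuates it slightly further; ensemble-mean realized r for a 0.6 target
is ≈ 0.54 with one lognormal partner.

**Ship track.** Lognormal step lengths with prescribed median and
coefficient of variation; heading random-walks with turn size shrinking as
`heading_persistence → 1`; positions advance on a local flat-earth
approximation (fine for sub-km steps); haversine distances use Earth radius
6371.0 km throughout.

**Raw optics stream.** Per-minute truth profiles of chlorophyll, γ and the
dissolved level generate 4 Hz spectra: dissolved baseline
`a_g(λ) = cdom · exp(−0.017(λ − 440))`; particulate absorption is a
chlorophyll-specific shape with Gaussian bands at 440 nm (0.05 m² mg⁻¹,
σ = 60 nm) and 676 nm (0.014 m² mg⁻¹, σ = 10 nm); particulate attenuation
`c_p(λ) = c_p(443)·(λ/443)^(−γ)`. Filtered-seawater periods (10 min every
60 min) see only the dissolved baseline. Noise is i.i.d. Gaussian per 4 Hz
sample (default 0.001 m⁻¹); bubble-like positive spikes (0.1–1 m⁻¹, one to
ten times a typical particulate signal) replace a configurable fraction of
samples.

Not emulated: physically coupled advection–reaction dynamics, 2D structure,
tides and diurnal cycles, instrument drift beyond the smooth dissolved
baseline, temperature–salinity absorption corrections, scattering
corrections. Passing tests therefore demonstrate the estimators' behaviour
under known scaling laws and realistic sampling artifacts — not that any
particular ocean process produces those scaling laws.

## Processing chain

* **Minute binning** trims each minute's 4 Hz samples to the
  [2.5th, 97.5th] percentile interval (linear-interpolation quantiles;
  boundary values retained) and reports the mean, standard deviation and
  retained count; an empty minute yields a missing value. With ≤ 1% spike
  rates the trim removes essentially all spikes; binomial fluctuations let
  rare spikes survive in isolated minute × wavelength cells.
* **Dissolved baseline.** Each filtered period is summarized by its median
  spectrum (robust to residual spikes) at its midpoint time. Baselines at
  total-seawater minutes are interpolated linearly in time, or scaled by
  the normalized fCDOM signal between bracketing period medians
  (`fcdom_scaled`), falling back to the time fraction when fCDOM is flat
  between brackets — so constant fCDOM reproduces the linear method
  exactly. Minutes outside the first/last filtered period take the nearest
  period's baseline; recovery guarantees apply to bracketed minutes.
  Particulate = total − baseline, exactly, at every minute and wavelength.
* **Segmentation** reindexes the stream onto a continuous 1-minute grid
  (absent minutes become missing slots) and cuts consecutive 500-slot legs,
  discarding the trailing remainder. Along-track distance sums haversine
  steps between valid consecutive positions. Because slots are minutes, a
  segmented leg always spans 499 minutes of wall clock; the elapsed-time QC
  rule exists for leg tables built from externally prepared (non-reindexed)
  records.
* **Leg QC** keeps a leg iff along-track distance ∈ [30, 150] km, the
  variable's coverage ≥ 0.80, and elapsed time ≤ 16 h, and reports
  machine-readable rejection reasons. "Distance traveled" is cumulative
  path length, not net displacement — a sailing vessel can tack 40 km while
  displacing 20.

## Optical proxies

* **Chlorophyll line height**: particulate absorption at 676 nm above the
  linear baseline through 650 and 715 nm (band values linearly interpolated
  on the wavelength grid). Exactly invariant to adding any affine function
  of wavelength, which is why it shrugs off residual dissolved baseline.
  The baseline wavelengths are conventions (configurable); only the 676 nm
  peak is intrinsic.
* **Particle-size proxy γ**: negated OLS slope of `ln c_p` vs `ln λ` over
  450–700 nm with the 660–690 nm chlorophyll-peak region excluded (the
  power-law model assumes a non-absorbing spectral shape); non-positive
  values (possible after baseline subtraction) are excluded from the
  log-space fit, and fewer than 5 usable wavelengths yields a missing
  value. Larger γ means smaller mean particle size.
* **c_p(443)**: linear interpolation at 443 nm, a particle-load proxy.

## Comparative statistics

Correlations between per-leg Γ values of two variables are Pearson on the
untransformed slopes (Spearman available), pairwise-complete over legs,
with two-sided p-values from the t reference distribution. Province
aggregation takes unweighted means of Γ and of absolute values per
(province, variable), keeping provinces with at least 25 contributing legs,
and joins optional per-province covariate tables (e.g. climatological
nutrients). The spatial correlogram bins all leg-centroid pairs by
haversine distance (10 logarithmic bins by default) and reports the
symmetrized Pearson correlation of paired Γ values per bin, flagging bins
with fewer than 10 pairs. Scale-restricted Γ refits the identical pipeline
on the window sizes at or below a chosen top scale (e.g. ≤ 25 samples
≈ 5 km), probing whether small-scale and full-range patchiness agree.

The design contrast the suite exercises end-to-end: two variables whose
*values* are strongly correlated (shared phasors) but whose spectral
exponents are drawn independently show a strong absolute-value correlation
and a Γ–Γ correlation indistinguishable from a permutation null —
patchiness is a property of spatial organization, not of magnitude.

## Problem sizes and determinism

Default test and calibration ensembles use 100–500 legs of 500 samples and
optics streams of 180–360 minutes; all stochastic tests run from fixed
seeds, and identical configs with identical seeds produce bit-identical
synthetic output. The acceptance script derives independent child seeds
from its `--seed` argument via `numpy.random.SeedSequence`.

## Known limitations

* The statistic is computed in time (minute bins), not distance; the QC
  distance band keeps the time-to-space conversion roughly uniform, but
  legs with strongly varying ship speed mix scales.
* The Γ↔Fourier-slope map is ensemble-specific: its coefficients depend on
  the β range and on legs being windows of longer records.
* No uncertainty is attached to individual Γ values (no bootstrap); fit
  R² and the scale count are reported instead.
* The correlogram is a binned Moran-style estimator; it is not an
  inferential variogram model.
* Province labels and covariates are consumed as prepared tables; no
  geospatial polygon work is done here.
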