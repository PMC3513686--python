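# Methods

This note documents the models, estimators, and numerical choices behind
fractkit, in the order an analysis flows: signal model and synthesis,
monofractal estimation, multifractal estimation and the formalism, the
automated strategy, performance evaluation, and voxel-wise mapping.

## Signal model: the fGn/fBm dichotomy

A scale-free series is modelled as a realization of one of two Gaussian
processes. Fractional Gaussian noise (fGn) is stationary with
autocovariance

    γ(k) = σ²/2 (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}),   H ∈ (0, 1);

fractional Brownian motion (fBm) is its cumulative sum: non-stationary,
self-affine with stationary increments. Every estimate is reported on the
**extended Hurst scale** H′ ∈ (0, 2): H′ = H for fGn and H′ = H + 1 for
fBm, so one number carries both the correlation strength and the class,
with the 1/f boundary at H′ = 1. The conversion algebra is affine in H′:
α = H′, β = 2H′ − 1 (equivalently β = 2H − 1 for fGn, 2H + 1 for fBm),
γ = 2 − 2H (fGn only), H = 2 − D. The literature also contains the
alternative relation β = (H∓1)/2, which is inconsistent with the
white-noise (H = 0.5 ⇔ β = 0) and Brownian (H = 0.5 ⇔ β = 2) anchors;
fractkit uses the anchored form throughout.

## Synthesis

**fGn (circulant embedding).** The target autocovariance γ(0..n) is
embedded in a circulant of order 2n whose eigenvalues are obtained with
one FFT; a Hermitian complex-Gaussian vector coloured by √λ and
transformed back yields n samples whose covariance is *exactly* γ, at
O(n log n). The eigenvalues are provably non-negative for fGn but are
checked anyway (tolerance −1e−8·λ_max, clipping below). H′ > 1 is
synthesized as the cumulative sum of fGn with H = H′ − 1. Randomness
comes from `numpy.random.default_rng`; composite seeds
(base, stream, index) make every realization individually reproducible.

**Cascades.** Deterministic multiplicative cascades (base b, weights pᵢ
summing to 1, depth d) produce b^d increments of a multifractal measure
with the closed-form multiscaling exponent τ(q) = −log_b Σᵢ pᵢ^q and
Hölder exponents h(q) = τ′(q) = −Σ pᵢ^q ln pᵢ / (Σ pᵢ^q ln b). These
closed forms are the package's independent oracle for every moment-based
estimator. The increments are what the estimators analyze; the cumulative
sum (the Devil's staircase) is available for wavelet analysis and display.

**Surrogates.** Shuffling permutes the samples, destroying serial
correlation while preserving the value distribution exactly.

**Phantoms.** 4D volumes with an integer region map; each voxel gets
amplitude × (exact fGn or summed fGn per the region's H′) plus iid
Gaussian noise of stated SD. Per-voxel seeds are (seed, flat index), and
noise uses a separate stream, so the phantom is reproducible voxel by
voxel. Defaults (n = 256 time points, dt = 1 s, noise SD 0) give a clean
recovery target; examples use noise SD 0.1 as a realistic instrument-noise
level relative to unit signal amplitude.

## Monofractal estimators

All estimators reduce a (scale, measure) set to a slope by ordinary least
squares on log10–log10 axes, one equally weighted point per scale. Scale
grids are log-spaced; window partitions are half-open `[start, start+n)`
forward passes with the tail remainder discarded. Default monofractal
window grids run from 4 (or detrend order + 2) to N/4.

- **DFA** — profile = cumulative sum of the demeaned signal; per-window
  polynomial detrending (default linear); F(n) is the RMS residual and
  α the slope. The fluctuation is deliberately the *root*-mean-square —
  the variance convention would double the exponent and break the
  α = H (fGn) / α = H + 1 (fBm) identities and the white-noise anchor
  α ≈ 0.5. α estimates H′ directly.
- **SWV / bdSWV** — mean within-window SD of the raw signal (optionally
  line- or bridge-detrended per window); slope = H of the fBm input. Only
  valid on fBm-class input.
- **SSC** — cumulative sum followed by bdSWV; the slope on the cumulant is
  H′ of the original signal, making SSC the class-independent reference
  method and the classifier: H′ ≤ 1 ⇒ fGn, H′ > 1 ⇒ fBm, with a
  "boundary" flag inside [0.9, 1.1] where classification is unreliable.
- **Low-frequency PSD** — preprocessing in the order mean subtraction,
  parabolic (Welch) taper, endmatching. The taper zeroes both ends, so
  endmatching is a near no-op in this order; endmatching *before* the
  taper would subtract a random line whose 1/f² spectrum biases β upward
  on weakly correlated signals (measured bias ≈ +0.8 on white noise at
  n = 256), which is why the order matters. β = −slope of the
  periodogram over the fit band, by default from the lowest frequency up
  to Nyquist/8 — discarding the high-frequency estimates that carry most
  of the bias for scale-free spectra. H′ = (β + 1)/2 in both classes.
- **Disp** — SD of the means of non-overlapping bins; H = 1 + slope;
  fGn only. Default bins 1..N/16 so every size keeps ≥ 16 bins.
- **AWC** — continuous wavelet transform (PyWavelets, Mexican hat =
  Gaussian second derivative); mean |W(a, b)| over b scales as a^{1/2+H}.
  The discretized wavelet extends ≈ 4 scale units each side, so a cone of
  influence of 4a is excluded at both edges (capped to keep a usable
  body) and scales run from 2 to N/16; with a 1a margin and scales up to
  N/4 the edge contamination inflates the slope by ~0.1 at n = 4096.
- **Raw FA** — RMS increment of the profile at lag τ, no detrending;
  kept for comparison with legacy analyses, trends bias it.

Degenerate inputs (constant series, exact lines under bridge detrending)
raise `DegenerateSignalError`; the detection threshold is relative
(1e−10 × signal SD) so rounding noise is not mistaken for structure.

## Multifractal estimators and the formalism

**Moment machinery.** Per-window RMS fluctuations F_v are pooled as
F_q = (mean F_v^q)^{1/q}, with q = 0 as the log-average limit
exp(mean ln F_v). The average is evaluated in log space so |q| = 15
neither overflows nor underflows. Zero-fluctuation windows are excluded
with a warning (they would blow up negative moments). DFA and MF-DFA
share this exact code path, so MF-DFA at q = 2 equals DFA to the last bit.

**MF-DFA** builds the profile with global mean subtraction; **MF-DMA**
cumulates without demeaning and removes a moving average of each window
size positioned by θ ∈ [0, 1] (0 backward — the default, the
best-performing variant in the MF-DMA literature — 0.5 centred, 1
forward), with the residual index range restricted to the positions where
the average is defined before splitting into ⌊N/n − 1⌋ windows. The
moving mean divides by the actual number of samples in the (floored)
window rather than nominally by n; the difference is at most one sample.
MF-DMA is valid only in the stationary range: on fBm input its H(2)
saturates near 1, which the package treats as a documented property to
test, not to correct.

Default multifractal scale grids run from 16 to N/8 (about 20 log-spaced
sizes): the coarsest scale keeps at least 8 windows in every moment
average (fewer makes the extreme moments q = ±15 fit noise), and scales
below 16 carry the small-window detrending bias. For cascade analyses the
natural choice is windows aligned with the construction scales (powers of
the base, starting at b³); misaligned or smaller windows leave a residual
|τ−τ_oracle| of up to ~0.2 at |q| = 5, aligned windows reduce it to
≤ 0.02 at depth 8.

**Formalism.** τ(q) = qH(q) − 1 (topological dimension 1 for series), so
τ(0) = −1 exactly; D(q) = τ(q)/(q − 1) with the q = 1 value interpolated.
The singularity spectrum comes from the numeric Legendre transform:
h = τ′(q) by centred finite differences, D(h) = qh − τ(q). Because the
transform requires concavity, points where h fails to decrease with q are
flagged and excluded from descriptors; a severely non-concave τ triggers
a warning. A consequence of τ(0) = −1 is that spectra derived from
MF-DFA/MF-DMA peak at exactly D = 1 at q = 0 — a structural property of
this formalism, not a measurement. (The identification τ = qH(q) − 1 is
known to be exact only in special cases; fractkit reports it as the
standard convention and leaves the caveat here.)

**Descriptors.** h_max and D_max locate the peak; W⁻/W⁺ are the widths
left/right of h_max at half maximum, located by linear interpolation
along each branch; FWHM = W⁻ + W⁺, P_c = h_max/(D_max·FWHM), W = W⁺/W⁻.
When a branch never descends to half maximum the affected descriptors are
None with a warning — this is correct behaviour, not failure: e.g. the
(0.2, 0.6, 0.2) cascade's right branch asymptotes to D = log₃2 ≈ 0.63,
above half maximum. Δh = h(−15) − h(+15) is always computed from a
dedicated wide grid q ∈ [−15, 15] by one-sided differences at the ends,
even when the reporting grid is ±5.

**WTMM.** The CWT uses the Gaussian-second-derivative wavelet evaluated
in closed form in the frequency domain ((aω)² e^{−(aω)²/2}), L1-normalized
so |W| ~ s^h along a singularity; a sampled-wavelet convolution ripples
at coarse scales and the ripples masquerade as modulus maxima. The signal
is bridge-detrended (harmless — the wavelet has two vanishing moments)
and zero-padded to twice its length to suppress circular wrap-around.
Local maxima use the asymmetric rule (≥ left, > right, so plateaus count
once); the cone of influence is excluded per scale. Chains are linked
fine→coarse to the nearest maximum within |Δt| ≤ the coarser scale;
maxima not connected down to the finest scale never enter the partition
function. Z(s, q) sums moduli at scale s along surviving chains (the
canonical supremum-along-line variant is available via `supremum=True`
and is more stable at negative q); τ(q) is the log-log slope of Z over
scales 4..N/8. Negative-moment bias is expected and documented: on the
cascade staircase the default settings keep |τ−τ_oracle| ≤ ~0.1 for
q ∈ [−2, 5], degrading below q = −2.

## Analytical strategy

`analyze_pipeline` runs: optional preprocessing → SSC classification →
monofractal fit over a selected scaling range → surrogate multifractality
test → (optionally) the full MF-DFA spectrum with descriptors, all
retained in a JSON-serializable report with stage-tagged errors.

Scaling-range selection drops the smallest and largest scale (both known
bias sources), then scores every contiguous window of ≥ 4 points by R²
and keeps the best, ties broken toward the wider range.

The multifractality verdict requires **both** Δh > 0.2 (the width below
which apparent multifractality is indistinguishable from estimation
noise on monofractals of practical lengths) **and** Δh above the 95th
percentile of Δh over ≥ 10 shuffled surrogates. The quantile rule is a
design choice: the comparison needed a concrete statistic and an upper
quantile controls the false-positive rate against the surrogate
distribution. A caveat found during validation and worth stating plainly:
for heavy-tailed deterministic cascades the *shuffled* series retain most
of the spectrum width (their multifractality is largely distributional,
not correlation-driven), so the surrogate condition may fail on a genuine
cascade — the verdict then correctly reports that a correlation origin
could not be confirmed. Series shorter than 2¹⁰ return "indeterminate":
the ±15 moments are not meaningful there.

## Performance evaluation

Grids mirror the standard protocol: lengths {2⁸, 2¹⁰, 2¹², 2¹⁴}, true H′
from 0.1 to 1.9 in steps of 0.1 skipping the boundary value 1.0, 20
realizations per cell, seeds (base, i_H, i_len, rep). Estimates are
stored on the H′ scale; estimator failures are missing values, never
fatal. Metrics per cell: precision index (fraction within H′ ± 0.1 by
default; the tolerance is a flag), bias, *population* variance — so
MSE = bias² + variance holds as an exact identity — and MSE. The
vignette renders signed mean error on a diverging map centred at zero
(warm = over-, cool = underestimation) with the 1/f boundary drawn in a
midscale grey; the 2×2 tiling of the raster is display-only and off by
default, since the scientific content is the single raster.

## Voxel-wise mapping

`map_parameters` applies the single-series estimators voxel by voxel —
map values are identical to running the estimator on the extracted
series, with no spatial processing. The spectral fit band defaults to
0.02–0.3 Hz when the sampling interval makes it realizable (at least 4
spectral estimates inside the band and the upper edge below Nyquist),
else to the estimator's low-frequency default. Bad voxels are nulled and
counted, never fatal; class maps code {1 fGn, 2 fBm, 0 boundary, −1
null}. Volumes read/write NIfTI-1 (dt from the time zoom or a JSON
sidecar) or a CSV matrix of voxel rows with a sidecar giving grid shape
and dt. Mapping requires ≥ 2⁷ time points. Scanner-side filtering can
distort the low-frequency band this pipeline fits; that is a data-quality
concern the software cannot detect, only document.

## What the synthetic data do and do not show

The generators produce *exact* Gaussian scale-free signals and *exact*
deterministic cascades. Passing tests therefore demonstrate estimator
correctness under the model, including the documented failure modes
(MF-DMA saturation, PSD's downward bias in the anticorrelated range,
negative-moment bias). They do not demonstrate robustness to
non-Gaussian amplitude distributions, nonstationary trends of
physiological origin, scanner filtering, or motion — real BOLD data
contain all of these. The phantom adds only white instrument noise and
region structure, deliberately the simplest departure from the pure
model.

## Problem sizes

Test and acceptance runs use the lengths the estimators are meant for:
2¹⁴ samples where spectrum widths and recovery are quantified, 2¹²–2¹³
for anchor checks, depth-8 cascades (6561 points) for oracle agreement,
and small multi-voxel phantoms (≤ 6×6 grid, 512 time points) for the
mapping pipeline. These sizes keep the full suite in the low minutes on
one CPU while staying inside each method's validated operating range.
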