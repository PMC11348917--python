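# Methods

This note documents the models, statistics and numerical choices behind
`geniculate`, and what the synthetic-data generators do and do not
emulate.

## Presynaptic specialization statistics

A rabies tracing from one postsynaptic dLGN neuron yields a cluster of
presynaptic retinal ganglion cells (RGCs), each carrying a morphological
type label and an eye of origin. Specialization asks whether the cluster
draws on fewer types than random sampling would produce.

**Null model.** Draw `n` cells i.i.d. from a reference type distribution
`p` and count distinct labels `K`. The Monte-Carlo estimate uses
multinomial draws (distributionally identical to counting distinct labels
among i.i.d. draws, and vectorizable), with 10⁵ replicates by default; a
seed is mandatory in the API. The closed-form moments

    E[K]   = Σ_t (1 − q_t),                      q_t = (1 − p_t)^n
    Var[K] = Σ_t q_t(1 − q_t) + Σ_{t≠u} [(1 − p_t − p_u)^n − q_t q_u]

serve as an independent oracle in the tests (themselves validated on tiny
cases by exhaustive enumeration).

**Z score.** `z = (observed distinct types − E[K]) / SD[K]`, with the
classified-cell count as `n`. A cluster is flagged specialized when
`z < −2`; under the uniform-40-type, `n = 50` null this places the
smallest non-specialized count at 25 distinct types.

**Reference distribution.** The weighted mixture
`p ∝ p_TCN·W_TCN·N_TCN + p_IN·W_IN·N_IN` with defaults `W_TCN = 0.8`,
`W_IN = 0.2`, `N_TCN = 20`, `N_IN = 96` (mean presynaptic cells per
thalamocortical neuron / interneuron; weights reflect TCN prevalence).

**Pooling experiments.** `pooling_experiment` models a cell specialized
toward a subset of equally frequent types, optionally after a k-to-1
pooling of type labels. The observed count is, by default, the number of
distinct pooled labels covering the *full* subset — the convention that a
large cluster realizes its entire specialized repertoire; this reproduces
all four worked Z scores (−1.4, −4.5, −5.0, +1.4). An alternative
`observed_convention="sampled"` (mean distinct count among `n` draws
restricted to the subset) is exposed but not default.

**Binocular randomness.** Per postsynaptic cell, the contralateral count
is modeled Binomial(total, `p_contra = 0.87`). The test statistic is the
summed absolute contra−ipsi difference; the p-value is the add-one
Monte-Carlo tail probability `(1 + #{sim ≥ obs})/(1 + n_reps)`. All
Monte-Carlo p-values in the package use this convention so that p = 0 is
impossible.

## ChAT-band flattening and RGC typing

The two ChAT bands are depth landmarks of the inner plexiform layer. The
default band detector is classical: light xy Gaussian smoothing followed
by a Gaussian matched filter along z (band width ≈ 1.5 planes), min-max
normalized to a probability stack. Any callable with the same contract —
3D stack in, probability stack out — can be substituted (e.g. a trained
network). Surface extraction takes the two strongest z-peaks per column,
fills isolated ambiguous columns from neighbors (failing if more than 20%
of columns are ambiguous), median-smooths over xy, and refuses to return
crossing surfaces.

Flattening maps each column linearly so the OFF band sits at relative
depth 0 and the ON band at 1, extrapolating linearly beyond, and resamples
at increments of 0.025 over [−0.625, 1.875] — the range that exactly
tiles ten strata of width 0.25 with strata 3 and 7 centered on the bands.

A cell's stratification profile is the per-stratum fraction of its masked,
non-negative signal. Derived quantities and their defaults (the original
criteria were qualitative, so these are declared thresholds, configurable
in the API):

- *dominant stratum set*: strata holding ≥ 10% of the signal;
- *cofasciculation with band k*: ≥ 25% of the signal within ±0.125 of the
  band center, and ≥ 50% of that in-band signal on columns with ChAT
  intensity above 25% of the band's maximum. (25% rather than 50% for the
  in-band fraction because a bistratified type-37 cell splits its arbor
  roughly evenly between both bands.)
- *asymmetry index*: |soma − dendritic center of mass| divided by the
  95th-percentile arbor radius; JAM-B-like when > 0.3;
- *minor branch*: stratum-3 fraction < 15% still qualifies a cell as
  type 7.

Type calls apply rules in fixed order (37, 7, 12_asym, 12, 189, 89, 4,
other); kinetics are transient for dominant strata within 3–7 and
sustained for 1, 2, 8–10 (majority fraction when mixed); polarity is ON
for strata 6–10 only, OFF for 1–4 only, ON-OFF otherwise.

## Grating tuning analysis

The protocol locks speed, temporal frequency and duration together:
40° spatial period (1200 μm at 30 μm/°), 4 cycles, so 400/1200/2400 μm/s
give 12/4/2 s at 0.33/1/2 Hz; 8 directions at 45°; gray interstimulus
interval (4 s default). Presentation order is pseudo-random per trial by
default (deterministic under `order_seed`).

Preprocessing: bidirectional line-phase correction estimated from the
time-average image (applied only when it clearly beats zero shift, so
structureless images are left alone), per-frame rigid registration to the
median image by correlation peak, and a centered 500-ms moving average.

ROIs seed at local maxima of the local-correlation image (mean Pearson
correlation with the 8 neighbors) above a floor of 0.3 and grow
8-connected while the correlation exceeds
`max(0.5 · seed value, background + 0.1)`, where the background level is
taken at the 5 darkest pixels within 15 μm. These three constants are
declared defaults; only the dependence structure is prescribed. The
background trace (same 5 pixels) is subtracted from each ROI trace.

Responses: per stimulus, the per-trial baseline (median of 1.75–0.25 s
pre-onset) is subtracted, the pointwise median across trials is smoothed
with the same 500-ms filter, and P = max(·, 0), N = max(−min(·), 0),
plus the stimulus-period mean. F0 is the smallest of the 24 average
baselines (display only; indices never depend on it — if it is ≤ 0 an
additive offset is applied for ΔF/F₀ display). SNR is the largest
amplitude divided by the SD of the pooled trial-median baseline segments.

Selectivity uses circular variance on the 8-direction amplitude vectors:

    DSI = |Σ_i A_i e^{iθ_i}| / Σ_i A_i      OSI = |Σ_i A_i e^{i2θ_i}| / Σ_i A_i

for A = P and A = N separately; preferred direction (orientation) is the
phase (half-phase) of the population vector, then rotated by the 20°
eye-axis correction (screen→retina by subtracting 20°; the sign is
configurable since only the magnitude is anatomically fixed). Indices are
forced to 0 when the corresponding SNR ≤ 2.5. Resultants below 1e-12 are
snapped to exactly 0 (floating-point residue of symmetric responses).

Significance permutes whole trials across direction labels within a speed
(1000 permutations default, seeded) and recomputes the index through the
identical median-filter-amplitude path; `p = (1 + #{perm ≥ obs})/(1 + n)`.
Speed-independent indices take the speed evoking the maximum positive
(respectively negative) response, ties toward the slowest speed (longest
stimulus, most data). A cell is suppressed-by-contrast when strictly more
than half of the 24 stimulus-period means fall below baseline. The unique
category applies the hierarchy DS > OS > DS_neg > OS_neg > SbC > broad
with DS requiring DSI > 0.3 and p < 0.05 (analogously for the others),
broad requiring DSI < 0.15 and OSI < 0.15, and `none` otherwise.

## Sparse-noise receptive fields

Per grid position, trials are aligned at flash onset, linearly
interpolated to 33 Hz, averaged, and smoothed with a 150-ms running mean.
ON amplitude is the signed extremum (max or min, larger magnitude)
during the flash against the 200–75 ms pre-onset baseline; OFF the
analogous extremum between flashes against the pre-offset baseline;
±75 ms around on/offset are excluded. The map statistic is the maximum
Pearson correlation of the (signed) map with its 8 one-pixel shifts,
computed on the overlapping sub-grid with both copies mean-centered. The
shuffle control permutes position labels within trials (10⁴ default) and
re-runs the identical averaging/amplitude pipeline, so observed and null
statistics share one code path.

Significant maps are smoothed by a 3×3 running average (shrink-at-border
normalization); the receptive field is the 8-connected above-half-max
region containing the maximum, its area the pixel count × 64 deg², its
position the intensity-weighted centroid. Note the 3×3 filter spreads a
single-pixel response over its 9-pixel support before the half-max cut,
so a delta has area 9 × 64 deg². Cells significant in both polarities use
the sum of both filtered maps. Retinotopic maps are Gaussian-weighted
means (σ = 75 μm, 300 × 300 μm truncation mask) of per-cell azimuth or
elevation over tissue coordinates; zero-weight coordinates are NaN.

## Dendrite-versus-soma correspondence

Compartments passing SNR > 2.5 are compared with their soma through the
16-dimensional response vector (8 P + 8 N at the cell's maximum-response
speed; the soma's best-DSI or best-OSI speed for selectivity-vs-distance
analyses). Distances are Euclidean between ROI centers — a lower bound on
dendritic path length. Summaries use 50-μm bins; decay of selectivity
with distance is fit by least squares to `y = Δ·exp(−x/λ) + y₀` with λ
bounded positive and 8 geometric multi-starts over the distance span;
flat data (|Δ| under 5% of the y-range) are flagged unidentifiable in λ.

## Synthetic data: what it emulates, and what it does not

All generators draw from a single seeded generator per call and are
bit-reproducible. Defaults follow the study conditions where stated
(p_contra = 0.87; 8°-square sparse noise, 0.6 s flash/gap, 116° × 86°
screen, 4–7 trials; 8 × 3 grating stimuli with 4-cycle durations); free
parameters were set once to values typical of two-photon recordings and
documented in the configs (noise SD 0.03–0.05 of a unit response,
indicator decay 1.5 s, 4–5 trials, 48-pixel fields of view).

- **Clusters** are exact i.i.d. draws from the configured distribution;
  they carry no spatial structure or classification error.
- **Retina phantoms** render two smooth, sinusoidally undulating band
  surfaces and dendrite polylines that track the true surfaces at their
  target strata (a 90° sector for asymmetric JAM-B-like arbors). No
  point-spread function, no tissue deformation other than the band
  undulation, no overlapping arbors.
- **Grating sessions** use von Mises tuning in direction (doubled angle
  for OS), boxcar stimulus drive convolved with a single-exponential
  indicator kernel, disk somata with thin dendrite polylines whose
  responses are the soma's scaled by an attenuation in (0, 1] (noise is
  not attenuated). Suppression kinds (SbC, DS_neg, OS_neg) add a tonic
  baseline with stimulus-locked dips. No eye movements, running, or
  adaptation.
- **Sparse-noise sessions** model the response transient as a raised
  cosine confined to its analysis window (fast-indicator idealization);
  the slow tail of real indicators, which bleeds ON responses into the
  OFF window, is deliberately absent — so passing recovery tests shows
  the mapping machinery is correct, not that slow-indicator crosstalk is
  handled.

Consequently, green end-to-end tests demonstrate correct recovery under
the generative model's assumptions; they do not certify performance under
real-data nuisances (scan artifacts beyond rigid jitter, neuropil
contamination beyond the 5-pixel background model, indicator
nonlinearity).

## Problem sizes and numerical choices

Monte-Carlo nulls use 10⁵ replicates (acceptance script and library
default; tests use 5 × 10⁴ where a looser tolerance permits). Calibration
suites use 200–500 simulated sessions with 200 permutations/shuffles
each, and the imaging end-to-end suites run one 48-pixel session at 4 Hz
per scenario — sizes chosen so the whole suite completes in about a
minute while keeping Monte-Carlo error well inside the asserted
tolerances. Degenerate inputs fail loudly: zero-SD nulls, empty clusters
and masks, crossing band surfaces, single-frame movies and missing grid
positions all raise with a description rather than returning defaults.
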