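# Methods

This note documents the models, estimators, numerical choices and known
limitations of `unitlfp`.

## Pre-processing

LFP is analysed band-pass filtered between 15 and 300 Hz.  The filter is
applied multiplicatively in the Fourier domain over the whole recording:
response 1 inside the pass-band, 0 deep in the stop-band, with Gaussian
roll-offs `exp(−(f − f_corner)²/(2w²))` at the corners to avoid ringing.
The roll-off width `w` (default 10 Hz) is the Gaussian **standard
deviation**.  The DC bin is forced to exactly zero: a band-pass filter must
reject a constant offset, and the covariance estimator below assumes a
mean-free signal.  Note that with `w = 10` Hz and a 15 Hz low corner the
roll-off at very low frequencies (1–5 Hz) is shallow (gain ≈ 0.3–0.4); only
DC is fully rejected.  Decimation to the 1250 Hz analysis rate uses a
zero-phase FIR anti-aliasing filter with cutoff at 0.4 × the target rate and
requires an integer rate ratio.

Artifact periods (`excluded_intervals`) are honoured by dropping spikes whose
peri-spike window touches them, not by zeroing the LFP — zeroing would inject
broadband spectral artifacts.

## Spike-triggered averaging

Spike times are mapped to the nearest LFP sample (round-half-even; at
1250 Hz a bin is 0.8 ms and sub-sample interpolation is out of scope).  The
default window is ±100 ms around each spike, covering the [−10, 15] ms
trough-analysis window with a wide margin.  The electrode that recorded the
trigger unit is removed from the map (spike-waveform artifact); its row is
absent rather than zero-filled.  No baseline subtraction is applied — the
15 Hz high-pass already removes offsets — so results are bit-reproducible.
Neighbour-average infill of missing grid sites exists for visualisation only
and is never used in analysis.

Two uncertainty bands are available: ±1.96 s.e.m. over the spike-segment
ensemble, and a distribution-free 95 % band from surrogate spike trains with
iid Gaussian time jitter (defaults: 1000 repetitions, 100 ms SD), taken as
pointwise 2.5th–97.5th percentiles across repetitions.  Percentiles rather
than Gaussian fits keep the band distribution-free.  Jitter of 100 ms
destroys locking at the tens-of-milliseconds scale while preserving slower
co-modulation, so exceedances mark genuinely spike-locked structure.  Each
random stage uses one named generator whose seed is derived from the
caller's master seed.

## Whitening

The ongoing-LFP spatial covariance is the plain second moment
`C_ij = ⟨LFP_i LFP_j⟩_t` over the full band-passed recording (the band-pass
removes the mean; "ongoing" is read as the raw filtered signal including
spike times — an `exclude_spike_windows` variant was considered and left
out as the spike-locked contribution to C is O(rate · kernel energy), which
is negligible at desk scales).  The whitening matrix is the ZCA
(symmetric) inverse square root `W = E D Eᵀ`, `D_ii = λ_i^{−1/2}`.
Eigenvalues below `reg_floor_rel · λ_max` (default 1e−8) are **zeroed**, not
floored, so a rank-deficient covariance yields a proper pseudo-inverse
square root; the number of zeroed modes is recorded on the filter.

The trigger electrode is removed *before* whitening: for each unit the
covariance submatrix over exactly the channels present in its st-LFP is
re-eigendecomposed (cheap at ≤96×96).  The alternative — one global W —
differs only in how the missing row is treated and is not implemented in the
core path.  A discrete-Laplacian spatial filter is provided as a comparison
baseline (`laplacian_matrix`); data-driven whitening filters resemble it
with extra off-centre structure.

## Distance profiles and fits

Electrodes are grouped by Manhattan distance (grid steps × 0.4 mm pitch,
default up to 3.2 mm = 8 steps), assuming isotropy of the st-LFP;
shell-averaged traces are computed first and troughs (global minimum in
[−10, 15] ms, ties to the earliest lag) are extracted from the averages —
the same order used for population averages, which pool neurons with more
than 1000 spikes.

Spatial decay is fitted by nonlinear least squares of `A exp(−x/λ) + C` to
the **absolute** trough depth (so A, C stay positive for either polarity),
initialised at `A = y(x_min) − y(x_max)`, `λ = 0.5 mm`, `C = y(x_max)`, with
non-negativity bounds.  Parameter SDs come from the fit covariance.  A fit
is flagged unreliable when λ exceeds 10 mm, the covariance is singular, or
the fitted exponential contributes nothing at the nearest measured distance
(constant data: λ is unidentified).  Fits are unweighted by default.

Propagation is ordinary least squares of trough latency on distance;
`speed = 1/slope` (ms/mm inverts to mm/ms ≡ m/s).  A non-positive slope
leaves the speed flagged undefined — latency decreasing with distance is not
a propagating wave.

Group comparisons: trough statistics are compared with a neuron-resampling
bootstrap (the compared quantities are across-neuron means, so neurons, not
spikes, are the exchangeable unit), two-sided
`p = 2·min(P(d*≤0), P(d*≥0))` with a +1 correction, default 1000 resamples.
Space constants are compared with a Wald z-statistic
`(λ_A − λ_B)/√(sd_A² + sd_B²)` on the fitted coefficients; an alternative
using across-neuron λ distributions would need per-neuron fits, which are
noisier at realistic spike counts.

## Waveform classification

Mean waveforms are reduced to four features: peak-to-valley amplitude,
positive and negative half-widths (full width at half the phase extremum,
with parabolic sub-sample refinement of the extrema and linear
interpolation of the half crossings), and the positive-to-negative
interval.  Features are z-scored and clustered with K-means (k = 2, 10
seeded restarts).  The cluster with the smaller mean negative half-width is
labelled FS (the thin-spike convention for putative inhibitory
interneurons).  Units closer than `quality_threshold` (default 0.5 z-units)
to the midpoint hyperplane between the centroids are left unclassified; the
threshold is a configuration knob, as no principled universal value exists.
Externally supplied labels (e.g. from cross-correlogram analysis) always
override the clustering.

## The synthetic forward model

The generator emulates a 10×10 Utah-array recording at 1250 Hz (0.4 mm
pitch, four dead corner channels) as a **linear superposition**:

* **Unitary kernels.**  A spike of the unit on channel `s` adds, on every
  channel at Manhattan distance `x ≤ r_max`, the trace
  `polarity · amp0 · exp(−(x − pitch)/λ_u) · h(t − d_syn − x/v)`, where `h`
  is a unit-peak biexponential `e^{−t/τ_d} − e^{−t/τ_r}`.  Defaults:
  negative polarity (both FS and RS sources produce negative-going unitary
  fields, with the RS contribution understood as di-synaptic through
  interneurons and therefore delayed), `amp0 = 10` (arbitrary µV-like
  units) at the nearest shell, `λ_u = 0.3 mm`, `r_max = 0.8 mm` (unitary
  fields reach well under 1 mm), `τ_r = 0.8 ms`, `τ_d = 4 ms` (IPSC-like),
  `d_syn = 0.5 ms` for FS and 1.5 ms for RS, axonal speed `v = 0.2 m/s`
  (unmyelinated-fibre range).  The source channel itself gets no kernel
  (the spike artifact is not modelled, matching the trigger-electrode
  exclusion).
* **Background.**  A Gaussian field with spatial covariance
  `σ² exp(−d²/2ℓ²)` (σ = 30, ℓ = 1.0 mm) and AR(1) temporal correlation
  (coefficient 0.95 at 1250 Hz, i.e. dominant low-frequency power), plus an
  independent per-electrode white sensor-noise floor (σ_w = 1) which also
  keeps the covariance numerically full rank.
* **Common drive.**  Each unit's Poisson rate is
  `r · exp(−g z_i(t) − g²/2)` where `z_i` is the background field at the
  unit's own electrode, smoothed over 20 ms and standardised, with
  `g = 0.5`: units fire preferentially when their local field is negative
  (depolarised, active states).  Nearby units share drive through the
  field's spatial correlation, so the spike-locked background component
  `E[B | spike]` is broad (decaying on ℓ), non-causal (symmetric around the
  spike on the drive timescale) and non-local — exactly the structure that
  dominates raw st-LFPs and that whitening removes.
* **Volume conduction.**  A final instantaneous row-normalised Gaussian
  spatial mixing of width 0.2 mm; the broad spatial correlations come
  mainly from the background field, and a wider mixing would smear the
  confined kernel itself beyond its cutoff.

Spike trains are Bernoulli-per-sample (at most one spike per 0.8 ms bin);
everything derives from one master seed through a fixed spawn order, so
sessions are bit-reproducible.  Two presets are exported:
`default_scenario` (kernel cutoff 0.8 mm, 6 units, 12 Hz, 150 s — the
validation conditions for spatial confinement and whitening recovery) and
`propagation_scenario` (cutoff 2.4 mm, λ_u = 1.0 mm, three same-type units
with ground-truth labels — a kernel confined to two shells cannot support a
three-point latency regression, so speed recovery needs the wider kernel).

**What the generator does not emulate:** realistic 1/f spectra beyond AR(1),
layer- or direction-specific (anisotropic) spread, spike waveform artifacts
on neighbouring channels, non-Poisson firing statistics (bursts,
refractoriness beyond the one-per-bin limit), epileptiform events, and
electrode drift.  Passing tests therefore show that the estimator chain
recovers the parameters of this linear model, not that real cortical
recordings satisfy its assumptions.

## Problem sizes

The shipped validation runs use 100–150 s sessions with 6–9 units at ~12 Hz
(≥1000 spikes per unit, the population-inclusion threshold), 1000 jitter
repetitions for surrogate bands, 200/100 Monte-Carlo replicates for the
decay/propagation fit calibrations and 10-seed suites for the end-to-end
checks — sizes at which every headline property is stable while a full run
remains a desk-scale computation.

## Known limitations

* Latencies are quantised to the 0.8 ms sample bin; sub-millisecond latency
  differences (e.g. the FS/RS di-synaptic delay of 1 ms) are resolved only
  to one bin.
* The whitened s.e.m. is propagated through |W| in quadrature, ignoring
  cross-channel error correlations; the surrogate band is dropped on
  whitening and must be recomputed on whitened data if needed.
* Long recordings are filtered in one FFT window; memory grows linearly
  with duration (a 12-hour session at 96 × 1250 Hz is ~40 GB and would need
  windowed filtering, which is not implemented).
* `population_average` intersects the distance grids of its inputs; units
  near the array edge, whose far shells are missing, restrict the common
  range.
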